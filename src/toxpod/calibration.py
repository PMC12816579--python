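"""Three-part uncertainty-calibration suite for interval-producing models.

* **Confidence-based**: does the level-p interval actually contain the
  observed value a fraction p of the time, over a grid of levels (default
  1-99%)? Summarized by the expected calibration error (ECE), the mean
  absolute gap between nominal and observed coverage.
* **Error-based**: after sorting chemicals by predictive SD into ~sqrt(n)
  batches, does the root mean uncertainty (RMU) of each batch track its
  RMSE? Summarized by the expected normalized calibration error (ENCE).
* **Distance-based**: does predictive SD track chemical unfamiliarity,
  measured as the mean Jaccard (Tanimoto) distance to the five nearest
  training-set Morgan fingerprints — an applicability-domain diagnostic.

These diagnose interval quality; nothing here rescales or recalibrates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr

DEFAULT_LEVELS = tuple(np.arange(1, 100) / 100.0)  # 1% .. 99%


@dataclass
class CalibrationCurve:
    """Ordered curve points plus summary statistic and correlations.

    kind "confidence": points are (expected level, observed fraction),
    summary is ECE. kind "error": points are (RMU_b, RMSE_b), summary ENCE.
    kind "distance": points are (RMU_b, mean Jaccard_b), summary None.
    """

    kind: str
    points: np.ndarray  # (B, 2)
    summary: Optional[float]
    pearson: Optional[float] = None
    spearman: Optional[float] = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "points": np.asarray(self.points).tolist(),
            "summary": self.summary,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "degenerate": self.degenerate,
        }


@dataclass
class UncertaintyBatches:
    """Equal-size (±1) batches of items sorted by predictive SD ascending."""

    n: int
    B: int
    assignment: np.ndarray  # item index -> batch index
    order: np.ndarray  # item indices sorted by sigma ascending (stable)
    sizes: np.ndarray

    def batch_indices(self, b: int) -> np.ndarray:
        return self.order[np.isin(self.assignment[self.order], b)]


def default_n_batches(n: int) -> int:
    """Entropy-based batch count: round(sqrt(n)), half-up for determinism."""
    return int(math.floor(math.sqrt(n) + 0.5))


def batch_by_uncertainty(
    sigma: Sequence[float], B: Optional[int] = None
) -> UncertaintyBatches:
    """Sort by sigma (stable; ties keep input order) and split into B batches.

    Sizes are floor(n/B), with the remainder given one extra item each to the
    highest-uncertainty batches.
    """
    s = np.asarray(sigma, dtype=float)
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 items to batch")
    if B is None:
        B = default_n_batches(n)
    if B > n:
        raise ValueError(f"B={B} exceeds n={n}")
    order = np.argsort(s, kind="stable")
    base = n // B
    rem = n - base * B
    sizes = np.full(B, base)
    if rem:
        sizes[-rem:] += 1  # extras go to the highest-uncertainty batches
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    assignment = np.empty(n, dtype=int)
    for b in range(B):
        assignment[order[bounds[b] : bounds[b + 1]]] = b
    return UncertaintyBatches(n, B, assignment, order, sizes)


def _correlations(x: np.ndarray, y: np.ndarray):
    if np.std(x) == 0 or np.std(y) == 0 or len(x) < 2:
        return None, None, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pr = float(pearsonr(x, y)[0])
        sr = float(spearmanr(x, y)[0])
    return pr, sr, False


def confidence_calibration(
    y: Sequence[float],
    interval_fn: Callable[[float], tuple],
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> CalibrationCurve:
    """Observed coverage vs nominal level, and the ECE.

    ``interval_fn(level)`` must return (lower, upper) arrays aligned with
    ``y``. observed(p) = fraction of y inside the level-p interval;
    ECE = mean over levels of |p - observed(p)|.
    """
    ya = np.asarray(y, dtype=float)
    if ya.size == 0:
        raise ValueError("y must be non-empty")
    pts = []
    for p in levels:
        lo, hi = interval_fn(float(p))
        lo, hi = np.asarray(lo, float), np.asarray(hi, float)
        observed = float(np.mean((ya >= lo) & (ya <= hi)))
        pts.append((float(p), observed))
    pts = np.asarray(pts)
    ece = float(np.mean(np.abs(pts[:, 0] - pts[:, 1])))
    pr, sr, degen = _correlations(pts[:, 0], pts[:, 1])
    return CalibrationCurve("confidence", pts, ece, pr, sr, degen)


def ece_from_interval_sets(y, intervals_by_level: dict) -> CalibrationCurve:
    """Confidence calibration from precomputed {level: list of IntervalPrediction}."""
    def fn(p):
        preds = intervals_by_level[p]
        return (np.array([q.lower for q in preds]), np.array([q.upper for q in preds]))

    return confidence_calibration(y, fn, levels=sorted(intervals_by_level))


def ence(
    y: Sequence[float],
    y_hat: Sequence[float],
    sigma: Sequence[float],
    B: Optional[int] = None,
) -> tuple[float, CalibrationCurve]:
    """Expected normalized calibration error and its (RMU, RMSE) curve.

    Per batch b of increasing predictive SD: RMU_b = sqrt(mean sigma^2),
    RMSE_b = sqrt(mean (y - y_hat)^2); ENCE = mean_b |RMU_b - RMSE_b| / RMU_b.
    """
    ya, ma, sa = (np.asarray(v, dtype=float) for v in (y, y_hat, sigma))
    if not (ya.size == ma.size == sa.size):
        raise ValueError("y, y_hat and sigma must have equal lengths")
    if np.any(sa < 0):
        raise ValueError("sigma must be nonnegative")
    batches = batch_by_uncertainty(sa, B)
    err2 = (ya - ma) ** 2
    pts = np.empty((batches.B, 2))
    bounds = np.concatenate([[0], np.cumsum(batches.sizes)])
    for b in range(batches.B):
        idx = batches.order[bounds[b] : bounds[b + 1]]
        rmu = math.sqrt(float(np.mean(sa[idx] ** 2)))
        rmse = math.sqrt(float(np.mean(err2[idx])))
        if rmu == 0.0:
            raise ValueError(f"RMU is zero in batch {b}; ENCE normalization undefined")
        pts[b] = (rmu, rmse)
    val = float(np.mean(np.abs(pts[:, 0] - pts[:, 1]) / pts[:, 0]))
    pr, sr, degen = _correlations(pts[:, 0], pts[:, 1])
    return val, CalibrationCurve("error", pts, val, pr, sr, degen)


def ence_sensitivity(
    y, y_hat, sigma, B_range: Sequence[int] = tuple(range(5, 201))
) -> np.ndarray:
    """ENCE as a function of the number of batches; rows (B, ENCE).

    ENCE is known to be sensitive to the batch count, so the default sweeps
    B = 5..200.
    """
    n = len(np.asarray(sigma))
    if max(B_range) > n:
        raise ValueError("max(B_range) exceeds the number of items")
    return np.array([(b, ence(y, y_hat, sigma, B=b)[0]) for b in B_range])


def jaccard_distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between binary fingerprint matrices.

    d(u, v) = 1 - |u & v| / |u | v|; a pair with empty union has distance 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape[1] != b.shape[1]:
        raise ValueError("fingerprints must have equal width")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on all-zero rows
        d = cdist(a, b, metric="jaccard")
    return np.nan_to_num(d, nan=0.0)


def knn_jaccard(
    query_fp: np.ndarray, train_fps: np.ndarray, k: int = 5
) -> np.ndarray:
    """Mean Jaccard distance of each query to its k nearest training fingerprints.

    Accepts a single fingerprint or a matrix of them; returns per-query means
    in [0, 1]. This is the applicability-domain distance: ~0 means close
    structural precedent in the training set, ~1 means unfamiliar.
    """
    q = np.atleast_2d(np.asarray(query_fp))
    t = np.atleast_2d(np.asarray(train_fps))
    if k > t.shape[0]:
        raise ValueError(f"k={k} exceeds the number of training fingerprints")
    d = jaccard_distance_matrix(q, t)
    part = np.partition(d, k - 1, axis=1)[:, :k]
    out = part.mean(axis=1)
    return out if np.asarray(query_fp).ndim > 1 else float(out[0])


def distance_calibration(
    sigma: Sequence[float],
    distances: Sequence[float],
    B: Optional[int] = None,
) -> CalibrationCurve:
    """(RMU, mean kNN Jaccard distance) per batch of increasing predictive SD."""
    sa = np.asarray(sigma, dtype=float)
    da = np.asarray(distances, dtype=float)
    if sa.size != da.size:
        raise ValueError("sigma and distances must have equal lengths")
    batches = batch_by_uncertainty(sa, B)
    bounds = np.concatenate([[0], np.cumsum(batches.sizes)])
    pts = np.empty((batches.B, 2))
    for b in range(batches.B):
        idx = batches.order[bounds[b] : bounds[b + 1]]
        pts[b] = (math.sqrt(float(np.mean(sa[idx] ** 2))), float(np.mean(da[idx])))
    pr, sr, degen = _correlations(pts[:, 0], pts[:, 1])
    return CalibrationCurve("distance", pts, None, pr, sr, degen)


@dataclass
class CalibrationReport:
    """Bundle of the three calibration curves plus batching metadata."""

    confidence: Optional[CalibrationCurve] = None
    error: Optional[CalibrationCurve] = None
    distance: Optional[CalibrationCurve] = None
    n: Optional[int] = None
    B: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def ece(self) -> Optional[float]:
        return self.confidence.summary if self.confidence else None

    @property
    def ence(self) -> Optional[float]:
        return self.error.summary if self.error else None

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "B": self.B,
            "ece": self.ece,
            "ence": self.ence,
            "meta": self.meta,
            "curves": {
                k: getattr(self, k).to_dict()
                for k in ("confidence", "error", "distance")
                if getattr(self, k) is not None
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
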