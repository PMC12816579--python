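"""Library-scale screening: predictions, chemical-space maps, class ranking.

A fitted interval model is applied to a chemical library; internal
log10(mol/kg-d) predictions are back-converted to mg/kg-d for presentation.
Chemicals are grouped by their lowest available ClassyFire taxonomy level
(subclass, else class, else superclass) and classes are ranked by median
predicted POD — most potent first — with a "high potency fraction": the
share of class members inside the library-wide top 1% most potent medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from toxpod.data_io import ChemicalRecord, invert_pod_units
from toxpod.descriptors import featurize


@dataclass
class ClassRankingRow:
    class_name: str
    level: str  # subclass | class | superclass
    n_chems: int
    median_pod: float  # mg/kg-d
    high_potency_fraction: float  # percent of members in the library-wide top 1%
    median_ci_width: float  # log10 units


def predict_library(
    estimator,
    library: Sequence[ChemicalRecord],
    endpoint: str,
    kind: str = "physchem_2d",
    provisional: bool = False,
    fp_bits: int = 1024,
    fp_radius: int = 2,
) -> pd.DataFrame:
    """One prediction row per library chemical, in presentation units.

    ``estimator`` must be fitted (retrain-on-all protocol with its internal
    calibration split) and expose ``predict(FeatureMatrix) -> intervals``.
    Chemicals whose structure cannot be featurized are flagged, not dropped.
    """
    rows = []
    ok_records = []
    for r in library:
        try:
            featurize([r], kind, fp_bits, fp_radius)
            ok_records.append(r)
        except Exception:
            rows.append(_failed_row(r, endpoint, provisional))
    if ok_records:
        fm = featurize(ok_records, kind, fp_bits, fp_radius)
        preds = estimator.predict(fm)
        for r, p in zip(ok_records, preds):
            mw = r.mol_weight if r.mol_weight else 100.0
            rows.append(
                {
                    "chem_id": r.chem_id,
                    "endpoint": endpoint,
                    "median": invert_pod_units(p.median, mw),
                    "lower": invert_pod_units(p.lower, mw),
                    "upper": invert_pod_units(p.upper, mw),
                    "median_log10": p.median,
                    "width_log10": p.width,
                    "standardized": r.standardized,
                    "provisional": provisional,
                    "failed": False,
                    "superclass": r.taxonomy[0],
                    "class": r.taxonomy[1],
                    "subclass": r.taxonomy[2],
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        # preserve input order
        order = {r.chem_id: i for i, r in enumerate(library)}
        df = df.sort_values("chem_id", key=lambda s: s.map(order), kind="stable")
        df = df.reset_index(drop=True)
    return df


def _failed_row(r: ChemicalRecord, endpoint: str, provisional: bool) -> dict:
    return {
        "chem_id": r.chem_id,
        "endpoint": endpoint,
        "median": np.nan,
        "lower": np.nan,
        "upper": np.nan,
        "median_log10": np.nan,
        "width_log10": np.nan,
        "standardized": r.standardized,
        "provisional": provisional,
        "failed": True,
        "superclass": r.taxonomy[0],
        "class": r.taxonomy[1],
        "subclass": r.taxonomy[2],
    }


def embed_chemical_space(
    fps: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE map of binary fingerprints; deterministic given seed."""
    x = np.asarray(getattr(fps, "values", fps), dtype=float)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 fingerprints to embed")
    perplexity = min(perplexity, (x.shape[0] - 1) / 3.0)
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    )
    return tsne.fit_transform(x)


def _lowest_level(row) -> Optional[tuple]:
    for level in ("subclass", "class", "superclass"):
        v = row.get(level)
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            return str(v), level
    return None


def rank_classes(
    table: pd.DataFrame, min_size: int = 30, top_pct: float = 1.0
) -> list[ClassRankingRow]:
    """Rank taxonomy classes by median predicted POD, most potent first.

    Each chemical joins exactly one class (its lowest available taxonomy
    level); classes below ``min_size`` members are excluded. The high-potency
    reference set is the library-wide ``top_pct`` percent lowest medians.
    """
    df = table[~table["failed"]].copy() if "failed" in table.columns else table.copy()
    assigned = df.apply(_lowest_level, axis=1)
    if assigned.notna().sum() == 0:
        raise ValueError("no chemicals carry taxonomy labels")
    df = df[assigned.notna()].copy()
    df["_class"] = [a[0] for a in assigned.dropna()]
    df["_level"] = [a[1] for a in assigned.dropna()]
    threshold = np.percentile(df["median"].to_numpy(float), top_pct)
    rows = []
    for (name, level), grp in df.groupby(["_class", "_level"], sort=False):
        if len(grp) < min_size:
            continue
        med = grp["median"].to_numpy(float)
        rows.append(
            ClassRankingRow(
                class_name=name,
                level=level,
                n_chems=len(grp),
                median_pod=float(np.median(med)),
                high_potency_fraction=float(100.0 * np.mean(med <= threshold)),
                median_ci_width=float(np.median(grp["width_log10"].to_numpy(float))),
            )
        )
    rows.sort(key=lambda r: r.median_pod)
    return rows


def ranking_to_frame(rows: Sequence[ClassRankingRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
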