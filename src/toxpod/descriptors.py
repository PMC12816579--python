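"""Molecular descriptor families and leakage-free feature preprocessing.

Four descriptor families are supported: MACCS keys (166-bit predefined
substructure fingerprint), Morgan circular fingerprints (default 1024 bits,
radius 2), continuous 2D physicochemical descriptors from RDKit, and
precomputed learned embeddings ingested from a feature table. Knowledge-based
families (MACCS, physchem) get a Pearson-correlation filter (|r| > 0.9 drops
the later feature of a pair); the physchem block additionally gets a
Yeo-Johnson power transform and zero-mean/unit-variance scaling. Structural
representations (Morgan, embeddings) pass through untouched, since their bits
are only meaningful jointly. All preprocessing parameters are fitted on
training rows only and applied unchanged to test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.preprocessing import PowerTransformer

from toxpod.data_io import ChemicalRecord

KINDS = ("maccs_keys", "morgan_fp", "physchem_2d", "learned_embedding")
BINARY_KINDS = ("maccs_keys", "morgan_fp")


@dataclass
class FeatureMatrix:
    """A descriptor block: n chemicals x d features of one descriptor family."""

    chem_ids: list
    kind: str
    values: np.ndarray
    feature_names: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.chem_ids):
            raise ValueError("row count must equal number of chem_ids")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal number of feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if self.kind in BINARY_KINDS and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError(f"{self.kind} matrix must be binary")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "chem_id", self.chem_ids)
        return df


class FeaturizationError(ValueError):
    pass


def _mol_for(record: ChemicalRecord) -> Chem.Mol:
    smi = record.smiles_std or record.smiles_raw
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise FeaturizationError(
            f"unparseable structure for chem_id {record.chem_id!r}: {smi!r}"
        )
    return mol


def featurize(
    records: Sequence[ChemicalRecord],
    kind: str,
    fp_bits: int = 1024,
    fp_radius: int = 2,
    embedding_table: Optional[pd.DataFrame] = None,
) -> FeatureMatrix:
    """Compute one descriptor family for a list of records.

    Deterministic; identical canonical structures yield identical rows. For
    ``learned_embedding`` a precomputed table (chem_id-indexed or with a
    chem_id column) must be supplied — embeddings come from a pretrained
    network and are consumed, never computed, here.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown descriptor kind {kind!r}; expected one of {KINDS}")
    ids = [r.chem_id for r in records]

    if kind == "learned_embedding":
        if embedding_table is None:
            raise FeaturizationError("learned_embedding requires an embedding_table")
        tbl = embedding_table
        if "chem_id" in tbl.columns:
            tbl = tbl.set_index("chem_id")
        missing = [i for i in ids if i not in tbl.index]
        if missing:
            raise FeaturizationError(f"embedding rows missing for chem_ids: {missing}")
        sub = tbl.loc[ids]
        return FeatureMatrix(ids, kind, sub.to_numpy(float), list(sub.columns))

    mols = [_mol_for(r) for r in records]

    if kind == "morgan_fp":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=fp_radius, fpSize=fp_bits)
        vals = np.array([gen.GetFingerprintAsNumPy(m) for m in mols], dtype=float)
        names = [f"morgan_{i}" for i in range(fp_bits)]
    elif kind == "maccs_keys":
        # RDKit MACCS bit 0 is unused; drop it for a 166-key block
        vals = np.array(
            [np.asarray(MACCSkeys.GenMACCSKeys(m))[1:] for m in mols], dtype=float
        )
        names = [f"maccs_{i}" for i in range(1, vals.shape[1] + 1)]
    else:  # physchem_2d
        rows = [Descriptors.CalcMolDescriptors(m) for m in mols]
        names = list(rows[0].keys())
        vals = np.array([[float(r[k]) for k in names] for r in rows])
        vals[~np.isfinite(vals)] = 0.0
    return FeatureMatrix(ids, kind, vals, names)


@dataclass
class FeaturePipeline:
    """Train-fitted preprocessing state for one descriptor family.

    ``kept_mask`` marks surviving features after (possible) zero-variance and
    correlation filtering; ``power`` holds fitted Yeo-Johnson + scaling
    parameters (physchem only). Identity for morgan_fp / learned_embedding.
    """

    kind: str
    feature_names: list
    kept_mask: np.ndarray
    power: Optional[PowerTransformer] = None
    fitted_: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.sum() < 1:
            raise ValueError("kept_mask must select at least one feature")


def _correlation_keep_mask(x: np.ndarray, threshold: float) -> np.ndarray:
    """Greedy filter: scan features in input order, drop the later of any pair
    with |Pearson r| > threshold against an already-kept feature."""
    d = x.shape[1]
    sd = x.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns give nan correlations
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    keep = np.zeros(d, dtype=bool)
    kept_idx: list[int] = []
    for j in range(d):
        if sd[j] > 0 and kept_idx and np.any(np.abs(corr[j, kept_idx]) > threshold):
            continue
        keep[j] = True
        kept_idx.append(j)
    return keep


def fit_feature_pipeline(
    train: FeatureMatrix, corr_threshold: float = 0.9
) -> FeaturePipeline:
    """Fit preprocessing on training rows only.

    maccs_keys: correlation filter. physchem_2d: drop zero-variance columns
    (warned), correlation filter, then Yeo-Johnson + standardization. Other
    kinds: identity.
    """
    if train.n < 2:
        raise ValueError("need at least 2 training rows to fit a pipeline")
    x = train.values
    d = x.shape[1]

    if train.kind in ("morgan_fp", "learned_embedding"):
        return FeaturePipeline(train.kind, list(train.feature_names), np.ones(d, bool))

    keep = np.ones(d, dtype=bool)
    if train.kind == "physchem_2d":
        zero_var = x.std(axis=0) == 0
        if zero_var.any():
            warnings.warn(
                f"dropping {int(zero_var.sum())} zero-variance physchem feature(s)",
                stacklevel=2,
            )
            keep &= ~zero_var
    sub = x[:, keep]
    corr_keep = _correlation_keep_mask(sub, corr_threshold)
    full = np.zeros(d, dtype=bool)
    full[np.flatnonzero(keep)[corr_keep]] = True

    power = None
    if train.kind == "physchem_2d":
        power = PowerTransformer(method="yeo-johnson", standardize=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            power.fit(x[:, full])
    return FeaturePipeline(train.kind, list(train.feature_names), full, power)


def apply_feature_pipeline(pipeline: FeaturePipeline, m: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted pipeline; never refits, never mutates the pipeline."""
    if m.kind != pipeline.kind:
        raise ValueError(f"kind mismatch: pipeline {pipeline.kind}, matrix {m.kind}")
    if list(m.feature_names) != list(pipeline.feature_names):
        raise ValueError("feature names do not match the pipeline's training features")
    vals = m.values[:, pipeline.kept_mask]
    if pipeline.power is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = pipeline.power.transform(vals)
    names = [n for n, k in zip(pipeline.feature_names, pipeline.kept_mask) if k]
    return FeatureMatrix(list(m.chem_ids), m.kind, np.asarray(vals, float), names)


def write_feature_table(m: FeatureMatrix, path) -> None:
    m.to_frame().to_csv(path, index=False)


def read_feature_table(path, kind: str) -> FeatureMatrix:
    df = pd.read_csv(path, dtype={"chem_id": str})
    ids = df["chem_id"].tolist()
    vals = df.drop(columns="chem_id").to_numpy(float)
    return FeatureMatrix(ids, kind, vals, list(df.columns[1:]))
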