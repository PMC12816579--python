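"""Synthetic structure-toxicity datasets with known ground truth.

Two generators:

* :func:`make_synthetic_qsar` builds a cluster-structured dataset that
  mimics the statistical shape of curated POD data — log10-scale targets
  with a controllable total variance (0.69 emulates the
  reproductive/developmental endpoint, 1.17 the general non-cancer one),
  heteroscedastic Gaussian noise, and binary pseudo-fingerprints with
  controlled within/between-cluster Jaccard similarity so distance-based
  calibration is exercisable. Pseudo-fingerprints are cluster prototypes
  with seeded bit flips, not real molecules: the calibration mathematics
  needs binary vectors with controlled similarity, not chemistry.

* :func:`make_toy_fixture` returns ~20 hand-listed real SMILES with
  fabricated PODs and support counts, covering every standardization branch
  (salt, organometallic, >1000 g/mol, inorganic, unparseable) and both
  endpoints, for exercising the real featurization path end to end.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from toxpod.data_io import ChemicalRecord, invert_pod_units
from toxpod.descriptors import FeatureMatrix


@dataclass
class SyntheticSpec:
    n_chems: int = 2000
    n_clusters: int = 8
    fp_bits: int = 1024
    bitflip_rate: float = 0.05
    n_latent: int = 5
    target_variance_goal: float = 0.69
    noise_base: float = 0.2  # aleatoric SD floor, log10 units
    noise_slope: float = 0.3  # heteroscedastic growth with the first latent
    endpoint: str = "nc"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.bitflip_rate <= 1.0):
            raise ValueError("bitflip_rate must lie in [0, 1]")
        if self.n_clusters > self.n_chems:
            raise ValueError("n_clusters cannot exceed n_chems")
        noise_var = (
            self.noise_base**2
            + 2.0 * self.noise_base * self.noise_slope * np.sqrt(2.0 / np.pi)
            + self.noise_slope**2
        )
        if self.target_variance_goal <= noise_var:
            raise ValueError(
                "target_variance_goal must exceed the mean noise variance "
                f"(~{noise_var:.3f}) so a signal component remains"
            )


@dataclass
class SyntheticDataset:
    records: list
    fingerprints: FeatureMatrix  # kind morgan_fp (pseudo)
    descriptors: FeatureMatrix  # continuous latent descriptors
    y: np.ndarray  # targets, log10 scale
    sigma_true: np.ndarray  # ground-truth aleatoric SD per item
    f_true: np.ndarray  # noise-free signal
    clusters: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)


def make_synthetic_qsar(spec: Optional[SyntheticSpec] = None) -> SyntheticDataset:
    """Generate one dataset; fully reproducible from ``spec.seed``.

    Construction: cluster prototype bit-vectors are drawn once
    (P(bit)=0.1); member fingerprints flip each prototype bit with
    ``bitflip_rate``. Continuous descriptors are cluster centers plus
    within-cluster noise, so cluster identity is recoverable from them.
    The target is a per-cluster offset plus a linear descriptor term,
    rescaled so that signal variance plus mean noise variance hits
    ``target_variance_goal``; noise SD is affine in the standardized first
    within-cluster coordinate, giving the heteroscedasticity that interval
    models must capture.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n, k, d = spec.n_chems, spec.n_clusters, spec.n_latent

    clusters = rng.integers(k, size=n)
    protos = (rng.random((k, spec.fp_bits)) < 0.1).astype(float)
    flips = rng.random((n, spec.fp_bits)) < spec.bitflip_rate
    fps = np.abs(protos[clusters] - flips.astype(float))

    centers = rng.normal(0.0, 2.0, size=(k, d))
    within = rng.normal(0.0, 0.6, size=(n, d))
    z = centers[clusters] + within

    u = within[:, 0] / 0.6  # standardized within-cluster coordinate ~ N(0,1)
    sigma_true = spec.noise_base + spec.noise_slope * np.abs(u)

    offsets = rng.normal(0.0, 1.0, size=k)
    w = rng.normal(0.0, 1.0, size=d) / np.sqrt(d)
    raw = offsets[clusters] + z @ w
    target_signal_var = spec.target_variance_goal - float(np.mean(sigma_true**2))
    raw = raw - raw.mean()
    raw_var = float(raw.var())
    f_true = raw * np.sqrt(target_signal_var / raw_var) if raw_var > 0 else raw
    y = f_true + sigma_true * rng.standard_normal(n)

    ids = [f"syn-{i:05d}" for i in range(n)]
    records = [
        ChemicalRecord(
            chem_id=ids[i],
            smiles_raw=f"[synthetic:{ids[i]}]",
            mol_weight=100.0,
            pod={spec.endpoint: invert_pod_units(float(y[i]), 100.0)},
            n_support={spec.endpoint: 5},
        )
        for i in range(n)
    ]
    fp_matrix = FeatureMatrix(
        ids, "morgan_fp", fps, [f"morgan_{j}" for j in range(spec.fp_bits)]
    )
    desc = FeatureMatrix(ids, "physchem_2d", z, [f"latent_{j}" for j in range(d)])
    return SyntheticDataset(
        records, fp_matrix, desc, y, sigma_true, f_true, clusters, spec
    )


# -- toy fixture -------------------------------------------------------------

# (chem_id, smiles, pod_rd, pod_nc, n_rd, n_nc, superclass, class, subclass)
# PODs (mg/kg-d) and support counts are fabricated; structures are real.
_TOY_ROWS = [
    ("tox-001", "CCO", 500.0, 800.0, 6, 9, "Organic oxygen compounds", "Alcohols", "Primary alcohols"),
    ("tox-002", "c1ccccc1", 50.0, 25.0, 5, 7, "Benzenoids", "Benzene and derivatives", None),
    ("tox-003", "CC(=O)Oc1ccccc1C(=O)O", 100.0, 90.0, 8, 4, "Benzenoids", "Benzoic acids", "Salicylic acids"),
    ("tox-004", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 30.0, 20.0, 4, 5, "Organoheterocyclic", "Imidazopyrimidines", "Purines"),
    ("tox-005", "Cc1ccccc1", 250.0, 220.0, 7, 6, "Benzenoids", "Benzene and derivatives", "Toluenes"),
    ("tox-006", "Oc1ccccc1", 60.0, 70.0, 5, 5, "Benzenoids", "Phenols", None),
    ("tox-007", "CC(C)=O", 900.0, 1000.0, 6, 8, "Organic oxygen compounds", "Ketones", None),
    ("tox-008", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 40.0, 45.0, 4, 4, "Benzenoids", "Benzene and derivatives", "Phenylpropanoic acids"),
    ("tox-009", "CN1CCCC1c1cccnc1", 1.0, 0.8, 6, 6, "Alkaloids", "Pyridine alkaloids", None),
    ("tox-010", "OCC1OC(O)C(O)C(O)C1O", 2000.0, 2500.0, 5, 5, "Organic oxygen compounds", "Carbohydrates", "Monosaccharides"),
    ("tox-011", "Clc1cc2Oc3cc(Cl)c(Cl)cc3Oc2cc1Cl", 0.0001, 0.00005, 7, 9, "Organoheterocyclic", "Benzodioxins", "Benzo-p-dioxins"),
    ("tox-012", "Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl", 0.05, 0.02, 5, 6, "Benzenoids", "Diphenylmethanes", None),
    ("tox-013", "[Na+].CC(=O)[O-]", 700.0, 750.0, 4, 4, "Organic acids", "Carboxylic acids", "Acetates"),  # salt
    ("tox-014", "c1ccncc1", 15.0, 12.0, 4, 5, "Organoheterocyclic", "Pyridines", None),
    ("tox-015", "Nc1ccccc1", 20.0, 18.0, 6, 4, "Benzenoids", "Anilines", None),
    ("tox-016", "CC(=O)O", 600.0, 650.0, 5, 6, "Organic acids", "Carboxylic acids", "Acetic acids"),
    ("tox-017", "c1ccc2ccccc2c1", 80.0, 90.0, 4, 4, "Benzenoids", "Naphthalenes", None),
    ("tox-018", "NC(N)=O", 1500.0, 1800.0, 6, 7, "Organic acids", "Ureas", None),
    ("tox-019", "ClC(Cl)Cl", 35.0, 30.0, 5, 5, "Organohalogens", "Halomethanes", None),
    ("tox-020", "CCCCCCCCO", 300.0, 350.0, 3, 2, "Organic oxygen compounds", "Alcohols", "Fatty alcohols"),  # low support
    ("tox-021", "CCOC(=O)C", 450.0, 400.0, 2, 3, "Organic acids", "Carboxylic esters", None),  # low support
    ("tox-022", "CC[Pb](CC)(CC)CC", 0.01, 0.005, 6, 6, None, None, None),  # organometallic
    ("tox-023", "C" * 72, 50.0, 55.0, 5, 5, None, None, None),  # > 1000 g/mol
    ("tox-024", "[Na+].[Cl-]", 3000.0, 3000.0, 5, 5, None, None, None),  # inorganic
    ("tox-025", "not_a_smiles", 10.0, 10.0, 5, 5, None, None, None),  # unparseable
]


def make_toy_fixture() -> list[ChemicalRecord]:
    """Deterministic ~25-record table exercising every standardization branch."""
    records = []
    for cid, smi, pod_rd, pod_nc, n_rd, n_nc, sup, cls, sub in _TOY_ROWS:
        records.append(
            ChemicalRecord(
                chem_id=cid,
                smiles_raw=smi,
                pod={"rd": pod_rd, "nc": pod_nc},
                n_support={"rd": n_rd, "nc": n_nc},
                taxonomy=(sup, cls, sub),
            )
        )
    return records
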