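"""Chemical-table I/O, structure standardization, unit conversion and filtering.

POD values arrive in mg/kg-d. Internally models work in log10(mol/kg-d), the
scale on which dose relates to molecular activity; :func:`convert_pod_units`
and :func:`invert_pod_units` move between the two. Structure standardization
follows common QSAR practice: strip salts/solvents by keeping the largest
organic component, exclude inorganics, organometallics and molecules above
1000 g/mol. Records failing standardization are retained with an exclusion
reason rather than dropped, so that models can optionally be trained on the
expanded (standardized + non-standardized) dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

ENDPOINTS = ("rd", "nc")

#: elements treated as "organic" for standardization; anything else is a metal
#: (or metalloid outside the usual QSAR scope) and triggers exclusion
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

MAX_MOL_WEIGHT = 1000.0  # g/mol; heavier retained components are excluded


class ExclusionReason(str, Enum):
    INORGANIC = "inorganic"
    ORGANOMETALLIC = "organometallic"
    TOO_LARGE = "too_large"
    UNPARSEABLE = "unparseable"


@dataclass
class StandardizationOutcome:
    """Result of standardizing one SMILES: either a canonical structure or a reason."""

    smiles_std: Optional[str] = None
    exclusion_reason: Optional[ExclusionReason] = None
    mol_weight: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.smiles_std is not None


@dataclass
class ChemicalRecord:
    """One chemical with identifiers, structures, per-endpoint PODs and metadata.

    ``pod`` maps endpoint ("rd"/"nc") to a POD in mg/kg-d; ``n_support`` maps
    endpoint to the number of underlying experimental data points backing that
    POD. ``taxonomy`` holds ClassyFire-style (superclass, class, subclass)
    labels, any of which may be None.
    """

    chem_id: str
    smiles_raw: str
    cas: Optional[str] = None
    smiles_std: Optional[str] = None
    standardized: bool = False
    exclusion_reason: Optional[ExclusionReason] = None
    mol_weight: Optional[float] = None
    pod: dict = field(default_factory=dict)
    n_support: dict = field(default_factory=dict)
    taxonomy: tuple = (None, None, None)

    def __post_init__(self) -> None:
        if self.standardized != (
            self.smiles_std is not None and self.exclusion_reason is None
        ):
            raise ValueError(
                "standardized must be True exactly when smiles_std is present "
                "and no exclusion_reason is set"
            )
        for ep, v in self.pod.items():
            if v is not None and v <= 0:
                raise ValueError(f"POD for endpoint {ep!r} must be positive, got {v}")
        for ep, n in self.n_support.items():
            if n < 0:
                raise ValueError(f"n_support for endpoint {ep!r} must be >= 0")


DEFAULT_SCHEMA = {
    "chem_id": "chem_id",
    "smiles": "smiles",
    "cas": "cas",
    "pod_rd": "pod_rd",
    "pod_nc": "pod_nc",
    "n_rd": "n_rd",
    "n_nc": "n_nc",
    "mol_weight": "mol_weight",
    "superclass": "superclass",
    "class": "class",
    "subclass": "subclass",
}


class SchemaError(ValueError):
    pass


def _opt_float(row, col) -> Optional[float]:
    if col is None or col not in row or pd.isna(row[col]) or row[col] == "":
        return None
    return float(row[col])


def _opt_int(row, col) -> Optional[int]:
    v = _opt_float(row, col)
    return None if v is None else int(v)


def _opt_str(row, col) -> Optional[str]:
    if col is None or col not in row or pd.isna(row[col]) or row[col] == "":
        return None
    return str(row[col])


def read_chemical_table(
    path, schema: Optional[Mapping[str, str]] = None, sep: Optional[str] = None
) -> list[ChemicalRecord]:
    """Read a CSV/TSV chemical table into :class:`ChemicalRecord` objects.

    ``schema`` maps logical names (keys of ``DEFAULT_SCHEMA``) to the file's
    column names; unmapped optional columns yield absent fields. Row order is
    preserved. Raises :class:`SchemaError` if a required column (chem_id,
    smiles) is missing.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={schema["chem_id"]: str})
    for required in ("chem_id", "smiles"):
        if schema[required] not in df.columns:
            raise SchemaError(
                f"required column {schema[required]!r} (for {required}) not found; "
                f"available: {list(df.columns)}"
            )
    if df.empty:
        warnings.warn(f"{path}: empty chemical table", stacklevel=2)
        return []

    records = []
    for _, row in df.iterrows():
        pod, n_support = {}, {}
        for ep in ENDPOINTS:
            v = _opt_float(row, schema.get(f"pod_{ep}"))
            if v is not None:
                pod[ep] = v
            n = _opt_int(row, schema.get(f"n_{ep}"))
            if n is not None:
                n_support[ep] = n
        std = _opt_str(row, "smiles_std") if "smiles_std" in df.columns else None
        records.append(
            ChemicalRecord(
                chem_id=str(row[schema["chem_id"]]),
                smiles_raw=str(row[schema["smiles"]]),
                cas=_opt_str(row, schema.get("cas")),
                smiles_std=std,
                standardized=std is not None,
                mol_weight=_opt_float(row, schema.get("mol_weight")),
                pod=pod,
                n_support=n_support,
                taxonomy=(
                    _opt_str(row, schema.get("superclass")),
                    _opt_str(row, schema.get("class")),
                    _opt_str(row, schema.get("subclass")),
                ),
            )
        )
    return records


def _has_metal(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in mol.GetAtoms())


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize_structure(smiles_raw: str) -> StandardizationOutcome:
    """Standardize a raw SMILES: strip salts/solvents, apply exclusion rules.

    Multi-component inputs keep the largest organic component (most heavy
    atoms; ties broken by molecular weight, then canonical-SMILES order, for
    determinism). Exclusions are returned, never raised:

    * no carbon in any component -> ``inorganic``
    * metal atom in the retained component -> ``organometallic``
    * retained component heavier than 1000 g/mol -> ``too_large``
    * RDKit cannot parse the input -> ``unparseable``
    """
    mol = Chem.MolFromSmiles(smiles_raw) if isinstance(smiles_raw, str) else None
    if mol is None:
        return StandardizationOutcome(exclusion_reason=ExclusionReason.UNPARSEABLE)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _has_carbon(f)]
    if not organic:
        return StandardizationOutcome(exclusion_reason=ExclusionReason.INORGANIC)

    def sort_key(f: Chem.Mol):
        return (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), Chem.MolToSmiles(f))

    retained = max(organic, key=sort_key)
    if _has_metal(retained):
        return StandardizationOutcome(exclusion_reason=ExclusionReason.ORGANOMETALLIC)
    mw = Descriptors.MolWt(retained)
    if mw > MAX_MOL_WEIGHT:
        return StandardizationOutcome(
            exclusion_reason=ExclusionReason.TOO_LARGE, mol_weight=mw
        )
    return StandardizationOutcome(smiles_std=Chem.MolToSmiles(retained), mol_weight=mw)


def standardize_records(records: Iterable[ChemicalRecord]) -> list[ChemicalRecord]:
    """Apply :func:`standardize_structure` to every record, in place semantics avoided."""
    out = []
    for r in records:
        res = standardize_structure(r.smiles_raw)
        out.append(
            ChemicalRecord(
                chem_id=r.chem_id,
                smiles_raw=r.smiles_raw,
                cas=r.cas,
                smiles_std=res.smiles_std,
                standardized=res.ok,
                exclusion_reason=res.exclusion_reason,
                mol_weight=res.mol_weight if res.mol_weight is not None else r.mol_weight,
                pod=dict(r.pod),
                n_support=dict(r.n_support),
                taxonomy=r.taxonomy,
            )
        )
    return out


def convert_pod_units(pod_mgkgd: float, mol_weight: float) -> float:
    """mg/kg-d -> log10(mol/kg-d) given the molecular weight in g/mol."""
    if pod_mgkgd <= 0:
        raise ValueError(f"POD must be positive, got {pod_mgkgd}")
    if mol_weight <= 0:
        raise ValueError(f"molecular weight must be positive, got {mol_weight}")
    return math.log10((pod_mgkgd / 1000.0) / mol_weight)


def invert_pod_units(log10_molkgd: float, mol_weight: float) -> float:
    """log10(mol/kg-d) -> mg/kg-d; inverse of :func:`convert_pod_units`."""
    if mol_weight <= 0:
        raise ValueError(f"molecular weight must be positive, got {mol_weight}")
    return (10.0**log10_molkgd) * mol_weight * 1000.0


def pod_from_tef(pod_reference: float, tef: float) -> float:
    """POD of a dioxin-like compound from the index compound's POD and its TEF.

    The toxic equivalency factor (TEF) is the compound's potency relative to
    the index compound (2,3,7,8-TCDD); higher relative potency means a lower
    POD, hence division.
    """
    if pod_reference <= 0 or tef <= 0:
        raise ValueError("pod_reference and tef must both be positive")
    return pod_reference / tef


def filter_by_support(
    records: Sequence[ChemicalRecord], endpoint: str, min_points: int = 4
) -> list[ChemicalRecord]:
    """Keep records whose POD for ``endpoint`` rests on >= ``min_points`` data points.

    Surrogate PODs derived from few underlying experimental observations carry
    high aleatoric uncertainty; the default of 4 drops them. Order preserved.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    return [
        r
        for r in records
        if r.pod.get(endpoint) is not None
        and r.n_support.get(endpoint, 0) >= min_points
    ]


def records_to_frame(records: Sequence[ChemicalRecord]) -> pd.DataFrame:
    """Normalized chemical table with one row per record."""
    rows = []
    for r in records:
        rows.append(
            {
                "chem_id": r.chem_id,
                "cas": r.cas,
                "smiles_raw": r.smiles_raw,
                "smiles_std": r.smiles_std,
                "standardized": r.standardized,
                "exclusion_reason": (
                    r.exclusion_reason.value if r.exclusion_reason else None
                ),
                "mol_weight": r.mol_weight,
                "pod_rd": r.pod.get("rd"),
                "pod_nc": r.pod.get("nc"),
                "n_rd": r.n_support.get("rd"),
                "n_nc": r.n_support.get("nc"),
                "superclass": r.taxonomy[0],
                "class": r.taxonomy[1],
                "subclass": r.taxonomy[2],
            }
        )
    return pd.DataFrame(rows)


def write_chemical_table(records: Sequence[ChemicalRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
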