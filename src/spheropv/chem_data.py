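"""Molecular descriptor data model and table I/O.

The screening pipeline consumes one physicochemical descriptor vector per
drug: molecular weight, logP, logS, hydrogen-bond acceptor/donor counts,
polar surface area, rotatable-bond count, molar refractivity and
polarizability (the nine QSAR predictors), plus auxiliary inputs for the
drug-likeness filters (heavy-atom count, aromatic-ring count, structural
alerts) and the membrane-permeability model (pKa and the fractions of
molecular surface area contributed by H-bond acceptor and donor atoms).

Descriptors are primarily *ingested* from delimited tables.  Computing them
from a structure string is an optional convenience path, clearly flagged in
the record's provenance, because computed logP/PSA differ across toolkits
and would silently change downstream regression results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    CapabilityError,
    ParseError,
    SchemaError,
    StructureError,
    ValidationError,
)

#: The nine QSAR predictor fields, in canonical order.
QSAR_DESCRIPTORS: tuple[str, ...] = (
    "mw",
    "logp",
    "logs",
    "hba_count",
    "hbd_count",
    "psa",
    "rotatable_bonds",
    "refractivity",
    "polarizability",
)

#: Mandatory columns of a descriptor table.
MANDATORY_COLUMNS: tuple[str, ...] = ("drug_id",) + QSAR_DESCRIPTORS

#: Optional columns (absent values stay absent — never imputed as zero).
OPTIONAL_COLUMNS: tuple[str, ...] = (
    "structure",
    "pka",
    "sa_ha_fraction",
    "sa_hd_fraction",
    "atom_count",
    "aromatic_ring_count",
    "alerts_count",
    "ic50_monolayer",
)

INTEGER_FIELDS = frozenset(
    {"hba_count", "hbd_count", "rotatable_bonds", "atom_count",
     "aromatic_ring_count", "alerts_count"}
)

# Case-insensitive header aliases; keys are canonical field names.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "drug_id": ("drug_id", "drug", "id", "name", "compound", "compound_id"),
    "structure": ("structure", "smiles", "canonical_smiles"),
    "mw": ("mw", "molweight", "molecular_weight", "mol_weight"),
    "logp": ("logp", "log_p", "alogp", "xlogp", "clogp"),
    "logs": ("logs", "log_s", "logsw", "solubility_logs"),
    "hba_count": ("hba_count", "hba", "h_bond_acceptors", "acceptors",
                  "hbond_acceptor_count", "acceptor_count"),
    "hbd_count": ("hbd_count", "hbd", "h_bond_donors", "donors",
                  "hbond_donor_count", "donor_count"),
    "psa": ("psa", "tpsa", "polar_surface_area"),
    "rotatable_bonds": ("rotatable_bonds", "rotb", "rot_bonds",
                        "n_rotatable_bonds", "rotatable_bond_count"),
    "refractivity": ("refractivity", "mr", "molar_refractivity", "cmr"),
    "polarizability": ("polarizability", "apol", "polarisability"),
    "pka": ("pka", "pk_a", "strongest_pka"),
    "sa_ha_fraction": ("sa_ha_fraction", "sa_ha", "saha", "frac_sa_hba"),
    "sa_hd_fraction": ("sa_hd_fraction", "sa_hd", "sahd", "frac_sa_hbd"),
    "atom_count": ("atom_count", "heavy_atoms", "heavy_atom_count", "natoms"),
    "aromatic_ring_count": ("aromatic_ring_count", "arom", "aromatic_rings",
                            "n_aromatic_rings"),
    "alerts_count": ("alerts_count", "alerts", "structural_alerts",
                     "n_alerts"),
    "ic50_monolayer": ("ic50_monolayer", "ic50", "ic50_um", "ic50_2d"),
}

_ALIAS_LOOKUP = {
    alias.lower(): canon
    for canon, aliases in COLUMN_ALIASES.items()
    for alias in aliases
}


@dataclass
class DrugDescriptorRecord:
    """One drug's physicochemical descriptor vector.

    ``None`` means "not supplied", never zero.  ``provenance`` maps field
    names to a short origin tag (``"table"`` or ``"computed"``); ``extra``
    carries unrecognized passthrough columns.
    """

    drug_id: str
    structure: str | None = None
    mw: float | None = None
    logp: float | None = None
    logs: float | None = None
    hba_count: int | None = None
    hbd_count: int | None = None
    psa: float | None = None
    rotatable_bonds: int | None = None
    refractivity: float | None = None
    polarizability: float | None = None
    pka: float | None = None
    sa_ha_fraction: float | None = None
    sa_hd_fraction: float | None = None
    atom_count: int | None = None
    aromatic_ring_count: int | None = None
    alerts_count: int | None = None
    ic50_monolayer: float | None = None
    provenance: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any hard-invariant violation."""
        if not self.drug_id:
            raise ValidationError("drug_id must be a non-empty string")
        if self.mw is not None and not self.mw > 0:
            raise ValidationError(f"{self.drug_id}: mw must be > 0, got {self.mw}")
        if self.psa is not None and self.psa < 0:
            raise ValidationError(f"{self.drug_id}: psa must be >= 0, got {self.psa}")
        for name in INTEGER_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if v < 0 or int(v) != v:
                raise ValidationError(
                    f"{self.drug_id}: {name} must be a non-negative integer, got {v}"
                )
        for name in ("sa_ha_fraction", "sa_hd_fraction"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.drug_id}: {name} must lie in [0, 1], got {v}"
                )

    def require(self, names: Sequence[str]) -> None:
        """Raise :class:`~spheropv.errors.MissingDataError` listing absent fields."""
        from .errors import MissingDataError

        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MissingDataError(missing, context=self.drug_id)


def _field_names() -> list[str]:
    return [f.name for f in dc_fields(DrugDescriptorRecord)
            if f.name not in ("provenance", "extra")]


def _coerce(name: str, value, row: int, column: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    if name in ("drug_id", "structure"):
        return str(value)
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {value!r} at row {row}, column {column!r}"
        ) from None
    if name in INTEGER_FIELDS:
        if x != int(x):
            raise ParseError(
                f"non-integral value {value!r} at row {row}, column {column!r}"
            )
        return int(x)
    return x


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_descriptor_table(
    path: str | Path, schema_policy: str = "strict"
) -> list[DrugDescriptorRecord]:
    """Load a delimited descriptor table into validated records.

    Parameters
    ----------
    path
        CSV (or ``.tsv`` tab-separated) file with a header row and one row
        per drug.  Header names are matched case-insensitively against the
        alias dictionary (:data:`COLUMN_ALIASES`); unrecognized columns are
        preserved as passthrough metadata on each record.
    schema_policy
        ``"strict"`` requires ``drug_id`` plus the nine QSAR descriptor
        columns; ``"lenient"`` requires only ``drug_id`` and leaves missing
        descriptors absent (downstream operations raise a missing-data
        error when they need them).
    """
    path = Path(path)
    if schema_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown schema_policy {schema_policy!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=object)
    colmap: dict[str, str] = {}  # original header -> canonical
    for col in df.columns:
        canon = _ALIAS_LOOKUP.get(str(col).strip().lower())
        if canon is not None:
            if canon in colmap.values():
                raise SchemaError(f"two columns map to field {canon!r}")
            colmap[col] = canon
    mandatory = MANDATORY_COLUMNS if schema_policy == "strict" else ("drug_id",)
    missing = [m for m in mandatory if m not in colmap.values()]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    extra_cols = [c for c in df.columns if c not in colmap]

    records: list[DrugDescriptorRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        kwargs = {}
        for orig, canon in colmap.items():
            kwargs[canon] = _coerce(canon, row[orig], int(i), orig)
        rec = DrugDescriptorRecord(**kwargs)
        rec.extra = {c: row[c] for c in extra_cols}
        rec.provenance = {
            k: "table" for k, v in kwargs.items() if v is not None and k != "drug_id"
        }
        if rec.drug_id in seen:
            raise ValidationError(f"duplicate drug_id {rec.drug_id!r}")
        seen.add(rec.drug_id)
        rec.validate()
        records.append(rec)
    return records


def records_to_frame(records: Iterable[DrugDescriptorRecord]) -> pd.DataFrame:
    """Tabulate records (defined fields only) as a DataFrame indexed 0..n-1."""
    names = _field_names()
    rows = [{n: getattr(r, n) for n in names} for r in records]
    df = pd.DataFrame(rows, columns=names)
    for extra_key in sorted({k for r in records for k in r.extra}):
        df[extra_key] = [r.extra.get(extra_key) for r in records]
    return df


def write_descriptor_table(
    records: Sequence[DrugDescriptorRecord], path: str | Path
) -> None:
    """Write records as a delimited table that :func:`load_descriptor_table` re-reads losslessly."""
    path = Path(path)
    df = records_to_frame(records)
    # drop all-absent optional columns so absence round-trips as absence
    df = df.dropna(axis="columns", how="all")
    df.to_csv(path, sep=_sep_for(path), index=False)


def compute_descriptors_from_structure(structure: str) -> DrugDescriptorRecord:
    """Compute a partial descriptor record from a SMILES string.

    Requires RDKit.  Fills mw, logp, hba_count, hbd_count, psa,
    rotatable_bonds, refractivity, atom_count, aromatic_ring_count and
    alerts_count, each flagged ``"computed"`` in provenance.  pKa, logS,
    polarizability and the surface-area fractions are never computed here
    (no reliable 2D route) and stay absent.

    Descriptor definitions follow the drug-likeness literature: HBA/HBD and
    alerts use the QED conventions, logP is Crippen, PSA is topological.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen, QED
    except ImportError as exc:  # pragma: no cover - rdkit present in CI env
        raise CapabilityError("RDKit is required to compute descriptors") from exc

    if not structure or not structure.strip():
        raise StructureError("empty structure string")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparseable structure: {structure!r}")
    props = QED.properties(mol)
    rec = DrugDescriptorRecord(
        drug_id=structure,
        structure=structure,
        mw=float(props.MW),
        logp=float(props.ALOGP),
        hba_count=int(props.HBA),
        hbd_count=int(props.HBD),
        psa=float(props.PSA),
        rotatable_bonds=int(props.ROTB),
        refractivity=float(Crippen.MolMR(mol)),
        atom_count=int(mol.GetNumHeavyAtoms()),
        aromatic_ring_count=int(props.AROM),
        alerts_count=int(props.ALERTS),
    )
    rec.provenance = {
        k: "computed"
        for k in ("mw", "logp", "hba_count", "hbd_count", "psa",
                  "rotatable_bonds", "refractivity", "atom_count",
                  "aromatic_ring_count", "alerts_count")
    }
    rec.validate()
    return rec


#: Soft plausibility screens for small-molecule drugs (warnings only).
PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "mw": (50.0, 2000.0),
    "logp": (-10.0, 15.0),
    "logs": (-15.0, 5.0),
    "hba_count": (0, 30),
    "hbd_count": (0, 20),
    "psa": (0.0, 500.0),
    "rotatable_bonds": (0, 40),
    "refractivity": (5.0, 400.0),
    "polarizability": (1.0, 400.0),
    "pka": (-5.0, 20.0),
    "ic50_monolayer": (1e-6, 1e5),
}


def validate_descriptor_ranges(
    records: Iterable[DrugDescriptorRecord],
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, list[str]]:
    """Screen records against plausible small-molecule ranges.

    Returns a mapping drug_id -> list of warning strings (empty list when
    everything is in range).  Never rejects a row: these are soft screens,
    not invariants.
    """
    ranges = dict(PLAUSIBLE_RANGES if ranges is None else ranges)
    report: dict[str, list[str]] = {}
    for rec in records:
        warnings = []
        for name, (lo, hi) in ranges.items():
            v = getattr(rec, name, None)
            if v is None:
                continue
            if not lo <= v <= hi:
                warnings.append(
                    f"{name}={v} outside plausible small-molecule range [{lo}, {hi}]"
                )
        report[rec.drug_id] = warnings
    return report
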