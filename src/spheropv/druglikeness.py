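"""Drug-likeness filters: Lipinski Ro5, Ghose, Veber and unweighted QED.

Each rule is a pure function of a :class:`~spheropv.chem_data.DrugDescriptorRecord`
and the configuration; re-evaluation is bit-identical.  Boundary conventions
follow the rules' original phrasings: Ro5 violations are *strict*
inequalities (mw > 500 etc., so a drug sitting exactly on a threshold does
not violate), while the Ghose and Veber bounds are inclusive.

The quantitative estimate of drug-likeness (QED) maps eight descriptors
through asymmetric double-sigmoid desirability functions, each normalized
by its maximum so d_i in (0, 1], and aggregates them as an equal-weight
geometric mean:

    QED = exp( (1/8) * sum_i ln d_i(x_i) )

The desirability parameters are the published fitted values, shipped as a
versioned data file (``data/qed_params.json``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .chem_data import DrugDescriptorRecord
from .errors import MissingDataError, NumericalError

#: Record field backing each QED descriptor.
QED_FIELDS: dict[str, str] = {
    "MW": "mw",
    "ALOGP": "logp",
    "HBA": "hba_count",
    "HBD": "hbd_count",
    "PSA": "psa",
    "ROTB": "rotatable_bonds",
    "AROM": "aromatic_ring_count",
    "ALERTS": "alerts_count",
}

RO5_FIELDS = ("mw", "logp", "hbd_count", "hba_count")
GHOSE_FIELDS = ("mw", "logp", "refractivity", "atom_count")
VEBER_FIELDS = ("rotatable_bonds", "psa")


def _load_qed_params() -> dict[str, dict[str, float]]:
    raw = resources.files("spheropv.data").joinpath("qed_params.json").read_text()
    return json.loads(raw)["parameters"]


QED_PARAMETERS: dict[str, dict[str, float]] = _load_qed_params()


@dataclass(frozen=True)
class DruglikenessConfig:
    """Configurable cutoffs for the four rules.

    ro5_max_violations defaults to 0: a drug matches the rule only with no
    violations; set 1 for the common "at most one violation" reading.
    qed_threshold dichotomizes drugs into QED-compliant vs not; 0.5 is the
    conventional mid-scale split and is configurable because no canonical
    cutoff exists.
    """

    ro5_max_violations: int = 0
    qed_threshold: float = 0.5


@dataclass
class DruglikenessProfile:
    drug_id: str
    ro5_violations: int | None = None
    ro5_pass: bool | None = None
    ghose_pass: bool | None = None
    veber_pass: bool | None = None
    qed_value: float | None = None
    qed_pass: bool | None = None
    per_rule_details: dict[str, list[str]] = field(default_factory=dict)


def evaluate_ro5(
    record: DrugDescriptorRecord, max_violations: int = 0
) -> tuple[int, bool, list[str]]:
    """Count Lipinski violations and decide pass/fail.

    Violations: mw > 500, logp > 5, hbd_count > 5, hba_count > 10 (strict
    inequalities).  Pass iff violations <= max_violations.
    """
    record.require(RO5_FIELDS)
    failed = []
    if record.mw > 500:
        failed.append(f"mw {record.mw} > 500")
    if record.logp > 5:
        failed.append(f"logp {record.logp} > 5")
    if record.hbd_count > 5:
        failed.append(f"hbd_count {record.hbd_count} > 5")
    if record.hba_count > 10:
        failed.append(f"hba_count {record.hba_count} > 10")
    n = len(failed)
    return n, n <= max_violations, failed


def evaluate_ghose(record: DrugDescriptorRecord) -> tuple[bool, list[str]]:
    """Ghose filter: 160<=mw<=480, -0.4<=logp<=5.6, 40<=MR<=130, 20<=atoms<=70 (inclusive)."""
    record.require(GHOSE_FIELDS)
    bounds = {
        "mw": (160.0, 480.0),
        "logp": (-0.4, 5.6),
        "refractivity": (40.0, 130.0),
        "atom_count": (20, 70),
    }
    failed = []
    for name, (lo, hi) in bounds.items():
        v = getattr(record, name)
        if v < lo:
            failed.append(f"{name} {v} below {lo}")
        elif v > hi:
            failed.append(f"{name} {v} above {hi}")
    return not failed, failed


def evaluate_veber(record: DrugDescriptorRecord) -> tuple[bool, list[str]]:
    """Veber's rule: rotatable_bonds <= 10 and psa <= 140 A^2 (inclusive)."""
    record.require(VEBER_FIELDS)
    failed = []
    if record.rotatable_bonds > 10:
        failed.append(f"rotatable_bonds {record.rotatable_bonds} > 10")
    if record.psa > 140:
        failed.append(f"psa {record.psa} > 140")
    return not failed, failed


def desirability(descriptor: str, x: float) -> float:
    """Max-normalized asymmetric double-sigmoid desirability d(x) in (0, 1]."""
    p = QED_PARAMETERS[descriptor]
    e1 = 1.0 + math.exp(-(x - p["c"] + p["d"] / 2.0) / p["e"])
    e2 = 1.0 + math.exp(-(x - p["c"] - p["d"] / 2.0) / p["f"])
    d = p["a"] + p["b"] / e1 * (1.0 - 1.0 / e2)
    return d / p["dmax"]


def compute_qed_unweighted(record: DrugDescriptorRecord) -> float:
    """Equal-weight geometric mean of the eight descriptor desirabilities.

    All eight descriptors must be present; a subset QED would silently
    change the statistic and is refused.
    """
    record.require([QED_FIELDS[k] for k in QED_PARAMETERS])
    logs = []
    for name in QED_PARAMETERS:
        d = desirability(name, float(getattr(record, QED_FIELDS[name])))
        if not (d > 0.0 and math.isfinite(d)):
            raise NumericalError(
                f"{record.drug_id}: non-positive desirability for {name}"
            )
        logs.append(math.log(d))
    return math.exp(sum(logs) / len(logs))


def profile_drug(
    record: DrugDescriptorRecord, config: DruglikenessConfig | None = None
) -> DruglikenessProfile:
    """Evaluate all four rules, tolerating per-rule missing descriptors.

    A rule whose inputs are absent is marked ``None`` ("not evaluable") and
    recorded in per_rule_details; the remaining rules are still evaluated.
    """
    config = config or DruglikenessConfig()
    prof = DruglikenessProfile(drug_id=record.drug_id)

    try:
        n, ok, failed = evaluate_ro5(record, config.ro5_max_violations)
        prof.ro5_violations, prof.ro5_pass = n, ok
        if failed:
            prof.per_rule_details["ro5"] = failed
    except MissingDataError as e:
        prof.per_rule_details["ro5"] = [f"not evaluable: {e}"]

    try:
        ok, failed = evaluate_ghose(record)
        prof.ghose_pass = ok
        if failed:
            prof.per_rule_details["ghose"] = failed
    except MissingDataError as e:
        prof.per_rule_details["ghose"] = [f"not evaluable: {e}"]

    try:
        ok, failed = evaluate_veber(record)
        prof.veber_pass = ok
        if failed:
            prof.per_rule_details["veber"] = failed
    except MissingDataError as e:
        prof.per_rule_details["veber"] = [f"not evaluable: {e}"]

    try:
        q = compute_qed_unweighted(record)
        prof.qed_value = q
        prof.qed_pass = q >= config.qed_threshold
        if not prof.qed_pass:
            prof.per_rule_details["qed"] = [
                f"qed {q:.4f} below threshold {config.qed_threshold}"
            ]
    except MissingDataError as e:
        prof.per_rule_details["qed"] = [f"not evaluable: {e}"]

    return prof


def profile_table(
    records: Iterable[DrugDescriptorRecord],
    config: DruglikenessConfig | None = None,
) -> pd.DataFrame:
    """One profile row per drug: drug_id, ro5_violations, ro5_pass, ghose_pass, veber_pass, qed_value, qed_pass."""
    rows = []
    for rec in records:
        p = profile_drug(rec, config)
        rows.append(
            {
                "drug_id": p.drug_id,
                "ro5_violations": p.ro5_violations,
                "ro5_pass": p.ro5_pass,
                "ghose_pass": p.ghose_pass,
                "veber_pass": p.veber_pass,
                "qed_value": p.qed_value,
                "qed_pass": p.qed_pass,
            }
        )
    return pd.DataFrame(rows)


def rule_labels(
    profiles: pd.DataFrame, rule: str
) -> Mapping[str, bool]:
    """Extract a drug_id -> pass mapping for one rule column of a profile table."""
    col = {"ro5": "ro5_pass", "ghose": "ghose_pass",
           "veber": "veber_pass", "qed": "qed_pass"}[rule]
    return dict(zip(profiles["drug_id"], profiles[col]))
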