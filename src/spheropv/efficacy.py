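"""Spheroid viability, drug efficacy and the permeability value (PV).

Drug efficacy in a spheroid is one minus viability, with viability the
treated/control luminescence ratio of an ATP assay:

    efficacy = 1 - signal_treated / signal_control

computed per spheroid composition: the multicellular stromal/cancer
co-culture (A:M), the stromal-only monoculture (ASC) and the cancer-only
monoculture (MDA).  The permeability value compares the co-culture response
with the mean monoculture response:

    PV = Eff_A:M - (Eff_ASC + Eff_MDA) / 2

A low PV means the multicellular architecture blocked drug penetration.
Efficacies and PVs are stored as *fractions*, rendered as percent only in
reports; negative efficacies (growth under treatment) are retained with a
warning rather than clipped, since clipping would bias the downstream
regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    MeasurementError,
    PairingError,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

COMPOSITIONS = ("multicellular_AM", "mono_ASC", "mono_MDA")


@dataclass(frozen=True)
class ViabilityMeasurement:
    """One well pair (treated + matched same-composition control)."""

    drug_id: str
    composition: str
    replicate: int
    signal_treated: float
    signal_control: float
    concentration: float | None = None

    def __post_init__(self):
        if self.composition not in COMPOSITIONS:
            raise ValidationError(
                f"composition must be one of {COMPOSITIONS}, got {self.composition!r}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        if self.signal_treated < 0:
            raise MeasurementError(
                f"{self.drug_id}/{self.composition}: negative treated signal"
            )
        if not self.signal_control > 0:
            raise MeasurementError(
                f"{self.drug_id}/{self.composition}: control signal must be > 0"
            )


@dataclass(frozen=True)
class EfficacyResult:
    drug_id: str
    composition: str
    replicate: int
    viability: float
    efficacy: float


@dataclass(frozen=True)
class PermeabilityValue:
    drug_id: str
    replicate: int | None
    pv: float


def compute_efficacy(m: ViabilityMeasurement) -> EfficacyResult:
    """Efficacy = 1 - treated/control; negative values kept with a warning."""
    viability = m.signal_treated / m.signal_control
    efficacy = 1.0 - viability
    if efficacy < 0:
        warnings.warn(
            f"{m.drug_id}/{m.composition}/rep{m.replicate}: growth under "
            f"treatment (efficacy {efficacy:.3f} < 0); value retained",
            stacklevel=2,
        )
    return EfficacyResult(m.drug_id, m.composition, m.replicate, viability, efficacy)


def compute_pv(eff_am, eff_asc, eff_mda) -> float:
    """PV = Eff_A:M - (Eff_ASC + Eff_MDA)/2.

    Accepts plain fractions or :class:`EfficacyResult` objects; with result
    objects the drug and replicate must match across the triple.
    """
    vals = []
    keys = []
    for e, comp in zip((eff_am, eff_asc, eff_mda), COMPOSITIONS):
        if isinstance(e, EfficacyResult):
            if e.composition != comp:
                raise PairingError(
                    f"expected composition {comp}, got {e.composition}"
                )
            keys.append((e.drug_id, e.replicate))
            vals.append(e.efficacy)
        else:
            vals.append(float(e))
    if keys and len(set(keys)) != 1:
        raise PairingError(f"mismatched (drug_id, replicate) across triple: {keys}")
    return vals[0] - 0.5 * (vals[1] + vals[2])


def efficacies_to_frame(effs: Iterable[EfficacyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": e.drug_id,
                "composition": e.composition,
                "replicate": e.replicate,
                "viability": e.viability,
                "efficacy": e.efficacy,
            }
            for e in effs
        ]
    )


def build_pv_table(
    efficacies: Sequence[EfficacyResult] | pd.DataFrame,
    aggregation: str = "replicate",
) -> pd.DataFrame:
    """Combine composition triples into PVs.

    aggregation="replicate": one PV per (drug, replicate) — with d drugs and
    r replicates the output has exactly d*r rows (the screen design of 16
    drugs x 3 replicates gives 48).  aggregation="mean": replicate
    efficacies are averaged per composition first, one PV per drug.

    Raises a pairing error naming every missing (drug, composition,
    replicate) cell if any triple is incomplete.
    """
    if aggregation not in ("replicate", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = efficacies if isinstance(efficacies, pd.DataFrame) else efficacies_to_frame(efficacies)
    if df.empty:
        raise InsufficientDataError("no efficacy results supplied")

    dup = df.duplicated(subset=["drug_id", "composition", "replicate"])
    if dup.any():
        raise ValidationError(
            f"duplicate (drug, composition, replicate) rows: "
            f"{df.loc[dup, ['drug_id', 'composition', 'replicate']].to_records(index=False)}"
        )

    # completeness: every drug must have all three compositions per replicate used
    missing = []
    for drug, g in df.groupby("drug_id", sort=False):
        reps = sorted(g["replicate"].unique())
        have = {(c, r) for c, r in zip(g["composition"], g["replicate"])}
        for r in reps:
            for c in COMPOSITIONS:
                if (c, r) not in have:
                    missing.append((drug, c, int(r)))
    if missing:
        raise PairingError(f"incomplete composition triples; missing cells: {missing}")

    wide = df.pivot(index=["drug_id", "replicate"], columns="composition", values="efficacy")
    if aggregation == "mean":
        wide = wide.groupby(level="drug_id", sort=False).mean()
        pv = wide["multicellular_AM"] - 0.5 * (wide["mono_ASC"] + wide["mono_MDA"])
        out = pv.reset_index().rename(columns={0: "pv"})
        out.columns = ["drug_id", "pv"]
        return out
    pv = wide["multicellular_AM"] - 0.5 * (wide["mono_ASC"] + wide["mono_MDA"])
    out = pv.reset_index()
    out.columns = ["drug_id", "replicate", "pv"]
    return out


@dataclass
class GroupComparison:
    """Two-sample comparison of PVs split by a boolean per-drug label."""

    label_name: str
    n_true: int
    n_false: int
    mean_true: float
    mean_false: float
    se_true: float
    se_false: float
    t_statistic: float
    p_value: float
    test: str
    n_dropped: int = 0
    degenerate_variance: bool = False


def compare_pv_groups(
    pv_table: pd.DataFrame,
    labels: Mapping[str, bool],
    test: str = "student",
    label_name: str = "label",
) -> GroupComparison:
    """Unpaired two-sample t-test on PVs grouped by a per-drug boolean label.

    test="student" is the classical equal-variance t-test; "welch" drops the
    equal-variance assumption.  PV rows for drugs absent from ``labels`` are
    dropped with a logged count.  Zero pooled variance with distinct means
    is reported as a degenerate-variance case (|t| = inf, p = 0) rather than
    NaN.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    if "pv" not in pv_table.columns or "drug_id" not in pv_table.columns:
        raise SchemaError("pv_table must have columns drug_id and pv")
    mask = pv_table["drug_id"].isin(labels.keys())
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("compare_pv_groups: dropped %d unlabeled PV rows", n_dropped)
    sub = pv_table[mask]
    lab = sub["drug_id"].map(dict(labels)).astype(bool)
    a = sub.loc[lab, "pv"].to_numpy(float)     # label True
    b = sub.loc[~lab, "pv"].to_numpy(float)    # label False
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 observations (got {len(a)} / {len(b)})"
        )
    degenerate = False
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math_inf_signed(a.mean() - b.mean())
            p = 0.0
            degenerate = True
    else:
        res = stats.ttest_ind(a, b, equal_var=(test == "student"))
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        label_name=label_name,
        n_true=len(a),
        n_false=len(b),
        mean_true=float(a.mean()),
        mean_false=float(b.mean()),
        se_true=float(stats.sem(a)) if len(a) > 1 else float("nan"),
        se_false=float(stats.sem(b)) if len(b) > 1 else float("nan"),
        t_statistic=t,
        p_value=p,
        test=test,
        n_dropped=n_dropped,
        degenerate_variance=degenerate,
    )


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def anova_pv_groups(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA across >= 3 groups (F statistic, p-value).

    Pairwise follow-ups, when needed, use Bonferroni-corrected unpaired
    t-tests via :func:`compare_pv_groups` on each pair.
    """
    if len(groups) < 3:
        raise InsufficientDataError("ANOVA needs at least 3 groups")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# table I/O

VIABILITY_COLUMNS = ("drug_id", "composition", "replicate",
                     "signal_treated", "signal_control")


def load_viability_table(path: str | Path) -> list[ViabilityMeasurement]:
    """Read a delimited viability table (one treated/control pair per row)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in VIABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ViabilityMeasurement(
                drug_id=str(row["drug_id"]),
                composition=str(row["composition"]),
                replicate=int(row["replicate"]),
                signal_treated=float(row["signal_treated"]),
                signal_control=float(row["signal_control"]),
                concentration=float(row["concentration"])
                if "concentration" in df.columns and pd.notna(row.get("concentration"))
                else None,
            )
        )
    keys = [(m.drug_id, m.composition, m.replicate) for m in out]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (drug, composition, replicate) rows")
    return out


def write_viability_table(
    measurements: Sequence[ViabilityMeasurement], path: str | Path
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        [
            {
                "drug_id": m.drug_id,
                "composition": m.composition,
                "replicate": m.replicate,
                "signal_treated": m.signal_treated,
                "signal_control": m.signal_control,
                "concentration": m.concentration,
            }
            for m in measurements
        ]
    ).to_csv(path, sep=sep, index=False)
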