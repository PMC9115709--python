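"""Predicted PAMPA permeability and Caco-2 class handling.

The parallel artificial membrane permeability assay (PAMPA) outcome is
predicted from four descriptors by a published linear model on the
log10(cm/s) permeability scale:

    logP_PAMPA = 0.42*logP - 0.26*|pKa - pH| - 1.11*SA_HA - 1.01*SA_HD - 4.93

where SA_HA and SA_HD are the fractions of molecular surface area occupied
by hydrogen-bond acceptor and donor atoms.  Drugs below a threshold of
-6.14 (strict "less than") are classed low-permeability.

Caco-2 monolayer permeability classes are *ingested* annotations (the
original study read them from external ADMET predictions); they are never
computed or imputed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_data import DrugDescriptorRecord
from .errors import NumericalError, ValidationError

# Linear-model constants (log10 cm/s scale).
PAMPA_LOGP_COEF = 0.42
PAMPA_PKA_COEF = -0.26
PAMPA_SAHA_COEF = -1.11
PAMPA_SAHD_COEF = -1.01
PAMPA_INTERCEPT = -4.93

#: Default low/high-permeability cutoff on the logP_PAMPA scale.
DEFAULT_PAMPA_THRESHOLD = -6.14
#: Default working pH (physiological).
DEFAULT_PH = 7.4

CACO2_LABELS = frozenset({"permeable", "impermeable", "unknown"})


@dataclass
class PermeabilityEstimate:
    drug_id: str
    logp_pampa: float
    pampa_class: str
    caco2_class: str = "unknown"
    ph: float = DEFAULT_PH


def predict_pampa(record: DrugDescriptorRecord, ph: float = DEFAULT_PH) -> float:
    """Evaluate the four-descriptor PAMPA model at the given working pH."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"ph must lie in [0, 14], got {ph}")
    record.require(("logp", "pka", "sa_ha_fraction", "sa_hd_fraction"))
    return (
        PAMPA_LOGP_COEF * record.logp
        + PAMPA_PKA_COEF * abs(record.pka - ph)
        + PAMPA_SAHA_COEF * record.sa_ha_fraction
        + PAMPA_SAHD_COEF * record.sa_hd_fraction
        + PAMPA_INTERCEPT
    )


def classify_pampa(
    logp_pampa: float, threshold: float = DEFAULT_PAMPA_THRESHOLD
) -> str:
    """"low" iff logp_pampa < threshold (strict), else "high"."""
    if not math.isfinite(logp_pampa):
        raise NumericalError(f"non-finite logP_PAMPA: {logp_pampa}")
    return "low" if logp_pampa < threshold else "high"


def attach_caco2_labels(
    estimates: Sequence[PermeabilityEstimate],
    label_table: Mapping[str, str],
) -> list[PermeabilityEstimate]:
    """Attach permeable/impermeable Caco-2 labels; unmatched drugs stay "unknown".

    Labels outside the {permeable, impermeable} vocabulary raise a
    validation error — no coercion, no imputation.
    """
    for drug, label in label_table.items():
        if label not in ("permeable", "impermeable"):
            raise ValidationError(
                f"Caco-2 label for {drug!r} must be 'permeable' or "
                f"'impermeable', got {label!r}"
            )
    out = []
    for est in estimates:
        label = label_table.get(est.drug_id, "unknown")
        out.append(
            PermeabilityEstimate(
                drug_id=est.drug_id,
                logp_pampa=est.logp_pampa,
                pampa_class=est.pampa_class,
                caco2_class=label,
                ph=est.ph,
            )
        )
    return out


def permeability_table(
    records: Iterable[DrugDescriptorRecord],
    ph: float = DEFAULT_PH,
    threshold: float = DEFAULT_PAMPA_THRESHOLD,
    caco2_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-drug table: drug_id, logp_pampa, pampa_class, caco2_class, ph."""
    ests = []
    for rec in records:
        lp = predict_pampa(rec, ph=ph)
        ests.append(
            PermeabilityEstimate(
                drug_id=rec.drug_id,
                logp_pampa=lp,
                pampa_class=classify_pampa(lp, threshold),
                ph=ph,
            )
        )
    if caco2_labels is not None:
        ests = attach_caco2_labels(ests, caco2_labels)
    return pd.DataFrame(
        {
            "drug_id": [e.drug_id for e in ests],
            "logp_pampa": [e.logp_pampa for e in ests],
            "pampa_class": [e.pampa_class for e in ests],
            "caco2_class": [e.caco2_class for e in ests],
            "ph": [e.ph for e in ests],
        }
    )
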