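"""End-to-end run orchestration: configuration, stage wiring, reporting.

``run_pipeline`` executes the full screening analysis — descriptor
ingestion, drug-likeness profiling, PAMPA prediction, viability ->
efficacy -> PV, stratified group comparisons, the QSAR fit with stepwise
selection, the 80/20 split and k-fold cross-validation — writing every
stage's table plus a machine-readable metadata record into one run
directory.  Text tables are written at 6 significant digits; model and
metadata JSON keep full precision.  One top-level seed fans out to
deterministic per-stage sub-seeds, so two runs with identical config and
inputs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem_data, druglikeness, efficacy, permeability, qsar
from .errors import InsufficientDataError, ReportingError, SpheroPVError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly through YAML."""

    descriptor_table: str
    viability_table: str
    output_dir: str
    caco2_labels: str | None = None
    seed: int = 0
    ph: float = permeability.DEFAULT_PH
    pampa_threshold: float = permeability.DEFAULT_PAMPA_THRESHOLD
    ro5_max_violations: int = 0
    qed_threshold: float = 0.5
    stepwise_criterion: str = "p_enter"
    p_enter: float = 0.05
    cv_folds: int = 5
    aggregation: str = "replicate"
    schema_policy: str = "strict"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sub_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0] % (2**31))


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _comparison_entry(pv_table, labels, name, test="student"):
    try:
        c = efficacy.compare_pv_groups(pv_table, labels, test=test, label_name=name)
        d = asdict(c)
        d["status"] = "ok"
        return d
    except InsufficientDataError as e:
        return {"label_name": name, "status": "not_evaluable", "reason": str(e)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error propagates (wrapped with the stage name); group
    comparisons that are not evaluable on the given data (a one-sided
    stratification, for instance) are recorded as such in the comparisons
    artifact instead of aborting the run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    flags: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except SpheroPVError as e:
                raise type(e)(f"[stage {name}] {e}") from e
        return deco

    # --- descriptors -------------------------------------------------------
    @stage("descriptors")
    def records():
        return chem_data.load_descriptor_table(
            config.descriptor_table, schema_policy=config.schema_policy
        )

    counts["descriptors"] = len(records)
    _write_table(chem_data.records_to_frame(records), out / "descriptors.csv")
    warnings_map = chem_data.validate_descriptor_ranges(records)
    (out / "descriptor_warnings.json").write_text(json.dumps(warnings_map, indent=2))

    # --- drug-likeness -----------------------------------------------------
    @stage("druglikeness")
    def profiles():
        cfg = druglikeness.DruglikenessConfig(
            ro5_max_violations=config.ro5_max_violations,
            qed_threshold=config.qed_threshold,
        )
        return druglikeness.profile_table(records, cfg)

    counts["druglikeness"] = len(profiles)
    _write_table(profiles, out / "druglikeness.csv")
    flags.append(
        "druglikeness: Ro5 'match' uses max_violations="
        f"{config.ro5_max_violations}; QED split at {config.qed_threshold} "
        "(no canonical cutoff exists)"
    )

    # --- permeability ------------------------------------------------------
    caco2 = None
    if config.caco2_labels:
        tbl = pd.read_csv(config.caco2_labels)
        caco2 = dict(zip(tbl["drug_id"].astype(str), tbl["caco2_class"].astype(str)))

    @stage("permeability")
    def perm():
        return permeability.permeability_table(
            records, ph=config.ph, threshold=config.pampa_threshold, caco2_labels=caco2
        )

    counts["permeability"] = len(perm)
    _write_table(perm, out / "permeability.csv")

    # --- efficacy / PV -----------------------------------------------------
    @stage("efficacy_pv")
    def pv_tables():
        measurements = efficacy.load_viability_table(config.viability_table)
        effs = [efficacy.compute_efficacy(m) for m in measurements]
        eff_df = efficacy.efficacies_to_frame(effs)
        pv_rep = efficacy.build_pv_table(eff_df, aggregation="replicate")
        pv_mean = efficacy.build_pv_table(eff_df, aggregation="mean")
        return eff_df, pv_rep, pv_mean

    eff_df, pv_rep, pv_mean = pv_tables
    counts["viability_rows"] = len(eff_df)
    counts["pv_replicate_rows"] = len(pv_rep)
    _write_table(eff_df, out / "efficacy.csv")
    _write_table(pv_rep, out / "pv_replicate.csv")
    _write_table(pv_mean, out / "pv_mean.csv")
    n_neg = int((eff_df["efficacy"] < 0).sum())
    if n_neg:
        flags.append(f"efficacy: {n_neg} negative efficacies retained (growth under treatment)")

    pv_for_groups = pv_rep if config.aggregation == "replicate" else pv_mean

    # --- group comparisons -------------------------------------------------
    comparisons = {}
    pampa_labels = dict(zip(perm["drug_id"], perm["pampa_class"] == "high"))
    comparisons["pampa_high_vs_low"] = _comparison_entry(
        pv_for_groups, pampa_labels, "pampa_high_vs_low"
    )
    caco_known = perm[perm["caco2_class"] != "unknown"]
    caco_labels = dict(zip(caco_known["drug_id"], caco_known["caco2_class"] == "permeable"))
    if caco_labels:
        comparisons["caco2_permeable_vs_impermeable"] = _comparison_entry(
            pv_for_groups, caco_labels, "caco2_permeable_vs_impermeable"
        )
    else:
        comparisons["caco2_permeable_vs_impermeable"] = {
            "label_name": "caco2_permeable_vs_impermeable",
            "status": "not_evaluable",
            "reason": "no Caco-2 labels supplied",
        }
    for rule in ("ro5", "ghose", "veber", "qed"):
        labels = druglikeness.rule_labels(profiles, rule)
        labels = {k: v for k, v in labels.items() if v is not None}
        comparisons[f"{rule}_pass_vs_fail"] = _comparison_entry(
            pv_for_groups, labels, f"{rule}_pass_vs_fail"
        )
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))

    # --- QSAR --------------------------------------------------------------
    design = pv_for_groups.merge(
        chem_data.records_to_frame(records)[["drug_id", *chem_data.QSAR_DESCRIPTORS]],
        on="drug_id",
        validate="many_to_one",
    )
    flags.append(
        f"qsar: regression input is {config.aggregation}-level PVs "
        f"({len(design)} rows; the replicate-level reading of the screen design)"
    )

    @stage("qsar_fit")
    def models():
        full = qsar.fit_ols(design)
        step = qsar.forward_stepwise(
            design, criterion=config.stepwise_criterion, p_enter=config.p_enter
        )
        return full, step

    full_model, step_model = models
    full_model.to_json(out / "qsar_full_model.json")
    step_model.to_json(out / "qsar_stepwise_model.json")
    _write_table(qsar.significance_summary(full_model), out / "qsar_significance.csv")
    residuals = design[["drug_id"] + (["replicate"] if "replicate" in design else [])].copy()
    residuals["pv"] = design["pv"]
    residuals["pv_predicted"] = qsar.predict(full_model, design)
    residuals["residual"] = residuals["pv"] - residuals["pv_predicted"]
    _write_table(residuals, out / "qsar_residuals.csv")

    @stage("qsar_split")
    def split_result():
        plan = qsar.split_pareto(list(design.index), seed=_sub_seed(config.seed, 10))
        train = design.loc[list(plan.training_ids)]
        val = design.loc[list(plan.validation_ids)]
        m = qsar.fit_ols(train)
        r2_t, rmse_t = qsar.evaluate(m, train)
        r2_v, rmse_v = qsar.evaluate(m, val)
        return {
            "seed": plan.seed,
            "n_training": len(plan.training_ids),
            "n_validation": len(plan.validation_ids),
            "training_r2": r2_t,
            "training_rmse": rmse_t,
            "validation_r2": r2_v,
            "validation_rmse": rmse_v,
        }

    (out / "split_evaluation.json").write_text(json.dumps(split_result, indent=2))

    @stage("qsar_crossval")
    def cv():
        return qsar.cross_validate(design, k=config.cv_folds,
                                   seed=_sub_seed(config.seed, 11))

    (out / "cv_report.json").write_text(
        json.dumps({k: v for k, v in asdict(cv).items() if k != "fold_assignments"},
                   indent=2)
    )

    # --- metadata ----------------------------------------------------------
    metadata = {
        "spheropv_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "row_counts": counts,
        "flags": flags,
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return out


REQUIRED_ARTIFACTS = (
    "descriptors.csv", "druglikeness.csv", "permeability.csv", "efficacy.csv",
    "pv_replicate.csv", "comparisons.json", "qsar_full_model.json",
    "qsar_stepwise_model.json", "split_evaluation.json", "cv_report.json",
    "run_metadata.json",
)


def write_report(run_dir: str | Path) -> Path:
    """Assemble a human-readable summary of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise ReportingError(f"incomplete run; missing artifact(s): {', '.join(missing)}")

    meta = json.loads((run_dir / "run_metadata.json").read_text())
    comparisons = json.loads((run_dir / "comparisons.json").read_text())
    split = json.loads((run_dir / "split_evaluation.json").read_text())
    cv = json.loads((run_dir / "cv_report.json").read_text())
    full = qsar.QsarModel.from_json(run_dir / "qsar_full_model.json")
    step = qsar.QsarModel.from_json(run_dir / "qsar_stepwise_model.json")

    lines = []
    lines.append("spheropv run report")
    lines.append("=" * 60)
    lines.append(f"package version : {meta['spheropv_version']}")
    lines.append(f"seed            : {meta['seed']}")
    lines.append(f"row counts      : {meta['row_counts']}")
    lines.append("")
    lines.append("Group comparisons (PV by label; unpaired t-test)")
    lines.append("-" * 60)
    for name, c in comparisons.items():
        if c.get("status") != "ok":
            lines.append(f"  {name}: NOT EVALUABLE ({c.get('reason')})")
            continue
        extra = "  [degenerate variance]" if c.get("degenerate_variance") else ""
        lines.append(
            f"  {name}: mean(true)={c['mean_true']:.4f}±{c['se_true']:.4f} "
            f"(n={c['n_true']}), mean(false)={c['mean_false']:.4f}±"
            f"{c['se_false']:.4f} (n={c['n_false']}), t={c['t_statistic']:.3f}, "
            f"p={c['p_value']:.3g}{extra}"
        )
    lines.append("")
    lines.append("QSAR model (all nine descriptors)")
    lines.append("-" * 60)
    lines.append(f"  intercept = {full.intercept:.4f}")
    for d in full.selected:
        p = full.p_values.get(d, float("nan"))
        star = " *" if p < 0.05 else ""
        lines.append(
            f"  {d:16s} coef={full.coefficients[d]: .4f}  "
            f"t={full.t_values.get(d, float('nan')): .3f}  p={p:.3g}{star}"
        )
    lines.append(f"  n={full.n_obs}  R2={full.r2:.4f}  RMSE={full.rmse:.4f}  "
                 f"overall p={full.overall_p:.3g}")
    lines.append(f"  stepwise selection order: {step.selection_order or '(none entered)'}")
    lines.append("")
    lines.append("80/20 split and cross-validation")
    lines.append("-" * 60)
    lines.append(
        f"  split {split['n_training']}/{split['n_validation']}: "
        f"training R2={split['training_r2']:.4f} RMSE={split['training_rmse']:.4f}; "
        f"validation R2={split['validation_r2']:.4f} RMSE={split['validation_rmse']:.4f}"
    )
    lines.append(
        f"  {cv['k']}-fold CV: training R2={cv['training_r2']:.4f} "
        f"RMSE={cv['training_rmse']:.4f}; validation R2={cv['validation_r2']:.4f} "
        f"RMSE={cv['validation_rmse']:.4f}"
    )
    lines.append("")
    if meta["flags"]:
        lines.append("Flags raised during the run")
        lines.append("-" * 60)
        for f in meta["flags"]:
            lines.append(f"  - {f}")
    text = "\n".join(lines) + "\n"
    path = run_dir / "report.txt"
    path.write_text(text)
    return path
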