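"""QSAR multiple linear regression of spheroid permeability values.

The model relates the permeability value (PV) of a drug to nine
physicochemical descriptors by ordinary least squares:

    PV_hat = a0 + b1*MW + b2*logP + b3*logS + b4*HBA + b5*HBD
                + b6*PSA + b7*RotB + b8*MR + b9*Polarizability

Descriptors enter untransformed, as tabulated.  Feature selection is
forward stepwise: starting from the intercept-only model, at each step the
candidate whose entry t-test has the smallest p-value joins the model if
that p-value is below ``p_enter`` (an AIC-improvement criterion is
available as an alternative).  Model quality is summarized by R², RMSE
(1/n convention, a plain root-mean-square of residuals), per-coefficient
t/p values and the overall F-test; generalization by a seeded 80/20
"Pareto" split and k-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem_data import QSAR_DESCRIPTORS, DrugDescriptorRecord
from .errors import (
    CollinearityError,
    InsufficientDataError,
    MissingDataError,
    SchemaError,
)

#: Reference coefficient set of the published spheroid-permeability QSAR fit
#: (intercept first); used as simulation ground truth by the synthetic-data
#: generator and available for prediction-only workflows.
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "intercept": 0.1235,
    "mw": 0.0036,
    "logp": 0.0309,
    "logs": 0.0340,
    "hba_count": -0.0005,
    "hbd_count": 0.0108,
    "psa": -0.0021,
    "rotatable_bonds": 0.0007,
    "refractivity": 0.0051,
    "polarizability": -0.0187,
}


@dataclass
class QsarModel:
    """A fitted (or externally supplied) linear PV model."""

    intercept: float
    coefficients: dict[str, float]
    selected: list[str]
    t_values: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    r2: float = float("nan")
    rmse: float = float("nan")
    n_obs: int = 0
    overall_p: float = float("nan")
    selection_order: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "QsarModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))

    @classmethod
    def from_reference(cls) -> "QsarModel":
        coefs = {k: v for k, v in REFERENCE_COEFFICIENTS.items() if k != "intercept"}
        return cls(
            intercept=REFERENCE_COEFFICIENTS["intercept"],
            coefficients=coefs,
            selected=list(coefs),
        )


@dataclass(frozen=True)
class SplitPlan:
    training_ids: tuple
    validation_ids: tuple
    proportions: tuple[float, float]
    seed: int


@dataclass
class CvReport:
    k: int
    seed: int
    fold_assignments: dict
    fold_training_r2: list[float]
    fold_training_rmse: list[float]
    fold_validation_r2: list[float]
    fold_validation_rmse: list[float]
    training_r2: float
    training_rmse: float
    validation_r2: float
    validation_rmse: float
    pooled_validation_r2: float = float("nan")
    pooled_validation_rmse: float = float("nan")


def _design_matrix(
    design: pd.DataFrame, descriptors: Sequence[str], response: str
) -> tuple[np.ndarray, np.ndarray]:
    missing_cols = [c for c in list(descriptors) + [response] if c not in design.columns]
    if missing_cols:
        raise SchemaError(f"design table missing column(s): {', '.join(missing_cols)}")
    sub = design[list(descriptors) + [response]]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise MissingDataError(bad, context="design table has missing values")
    X = sub[list(descriptors)].to_numpy(float)
    y = sub[response].to_numpy(float)
    return X, y


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name columns that are linear combinations of their predecessors
        dependent = []
        for j in range(1, Xc.shape[1]):
            if np.linalg.matrix_rank(Xc[:, : j + 1]) == np.linalg.matrix_rank(Xc[:, :j]):
                dependent.append(names[j - 1])
        raise CollinearityError(dependent or list(names))


def fit_ols(
    design: pd.DataFrame,
    descriptors: Sequence[str] = QSAR_DESCRIPTORS,
    response: str = "pv",
) -> QsarModel:
    """Ordinary least squares of ``response`` on ``descriptors`` with intercept.

    RMSE is sqrt(SS_res / n) — the plain root-mean-square of residuals,
    without a degrees-of-freedom correction.
    """
    descriptors = list(descriptors)
    X, y = _design_matrix(design, descriptors, response)
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError(
            f"need more than {p + 1} observations for {p} descriptors, got {n}"
        )
    _check_rank(X, descriptors)
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    names = ["intercept"] + descriptors
    params = dict(zip(names, map(float, res.params)))
    return QsarModel(
        intercept=params["intercept"],
        coefficients={k: params[k] for k in descriptors},
        selected=descriptors,
        t_values=dict(zip(names, map(float, res.tvalues))),
        p_values=dict(zip(names, map(float, res.pvalues))),
        std_errors=dict(zip(names, map(float, res.bse))),
        r2=float(res.rsquared),
        rmse=float(np.sqrt(res.ssr / n)),
        n_obs=int(n),
        overall_p=float(res.f_pvalue) if p > 0 else float("nan"),
    )


def predict(
    model: QsarModel,
    data: DrugDescriptorRecord | pd.DataFrame | Mapping[str, float],
) -> float | np.ndarray:
    """Evaluate the linear model on a record, mapping or design table."""
    if isinstance(data, pd.DataFrame):
        missing = [d for d in model.selected if d not in data.columns]
        if missing:
            raise MissingDataError(missing, context="prediction table")
        X = data[model.selected].to_numpy(float)
        if np.isnan(X).any():
            bad = [d for d in model.selected if data[d].isna().any()]
            raise MissingDataError(bad, context="prediction table")
        beta = np.array([model.coefficients[d] for d in model.selected])
        return model.intercept + X @ beta
    if isinstance(data, DrugDescriptorRecord):
        data.require(model.selected)
        values = {d: getattr(data, d) for d in model.selected}
    else:
        missing = [d for d in model.selected if data.get(d) is None]
        if missing:
            raise MissingDataError(missing, context="prediction input")
        values = {d: data[d] for d in model.selected}
    return model.intercept + sum(
        model.coefficients[d] * float(values[d]) for d in model.selected
    )


def forward_stepwise(
    design: pd.DataFrame,
    candidates: Sequence[str] = QSAR_DESCRIPTORS,
    criterion: str = "p_enter",
    p_enter: float = 0.05,
    response: str = "pv",
) -> QsarModel:
    """Forward stepwise descriptor selection.

    criterion="p_enter": at each step fit every one-term extension, pick the
    candidate with the smallest coefficient p-value and admit it if
    p < p_enter; stop otherwise.  criterion="aic": admit the candidate with
    the largest AIC improvement while AIC decreases.  The final model is a
    plain OLS refit on the selected set; the selection order is recorded.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if criterion not in ("p_enter", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    X, y = _design_matrix(design, candidates, response)
    n = len(y)

    selected: list[str] = []
    remaining = list(candidates)

    def _fit(cols: list[str]):
        idx = [candidates.index(c) for c in cols]
        M = sm.add_constant(X[:, idx], has_constant="add")
        return sm.OLS(y, M).fit()

    current = _fit([])
    while remaining:
        best = None
        for cand in remaining:
            if n <= len(selected) + 2:
                break
            trial_cols = selected + [cand]
            idx = [candidates.index(c) for c in trial_cols]
            Xc = np.column_stack([np.ones(n), X[:, idx]])
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                continue  # candidate collinear with current model
            trial = _fit(trial_cols)
            if criterion == "p_enter":
                score = float(trial.pvalues[-1])  # entering coefficient
            else:
                score = float(trial.aic)
            if best is None or score < best[0]:
                best = (score, cand, trial)
        if best is None:
            break
        score, cand, trial = best
        if criterion == "p_enter":
            if not score < p_enter:
                break
        else:
            if not trial.aic < current.aic:
                break
        selected.append(cand)
        remaining.remove(cand)
        current = trial

    if not selected:
        return QsarModel(
            intercept=float(y.mean()),
            coefficients={},
            selected=[],
            r2=0.0,
            rmse=float(np.sqrt(np.mean((y - y.mean()) ** 2))),
            n_obs=n,
        )
    model = fit_ols(design, selected, response=response)
    model.selection_order = list(selected)
    return model


def split_pareto(
    ids: Sequence, seed: int, proportions: tuple[float, float] = (0.8, 0.2)
) -> SplitPlan:
    """Seeded random 80/20 training/validation split.

    Validation size is floor(0.2 * n), so 48 records split into 39 training
    and 9 validation.
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 records to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.floor(proportions[1] * n))
    val = tuple(ids[i] for i in perm[:n_val])
    train = tuple(ids[i] for i in perm[n_val:])
    return SplitPlan(training_ids=train, validation_ids=val,
                     proportions=proportions, seed=seed)


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, float(np.sqrt(ss_res / len(y)))


def evaluate(
    model: QsarModel, design: pd.DataFrame, response: str = "pv"
) -> tuple[float, float]:
    """(R², RMSE) of a fitted model on an arbitrary design table."""
    yhat = np.asarray(predict(model, design), float)
    y = design[response].to_numpy(float)
    return _metrics(y, yhat)


def cross_validate(
    design: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    descriptors: Sequence[str] = QSAR_DESCRIPTORS,
    criterion: str | None = None,
    p_enter: float = 0.05,
    response: str = "pv",
) -> CvReport:
    """Seeded k-fold cross-validation.

    Rows are shuffled once under ``seed`` and cut into k disjoint folds
    whose sizes differ by at most one (n=48, k=5 gives {10,10,10,9,9}, i.e.
    38 or 39 training rows per fold).  For each fold the model is fitted on
    the complement — plain OLS on ``descriptors``, or forward stepwise when
    ``criterion`` is given — and R²/RMSE are evaluated on both partitions.
    Aggregates are unweighted means over folds; pooled metrics evaluate the
    concatenated out-of-fold predictions in one pass (less sensitive to
    small-fold noise than the per-fold mean).
    """
    n = len(design)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise InsufficientDataError(f"need k <= n, got n={n}, k={k}")
    # k = n is leave-one-out (single-row folds; per-fold R^2 undefined there,
    # pooled metrics remain meaningful)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    tr_r2, tr_rmse, va_r2, va_rmse = [], [], [], []
    assignments: dict = {}
    index = list(design.index)
    y_all = design[response].to_numpy(float)
    yhat_oof = np.empty(n)
    for fold_no, fold_idx in enumerate(folds):
        for i in fold_idx:
            assignments[index[i]] = fold_no
        mask = np.zeros(n, bool)
        mask[fold_idx] = True
        train_df = design.iloc[~mask]
        val_df = design.iloc[mask]
        if criterion is None:
            model = fit_ols(train_df, descriptors, response=response)
        else:
            model = forward_stepwise(train_df, descriptors, criterion=criterion,
                                     p_enter=p_enter, response=response)
        r2_t, rmse_t = evaluate(model, train_df, response)
        r2_v, rmse_v = evaluate(model, val_df, response)
        yhat_oof[mask] = np.asarray(predict(model, val_df), float)
        tr_r2.append(r2_t)
        tr_rmse.append(rmse_t)
        va_r2.append(r2_v)
        va_rmse.append(rmse_v)

    pooled_r2, pooled_rmse = _metrics(y_all, yhat_oof)
    return CvReport(
        k=k,
        seed=seed,
        fold_assignments=assignments,
        fold_training_r2=tr_r2,
        fold_training_rmse=tr_rmse,
        fold_validation_r2=va_r2,
        fold_validation_rmse=va_rmse,
        training_r2=float(np.mean(tr_r2)),
        training_rmse=float(np.mean(tr_rmse)),
        validation_r2=float(np.mean(va_r2)),
        validation_rmse=float(np.mean(va_rmse)),
        pooled_validation_r2=pooled_r2,
        pooled_validation_rmse=pooled_rmse,
    )


def significance_summary(model: QsarModel, alpha: float = 0.05) -> pd.DataFrame:
    """Per-descriptor coefficient table ordered by |t| descending.

    Columns: descriptor, coefficient, t, p, significant (two-tailed
    p < alpha).  A saturated zero-residual fit has no finite t statistics;
    such degenerate-variance coefficients are flagged rather than dropped.
    """
    rows = []
    for d in model.selected:
        t = model.t_values.get(d, float("nan"))
        p = model.p_values.get(d, float("nan"))
        rows.append(
            {
                "descriptor": d,
                "coefficient": model.coefficients[d],
                "t": t,
                "p": p,
                "significant": bool(np.isfinite(p) and p < alpha),
                "degenerate_variance": not np.isfinite(t),
            }
        )
    df = pd.DataFrame(
        rows, columns=["descriptor", "coefficient", "t", "p",
                       "significant", "degenerate_variance"]
    )
    if df.empty:
        return df
    return (
        df.reindex(df["t"].abs().sort_values(ascending=False, na_position="last").index)
        .reset_index(drop=True)
    )
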