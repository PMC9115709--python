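import numpy as np
import pandas as pd
import pytest

from spheropv import qsar
from spheropv.chem_data import QSAR_DESCRIPTORS
from spheropv.errors import CollinearityError, InsufficientDataError, MissingDataError


def _random_design(rng, n, p, beta=None, sigma=0.0, names=None):
    names = names or [f"x{i}" for i in range(p)]
    X = rng.normal(0.0, 1.0, (n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    y = 0.5 + X @ beta + rng.normal(0.0, sigma, n)
    df = pd.DataFrame(X, columns=names)
    df["pv"] = y
    return df, names


def _normal_equations(df, names, response="pv"):
    """Independent brute-force OLS oracle."""
    X = np.column_stack([np.ones(len(df)), df[names].to_numpy(float)])
    y = df[response].to_numpy(float)
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitOls:
    def test_exact_linear_data(self):
        mw = np.linspace(150, 900, 20)
        df = pd.DataFrame({"mw": mw, "pv": 0.1 + 0.002 * mw})
        m = qsar.fit_ols(df, ["mw"])
        assert m.intercept == pytest.approx(0.1, abs=1e-10)
        assert m.coefficients["mw"] == pytest.approx(0.002, abs=1e-10)
        assert m.r2 == pytest.approx(1.0, abs=1e-10)
        assert m.rmse == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n, p", [(10, 3), (30, 5), (200, 12)])
    def test_matches_normal_equations_oracle(self, n, p):
        rng = np.random.default_rng(n * 100 + p)
        df, names = _random_design(rng, n, p, beta=rng.normal(0, 1, p), sigma=0.3)
        m = qsar.fit_ols(df, names)
        oracle = _normal_equations(df, names)
        assert m.intercept == pytest.approx(oracle[0], abs=1e-8)
        for j, name in enumerate(names):
            assert m.coefficients[name] == pytest.approx(oracle[j + 1], abs=1e-8)

    def test_rmse_uses_plain_mean_square(self):
        rng = np.random.default_rng(3)
        df, names = _random_design(rng, 25, 2, beta=[1.0, -1.0], sigma=0.5)
        m = qsar.fit_ols(df, names)
        beta = _normal_equations(df, names)
        resid = df["pv"] - beta[0] - df[names].to_numpy() @ beta[1:]
        assert m.rmse == pytest.approx(float(np.sqrt(np.mean(resid**2))), abs=1e-10)

    def test_duplicate_column_is_collinearity_error(self):
        rng = np.random.default_rng(0)
        df, names = _random_design(rng, 20, 3)
        df["x_dup"] = df["x0"]
        with pytest.raises(CollinearityError, match="x_dup"):
            qsar.fit_ols(df, names + ["x_dup"])

    def test_too_few_rows(self):
        rng = np.random.default_rng(0)
        df, names = _random_design(rng, 4, 3)
        with pytest.raises(InsufficientDataError):
            qsar.fit_ols(df, names)

    def test_missing_values_refused(self):
        df = pd.DataFrame({"x0": [1.0, np.nan, 3.0], "pv": [1, 2, 3]})
        with pytest.raises(MissingDataError):
            qsar.fit_ols(df, ["x0"])


class TestPredict:
    def test_reference_model_at_origin_and_ones(self, make_record):
        model = qsar.QsarModel.from_reference()
        zeros = {d: 0.0 for d in QSAR_DESCRIPTORS}
        assert qsar.predict(model, zeros) == pytest.approx(0.1235)
        ones = {d: 1.0 for d in QSAR_DESCRIPTORS}
        # sum of the reference intercept and all nine coefficients
        assert qsar.predict(model, ones) == pytest.approx(0.1873, abs=1e-12)

    def test_unit_increase_changes_prediction_by_coefficient(self, make_record):
        model = qsar.QsarModel.from_reference()
        base = make_record()
        bumped = make_record(psa=base.psa + 1.0)
        delta = qsar.predict(model, bumped) - qsar.predict(model, base)
        assert delta == pytest.approx(model.coefficients["psa"], abs=1e-12)

    def test_missing_selected_descriptor(self, make_record):
        model = qsar.QsarModel.from_reference()
        rec = make_record()
        rec.polarizability = None
        with pytest.raises(MissingDataError, match="polarizability"):
            qsar.predict(model, rec)

    def test_json_round_trip(self, synthetic_design, tmp_path):
        m = qsar.fit_ols(synthetic_design)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = qsar.QsarModel.from_json(path)
        assert back == m


class TestForwardStepwise:
    def test_dominant_candidate_enters_first(self):
        rng = np.random.default_rng(11)
        df, names = _random_design(rng, 60, 9, beta=[2.0] + [0.0] * 8, sigma=0.2)
        m = qsar.forward_stepwise(df, names)
        assert m.selection_order[0] == "x0"
        # exhaustive single-step search agrees on the first entrant
        best = min(names, key=lambda c: qsar.fit_ols(df, [c]).p_values[c])
        assert best == "x0"

    def test_zero_p_enter_returns_intercept_only(self, synthetic_design):
        m = qsar.forward_stepwise(synthetic_design, p_enter=0.0)
        assert m.selected == []
        assert m.intercept == pytest.approx(float(synthetic_design["pv"].mean()))

    def test_forcing_all_candidates_equals_full_fit(self, synthetic_design):
        forced = qsar.forward_stepwise(synthetic_design, p_enter=1.0)
        full = qsar.fit_ols(synthetic_design)
        assert set(forced.selected) == set(QSAR_DESCRIPTORS)
        for d in QSAR_DESCRIPTORS:
            assert forced.coefficients[d] == pytest.approx(full.coefficients[d], abs=1e-10)

    def test_r2_non_decreasing_along_selection_path(self, synthetic_design):
        m = qsar.forward_stepwise(synthetic_design, p_enter=1.0)
        r2s = [
            qsar.fit_ols(synthetic_design, m.selection_order[: k + 1]).r2
            for k in range(len(m.selection_order))
        ]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_aic_criterion_runs(self, synthetic_design):
        m = qsar.forward_stepwise(synthetic_design, criterion="aic")
        assert isinstance(m.selected, list)


class TestSplit:
    def test_pareto_arithmetic(self):
        plan = qsar.split_pareto(list(range(48)), seed=0)
        assert len(plan.training_ids) == 39 and len(plan.validation_ids) == 9

    def test_exact_split_small(self):
        plan = qsar.split_pareto(list(range(10)), seed=5)
        assert len(plan.training_ids) == 8 and len(plan.validation_ids) == 2

    def test_deterministic_and_partitioning(self):
        ids = [f"r{i}" for i in range(48)]
        a = qsar.split_pareto(ids, seed=7)
        b = qsar.split_pareto(ids, seed=7)
        assert a == b
        assert set(a.training_ids) | set(a.validation_ids) == set(ids)
        assert set(a.training_ids) & set(a.validation_ids) == set()

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            qsar.split_pareto([1, 2, 3], seed=0)


class TestCrossValidate:
    def test_screen_fold_sizes(self, synthetic_design):
        rep = qsar.cross_validate(synthetic_design, k=5, seed=0)
        sizes = sorted(
            list(np.bincount([rep.fold_assignments[i] for i in synthetic_design.index]))
        )
        assert sizes == [9, 9, 10, 10, 10]  # training complements: 39/39/38/38/38

    def test_zero_noise_data_validates_perfectly(self):
        rng = np.random.default_rng(2)
        df, names = _random_design(rng, 40, 3, beta=[1.0, 2.0, -1.0], sigma=0.0)
        rep = qsar.cross_validate(df, k=5, seed=1, descriptors=names)
        assert rep.validation_r2 == pytest.approx(1.0, abs=1e-9)
        assert rep.validation_rmse == pytest.approx(0.0, abs=1e-9)

    def test_aggregates_are_fold_means(self, synthetic_design):
        rep = qsar.cross_validate(synthetic_design, k=5, seed=3)
        assert rep.training_rmse == pytest.approx(np.mean(rep.fold_training_rmse))
        assert rep.validation_r2 == pytest.approx(np.mean(rep.fold_validation_r2))

    def test_k_equals_n_reduces_to_leave_one_out(self):
        rng = np.random.default_rng(9)
        df, names = _random_design(rng, 14, 2, beta=[1.0, -0.5], sigma=0.4)
        rep = qsar.cross_validate(df, k=len(df), seed=0, descriptors=names)
        # direct leave-one-out oracle
        rmses = []
        for i in range(len(df)):
            train = df.drop(index=i)
            beta = _normal_equations(train, names)
            pred = beta[0] + df.loc[i, names].to_numpy(float) @ beta[1:]
            rmses.append(abs(df.loc[i, "pv"] - pred))
        assert rep.validation_rmse == pytest.approx(float(np.mean(rmses)), abs=1e-8)

    def test_pooled_out_of_fold_metrics_present(self, synthetic_design):
        rep = qsar.cross_validate(synthetic_design, k=5, seed=0)
        assert np.isfinite(rep.pooled_validation_r2)
        assert rep.pooled_validation_rmse > 0


class TestSignificance:
    def test_single_true_effect_is_flagged(self):
        """With one strong effect among nine candidates, it is flagged in >=95% of runs."""
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            df, names = _random_design(
                rng, 48, 9, beta=[1.0] + [0.0] * 8, sigma=0.1
            )
            m = qsar.fit_ols(df, names)
            summary = qsar.significance_summary(m)
            flagged = set(summary.loc[summary["significant"], "descriptor"])
            if "x0" in flagged:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_saturated_fit_reports_degeneracy_without_crashing(self):
        mw = np.linspace(100, 500, 12)
        df = pd.DataFrame({"mw": mw, "pv": 0.1 + 0.002 * mw})
        m = qsar.fit_ols(df, ["mw"])
        summary = qsar.significance_summary(m)
        assert len(summary) == 1  # zero-residual fit handled

    def test_flags_invariant_to_column_order(self, synthetic_design):
        a = qsar.fit_ols(synthetic_design, list(QSAR_DESCRIPTORS))
        b = qsar.fit_ols(synthetic_design, list(reversed(QSAR_DESCRIPTORS)))
        fa = qsar.significance_summary(a).set_index("descriptor")["significant"]
        fb = qsar.significance_summary(b).set_index("descriptor")["significant"]
        assert fa.sort_index().equals(fb.sort_index())

    def test_ordering_by_absolute_t(self, synthetic_design):
        s = qsar.significance_summary(qsar.fit_ols(synthetic_design))
        ts = s["t"].abs().to_numpy()
        assert all(ts[i] >= ts[i + 1] for i in range(len(ts) - 1))
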