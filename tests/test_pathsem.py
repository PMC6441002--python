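import itertools

import numpy as np
import pandas as pd
import pytest

from foodwebsem import (
    bootstrap_se,
    compare_models,
    effect_decomposition,
    fit_ml,
    implied_covariance,
    parse_model_spec,
    saturated_spec,
    simulate_sem_data,
    standardize,
)
from foodwebsem.pathsem import FitError, ModelSpecError
from foodwebsem.synthgen import theta_from_paths, unit_variance_theta

from conftest import frame


class TestStandardize:
    def test_three_point_column(self):
        out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out.values[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        out = standardize(pd.DataFrame({"x": rng.gamma(2, 2, size=50),
                                        "b": rng.integers(0, 2, size=50)}))
        assert out.values.mean(axis=0) == pytest.approx([0, 0], abs=1e-12)
        assert out.values.std(axis=0, ddof=1) == pytest.approx([1, 1], abs=1e-12)

    def test_constant_column_error_names_column(self):
        with pytest.raises(ValueError, match="aquatic"):
            standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0], "aquatic": [1, 1, 1]}))


class TestParseModelSpec:
    def test_single_equation(self):
        spec = parse_model_spec("y ~ x")
        assert spec.equations == (("y", ("x",)),)
        assert spec.exogenous == ("x",)
        assert spec.df == 0  # 3 moments - 3 free parameters

    def test_chain_with_comments(self):
        spec = parse_model_spec("# chain\ntemp ~ lat\nS ~ temp\n")
        assert spec.endogenous == ("temp", "S")
        assert spec.exogenous == ("lat",)

    def test_cycle_error_lists_cycle(self):
        with pytest.raises(ModelSpecError, match="a -> b|b -> a"):
            parse_model_spec("a ~ b\nb ~ a")

    def test_repeated_outcome_error(self):
        with pytest.raises(ModelSpecError, match="repeated"):
            parse_model_spec("y ~ x\ny ~ z")


class TestImpliedCovariance:
    def test_no_paths_identity(self):
        spec = parse_model_spec("y ~ x")
        theta = theta_from_paths(spec, {("y", "x"): 0.0})
        assert implied_covariance(spec, theta) == pytest.approx(np.eye(2))

    def test_single_regression_closed_form(self):
        spec = parse_model_spec("y ~ x")
        beta, phi, psi = 0.7, 2.0, 0.5
        theta = theta_from_paths(spec, {("y", "x"): beta},
                                 residual_var=psi, exog_var=phi)
        Sigma = implied_covariance(spec, theta)
        i = {v: k for k, v in enumerate(spec.variables)}
        assert Sigma[i["x"], i["x"]] == pytest.approx(phi)
        assert Sigma[i["y"], i["y"]] == pytest.approx(beta**2 * phi + psi)
        assert Sigma[i["x"], i["y"]] == pytest.approx(beta * phi)

    def test_monte_carlo_three_variable_chain(self):
        spec = parse_model_spec("m ~ x\ny ~ m")
        theta = unit_variance_theta(spec, {("m", "x"): 0.6, ("y", "m"): -0.4})
        X = simulate_sem_data(spec, theta, 1_000_000, seed=99)
        S = np.cov(X, rowvar=False, ddof=1)
        assert S == pytest.approx(implied_covariance(spec, theta), abs=0.01)


class TestFitML:
    def test_saturated_reproduces_sample_covariance(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 200, seed=1)
        sat = saturated_spec(spec.variables)
        fit = fit_ml(sat, standardize(frame(X, spec)))
        assert fit.F_ML == pytest.approx(0.0, abs=1e-10)
        assert fit.Sigma_model == pytest.approx(fit.S_sample, abs=1e-8)

    def test_single_regression_equals_pearson_r(self):
        spec = parse_model_spec("y ~ x")
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = 0.6 * x + rng.normal(size=80)
        data = standardize(pd.DataFrame({"x": x, "y": y}))
        fit = fit_ml(spec, data)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.coefficient("y", "x") == pytest.approx(r, abs=1e-6)
        assert fit.R2["y"] == pytest.approx(r**2, abs=1e-6)

    def test_ml_equals_ols_on_overidentified_model(self, mediation_model):
        spec, _, theta = mediation_model
        # drop two paths -> df = 2, ML must still equal per-equation OLS
        sub = parse_model_spec("m ~ x\nw ~ m\ny ~ m + w")
        X = simulate_sem_data(spec, theta, 150, seed=8)
        data = standardize(frame(X, spec))
        fit = fit_ml(sub, data)
        cols = {v: data.values[:, list(data.columns).index(v)] for v in spec.variables}
        for outcome, preds in sub.equations:
            Xp = np.column_stack([cols[p] for p in preds])
            beta = np.linalg.lstsq(Xp, cols[outcome], rcond=None)[0]
            for pr, b in zip(preds, beta):
                assert fit.coefficient(outcome, pr) == pytest.approx(b, abs=1e-6)

    def test_needs_more_rows_than_variables(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 30, seed=2)
        data = standardize(frame(X, spec))
        short = type(data)(columns=data.columns, values=data.values[:4],
                           means=data.means, sds=data.sds)
        with pytest.raises(FitError, match="n > p"):
            fit_ml(spec, short)

    def test_non_pd_sample_covariance_error(self):
        spec = parse_model_spec("y ~ x + z")
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "z": -x + np.arange(10) * 1e-18, "y": x})
        data = standardize(df)
        with pytest.raises(FitError, match="positive definite"):
            fit_ml(spec, data)


class TestFitIndices:
    def test_saturated_zero_point(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 120, seed=3)
        fit = fit_ml(saturated_spec(spec.variables), standardize(frame(X, spec)))
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.CFI == 1.0
        assert fit.RMSEA == 0.0
        assert fit.SRMR <= 1e-8
        assert fit.df_zero_conventions

    def test_nested_delta_aic_identity(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 90, seed=4)
        data = standardize(frame(X, spec))
        full = fit_ml(parse_model_spec("m ~ x\nw ~ x + m\ny ~ x + m + w"), data)
        restricted = fit_ml(parse_model_spec("m ~ x\nw ~ m\ny ~ m + w"), data)
        n = data.n
        d_aic = restricted.AIC - full.AIC
        d_chi2 = restricted.chi2 - full.chi2
        d_df = restricted.df - full.df
        assert d_aic == pytest.approx(d_chi2 * n / (n - 1) - 2 * d_df, abs=1e-8)

    def test_chi2_scale_switch(self, mediation_model):
        spec, _, theta = mediation_model
        sub = parse_model_spec("m ~ x\nw ~ m\ny ~ m + w")
        X = simulate_sem_data(spec, theta, 70, seed=6)
        data = standardize(frame(X, spec))
        wishart = fit_ml(sub, data)
        ml = fit_ml(sub, data, chi2_scale="N")
        assert ml.chi2 == pytest.approx(wishart.chi2 * data.n / (data.n - 1))


def enumerate_path_products(A):
    """Independent oracle: total effect as an explicit sum over all
    directed paths of the product of path coefficients."""
    p = A.shape[0]
    children = {j: [i for i in range(p) if A[i, j] != 0] for j in range(p)}
    total = np.zeros((p, p))
    for start in range(p):
        stack = [(start, 1.0)]
        while stack:
            node, prod = stack.pop()
            for nxt in children[node]:
                total[nxt, start] += prod * A[nxt, node]
                stack.append((nxt, prod * A[nxt, node]))
    return total


class TestEffects:
    def test_mediation_closed_form(self):
        spec = parse_model_spec("m ~ x\ny ~ m")
        a, b = 0.5, -0.4
        theta = unit_variance_theta(spec, {("m", "x"): a, ("y", "m"): b})
        X = simulate_sem_data(spec, theta, 500, seed=10)
        fit = fit_ml(spec, standardize(frame(X, spec)))
        tab = effect_decomposition(fit).set_index(["cause", "outcome"])
        row = tab.loc[("x", "y")]
        ahat = fit.coefficient("m", "x")
        bhat = fit.coefficient("y", "m")
        assert row["direct"] == 0.0
        assert row["indirect"] == pytest.approx(ahat * bhat, abs=1e-12)
        assert row["total"] == pytest.approx(ahat * bhat, abs=1e-12)

    def test_no_directed_path_means_no_effect(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 100, seed=11)
        fit = fit_ml(spec, standardize(frame(X, spec)))
        tab = effect_decomposition(fit)
        pairs = set(zip(tab["cause"], tab["outcome"]))
        assert ("y", "x") not in pairs  # effects only run downstream

    def test_matrix_formula_matches_path_enumeration(self):
        rng = np.random.default_rng(123)
        p = 7
        for _ in range(20):
            A = np.zeros((p, p))
            for j, i in itertools.combinations(range(p), 2):
                if rng.random() < 0.5:
                    A[i, j] = rng.uniform(-0.8, 0.8)  # lower-triangular: acyclic
            total = np.linalg.inv(np.eye(p) - A) - np.eye(p)
            oracle = enumerate_path_products(A)
            assert total == pytest.approx(oracle, abs=1e-10)


class TestBootstrap:
    def test_same_seed_identical_table(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 60, seed=12)
        data = standardize(frame(X, spec))
        t1 = bootstrap_se(spec, data, B=100, seed=77)
        t2 = bootstrap_se(spec, data, B=100, seed=77)
        pd.testing.assert_frame_equal(t1, t2)

    def test_se_close_to_analytic_ols_se(self):
        spec = parse_model_spec("y ~ x")
        theta = unit_variance_theta(spec, {("y", "x"): 0.5})
        X = simulate_sem_data(spec, theta, 200, seed=13)
        data = standardize(frame(X, spec))
        tab = bootstrap_se(spec, data, B=600, seed=14).set_index(["cause", "outcome"])
        r = float(np.corrcoef(data.values.T)[0, 1])
        analytic = np.sqrt((1 - r**2) / (200 - 2))
        se = tab.loc[("x", "y"), "se_direct"]
        assert abs(se - analytic) / analytic < 0.25

    def test_null_effect_type_one_error_rate(self):
        # true coefficient zero: the significance flag should fire ~5% of runs
        spec = parse_model_spec("y ~ x")
        theta = unit_variance_theta(spec, {("y", "x"): 0.0})
        hits = 0
        reps = 400
        for r in range(reps):
            X = simulate_sem_data(spec, theta, 100, seed=50_000 + r)
            data = standardize(frame(X, spec))
            tab = bootstrap_se(spec, data, B=120, seed=60_000 + r)
            row = tab.set_index(["cause", "outcome"]).loc[("x", "y")]
            hits += bool(row["sig_direct"])
        assert 0.02 <= hits / reps <= 0.09

    def test_requires_seed_and_minimum_replicates(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 60, seed=15)
        data = standardize(frame(X, spec))
        with pytest.raises(ValueError, match="seed"):
            bootstrap_se(spec, data, B=100)
        with pytest.raises(ValueError, match="100"):
            bootstrap_se(spec, data, B=50, seed=1)


class TestCompareModels:
    def test_identical_specs_tie_at_zero(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 80, seed=16)
        data = standardize(frame(X, spec))
        fit = fit_ml(spec, data)
        table = compare_models({"a": fit, "b": fit})
        assert list(table["dAIC"]) == [0.0, 0.0]

    def test_true_model_beats_null_under_strong_paths(self):
        spec = parse_model_spec("m ~ x\ny ~ x + m")
        theta = unit_variance_theta(
            spec, {("m", "x"): 0.5, ("y", "x"): 0.5, ("y", "m"): 0.5}
        )
        X = simulate_sem_data(spec, theta, 65, seed=17)
        data = standardize(frame(X, spec))
        null = parse_model_spec("m ~ x\ny ~ x + m")
        null_theta_spec = parse_model_spec("# same variables, no structure\n"
                                           "m ~ x\ny ~ m")
        fits = {"true": fit_ml(spec, data), "null": fit_ml(null_theta_spec, data)}
        table = compare_models(fits)
        assert table.iloc[0]["model"] == "true"

    def test_column_order(self, mediation_model):
        spec, _, theta = mediation_model
        X = simulate_sem_data(spec, theta, 80, seed=18)
        fit = fit_ml(spec, standardize(frame(X, spec)))
        table = compare_models({"m": fit})
        assert list(table.columns) == [
            "model", "chi2", "df", "p_value", "CFI", "RMSEA", "SRMR",
            "AGFI", "AIC", "dAIC",
        ]

    def test_mismatched_variable_sets_error(self):
        s1 = parse_model_spec("y ~ x")
        s2 = parse_model_spec("y ~ z")
        rng = np.random.default_rng(19)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x", "y", "z"])
        data = standardize(df)
        f1, f2 = fit_ml(s1, data), fit_ml(s2, data)
        with pytest.raises(ValueError, match="not comparable"):
            compare_models({"a": f1, "b": f2})
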