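"""Mixed-model machinery: design coding, quadrature accuracy, fitting, LRTs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from careload import simulate as sim
from careload.glmm import (FitOptions, GlmmError, ModelSpec, build_design,
                           fit_glmm, lr_test, marginal_loglik)
from careload.pipeline import behavior_spec


def brute_force_loglik(design, beta, sigma2, n_grid=10_001, half_width=10.0):
    """Trapezoid integration of the random intercept, group by group."""
    from scipy.special import gammaln

    eta0 = design.X @ beta
    s = np.sqrt(sigma2)
    b = np.linspace(-half_width * s, half_width * s, n_grid)
    total = 0.0
    f = design.factors[0]
    y, n = design.y, design.trials
    for g in range(f.n_levels):
        m = f.codes == g
        e = eta0[m][:, None] + b
        ll = (y[m][:, None] * e - n[m][:, None] * np.logaddexp(0, e)).sum(axis=0)
        dens = np.exp(ll) * np.exp(-b**2 / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)
        total += np.log(np.trapezoid(dens, b))
    total += float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    return total


class TestBuildDesign:
    def test_three_level_factor_gets_two_contrast_columns(self):
        df = pd.DataFrame({"y": [1, 2, 1], "n": [5, 5, 5],
                           "treatment": ["a", "b", "c"]})
        spec = ModelSpec("binomial", "y", ("treatment",), trials="n")
        d = build_design(spec, df)
        assert d.colnames == ["(Intercept)", "treatment[b]", "treatment[c]"]

    def test_degree2_poly_columns_orthonormal(self):
        df = pd.DataFrame({"y": np.arange(20) % 4, "n": np.full(20, 5),
                           "t": np.tile(np.arange(1, 6), 4)})
        spec = ModelSpec("binomial", "y", ("poly(t,2)",), trials="n")
        d = build_design(spec, df)
        P = d.X[:, 1:]
        gram = P.T @ P
        assert np.allclose(gram, np.eye(2), atol=1e-10)
        assert np.allclose(P.sum(axis=0), 0.0, atol=1e-10)

    def test_behavior_spec_three_way_interaction_has_df_4(self):
        tab = sim.gen_behavior(sim.BehaviorDesign(n_trials=3),
                               sim.BehaviorParams(), seed=0)
        spec = behavior_spec()
        d = build_design(spec, tab)
        assert len(d.term_columns["treatment:run:poly(time_index,2)"]) == 4
        assert len(d.term_columns["treatment:poly(run,2)"]) == 4
        assert len(d.term_columns["treatment"]) == 2

    def test_unknown_column_and_single_level_factor_raise(self):
        df = pd.DataFrame({"y": [1, 1], "n": [5, 5], "g": ["a", "a"]})
        with pytest.raises(GlmmError, match="unknown column"):
            build_design(ModelSpec("binomial", "y", ("zzz",), trials="n"), df)
        with pytest.raises(GlmmError, match="single level"):
            build_design(ModelSpec("binomial", "y", ("g",), trials="n"), df)

    def test_prediction_row_matches_design_row(self):
        df = pd.DataFrame({"y": [1, 2, 3], "n": [5, 5, 5],
                           "g": ["a", "b", "c"], "x": [0.0, 1.0, 2.0]})
        spec = ModelSpec("binomial", "y", ("g", "x", "g:x"), trials="n")
        d = build_design(spec, df)
        row = d.row({"g": "b", "x": 1.0})
        assert np.allclose(row, d.X[1])


class TestMarginalLoglik:
    def test_zero_variance_equals_glm_loglik(self, tiny_binomial_df):
        spec = ModelSpec("binomial", "y", ("x",), random=("g",), trials="n")
        d = build_design(spec, tiny_binomial_df)
        beta = np.array([0.2, 0.5])
        glm = sm.GLM(np.column_stack([d.y, d.trials - d.y]), d.X,
                     family=sm.families.Binomial())
        ll = marginal_loglik(spec, tiny_binomial_df,
                             {"beta": beta, "variances": [0.0]}, n_nodes=7)
        assert abs(ll - glm.loglike(beta)) < 1e-10

    @pytest.mark.parametrize("sigma2", [0.3, 1.0])
    def test_agq_matches_brute_force_integration(self, tiny_binomial_df, sigma2):
        spec = ModelSpec("binomial", "y", ("x",), random=("g",), trials="n")
        d = build_design(spec, tiny_binomial_df)
        beta = np.array([0.2, 0.5])
        oracle = brute_force_loglik(d, beta, sigma2)
        agq = marginal_loglik(spec, tiny_binomial_df,
                              {"beta": beta, "variances": [sigma2]}, n_nodes=15)
        assert abs(agq - oracle) < 1e-6

    def test_more_nodes_refine_toward_oracle(self, tiny_binomial_df):
        spec = ModelSpec("binomial", "y", ("x",), random=("g",), trials="n")
        d = build_design(spec, tiny_binomial_df)
        beta = np.array([0.2, 0.5])
        oracle = brute_force_loglik(d, beta, 1.0)
        params = {"beta": beta, "variances": [1.0]}
        err3 = abs(marginal_loglik(spec, tiny_binomial_df, params, 3) - oracle)
        err25 = abs(marginal_loglik(spec, tiny_binomial_df, params, 25) - oracle)
        assert err25 <= err3

    def test_nonfinite_predictor_names_offending_row(self, tiny_binomial_df):
        spec = ModelSpec("binomial", "y", ("x",), random=("g",), trials="n")
        with pytest.raises(GlmmError, match="row"):
            marginal_loglik(spec, tiny_binomial_df,
                            {"beta": [np.inf, 0.0], "variances": [0.1]})


def _simulate_groups(rng, n_groups, per_group, beta0, beta_x, sd):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sd)
        x = rng.normal(size=per_group)
        p = 1 / (1 + np.exp(-(beta0 + beta_x * x + b)))
        y = rng.binomial(8, p)
        for xi, yi in zip(x, y):
            rows.append((g, xi, yi, 8))
    return pd.DataFrame(rows, columns=["g", "x", "y", "n"])


class TestFitGlmm:
    spec = ModelSpec("binomial", "y", ("x",), random=("g",), trials="n")

    def test_recovers_generating_coefficients_within_3se(self):
        rng = np.random.default_rng(11)
        df = _simulate_groups(rng, 200, 5, beta0=-0.5, beta_x=0.8, sd=0.5)
        fit = fit_glmm(self.spec, df, FitOptions(n_nodes=11))
        assert fit.converged
        for name, truth in [("(Intercept)", -0.5), ("x", 0.8)]:
            assert abs(fit.params[name] - truth) < 3 * fit.se[name]
        assert abs(fit.variances["g"] - 0.25) < 0.15

    def test_zero_generating_variance_estimated_near_boundary(self):
        rng = np.random.default_rng(12)
        df = _simulate_groups(rng, 80, 5, beta0=0.3, beta_x=0.5, sd=0.0)
        fit = fit_glmm(self.spec, df, FitOptions(n_nodes=7))
        assert fit.variances["g"] < 0.05

    def test_loglik_invariant_to_row_permutation(self):
        rng = np.random.default_rng(13)
        df = _simulate_groups(rng, 30, 4, beta0=0.0, beta_x=0.5, sd=0.4)
        fit1 = fit_glmm(self.spec, df, FitOptions(n_nodes=9, compute_cov=False))
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_glmm(self.spec, shuffled,
                        FitOptions(n_nodes=9, compute_cov=False))
        assert abs(fit1.loglik - fit2.loglik) < 1e-8

    def test_empty_table_rejected(self):
        df = pd.DataFrame({"y": [], "n": [], "x": [], "g": []})
        with pytest.raises(GlmmError):
            fit_glmm(self.spec, df)


class TestLrTest:
    def _fits(self, seed=21, n_groups=40):
        rng = np.random.default_rng(seed)
        df = _simulate_groups(rng, n_groups, 4, beta0=0.2, beta_x=0.6, sd=0.3)
        spec_full = ModelSpec("binomial", "y", ("x",), random=("g",), trials="n")
        spec_red = spec_full.drop_terms(["x"])
        opts = FitOptions(n_nodes=9, compute_cov=False)
        return fit_glmm(spec_full, df, opts), fit_glmm(spec_red, df, opts), df

    def test_identical_models_give_zero_statistic_p_one(self):
        full, _, df = self._fits()
        t = lr_test(full, full)
        assert t.statistic == 0.0
        assert t.df == 0
        assert t.p_value == 1.0

    def test_dropping_treatment_by_run_interaction_has_df_4(self):
        tab = sim.gen_behavior(sim.BehaviorDesign(n_trials=6, obs_per_run=5),
                               sim.BehaviorParams(), seed=2)
        spec = behavior_spec()
        opts = FitOptions(n_nodes=5, compute_cov=False)
        full = fit_glmm(spec, tab, opts)
        red = fit_glmm(spec.drop_terms(["treatment:poly(run,2)"]), tab, opts)
        t = lr_test(full, red)
        assert t.df == 4
        red3 = fit_glmm(spec.drop_terms(["treatment:run:poly(time_index,2)"]),
                        tab, opts)
        assert lr_test(full, red3).df == 4

    def test_statistic_invariant_to_polynomial_coding(self):
        tab = sim.gen_behavior(sim.BehaviorDesign(n_trials=4, obs_per_run=5),
                               sim.BehaviorParams(), seed=3)
        tab = tab.copy()
        tab["t1"] = tab["time_index"].astype(float)
        tab["t2sq"] = tab["t1"] ** 2
        opts = FitOptions(n_nodes=5, compute_cov=False)

        def stat(time_terms):
            full = ModelSpec("binomial", "n_on_uninfested",
                             tuple(time_terms) + ("treatment",),
                             random=("trial_id",), trials="n_females")
            red = full.drop_terms(["treatment"])
            return lr_test(fit_glmm(full, tab, opts),
                           fit_glmm(red, tab, opts)).statistic

        s_orth = stat(["poly(time_index,2)"])
        s_raw = stat(["t1", "t2sq"])
        assert abs(s_orth - s_raw) < 1e-6

    def test_non_nested_models_rejected(self):
        full, red, df = self._fits()
        with pytest.raises(GlmmError, match="nested"):
            lr_test(red, full)
        other = ModelSpec("binomial", "y", ("x",), random=(), trials="n")
        fit_other = fit_glmm(other, df, FitOptions(n_nodes=1, compute_cov=False))
        with pytest.raises(GlmmError, match="random"):
            lr_test(full, fit_other)
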