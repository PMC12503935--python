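"""Selection arithmetic, posterior transforms, IGE covariance summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from careload import simulate as sim
from careload.mcmc import pmcmc
from careload.pipeline import egg_count_spec
from careload.selection import (SelectionError, care_survival_ellipse,
                                delta_omega, delta_omega_posterior,
                                expected_fitness, inbreeding_depression,
                                selection_coefficient, treatment_selection,
                                viability_at)
from conftest import make_posterior


class TestViabilityAt:
    def test_zero_coefficients_give_half_everywhere(self, survival_draw_maker):
        draws = survival_draw_maker([[0, 0, 0, 0, 0.1]] * 5)
        for c in (0, 3, 6):
            assert np.allclose(viability_at(draws, "inbred", c), 0.5)
            assert np.allclose(viability_at(draws, "outbred", c), 0.5)

    def test_hand_computed_inverse_logit(self, survival_draw_maker):
        # intercept 1.0, competition slope -0.3 at c = 6 -> logit^-1(-0.8)
        draws = survival_draw_maker([[1.0, 0.0, -0.3, 0.0, 0.1]] * 3)
        v = viability_at(draws, "inbred", 6)
        assert np.allclose(v, expit(-0.8))
        assert v[0] == pytest.approx(0.3100, abs=2e-4)

    def test_extreme_predictor_clamped_into_open_interval(self,
                                                          survival_draw_maker):
        draws = survival_draw_maker([[-40.0, 0.0, 0.0, 0.0, 0.1]])
        v = viability_at(draws, "inbred", 0)
        assert 0.0 < v[0] <= 1e-15 * 10

    def test_out_of_range_competition_rejected(self, survival_draw_maker):
        draws = survival_draw_maker([[0.5, 0, 0, 0, 0.1]])
        with pytest.raises(SelectionError, match="range"):
            viability_at(draws, "inbred", 7)


class TestDeltaOmega:
    @pytest.mark.parametrize("vi,vo,expected", [
        (0.8, 0.8, 0.0), (0.4, 0.8, 0.5), (0.9, 0.6, -0.5),
    ])
    def test_arithmetic(self, vi, vo, expected):
        assert delta_omega(vi, vo) == pytest.approx(expected)

    def test_zero_outbred_viability_rejected(self):
        with pytest.raises(SelectionError):
            delta_omega(0.5, 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(vi=st.floats(0.01, 0.99), vo=st.floats(0.01, 0.99),
           k=st.floats(0.1, 10))
    def test_scale_invariance(self, vi, vo, k):
        assert delta_omega(k * vi, k * vo) == pytest.approx(delta_omega(vi, vo))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(vo=st.floats(0.2, 0.99), lo=st.floats(0.01, 0.5),
           hi=st.floats(0.51, 0.99))
    def test_strictly_decreasing_in_inbred_viability(self, vo, lo, hi):
        assert delta_omega(hi * vo, vo) < delta_omega(lo * vo, vo)

    def test_posterior_zero_width_when_crosses_identical(self,
                                                         survival_draw_maker):
        draws = survival_draw_maker([[1.2, 0.0, -0.4, 0.0, 0.1]] * 10)
        est = delta_omega_posterior(draws, 2)
        assert est.mean == pytest.approx(0.0)
        assert est.ci_low == est.ci_high == pytest.approx(0.0)

    def test_constructed_viabilities_016_020_give_exactly_020(
            self, survival_draw_maker):
        # inbred v = 0.16, outbred v = 0.20 at every draw and C = 0
        rows = [[logit(0.16), logit(0.20) - logit(0.16), 0.0, 0.0, 0.1]] * 8
        est = delta_omega_posterior(survival_draw_maker(rows), 0)
        assert est.mean == pytest.approx(0.20, abs=1e-12)

    def test_ordering_follows_negative_interaction_drawwise(
            self, survival_draw_maker):
        rng = np.random.default_rng(5)
        rows = np.column_stack([
            rng.normal(0.9, 0.2, 50), rng.normal(1.0, 0.2, 50),
            rng.normal(-0.5, 0.1, 50), rng.uniform(0.05, 0.4, 50),
            np.full(50, 0.1)])
        draws = survival_draw_maker(rows)
        vi0, vo0 = (viability_at(draws, ct, 0) for ct in ("inbred", "outbred"))
        vi6, vo6 = (viability_at(draws, ct, 6) for ct in ("inbred", "outbred"))
        d0 = delta_omega(vi0, vo0)
        d6 = delta_omega(vi6, vo6)
        # positive outbred:C interaction means inbred larvae suffer more
        # from competition in every draw, so the cost must rise with C
        assert np.all(d6 > d0)


class TestFitnessAndS:
    @pytest.mark.parametrize("eu,ei,v0,v3,expected", [
        (10, 0, 0.9, 0.5, 9.0), (6, 4, 0.9, 0.5, 7.4), (0, 0, 0.9, 0.5, 0.0),
    ])
    def test_expected_fitness_arithmetic(self, eu, ei, v0, v3, expected):
        assert expected_fitness(eu, ei, v0, v3) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(SelectionError):
            expected_fitness(-1, 0, 0.5, 0.5)
        with pytest.raises(SelectionError):
            expected_fitness(1, 1, 1.5, 0.5)

    @pytest.mark.parametrize("oi,oo,expected", [
        (1.0, 1.0, 0.0), (0.52, 1.0, 0.48), (0.36, 1.0, 0.64),
    ])
    def test_selection_coefficient_matches_printed_scale(self, oi, oo, expected):
        assert selection_coefficient(oi, oo) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(oi=st.floats(0.01, 5), oo=st.floats(0.01, 5), k=st.floats(0.1, 10))
    def test_selection_scale_invariance(self, oi, oo, k):
        assert selection_coefficient(k * oi, k * oo) == pytest.approx(
            selection_coefficient(oi, oo))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(v=st.floats(0.05, 0.95), eu=st.floats(0, 20), ei=st.floats(0, 20),
           oi_frac=st.floats(0.1, 1.0))
    def test_equal_viabilities_make_s_independent_of_egg_split(
            self, v, eu, ei, oi_frac):
        """With v0 = v3 the weighting collapses and only totals matter."""
        tot = eu + ei + 1.0
        s_split = selection_coefficient(
            expected_fitness(eu * oi_frac, (tot - eu) * oi_frac, v, v),
            expected_fitness(eu, tot - eu, v, v))
        s_pooled = selection_coefficient(
            expected_fitness(tot * oi_frac, 0.0, v, v),
            expected_fitness(tot, 0.0, v, v))
        assert s_split == pytest.approx(s_pooled, abs=1e-12)


def _constant_egg_draws(spec_response, table, cell_log_means, n_draws=6):
    """Egg-model draws whose cell expectations are exp(cell_log_means)."""
    # columns: (Intercept), cross_type[outbred], treatment[reliable],
    # treatment[unreliable], interactions..., var[trial_id]
    from careload.glmm import build_design
    spec = egg_count_spec(spec_response, crossed=True)
    design = build_design(spec, table)
    rows = []
    X = {}
    for t in ("none", "reliable", "unreliable"):
        for ct in ("inbred", "outbred"):
            X[(t, ct)] = design.row({"treatment": t, "cross_type": ct})
    A = np.array([X[k] for k in sorted(X)])
    b = np.array([cell_log_means[k] for k in sorted(X)])
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.allclose(A @ beta, b), "cell means not representable"
    row = list(beta) + [0.0]      # zero trial variance
    return make_posterior(spec, table, np.array([row] * n_draws))


class TestTreatmentSelection:
    @pytest.fixture()
    def egg_table(self):
        d = sim.BehaviorDesign(n_trials=18, cross_types=("inbred", "outbred"))
        return sim.gen_eggs(d, sim.EggParams(), seed=0)

    def test_constructed_fixture_gives_deterministic_differences(
            self, egg_table, survival_draw_maker):
        # viabilities equal at C=0 and C=3 (slope 0): s depends on totals only
        surv = survival_draw_maker([[logit(0.5), 0.0, 0.0, 0.0, 0.1]] * 6)
        # fitness ratios chosen so s = 0.48 / 0.60 / 0.64 in every draw
        ratios = {"reliable": 0.52, "unreliable": 0.40, "none": 0.36}
        cells = {}
        for t, r in ratios.items():
            cells[(t, "outbred")] = np.log(10.0)
            cells[(t, "inbred")] = np.log(10.0 * r)
        eu = _constant_egg_draws("eggs_uninfested", egg_table, cells)
        zero = {k: -40.0 for k in cells}
        ei = _constant_egg_draws("eggs_infested", egg_table, zero)
        res = treatment_selection(eu, ei, surv)
        assert res.per_treatment["reliable"].mean == pytest.approx(0.48, abs=1e-9)
        assert res.per_treatment["unreliable"].mean == pytest.approx(0.60, abs=1e-9)
        assert res.per_treatment["none"].mean == pytest.approx(0.64, abs=1e-9)
        assert res.contrasts["s[unreliable]-s[reliable]"].mean == pytest.approx(
            0.12, abs=1e-9)
        assert res.contrasts["s[none]-s[reliable]"].mean == pytest.approx(
            0.16, abs=1e-9)
        assert res.contrasts["s[none]-s[unreliable]"].mean == pytest.approx(
            0.04, abs=1e-9)

    def test_identical_treatments_give_zero_contrasts_p_one(
            self, egg_table, survival_draw_maker):
        surv = survival_draw_maker([[1.0, 0.5, -0.3, 0.1, 0.1]] * 6)
        cells = {(t, ct): (np.log(8.0) if ct == "outbred" else np.log(4.0))
                 for t in ("none", "reliable", "unreliable")
                 for ct in ("inbred", "outbred")}
        eu = _constant_egg_draws("eggs_uninfested", egg_table, cells)
        ei = _constant_egg_draws("eggs_infested", egg_table, cells)
        res = treatment_selection(eu, ei, surv)
        for est in res.contrasts.values():
            assert est.mean == pytest.approx(0.0, abs=1e-12)
        assert all(p == 1.0 for p in res.pmcmc.values())


class TestInbreedingDepression:
    def _table(self, inbred_value, outbred_value, n=6):
        rows = []
        fid = 0
        for i in (1, 2, 3):
            for _ in range(n):
                fid += 1
                rows.append((fid, f"line{i}-inbred", inbred_value))
            for _ in range(n):
                fid += 1
                rows.append((fid, f"cross{i}-outbred", outbred_value))
        return pd.DataFrame(rows,
                            columns=["female_id", "cross_label", "hatched_eggs"])

    def test_equal_means_give_zero(self):
        est = inbreeding_depression(self._table(50, 50), n_boot=50)
        assert np.allclose(est["reduction"], 0.0)

    def test_forty_vs_hundred_gives_06(self):
        est = inbreeding_depression(self._table(40, 100), n_boot=50)
        assert np.allclose(est["reduction"], 0.6)

    def test_requires_replication(self):
        with pytest.raises(SelectionError):
            inbreeding_depression(self._table(40, 100, n=1), n_boot=10)


class TestEllipse:
    def test_identical_points_degenerate_zero_matrix(self):
        pts = pd.DataFrame({"care": [50.0] * 6, "survival": [70.0] * 6})
        ell = care_survival_ellipse(pts)
        assert ell.degenerate
        assert np.allclose(ell.cov, 0.0)

    def test_collinear_points_have_zero_minor_axis(self):
        pts = pd.DataFrame({"care": [0.0, 1, 2], "survival": [0.0, 1, 2]})
        ell = care_survival_ellipse(pts)
        assert ell.semi_axes[1] == pytest.approx(0.0, abs=1e-9)
        corr = ell.cov[0, 1] / np.sqrt(ell.cov[0, 0] * ell.cov[1, 1])
        assert corr == pytest.approx(1.0)

    def test_sample_covariance_matches_brute_force_formula(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 5, 6)
        y = 0.8 * x + rng.normal(0, 2, 6)
        pts = pd.DataFrame({"care": x, "survival": y})
        ell = care_survival_ellipse(pts)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / (len(x) - 1)
        assert ell.cov[0, 1] == pytest.approx(oracle, abs=1e-10)
        assert ell.ige_direction == np.sign(oracle)
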