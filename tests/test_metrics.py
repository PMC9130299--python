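"""Unit and oracle tests for the no-censoring survival metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter

from gliosurv.metrics import (
    MetricWithCI,
    SurvivalCurveSet,
    bootstrap_ci,
    brier_score,
    concordance_index,
    ibs_reduction_pct,
    integrated_brier_score,
    kaplan_meier,
)


def brute_force_cindex(risk, times):
    """O(n²) pair-counting oracle."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_reverse_ordered_scores_are_perfect(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-times, times) == 1.0

    def test_constant_scores_are_random(self):
        assert concordance_index([2, 2, 2], [1.0, 5.0, 9.0]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(12, size=30)
        risk = np.round(rng.normal(size=30), 1)  # rounded to force score ties
        assert concordance_index(risk, times) == pytest.approx(
            brute_force_cindex(risk, times), abs=1e-12
        )

    def test_single_patient_is_undefined(self):
        with pytest.raises(ValueError):
            concordance_index([1.0], [2.0])

    @given(st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(12, size=20)
        risk = rng.normal(size=20)
        base = concordance_index(risk, times)
        assert concordance_index(np.exp(3 * risk), times) == pytest.approx(base)


class TestKaplanMeier:
    def test_empirical_survival(self):
        km = kaplan_meier([1.0, 2.0, 3.0])
        assert km.at(1.5)[0] == pytest.approx(2 / 3)
        assert km.at(0)[0] == 1.0
        assert km.at(3.0)[0] == 0.0

    def test_matches_product_limit_on_tied_times(self):
        # product-limit by hand: S(1)=4/6, S(2)=4/6·3/4=1/2, S(3)=0
        km = kaplan_meier([1, 1, 2, 3, 3, 3])
        assert km.at(1)[0] == pytest.approx(4 / 6)
        assert km.at(2.5)[0] == pytest.approx(0.5)
        assert km.at(3)[0] == 0.0

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(12, 40), 0) + 1
        km = kaplan_meier(t)
        lf = KaplanMeierFitter().fit(t, event_observed=np.ones(40))
        for q in (2.0, 5.0, 11.0, 20.0):
            if q <= km.grid[-1]:
                assert km.at(q)[0] == pytest.approx(
                    float(lf.predict(q)), abs=1e-12
                )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            kaplan_meier([])


def oracle_curves(times):
    """Per-patient step curves dropping from 1 to 0 at the true event time."""
    t = np.asarray(times, dtype=float)
    grid = np.unique(np.concatenate(([0.0], t)))
    surv = (t[:, None] > grid[None, :]).astype(float)
    surv[:, 0] = 1.0
    return SurvivalCurveSet(grid=grid, surv=surv)


class TestBrier:
    def test_constant_half_curve(self):
        times = np.array([2.0, 5.0, 9.0])
        grid = np.array([0.0, 2.0, 5.0, 9.0])
        curves = SurvivalCurveSet(
            grid=grid, surv=np.array([[1.0, 0.5, 0.5, 0.5]])
        )
        assert brier_score(curves, times, 3.0) == pytest.approx(0.25)

    def test_oracle_curves_score_zero(self):
        times = np.array([2.0, 5.0, 9.0])
        curves = oracle_curves(times)
        for t in (1.0, 3.0, 6.0, 8.5):
            assert brier_score(curves, times, t) == 0.0

    def test_three_patient_km_reference_hand_value(self):
        # S_KM(4) = 2/3; BS(4) = ((0-2/3)² + 2·(1-2/3)²)/3 = 2/9
        times = np.array([2.0, 5.0, 9.0])
        assert brier_score(kaplan_meier(times), times, 4.0) == pytest.approx(2 / 9)

    def test_t_outside_grid_errors(self):
        times = np.array([2.0, 5.0, 9.0])
        with pytest.raises(ValueError):
            brier_score(kaplan_meier(times), times, 20.0)


class TestIntegratedBrier:
    def test_oracle_curves_integrate_to_zero(self):
        times = np.array([2.0, 5.0, 9.0])
        assert integrated_brier_score(oracle_curves(times), times, 9.0) == 0.0

    def test_constant_half_curves(self):
        times = np.array([2.0, 5.0, 9.0])
        grid = np.array([0.0, 2.0, 5.0, 9.0])
        curves = SurvivalCurveSet(grid=grid, surv=np.array([[1.0, 0.5, 0.5, 0.5]]))
        # S(0)=1 forces BS(0)=0, so the trapezoid over [0,2] averages up to 0.25
        grid_pts = np.array([0.0, 2.0, 5.0, 9.0])
        bs = [brier_score(curves, times, g) for g in grid_pts]
        expected = np.trapezoid(bs, grid_pts) / 9.0
        assert integrated_brier_score(curves, times, 9.0) == pytest.approx(expected)

    def test_toy_km_reference_matches_hand_integral(self):
        times = np.array([2.0, 5.0, 9.0])
        km = kaplan_meier(times)
        grid = np.array([0.0, 2.0, 5.0, 9.0])
        # BS at the grid, by hand: 0; (4/9+1/9+1/9)/3; (1/9+1/9+4/9)/3; 0
        bs_hand = [0.0, 2 / 9, 2 / 9, 0.0]
        expected = np.trapezoid(bs_hand, grid) / 9.0
        assert integrated_brier_score(km, times, 9.0) == pytest.approx(expected)

    def test_km_reference_never_beats_oracle(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(12, 50)
        tau = float(np.quantile(times, 0.95))
        ibs_km = integrated_brier_score(kaplan_meier(times), times, tau)
        ibs_oracle = integrated_brier_score(oracle_curves(times), times, tau)
        assert ibs_oracle == 0.0
        assert ibs_km >= ibs_oracle


class TestIbsReduction:
    def test_identity_is_zero(self):
        assert ibs_reduction_pct(0.1, 0.1) == 0.0

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            ibs_reduction_pct(0.1, 0.0)


class TestBootstrap:
    def test_ci_covers_true_mean(self):
        sample = np.arange(1, 1001, dtype=float)
        ci = bootstrap_ci(np.mean, sample, n_boot=2000, seed=0)
        assert ci.lower <= 500.5 <= ci.upper

    def test_constant_sample_zero_width(self):
        ci = bootstrap_ci(np.mean, np.full(20, 3.0), n_boot=200, seed=1)
        assert ci.lower == ci.upper == ci.point == 3.0

    def test_deterministic_given_seed(self):
        sample = np.random.default_rng(2).normal(size=50)
        a = bootstrap_ci(np.median, sample, n_boot=300, seed=9)
        b = bootstrap_ci(np.median, sample, n_boot=300, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_degenerate_sample_errors(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.array([1.0]), n_boot=200, seed=0)


class TestCurveValidation:
    def test_rejects_increasing_curves(self):
        with pytest.raises(ValueError):
            SurvivalCurveSet(
                grid=np.array([0.0, 1.0]), surv=np.array([[1.0, 1.1]])
            )

    def test_rejects_bad_start(self):
        with pytest.raises(ValueError):
            SurvivalCurveSet(
                grid=np.array([0.0, 1.0]), surv=np.array([[0.9, 0.5]])
            )

    def test_metric_ci_bracket_enforced(self):
        with pytest.raises(ValueError):
            MetricWithCI(point=0.5, lower=0.6, upper=0.7, n_boot=100, seed=0)
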