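"""Kaplan-Meier, log-rank, Cox and restricted-mean checks against
independent oracles (hand product-limit, grid-search partial likelihood,
closed forms)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from routesurv import survival
from routesurv._coxfast import fast_cox, per_case_rms


class TestKaplanMeier:
    def test_all_events_by_hand(self, tiny_survival):
        t, e = tiny_survival
        curve = survival.km_fit(t, e)
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2.0

    def test_all_censored_flat_curve(self):
        curve = survival.km_fit([5.0, 8.0, 13.0], [False, False, False])
        assert np.allclose(curve.survival, 1.0)
        assert curve.median is None

    def test_matches_brute_force_product_limit(self, rng, km_oracle):
        t = rng.exponential(10, 20).round(1)
        e = rng.random(20) < 0.7
        curve = survival.km_fit(t, e)
        for grid_t, s in km_oracle(t, e):
            i = np.searchsorted(curve.times, grid_t)
            assert curve.survival[i] == pytest.approx(s, abs=1e-12)

    def test_survival_starts_at_one_and_is_nonincreasing(self, rng):
        t = rng.exponential(20, 50)
        e = rng.random(50) < 0.6
        curve = survival.km_fit(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            survival.km_fit([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([True] * 8)
        g = np.array(["a"] * 4 + ["b"] * 4)
        stat, p = survival.logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_observed_minus_expected(self):
        # groups A: events at 1, 3; B: events at 2, 4.  At each event time
        # O-E for group A: t=1: 1 - 2/4; t=2: 0 - 1/3 (A risk {3}, B {2,4});
        # t=3: 1 - 1/2; t=4: 0 - 0 (only B at risk).  U = 2/3.
        # Var terms: t=1: (2*2)/(4*4*3)*1*... use standard hypergeometric:
        # v_j = n1 n2 d (n-d) / (n^2 (n-1)) with d=1: 4/16=0.25, 2/9, 0.25, 0.
        t = np.array([1.0, 3.0, 2.0, 4.0])
        e = np.array([True, True, True, True])
        g = np.array(["A", "A", "B", "B"])
        u = (1 - 2 / 4) + (0 - 1 / 3) + (1 - 1 / 2) + 0.0
        v = 0.25 + 2 / 9 + 0.25 + 0.0
        stat, p = survival.logrank(t, e, g)
        assert stat == pytest.approx(u**2 / v, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            survival.logrank([1.0, 2.0], [True, True], ["a", "a"])


def _partial_loglik_binary(beta, times, events, x):
    """Exact no-ties partial log-likelihood, written independently."""
    ll = 0.0
    for i in np.nonzero(events)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_identical_groups_null_coefficient(self):
        t = np.tile([2.0, 5.0, 7.0, 11.0, 13.0], 2)
        e = np.ones(10, bool)
        X = pd.DataFrame({"g": [0.0] * 5 + [1.0] * 5})
        fit = survival.cox_fit(t, e, X)
        assert fit.coef["g"] == pytest.approx(0.0, abs=1e-6)
        assert fit.hr["g"] == pytest.approx(1.0, abs=1e-5)

    def test_matches_grid_search_partial_likelihood(self, rng):
        """beta-hat agrees with the arg-max of the exact partial likelihood
        located by brute-force 1-D grid search."""
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        t = np.array([3.1, 1.2, 7.6, 2.3, 4.4, 9.9, 0.7, 6.2])
        e = np.array([True, True, True, False, True, True, True, False])
        fit = survival.cox_fit(t, e, pd.DataFrame({"x": x}))
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [_partial_loglik_binary(b, t, e, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.coef["x"] == pytest.approx(beta_grid, abs=1e-4)

    def test_two_subject_score_equation_bisection(self):
        """n=2, one binary covariate, both events: the score equation
        d/db [b - log(1+e^b)] has no finite root when the x=1 subject fails
        first; with the x=0 subject first, beta solves the score at the
        bisection root of the reduced problem (here an extra tied-free pair
        keeps the MLE finite)."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, True, True, True])
        x = np.array([0.0, 1.0, 1.0, 0.0])

        def score(b):
            eps = 1e-6
            return (
                _partial_loglik_binary(b + eps, t, e, x)
                - _partial_loglik_binary(b - eps, t, e, x)
            ) / (2 * eps)

        lo, hi = -10.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if score(mid) > 0:
                lo = mid
            else:
                hi = mid
        fit = survival.cox_fit(t, e, pd.DataFrame({"x": x}))
        assert fit.coef["x"] == pytest.approx((lo + hi) / 2, abs=1e-5)

    def test_consistency_hazard_ratio_recovery(self):
        """exp(beta-hat) approaches the generating HR as n grows."""
        errs = []
        for n in (300, 3000):
            rng = np.random.default_rng(5)
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / np.exp(0.5 * x))
            fit = survival.cox_fit(t, np.ones(n, bool), pd.DataFrame({"x": x}))
            errs.append(abs(fit.coef["x"] - 0.5))
        assert errs[1] < errs[0]
        assert errs[1] < 0.1

    def test_predicted_survival_baseline_at_zero(self):
        rng = np.random.default_rng(3)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * x) * 10)
        fit = survival.cox_fit(t, np.ones(n, bool), pd.DataFrame({"x": x}))
        _, s = survival.predicted_survival(fit, [0.0])
        assert np.allclose(s, np.exp(-fit.baseline_cumhaz))

    def test_predicted_survival_monotone_in_harmful_covariate(self):
        rng = np.random.default_rng(4)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.6 * x) * 10)
        fit = survival.cox_fit(t, np.ones(n, bool), pd.DataFrame({"x": x}))
        assert fit.coef["x"] > 0
        _, s_lo = survival.predicted_survival(fit, [-1.0])
        _, s_hi = survival.predicted_survival(fit, [1.0])
        assert np.all(s_hi <= s_lo + 1e-12)

    def test_dimension_mismatch_rejected(self):
        fit = survival.cox_fit(
            [1.0, 2.0, 3.0], [True, True, True], pd.DataFrame({"x": [0.0, 1.0, 0.5]})
        )
        with pytest.raises(ValueError):
            survival.predicted_survival(fit, [1.0, 2.0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            survival.cox_fit([1.0, 2.0], [False, False], pd.DataFrame({"x": [0.0, 1.0]}))


class TestFastCoxEngine:
    """The streamlined Newton solver used inside permutation loops must
    agree with the full fitter."""

    @pytest.mark.parametrize("round_times", [False, True])
    def test_agrees_with_reference_fitter(self, rng, round_times):
        n = 120
        X = np.column_stack(
            [rng.normal(size=n), (rng.random(n) < 0.5).astype(float), rng.normal(59, 11, n)]
        )
        t = rng.exponential(20 * np.exp(-(0.4 * X[:, 0] - 0.3 * X[:, 1])))
        c = rng.exponential(50, n)
        e = t <= c
        tt = np.minimum(t, c)
        if round_times:
            tt = np.round(tt)
            keep = tt > 0
            tt, e, X = tt[keep], e[keep], X[keep]
        beta, bt, H0 = fast_cox(tt, e, X)
        fit = survival.cox_fit(tt, e, pd.DataFrame(X, columns=["a", "b", "c"]))
        # tolerance reflects the reference fitter's own convergence precision
        assert np.max(np.abs(beta - fit.coef.to_numpy())) < 5e-5
        idx = np.searchsorted(bt, fit.baseline_times, side="right") - 1
        mine = np.where(idx >= 0, H0[np.maximum(idx, 0)], 0.0)
        assert np.max(np.abs(mine - fit.baseline_cumhaz)) < 1e-4

    def test_per_case_rms_matches_composed_path(self, rng):
        n = 80
        X = rng.normal(size=(n, 2))
        t = rng.exponential(15 * np.exp(-0.3 * X[:, 0]))
        e = np.ones(n, bool)
        beta, bt, H0 = fast_cox(t, e, X)
        fit = survival.cox_fit(t, e, pd.DataFrame(X, columns=["a", "b"]))
        fast_vals = per_case_rms(beta, bt, H0, X[:5], 60.0)
        for i in range(5):
            ts, s = survival.predicted_survival(fit, X[i])
            ref = survival.rms(ts, s, 60.0).value
            assert fast_vals[i] == pytest.approx(ref, abs=1e-3)


class TestRestrictedMean:
    def test_zero_horizon(self):
        assert survival.rms([1.0], [0.5], 0.0).value == 0.0

    def test_flat_curve_attains_horizon(self):
        assert survival.rms([70.0], [1.0], 60.0).value == pytest.approx(60.0)

    def test_exponential_closed_form_on_fine_grid(self):
        """Exponential survival, mean 30 months, tau=60:
        RMS = 30 (1 - e^-2) ~ 25.94, converging with grid refinement."""
        target = 30.0 * (1.0 - np.exp(-2.0))
        errs = []
        for n_grid in (2_000, 60_000):
            t = np.linspace(0, 60, n_grid)[1:]
            s = np.exp(-t / 30.0)
            errs.append(abs(survival.rms(t, s, 60.0).value - target))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3

    def test_monotone_in_tau_and_bounded(self):
        t = np.array([5.0, 20.0, 45.0])
        s = np.array([0.8, 0.5, 0.2])
        vals = [survival.rms(t, s, tau).value for tau in (10, 30, 60)]
        assert vals == sorted(vals)
        for tau, v in zip((10, 30, 60), vals):
            assert 0 <= v <= tau

    def test_pointwise_larger_survival_gives_larger_rms(self):
        t = np.array([10.0, 30.0])
        hi = survival.rms(t, np.array([0.9, 0.6]), 60.0).value
        lo = survival.rms(t, np.array([0.7, 0.3]), 60.0).value
        assert hi > lo

    def test_km_compose_equals_rectangle_sum(self, rng):
        t = rng.exponential(25, 30)
        e = rng.random(30) < 0.7
        curve = survival.km_fit(t, e)
        val = survival.rms(curve.times, curve.survival, 60.0).value
        # independent rectangle summation
        grid = np.concatenate([[0.0], curve.times[curve.times < 60], [60.0]])
        s = np.concatenate([[1.0], curve.survival[curve.times < 60]])
        brute = sum((grid[i + 1] - grid[i]) * s[i] for i in range(len(grid) - 1))
        assert val == pytest.approx(brute, abs=1e-12)

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError):
            survival.rms([1.0], [1.5], 60.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 10), st.integers(0, 1000))
    def test_rms_never_exceeds_tau_property(self, n_steps, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 80, n_steps))
        s = np.sort(rng.uniform(0, 1, n_steps))[::-1]
        v = survival.rms(t, s, 60.0)
        assert 0.0 <= v.value <= 60.0
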