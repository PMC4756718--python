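"""Quantile normalization, RMS curves, window deltas, permutation tests,
and candidate calling."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from routesurv import rms_perm, survival
from routesurv.cohort import analysis_subset, encode_covariates


class TestNormalizeRelativeExpression:
    def test_rank_formula_by_hand(self):
        q = rms_perm.normalize_relative_expression([5.0, 1.0, 9.0])
        assert np.allclose(q.to_numpy(), [0.5, 0.0, 1.0])

    def test_tied_minima_average_rank(self):
        # two tied minima among n=3: average rank 1.5 -> q = 0.25
        q = rms_perm.normalize_relative_expression([2.0, 2.0, 7.0])
        assert np.allclose(q.to_numpy(), [0.25, 0.25, 1.0])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        q1 = rms_perm.normalize_relative_expression(x)
        q2 = rms_perm.normalize_relative_expression(np.exp(3 * x) + 5)
        assert np.allclose(q1.to_numpy(), q2.to_numpy())

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            rms_perm.normalize_relative_expression([4.0, 4.0, 4.0])

    def test_range_and_monotonicity(self, rng):
        x = rng.normal(size=25)
        q = rms_perm.normalize_relative_expression(x).to_numpy()
        assert q.min() == 0.0 and q.max() == 1.0
        order = np.argsort(x)
        assert (np.diff(q[order]) >= 0).all()


def _arm_frame(n, rng, beta_q=0.0, lam=1 / 25.0, route="IV"):
    q = np.linspace(0, 1, n)
    t = rng.exponential(1.0 / (lam * np.exp(beta_q * q)))
    records = pd.DataFrame(
        {
            "case_id": [f"{route}{i}" for i in range(n)],
            "route": [route] * n,
            "age": rng.normal(59, 11, n),
            "stage": rng.choice(["IIIA/B", "IIIC", "IV"], n),
            "grade": rng.choice(["G2", "G3"], n),
            "cytoreduction": ["optimal"] * n,
            "race": ["White"] * n,
            "pfs_months": np.minimum(t, 80.0),
            "pfs_event": t <= 80.0,
            "os_months": np.minimum(t, 80.0),
            "os_event": t <= 80.0,
        }
    )
    return records, pd.Series(q, index=records["case_id"].to_numpy())


class TestRmsCurve:
    def test_null_gene_flat_curve_near_baseline(self, rng):
        records, q = _arm_frame(250, rng, beta_q=0.0)
        curve = rms_perm.rms_curve(records, q, "G", "IV", "PFS", n_bootstrap=0, seed=1)
        spread = curve.rms.max() - curve.rms.min()
        assert spread < 6.0  # no systematic trend, only fit noise
        km = survival.km_rms(
            records["pfs_months"].to_numpy(), records["pfs_event"].to_numpy(bool)
        )
        assert curve.rms.mean() == pytest.approx(km.value, abs=4.0)

    def test_harmful_expression_gives_decreasing_curve(self, rng):
        records, q = _arm_frame(400, rng, beta_q=1.0)
        curve = rms_perm.rms_curve(records, q, "G", "IV", "PFS", n_bootstrap=0, seed=1)
        assert curve.rms[0] > curve.rms[-1]
        assert (np.diff(curve.rms) <= 1e-9).all()

    def test_matches_exponential_closed_form(self, rng):
        """With exponential baseline hazard lam and log-HR beta per unit q,
        RMS(q) = (1 - exp(-lam e^{beta q} tau)) / (lam e^{beta q})."""
        lam, beta = 1 / 25.0, 0.8
        records, q = _arm_frame(4000, rng, beta_q=beta, lam=lam)
        curve = rms_perm.rms_curve(records, q, "G", "IV", "PFS", n_bootstrap=0, seed=1)
        rate = lam * np.exp(beta * curve.grid)
        closed = (1.0 - np.exp(-rate * 60.0)) / rate
        assert np.max(np.abs(curve.rms - closed)) < 2.5

    def test_bootstrap_band_brackets_centre(self, rng):
        records, q = _arm_frame(150, rng, beta_q=0.5)
        curve = rms_perm.rms_curve(records, q, "G", "IV", "PFS", n_bootstrap=60, seed=4)
        assert np.all(curve.ci_lower <= curve.rms + 1e-9)
        assert np.all(curve.rms <= curve.ci_upper + 1e-9)
        assert np.all(curve.ci_upper <= 60.0 + 1e-9)

    def test_no_events_rejected(self, rng):
        records, q = _arm_frame(20, rng)
        records["pfs_event"] = False
        with pytest.raises(ValueError):
            rms_perm.rms_curve(records, q, "G", "IV", "PFS")


class TestAdjustedRmsPerCase:
    def test_values_bounded_by_tau(self, rng):
        records, q = _arm_frame(120, rng, beta_q=0.6)
        vals = rms_perm.adjusted_rms_per_case(records, q, "IV", "PFS")
        assert ((vals > 0) & (vals <= 60.0)).all()

    def test_mean_close_to_km_rms(self, rng):
        """Average model-based per-case RMS approximates the arm's
        empirical KM-based RMS."""
        records, q = _arm_frame(300, rng, beta_q=0.5)
        vals = rms_perm.adjusted_rms_per_case(records, q, "IV", "PFS")
        km = survival.km_rms(
            records["pfs_months"].to_numpy(), records["pfs_event"].to_numpy(bool)
        )
        assert vals.mean() == pytest.approx(km.value, rel=0.08)

    def test_index_is_case_ids_of_analysis_subset(self, rng):
        records, q = _arm_frame(50, rng)
        records.loc[records.index[:5], "age"] = None
        vals = rms_perm.adjusted_rms_per_case(records, q, "IV", "PFS")
        assert len(vals) == 45
        assert set(vals.index) <= set(records["case_id"])


class TestWindowDelta:
    def _members(self, rng, n=30):
        records, q = _arm_frame(n, rng)
        records.loc[records.index[n // 2 :], "route"] = "IP"
        rms_vals = pd.Series(
            rng.uniform(10, 50, n), index=records["case_id"].to_numpy()
        )
        routes = records.set_index("case_id")["route"]
        return rms_vals, q, routes

    def test_full_window_selects_everyone(self, rng):
        rms_vals, q, routes = self._members(rng)
        delta, members = rms_perm.window_delta(rms_vals, q, routes, (0.0, 1.0))
        assert len(members) == len(rms_vals)
        assert not math.isnan(delta)

    def test_arm_swap_negates_delta(self, rng):
        rms_vals, q, routes = self._members(rng)
        d1, _ = rms_perm.window_delta(rms_vals, q, routes, (0.0, 1.0))
        swapped = routes.map({"IP": "IV", "IV": "IP"})
        d2, _ = rms_perm.window_delta(rms_vals, q, swapped, (0.0, 1.0))
        assert d1 == pytest.approx(-d2)

    def test_top_decile_member_count(self, rng):
        n = 100
        records, q = _arm_frame(n, rng)
        rms_vals = pd.Series(np.full(n, 30.0), index=records["case_id"].to_numpy())
        routes = records.set_index("case_id")["route"]
        _, members = rms_perm.window_delta(rms_vals, q, routes, (0.9, 1.0))
        assert abs(len(members) - math.ceil(0.1 * n)) <= 1

    def test_empty_arm_flagged_nan(self, rng):
        rms_vals, q, routes = self._members(rng)
        routes[:] = "IV"
        delta, _ = rms_perm.window_delta(rms_vals, q, routes, (0.0, 1.0))
        assert math.isnan(delta)

    def test_invalid_window_rejected(self, rng):
        rms_vals, q, routes = self._members(rng)
        with pytest.raises(ValueError):
            rms_perm.window_delta(rms_vals, q, routes, (0.8, 0.2))


def _members_frame(values_ip, values_iv):
    vals = list(values_ip) + list(values_iv)
    return pd.DataFrame(
        {
            "q": np.linspace(0, 1, len(vals)),
            "rms": vals,
            "route": ["IP"] * len(values_ip) + ["IV"] * len(values_iv),
        },
        index=[f"m{i}" for i in range(len(vals))],
    )


class TestPermutationTestFixed:
    def test_identical_multisets_p_near_one(self):
        members = _members_frame([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        res = rms_perm.permutation_test(members, n_perm=2000, seed=0)
        assert res.delta == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.9

    def test_determinism_same_seed(self):
        members = _members_frame([40.0, 45.0, 50.0, 35.0], [20.0, 25.0, 15.0, 30.0])
        a = rms_perm.permutation_test(members, n_perm=500, seed=42, method="sampled")
        b = rms_perm.permutation_test(members, n_perm=500, seed=42, method="sampled")
        assert a.p == b.p

    def test_exact_enumeration_3v3(self):
        """Sampled p agrees with full enumeration over C(6,3) label
        assignments, written here independently."""
        members = _members_frame([42.0, 35.0, 50.0], [20.0, 28.0, 33.0])
        v = members["rms"].to_numpy()
        d_obs = v[:3].mean() - v[3:].mean()
        hits = 0
        for combo in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in combo]
            d = v[list(combo)].mean() - v[rest].mean()
            if abs(d) >= abs(d_obs) - 1e-12:
                hits += 1
        p_exact = hits / math.comb(6, 3)
        res_exact = rms_perm.permutation_test(members, method="exact")
        assert res_exact.p == pytest.approx(p_exact, abs=1e-12)
        res_sampled = rms_perm.permutation_test(
            members, n_perm=20_000, seed=3, method="sampled"
        )
        # sampled p within Monte-Carlo error (+1 correction) of the exact p
        assert res_sampled.p == pytest.approx(p_exact, abs=0.02)

    def test_auto_switches_to_exact_for_small_windows(self):
        members = _members_frame([40.0, 50.0], [20.0, 25.0])
        res = rms_perm.permutation_test(members, n_perm=10_000, seed=1)
        assert res.method == "exact"

    def test_degenerate_single_arm(self):
        members = _members_frame([40.0, 50.0], [])
        res = rms_perm.permutation_test(members)
        assert res.degenerate and res.p == 1.0


class TestPermutationTestRefit:
    def _setup(self, rng, n=120, route_log_hr=0.0):
        records, q = _arm_frame(n, rng)
        ip_rows = rng.permutation(n)[: n // 2]
        records.loc[records.index[ip_rows], "route"] = "IP"
        t = records["pfs_months"].to_numpy().copy()
        is_ip = (records["route"] == "IP").to_numpy()
        t[is_ip] *= math.exp(-route_log_hr)  # exponential: scale times
        records["pfs_months"] = np.minimum(t, 80.0)
        sub = analysis_subset(records, ["pfs_months", "pfs_event", "age", "stage", "grade"])
        X = encode_covariates(sub, ["age", "stage", "grade"])
        qv = q.loc[sub["case_id"]].to_numpy(float)
        X.insert(0, "q", qv)
        return (
            sub["pfs_months"].to_numpy(float),
            sub["pfs_event"].to_numpy(bool),
            X.to_numpy(float),
            (sub["route"] == "IP").to_numpy(),
            (qv >= 0.0) & (qv <= 1.0),
        )

    def test_determinism(self, rng):
        args = self._setup(rng)
        a = rms_perm.permutation_test_refit(*args, n_perm=100, seed=5)
        b = rms_perm.permutation_test_refit(*args, n_perm=100, seed=5)
        assert a.p == b.p and a.delta == b.delta

    def test_detects_strong_route_effect(self, rng):
        args = self._setup(rng, n=160, route_log_hr=-1.0)
        res = rms_perm.permutation_test_refit(*args, n_perm=200, seed=5)
        assert res.delta > 0
        assert res.p < 0.05

    def test_null_not_rejected_typically(self):
        ps = []
        for i in range(3):
            args = self._setup(np.random.default_rng(100 + i), n=120, route_log_hr=0.0)
            ps.append(rms_perm.permutation_test_refit(*args, n_perm=200, seed=6 + i).p)
        assert sum(p > 0.05 for p in ps) >= 2


class TestCallCandidates:
    def _res(self, gene, endpoint, delta, p, window=(0.9, 1.0)):
        return rms_perm.PermutationResult(
            gene=gene, endpoint=endpoint, window=window, delta=delta, p=p,
            n_perm=100, n_ip=5, n_iv=10, seed=0,
        )

    def test_clear_ip_benefit_both_platforms_not_candidate(self):
        micro = [self._res("A", "PFS", 8.0, 0.001)]
        rnaseq = [self._res("A", "PFS", 9.0, 0.002)]
        out = rms_perm.call_candidates(micro, rnaseq)
        assert not bool(out.iloc[0]["candidate"])

    def test_mixed_ns_and_significant_decrease_is_candidate(self):
        """No significant PFS benefit on one platform plus a significant
        decrease on the other (the published STT3A pattern) flags both."""
        micro = [self._res("STT3A", "PFS", 1.4, 0.4101)]
        rnaseq = [self._res("STT3A", "PFS", -6.2, 0.0046)]
        out = rms_perm.call_candidates(micro, rnaseq)
        assert bool(out.iloc[0]["candidate"])

    def test_significant_benefit_on_one_platform_blocks(self):
        micro = [self._res("B", "OS", 7.0, 0.001)]
        rnaseq = [self._res("B", "OS", 0.3, 0.8)]
        out = rms_perm.call_candidates(micro, rnaseq)
        assert bool(out.iloc[0]["flagged_rnaseq"])
        assert not bool(out.iloc[0]["flagged_microarray"])
        assert not bool(out.iloc[0]["candidate"])

    def test_degenerate_platform_never_flags(self):
        micro = [self._res("C", "OS", float("nan"), 1.0)]
        micro[0].degenerate = True
        rnaseq = [self._res("C", "OS", -5.0, 0.01)]
        out = rms_perm.call_candidates(micro, rnaseq)
        assert not bool(out.iloc[0]["candidate"])

    def test_join_on_gene_endpoint_window(self):
        micro = [self._res("D", "OS", -5.0, 0.01), self._res("D", "PFS", 2.0, 0.7)]
        rnaseq = [self._res("D", "OS", -4.0, 0.02), self._res("D", "PFS", 8.0, 0.001)]
        out = rms_perm.call_candidates(micro, rnaseq).set_index("endpoint")
        assert bool(out.loc["OS", "candidate"])
        assert not bool(out.loc["PFS", "candidate"])


def test_plot_rms_curves_writes_file(tmp_path, rng):
    records, q = _arm_frame(100, rng, beta_q=0.6)
    curve = rms_perm.rms_curve(records, q, "G", "IV", "PFS", n_bootstrap=30, seed=2)
    out = tmp_path / "curve.png"
    rms_perm.plot_rms_curves([curve], path=out)
    assert out.exists() and out.stat().st_size > 0
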