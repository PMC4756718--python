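"""RMS-versus-expression curves and the quantile-window permutation test.

This is the biomarker-calling machinery.  For one gene on one platform:

1. Expression is rank-normalized to a relative quantile q in [0, 1] over
   the pooled IP+IV analyzed cohort.
2. Within each arm, a Cox model of the endpoint on q (univariate, for
   curves) or on q plus clinical covariates (multivariate, for testing)
   yields predicted survival per case; its area to tau = 60 months is the
   case's restricted mean survival (RMS).
3. Cases whose q falls in a quantile window (defaults: bottom and top
   deciles) are compared between arms: Delta = mean RMS_IP - mean RMS_IV,
   with significance from a permutation test that shuffles arm labels
   among the window members while holding each case's RMS fixed.
4. A platform flags the gene when IP patients in the window show either a
   significant survival *decrease* or no significant difference (i.e. no
   demonstrated IP benefit); a gene flagged on both platforms for the
   same endpoint is a candidate biomarker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import survival
from ._coxfast import fast_cox, per_case_rms
from .cohort import ExpressionMatrix, analysis_subset, encode_covariates

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_relative_expression",
    "RmsCurve",
    "rms_curve",
    "adjusted_rms_per_case",
    "window_delta",
    "PermutationResult",
    "permutation_test",
    "call_candidates",
    "window_permutation_analysis",
]

ENDPOINT_COLS = {"PFS": ("pfs_months", "pfs_event"), "OS": ("os_months", "os_event")}
TAU_DEFAULT = 60.0


def normalize_relative_expression(values, index=None) -> pd.Series:
    """Continuous relative quantile q in [0, 1] of each expression value.

    q_i = (rank_i - 1) / (n - 1) with average ranks for ties; the minimum
    maps to 0 and the maximum to 1, and q is invariant to strictly
    monotone transforms of the raw values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 values")
    if np.unique(x).size == 1:
        raise ValueError("all values identical; no ordering exists")
    q = (rankdata(x, method="average") - 1.0) / (x.size - 1.0)
    return pd.Series(q, index=index)


@dataclass
class RmsCurve:
    gene: str
    arm: str
    endpoint: str
    grid: np.ndarray  # q values
    rms: np.ndarray  # months
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    tau: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.grid, "rms": self.rms,
             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}
        )


def plot_rms_curves(curves: list[RmsCurve], path=None, ax=None):
    """Overlay RMS-vs-expression curves (one per arm) with CI bands.

    Returns the matplotlib axes; saves to ``path`` when given.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"IP": "tab:red", "IV": "tab:blue"}
    for c in curves:
        color = colors.get(c.arm)
        ax.plot(c.grid, c.rms, label=f"{c.arm} {c.endpoint}", color=color)
        if np.isfinite(c.ci_lower).all():
            ax.fill_between(c.grid, c.ci_lower, c.ci_upper, alpha=0.2, color=color)
    ax.set_xlabel("relative expression quantile")
    ax.set_ylabel(f"restricted mean survival (months, tau={curves[0].tau:g})")
    ax.set_title(curves[0].gene)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax


def _fit_rms_of_q(times, events, q_values, tau: float):
    """Fit univariate Cox on q; return callable q -> RMS (vectorized)."""
    X = pd.DataFrame({"q": np.asarray(q_values, dtype=float)})
    fit = survival.cox_fit(times, events, X)
    beta = float(fit.coef["q"])
    bt, bh = fit.baseline_times, fit.baseline_cumhaz

    def curve(qs: np.ndarray) -> np.ndarray:
        out = np.empty(len(qs))
        for i, qv in enumerate(qs):
            s = np.exp(-bh * math.exp(beta * qv))
            out[i] = survival.rms(bt, s, tau).value
        return out

    return curve


def rms_curve(
    records: pd.DataFrame,
    q: pd.Series,
    gene: str,
    arm: str,
    endpoint: str,
    *,
    grid_resolution: int = 21,
    tau: float = TAU_DEFAULT,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> RmsCurve:
    """RMS as a function of relative expression within one arm.

    ``q`` maps case_id -> pooled-cohort relative quantile for ``gene``.
    Pointwise 95% CI by case-resampling bootstrap (percentile method).
    """
    tcol, ecol = ENDPOINT_COLS[endpoint]
    sub = records[(records["route"] == arm) & records["case_id"].isin(q.index)]
    sub = analysis_subset(sub, [tcol, ecol])
    if sub.empty or not sub[ecol].astype(bool).any():
        raise ValueError(f"no events in arm {arm} for {endpoint}")
    times = sub[tcol].to_numpy(float)
    events = sub[ecol].to_numpy(bool)
    qv = q.loc[sub["case_id"]].to_numpy(float)

    grid = np.linspace(0.0, 1.0, grid_resolution)
    center = _fit_rms_of_q(times, events, qv, tau)(grid)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, grid.size))
    n = len(sub)
    kept = 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        if not events[idx].any() or np.unique(qv[idx]).size < 2:
            continue
        try:
            boots[kept] = _fit_rms_of_q(times[idx], events[idx], qv[idx], tau)(grid)
        except (ValueError, RuntimeError):
            continue
        kept += 1
    if kept >= 20:
        lo = np.percentile(boots[:kept], 2.5, axis=0)
        hi = np.percentile(boots[:kept], 97.5, axis=0)
    else:  # not enough successful resamples for a band
        lo = np.full(grid.size, np.nan)
        hi = np.full(grid.size, np.nan)
    return RmsCurve(gene, arm, endpoint, grid, center, lo, hi, tau)


def adjusted_rms_per_case(
    records: pd.DataFrame,
    q: pd.Series,
    arm: str,
    endpoint: str,
    covariates: tuple[str, ...] = ("age", "stage", "grade"),
    *,
    tau: float = TAU_DEFAULT,
) -> pd.Series:
    """Per-case covariate-adjusted RMS within one arm.

    Fits a multivariate Cox of the endpoint on (q, covariates) within the
    arm and integrates each case's predicted survival to tau.  Returns a
    Series indexed by case_id.
    """
    tcol, ecol = ENDPOINT_COLS[endpoint]
    sub = records[(records["route"] == arm) & records["case_id"].isin(q.index)]
    sub = analysis_subset(sub, [tcol, ecol, *covariates])
    if sub.empty:
        raise ValueError(f"empty analysis subset for arm {arm}")
    X = encode_covariates(sub, list(covariates))
    X.insert(0, "q", q.loc[sub["case_id"]].to_numpy(float))
    fit = survival.cox_fit(sub[tcol].to_numpy(float), sub[ecol].to_numpy(bool), X)

    bt, bh = fit.baseline_times, fit.baseline_cumhaz
    lp = X.to_numpy(float) @ fit.coef.to_numpy()
    values = np.empty(len(sub))
    for i, lpi in enumerate(lp):
        s = np.exp(-bh * math.exp(lpi))
        values[i] = survival.rms(bt, s, tau).value
    return pd.Series(values, index=sub["case_id"].to_numpy(), name=f"rms_{endpoint.lower()}")


def window_delta(
    rms_by_case: pd.Series,
    q: pd.Series,
    routes: pd.Series,
    window: tuple[float, float],
) -> tuple[float, pd.DataFrame]:
    """Mean adjusted RMS difference (IP - IV) among window members.

    Membership: q in the closed interval [q_lo, q_hi]; q is computed on
    the pooled analyzed cohort.  Returns (Delta, members) where members
    has columns q, rms, route.  Delta is NaN when an arm is empty in the
    window (flagged not-computable by callers).
    """
    q_lo, q_hi = window
    if not (0 <= q_lo < q_hi <= 1):
        raise ValueError("window must satisfy 0 <= q_lo < q_hi <= 1")
    common = rms_by_case.index.intersection(q.index)
    qv = q.loc[common]
    members_idx = qv.index[(qv >= q_lo) & (qv <= q_hi)]
    members = pd.DataFrame(
        {
            "q": q.loc[members_idx],
            "rms": rms_by_case.loc[members_idx],
            "route": routes.loc[members_idx],
        }
    )
    n_ip = int((members["route"] == "IP").sum())
    n_iv = int((members["route"] == "IV").sum())
    if n_ip == 0 or n_iv == 0:
        return float("nan"), members
    delta = float(
        members.loc[members["route"] == "IP", "rms"].mean()
        - members.loc[members["route"] == "IV", "rms"].mean()
    )
    return delta, members


@dataclass
class PermutationResult:
    gene: str
    endpoint: str
    window: tuple[float, float]
    delta: float  # mean RMS_IP - mean RMS_IV, months
    p: float  # two-tailed
    n_perm: int
    n_ip: int
    n_iv: int
    seed: int
    method: str = "sampled"  # or "exact"
    degenerate: bool = False


def permutation_test(
    members: pd.DataFrame,
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    gene: str = "",
    endpoint: str = "",
    window: tuple[float, float] = (0.0, 1.0),
    method: str = "auto",
) -> PermutationResult:
    """Two-tailed permutation test of the window Delta-RMS.

    The null is generated by shuffling arm labels among the window members
    with each case's adjusted RMS held fixed.  Sampled mode uses the +1
    correction p = (1 + #{|D*| >= |D|}) / (n_perm + 1); when the number of
    distinct label assignments C(n, n_ip) is at most ``n_perm`` (and
    ``method`` is "auto" or "exact") all assignments are enumerated and p
    is the exact tail proportion (the identity assignment guarantees p > 0).
    """
    v = members["rms"].to_numpy(float)
    is_ip = (members["route"] == "IP").to_numpy()
    n = v.size
    n_ip = int(is_ip.sum())
    n_iv = n - n_ip
    base = dict(gene=gene, endpoint=endpoint, window=window, n_perm=n_perm, seed=seed)
    if n_ip == 0 or n_iv == 0:
        return PermutationResult(delta=float("nan"), p=1.0, n_ip=n_ip, n_iv=n_iv,
                                 degenerate=True, method="degenerate", **base)
    delta_obs = float(v[is_ip].mean() - v[~is_ip].mean())
    total = v.sum()
    tol = 1e-9 * max(1.0, abs(delta_obs))

    n_assign = math.comb(n, n_ip)
    if n_assign < 2:
        return PermutationResult(delta=delta_obs, p=1.0, n_ip=n_ip, n_iv=n_iv,
                                 degenerate=True, method="degenerate", **base)

    if method == "exact" or (method == "auto" and n_assign <= n_perm):
        hits = 0
        for combo in combinations(range(n), n_ip):
            s = v[list(combo)].sum()
            d = s / n_ip - (total - s) / n_iv
            if abs(d) >= abs(delta_obs) - tol:
                hits += 1
        return PermutationResult(delta=delta_obs, p=hits / n_assign, n_ip=n_ip,
                                 n_iv=n_iv, method="exact", **base)

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :n_ip]
        sums = v[order].sum(axis=1)
        d = sums / n_ip - (total - sums) / n_iv
        hits += int(np.sum(np.abs(d) >= abs(delta_obs) - tol))
        done += m
    p = (1 + hits) / (n_perm + 1)
    return PermutationResult(delta=delta_obs, p=p, n_ip=n_ip, n_iv=n_iv,
                             method="sampled", **base)


def permutation_test_refit(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    is_ip: np.ndarray,
    in_window: np.ndarray,
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    tau: float = TAU_DEFAULT,
    gene: str = "",
    endpoint: str = "",
    window: tuple[float, float] = (0.0, 1.0),
    shuffle: str = "cohort",
) -> PermutationResult:
    """Refit-based permutation test of the window Delta-RMS.

    Arm labels are shuffled; for every relabeling both arm Cox models (on
    ``X``: q plus encoded covariates) are refit and the window members'
    per-case RMS recomputed before taking Delta*.  Refitting propagates
    the sampling noise of the arm-specific fits into the permutation null,
    which keeps the test calibrated — shuffling labels around *fixed*
    fitted RMS values treats that fit noise as treatment signal and is
    anti-conservative (see docs).

    ``shuffle="cohort"`` (default) permutes labels over the whole analyzed
    cohort: the null is route exchangeability at every expression level,
    so a genuine arm difference anywhere the model can see lends power to
    reject.  ``shuffle="window"`` permutes labels only among window
    members, testing window-local association; with model-based RMS values
    this variant has little power because the route effect embedded in the
    arm baselines survives the relabeling.  Permutations in which a
    relabeled arm cannot be fit (e.g. no events) or the window loses an
    arm are skipped.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    X = np.asarray(X, float)
    is_ip = np.asarray(is_ip, bool)
    in_window = np.asarray(in_window, bool)
    win_idx = np.nonzero(in_window)[0]
    n_ip_w = int(is_ip[win_idx].sum())
    n_iv_w = int(win_idx.size - n_ip_w)
    base = dict(gene=gene, endpoint=endpoint, window=window, n_perm=n_perm, seed=seed)
    if n_ip_w == 0 or n_iv_w == 0 or math.comb(win_idx.size, n_ip_w) < 2:
        return PermutationResult(delta=float("nan"), p=1.0, n_ip=n_ip_w, n_iv=n_iv_w,
                                 degenerate=True, method="degenerate", **base)

    if shuffle not in ("cohort", "window"):
        raise ValueError("shuffle must be 'cohort' or 'window'")

    warm: dict[bool, np.ndarray | None] = {True: None, False: None}

    def delta_for(labels: np.ndarray) -> float:
        # same tolerance for the observed and every permuted fit, so the
        # statistic is computed identically across the ensemble
        out = {}
        for arm_val in (True, False):
            rows = labels == arm_val
            sel = rows & in_window
            if not sel.any():
                raise ValueError("window lost an arm under relabeling")
            beta, bt, H0 = fast_cox(
                times[rows], events[rows], X[rows], beta0=warm[arm_val], tol=1e-7
            )
            warm[arm_val] = beta
            out[arm_val] = per_case_rms(beta, bt, H0, X[sel], tau)
        return float(out[True].mean() - out[False].mean())

    delta_obs = delta_for(is_ip)
    tol = 1e-9 * max(1.0, abs(delta_obs))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    for _ in range(n_perm):
        if shuffle == "cohort":
            labels = rng.permutation(is_ip)
        else:
            labels = is_ip.copy()
            labels[win_idx] = is_ip[rng.permutation(win_idx)]
        try:
            d = delta_for(labels)
        except (ValueError, np.linalg.LinAlgError):
            continue
        done += 1
        if abs(d) >= abs(delta_obs) - tol:
            hits += 1
    p = (1 + hits) / (done + 1)
    return PermutationResult(delta=delta_obs, p=p, n_ip=n_ip_w, n_iv=n_iv_w,
                             method=f"refit-{shuffle}", **base)


def platform_flag(delta: float, p: float, alpha: float = 0.05) -> bool:
    """A platform flags a gene when the window shows no IP benefit:
    either a significant IP decrease (Delta < 0, p < alpha) or no
    significant difference (p >= alpha)."""
    if math.isnan(delta):
        return False
    return (delta < 0 and p < alpha) or (p >= alpha)


def call_candidates(
    micro: list[PermutationResult],
    rnaseq: list[PermutationResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Candidate-biomarker calls from per-platform permutation results.

    Results are joined on (gene, endpoint, window); a candidate is flagged
    on both platforms.
    """
    def key(r: PermutationResult):
        return (r.gene, r.endpoint, tuple(r.window))

    m = {key(r): r for r in micro}
    r_ = {key(r): r for r in rnaseq}
    rows = []
    for k in sorted(set(m) | set(r_), key=str):
        rm, rr = m.get(k), r_.get(k)
        fm = platform_flag(rm.delta, rm.p, alpha) if rm and not rm.degenerate else False
        fr = platform_flag(rr.delta, rr.p, alpha) if rr and not rr.degenerate else False
        rows.append(
            {
                "gene": k[0],
                "endpoint": k[1],
                "window_lo": k[2][0],
                "window_hi": k[2][1],
                "delta_microarray": rm.delta if rm else float("nan"),
                "p_microarray": rm.p if rm else float("nan"),
                "delta_rnaseq": rr.delta if rr else float("nan"),
                "p_rnaseq": rr.p if rr else float("nan"),
                "flagged_microarray": fm,
                "flagged_rnaseq": fr,
                "candidate": fm and fr,
            }
        )
    columns = [
        "gene", "endpoint", "window_lo", "window_hi",
        "delta_microarray", "p_microarray", "delta_rnaseq", "p_rnaseq",
        "flagged_microarray", "flagged_rnaseq", "candidate",
    ]
    return pd.DataFrame(rows, columns=columns)


def window_permutation_analysis(
    records: pd.DataFrame,
    expr: ExpressionMatrix,
    genes: list[str],
    *,
    windows: list[tuple[float, float]] = ((0.0, 0.1), (0.9, 1.0)),
    endpoints: tuple[str, ...] = ("PFS", "OS"),
    covariates: tuple[str, ...] = ("age", "stage", "grade"),
    n_perm: int = 10_000,
    tau: float = TAU_DEFAULT,
    seed: int = 0,
    refit: bool = True,
    shuffle: str = "cohort",
) -> list[PermutationResult]:
    """Run the full window Delta-RMS permutation analysis on one platform.

    For each gene: pooled-cohort quantile normalization, per-arm Cox models
    of the endpoint on (q, covariates), per-case adjusted RMS, then one
    permutation test per (endpoint, window).  ``refit=True`` (default)
    refits the arm models under every relabeling, which keeps the test
    calibrated; ``refit=False`` holds the observed per-case RMS fixed
    (fast, but anti-conservative because between-arm fit noise is not
    permuted).  Not-computable combinations (empty window arm, failed
    fits) are returned as degenerate results.
    """
    results: list[PermutationResult] = []
    present = records[records["case_id"].isin(expr.samples)]
    counter = 0

    def sub_seed() -> int:
        return int(
            np.random.SeedSequence(entropy=seed, spawn_key=(counter,)).generate_state(1)[0]
            % 2**31
        )

    def degenerate(gene, endpoint, window):
        return PermutationResult(gene, endpoint, tuple(window), float("nan"),
                                 1.0, n_perm, 0, 0, seed, "degenerate", True)

    for gene in genes:
        if gene not in set(expr.genes):
            logger.info("gene %s absent from %s matrix", gene, expr.platform)
            continue
        raw = expr.values.loc[gene, present["case_id"]]
        q = normalize_relative_expression(raw.to_numpy(), index=present["case_id"].to_numpy())
        for endpoint in endpoints:
            tcol, ecol = ENDPOINT_COLS[endpoint]
            sub = analysis_subset(present, [tcol, ecol, *covariates])
            if refit:
                by_arm_events = sub.groupby("route")[ecol].apply(lambda s: s.astype(bool).sum())
                if len(by_arm_events) < 2 or (by_arm_events < 1).any():
                    logger.warning("%s %s %s: an arm has no events", gene, expr.platform, endpoint)
                    results.extend(degenerate(gene, endpoint, w) for w in windows)
                    continue
                X = encode_covariates(sub, list(covariates))
                qv = q.loc[sub["case_id"]].to_numpy(float)
                X.insert(0, "q", qv)
                Xa = X.to_numpy(float)
                times = sub[tcol].to_numpy(float)
                events_arr = sub[ecol].to_numpy(bool)
                is_ip = (sub["route"] == "IP").to_numpy()
                for window in windows:
                    counter += 1
                    lo, hi = window
                    in_window = (qv >= lo) & (qv <= hi)
                    try:
                        results.append(
                            permutation_test_refit(
                                times, events_arr, Xa, is_ip, in_window,
                                n_perm=n_perm, seed=sub_seed(), tau=tau,
                                gene=gene, endpoint=endpoint, window=tuple(window),
                                shuffle=shuffle,
                            )
                        )
                    except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
                        logger.warning("%s %s %s %s: %s", gene, expr.platform, endpoint, window, err)
                        results.append(degenerate(gene, endpoint, window))
                continue
            routes = present.set_index("case_id")["route"]
            try:
                rms_parts = [
                    adjusted_rms_per_case(present, q, arm, endpoint, covariates, tau=tau)
                    for arm in ("IP", "IV")
                ]
            except (ValueError, RuntimeError) as err:
                logger.warning("%s %s %s: %s", gene, expr.platform, endpoint, err)
                results.extend(degenerate(gene, endpoint, w) for w in windows)
                continue
            rms_by_case = pd.concat(rms_parts)
            for window in windows:
                counter += 1
                _, members = window_delta(rms_by_case, q, routes, tuple(window))
                results.append(
                    permutation_test(
                        members,
                        n_perm=n_perm,
                        seed=sub_seed(),
                        gene=gene,
                        endpoint=endpoint,
                        window=tuple(window),
                    )
                )
    return results
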