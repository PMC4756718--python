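"""Core survival mathematics: Kaplan-Meier, log-rank, Cox PH, restricted means.

All downstream stages (route comparison, per-gene validation, RMS curves)
call through this module.  Model fitting is delegated to lifelines; the
restricted-mean integration and the step-function survival predictions are
implemented here because they are the quantities the rest of the pipeline
is built on.

Conventions
-----------
* Times are in months, nonnegative.  Events are booleans (True = event
  observed, False = censored).
* Survival curves are right-continuous step functions with S(0) = 1.
* Hazard-ratio confidence intervals are Wald intervals at the 95% level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceWarning

__all__ = [
    "KMCurve",
    "CoxFit",
    "RmsValue",
    "km_fit",
    "logrank",
    "cox_fit",
    "predicted_survival",
    "rms",
    "km_rms",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class KMCurve:
    """Product-limit survival estimate for one sample."""

    times: np.ndarray  # event/censor time grid (sorted, unique)
    survival: np.ndarray  # S(t) at each grid time (right-continuous)
    at_risk: np.ndarray  # number at risk just before each grid time
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None  # first time S(t) <= 0.5, None if never reached
    n: int

    def step(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, survival) as arrays defining the step function."""
        return self.times, self.survival

    def to_frame(self) -> pd.DataFrame:
        """Curve as a tidy frame (exportable to TSV for plotting)."""
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``baseline_cumhaz`` is the Breslow cumulative hazard at the zero
    covariate vector, so S(t | x) = exp(-H0(t) * exp(beta @ x)).
    """

    covariates: list[str]
    coef: pd.Series  # log hazard ratios
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series  # Wald two-sided
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray  # H0(t) at x = 0, nondecreasing
    n_used: int
    n_events: int
    ties: str = "efron"
    warnings: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_lower": self.ci_lower,
                "hr_ci_upper": self.ci_upper,
                "p": self.p,
            }
        )


@dataclass
class RmsValue:
    """Restricted mean survival: area under S(t) on [0, tau], in months."""

    value: float
    tau: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.value <= self.tau + 1e-9:
            raise ValueError(f"RMS {self.value} outside [0, {self.tau}]")


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood 95% CI.

    The median is read off the curve as the first time at which S(t)
    drops to 0.5 or below (no interpolation); it is None when the curve
    never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if np.all((times == 0) & ~events):
        raise ValueError("all observations censored at time zero")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    ci = kmf.confidence_interval_
    lower = ci.iloc[:, 0].to_numpy()
    upper = ci.iloc[:, 1].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(dtype=float)
    if grid.size and grid[0] == 0.0 and not np.any(times == 0.0):
        # drop the synthetic t=0 anchor; S(0)=1 is implied by the step convention
        grid, surv, lower, upper, at_risk = (
            grid[1:], surv[1:], lower[1:], upper[1:], at_risk[1:]
        )

    below = np.nonzero(surv <= 0.5)[0]
    median = float(grid[below[0]]) if below.size else None
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        ci_lower=lower,
        ci_upper=upper,
        median=median,
        n=int(times.size),
    )


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(labels)}")
    mask = group == labels[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("one group is empty")
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times,
    events,
    covariate_table: pd.DataFrame,
    *,
    ties: str = "efron",
    tol: float = 1e-8,
    max_steps: int = 500,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    times, events : arrays aligned with ``covariate_table`` rows.
    covariate_table : numeric design matrix (caller encodes categoricals
        and removes missing rows; see :func:`routesurv.cohort.encode_covariates`).
    ties : ``"efron"`` (default) or ``"breslow"``.

    Raises a diagnostic error on non-convergence; near-separation is
    surfaced as a warning string on the returned fit.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if events.sum() < 1:
        raise ValueError("Cox model requires at least one event")
    X = covariate_table.reset_index(drop=True).astype(float)
    if X.isna().any().any():
        raise ValueError("missing covariate values; apply analysis_subset first")

    df = X.copy()
    df["_time"] = times
    df["_event"] = events.astype(int)
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"step_size": 0.95, "precision": tol, "max_steps": max_steps},
            )
        except ConvergenceError as err:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    for w in wlist:
        if issubclass(w.category, ConvergenceWarning):
            caught.append(str(w.message))

    coef = cph.params_
    se = cph.standard_errors_
    # Breslow baseline at the zero covariate vector: lifelines reports the
    # baseline at the training covariate means, so shift it back.
    bch = cph.baseline_cumulative_hazard_
    bt = bch.index.to_numpy(dtype=float)
    h_mean = bch.iloc[:, 0].to_numpy(dtype=float)
    mean_shift = float(np.dot(coef.to_numpy(), cph._norm_mean.to_numpy()))
    h_zero = h_mean * np.exp(-mean_shift)

    return CoxFit(
        covariates=list(X.columns),
        coef=coef,
        se=se,
        hr=np.exp(coef),
        ci_lower=np.exp(coef - Z_95 * se),
        ci_upper=np.exp(coef + Z_95 * se),
        p=cph.summary["p"],
        baseline_times=bt,
        baseline_cumhaz=h_zero,
        n_used=int(len(df)),
        n_events=int(events.sum()),
        ties=ties,
        warnings=caught,
    )


def predicted_survival(fit: CoxFit, covariate_vector) -> tuple[np.ndarray, np.ndarray]:
    """Predicted survival step function S(t | x) = exp(-H0(t) e^{beta'x}).

    Returns (times, survival) on the fit's baseline event-time grid.
    """
    x = np.asarray(covariate_vector, dtype=float).ravel()
    if x.size != len(fit.covariates):
        raise ValueError(
            f"covariate vector has {x.size} entries, fit has {len(fit.covariates)}"
        )
    lp = float(np.dot(fit.coef.to_numpy(), x))
    surv = np.exp(-fit.baseline_cumhaz * np.exp(lp))
    return fit.baseline_times, surv


def rms(times, survival, tau: float = 60.0) -> RmsValue:
    """Exact area under a right-continuous survival step function on [0, tau].

    The curve is taken to start at S = 1 at t = 0 and the last value is
    extended to tau.  ``times`` must be sorted ascending.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    t = np.asarray(times, dtype=float)
    s = np.asarray(survival, dtype=float)
    if t.size != s.size:
        raise ValueError("times and survival must align")
    if np.any((s < -1e-12) | (s > 1 + 1e-12)):
        raise ValueError("survival values outside [0, 1]")
    if tau == 0:
        return RmsValue(0.0, 0.0)
    t = np.concatenate([[0.0], t])
    s = np.concatenate([[1.0], s])
    mask = t < tau
    grid = np.append(t[mask], tau)
    area = float(np.sum(np.diff(grid) * s[mask]))
    return RmsValue(area, float(tau))


def km_rms(times, events, tau: float = 60.0) -> RmsValue:
    """Restricted mean survival of the KM curve of a sample."""
    curve = km_fit(times, events)
    return rms(curve.times, curve.survival, tau)
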