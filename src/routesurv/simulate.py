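"""Synthetic two-arm cohorts with proportional-hazards survival structure.

The generator emulates the data layout of a dual-platform tumor-expression
cohort: a clinical table (route, covariates, censored PFS/OS), a
"microarray" expression matrix covering every case, and a noisier "rnaseq"
matrix covering a subset.  Survival times follow an exact proportional-
hazards model so generating coefficients can be recovered by Cox fits:

    h(t | x) = h0(t) * exp(route + sum_g beta_g * expr_g + covariate effects)

Expression is marginally standard normal pre-noise, so per-gene log-HRs
are per-SD and comparable across genes.  Gene effects may be prognostic
(same log-HR in both arms) or route-specific (separate IP and IV log-HRs,
the "predictive" case the pipeline is designed to detect).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CLINICAL_COLUMNS, GRADE_ORDER, RACE_LEVELS, STAGE_ORDER, ExpressionMatrix

__all__ = ["SimulationConfig", "SyntheticCohort", "generate", "make_fixture", "write_cohort"]

# clinical covariate log-hazard effects applied in both arms; magnitudes are
# in the range reported for ovarian-cancer prognostic factors (age per year,
# stage per ordinal level, grade G3 vs G2, suboptimal cytoreduction)
DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.02,
    "stage": 0.30,
    "grade": 0.15,
    "cytoreduction": 0.50,
}

# marginal covariate distributions, loosely matched to a high-grade serous
# ovarian-cancer surgical cohort
STAGE_PROBS = [0.05, 0.06, 0.73, 0.16]
GRADE_PROBS = [0.12, 0.88]
RACE_PROBS = [0.90, 0.05, 0.04, 0.01]
P_OPTIMAL = 0.72
AGE_MEAN, AGE_SD = 59.0, 11.0

# default missingness per field, mirroring the heavy outcome missingness of
# registry-style clinical reporting
DEFAULT_MISSINGNESS = {
    "age": 0.02,
    "stage": 0.05,
    "grade": 0.06,
    "cytoreduction": 0.21,
    "race": 0.04,
    "os": 0.20,
    "pfs": 0.09,
}


@dataclass
class SimulationConfig:
    n_ip: int = 90
    n_iv: int = 398
    n_genes: int = 50
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    # gene -> (log-HR in IP arm, log-HR in IV arm)
    predictive_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    route_log_hr: float = math.log(0.45)
    # exponential baseline rates per endpoint (per month), IV-arm scale;
    # defaults put the IV medians near 16 (PFS) and 38 (OS) months
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"pfs": math.log(2) / 16.0, "os": math.log(2) / 38.0}
    )
    # Weibull shape per endpoint (1.0 = exponential)
    weibull_shape: dict[str, float] = field(default_factory=lambda: {"pfs": 1.0, "os": 1.0})
    censoring_rate: float = 0.012  # exponential censoring hazard per month
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    platform_overlap: float = 0.5  # fraction of cases also measured on rnaseq
    platform_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ip <= 0 or self.n_iv <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.platform_overlap <= 1:
            raise ValueError("platform_overlap must be in [0, 1]")
        for v in self.missingness.values():
            if not 0 <= v <= 1:
                raise ValueError("missingness probabilities must be in [0, 1]")

    def gene_names(self) -> list[str]:
        named = list(self.prognostic_genes) + list(self.predictive_genes)
        fillers = [f"G{i:04d}" for i in range(self.n_genes)]
        out = list(dict.fromkeys(named + fillers))[: max(self.n_genes, len(named))]
        return out


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    microarray: ExpressionMatrix
    rnaseq: ExpressionMatrix
    truth: dict
    config: SimulationConfig


def _spawn(seed: int, stream: int) -> np.random.Generator:
    """Per-component generator from a root seed and a stream counter."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort.  Fully determined by ``config`` (incl. seed).

    Survival times come from inverse-transform sampling of the Weibull
    (default exponential) cumulative hazard scaled by exp(linear predictor),
    independently per endpoint; censoring is independent exponential;
    missingness is applied after generation.
    """
    n = config.n_ip + config.n_iv
    if min(config.n_ip, config.n_iv) < 2:
        import warnings

        warnings.warn("degenerate config: fewer than 2 cases in an arm", stacklevel=2)
    genes = config.gene_names()

    rng_clin = _spawn(config.seed, 0)
    rng_expr = _spawn(config.seed, 1)
    rng_surv = _spawn(config.seed, 2)
    rng_cens = _spawn(config.seed, 3)
    rng_miss = _spawn(config.seed, 4)
    rng_plat = _spawn(config.seed, 5)

    case_id = np.array([f"CASE-{i:04d}" for i in range(n)])
    route = np.array(["IP"] * config.n_ip + ["IV"] * config.n_iv)
    age = rng_clin.normal(AGE_MEAN, AGE_SD, n)
    stage = rng_clin.choice(len(STAGE_ORDER), n, p=STAGE_PROBS)
    grade = rng_clin.choice(len(GRADE_ORDER), n, p=GRADE_PROBS)
    cyto = rng_clin.random(n) < P_OPTIMAL
    race = rng_clin.choice(len(RACE_LEVELS), n, p=RACE_PROBS)

    expr = rng_expr.standard_normal((len(genes), n))
    expr_df = pd.DataFrame(expr, index=genes, columns=case_id)

    eff = config.covariate_effects
    lin = (
        eff.get("age", 0.0) * (age - AGE_MEAN)
        + eff.get("stage", 0.0) * (stage - 2)
        + eff.get("grade", 0.0) * (grade - 1)
        + eff.get("cytoreduction", 0.0) * (~cyto).astype(float)
    )
    lin = lin + np.where(route == "IP", config.route_log_hr, 0.0)
    for g, beta in config.prognostic_genes.items():
        lin = lin + beta * expr_df.loc[g].to_numpy()
    for g, (b_ip, b_iv) in config.predictive_genes.items():
        lin = lin + np.where(route == "IP", b_ip, b_iv) * expr_df.loc[g].to_numpy()

    times = {}
    events = {}
    for endpoint in ("pfs", "os"):
        lam = config.baseline_hazard[endpoint]
        shape = config.weibull_shape.get(endpoint, 1.0)
        u = rng_surv.random(n)
        # inverse of H(t) = lam * t^shape scaled by exp(lin)
        t_event = (-np.log(u) / (lam * np.exp(lin))) ** (1.0 / shape)
        if config.censoring_rate > 0:
            t_cens = rng_cens.exponential(1.0 / config.censoring_rate, n)
        else:
            t_cens = np.full(n, np.inf)
        times[endpoint] = np.minimum(t_event, t_cens)
        events[endpoint] = t_event <= t_cens

    clinical = pd.DataFrame(
        {
            "case_id": case_id,
            "route": route,
            "age": np.round(age, 1),
            "stage": np.array(STAGE_ORDER)[stage],
            "grade": np.array(GRADE_ORDER)[grade],
            "cytoreduction": np.where(cyto, "optimal", "suboptimal"),
            "race": np.array(RACE_LEVELS)[race],
            "pfs_months": times["pfs"],
            "pfs_event": events["pfs"],
            "os_months": times["os"],
            "os_event": events["os"],
        }
    )

    miss = config.missingness
    field_cols = {
        "age": ["age"],
        "stage": ["stage"],
        "grade": ["grade"],
        "cytoreduction": ["cytoreduction"],
        "race": ["race"],
        "pfs": ["pfs_months", "pfs_event"],
        "os": ["os_months", "os_event"],
    }
    for fld, cols in field_cols.items():
        p = miss.get(fld, 0.0)
        if p > 0:
            hit = rng_miss.random(n) < p
            for c in cols:
                clinical[c] = clinical[c].astype(object)
                clinical.loc[hit, c] = None
    # numeric columns stay float dtype (missing -> NaN) so comparisons and
    # clipping behave downstream
    for c in ("age", "pfs_months", "os_months"):
        clinical[c] = pd.to_numeric(clinical[c])

    # rnaseq platform: per-arm subset, noisier copy of the same expression
    keep = np.zeros(n, dtype=bool)
    for arm in ("IP", "IV"):
        idx = np.nonzero(route == arm)[0]
        k = int(round(config.platform_overlap * idx.size))
        keep[rng_plat.choice(idx, size=k, replace=False)] = True
    rnaseq_vals = expr_df.loc[:, keep] + config.platform_noise_sd * rng_plat.standard_normal(
        (len(genes), int(keep.sum()))
    )

    truth = {
        "route_log_hr": config.route_log_hr,
        "prognostic_genes": dict(config.prognostic_genes),
        "predictive_genes": {g: list(v) for g, v in config.predictive_genes.items()},
        "covariate_effects": dict(eff),
        "baseline_hazard": dict(config.baseline_hazard),
        "seed": config.seed,
    }
    return SyntheticCohort(
        clinical=clinical[CLINICAL_COLUMNS],
        microarray=ExpressionMatrix("microarray", expr_df),
        rnaseq=ExpressionMatrix("rnaseq", rnaseq_vals),
        truth=truth,
        config=config,
    )


def make_fixture(name: str, seed: int = 0) -> SyntheticCohort:
    """Named study-condition fixtures.

    * ``tcga_like`` — 90 IP / 398 IV cases, rnaseq covering 34/90 and
      187/398 of the arms, a TCGA-scale treatment effect, a few planted
      prognostic and route-specific genes.
    * ``null_cohort`` — no route effect and no gene effects.
    * ``predictive_gene_demo`` — one gene with an IV-arm-only hazard effect.
    """
    if name == "tcga_like":
        cfg = SimulationConfig(
            n_ip=90,
            n_iv=398,
            n_genes=60,
            prognostic_genes={"PROG1": 0.3, "PROG2": -0.3},
            predictive_genes={"PRED_IV1": (0.0, 0.5), "PRED_IP1": (0.5, 0.0)},
            route_log_hr=math.log(0.45),
            platform_overlap=34.0 / 90.0,
            seed=seed,
        )
        cohort = generate(cfg)
        # rnaseq coverage differs per arm (34/90 IP, 187/398 IV); redraw the
        # platform subset at arm-specific rates
        return _redraw_overlap(cohort, {"IP": 34 / 90, "IV": 187 / 398})
    if name == "null_cohort":
        cfg = SimulationConfig(
            n_ip=100,
            n_iv=100,
            n_genes=20,
            route_log_hr=0.0,
            covariate_effects=dict(DEFAULT_COVARIATE_EFFECTS),
            seed=seed,
        )
        return generate(cfg)
    if name == "predictive_gene_demo":
        cfg = SimulationConfig(
            n_ip=200,
            n_iv=200,
            n_genes=20,
            predictive_genes={"PRED_IV1": (0.0, 0.5)},
            prognostic_genes={"PROG1": 0.5},
            route_log_hr=math.log(0.45),
            platform_overlap=0.5,
            seed=seed,
        )
        return generate(cfg)
    raise ValueError(f"unknown fixture {name!r}")


def _redraw_overlap(cohort: SyntheticCohort, rates: dict[str, float]) -> SyntheticCohort:
    """Re-select the rnaseq sample subset with per-arm coverage rates."""
    rng = _spawn(cohort.config.seed, 6)
    clin = cohort.clinical
    keep_ids: list[str] = []
    for arm, rate in rates.items():
        ids = clin.loc[clin["route"] == arm, "case_id"].to_numpy()
        k = int(round(rate * ids.size))
        keep_ids.extend(rng.choice(ids, size=k, replace=False))
    base = cohort.microarray.values[keep_ids]
    noisy = base + cohort.config.platform_noise_sd * rng.standard_normal(base.shape)
    return SyntheticCohort(
        clinical=cohort.clinical,
        microarray=cohort.microarray,
        rnaseq=ExpressionMatrix("rnaseq", noisy),
        truth=cohort.truth,
        config=cohort.config,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write clinical + expression TSVs (the formats cohort loaders read)
    and a truth JSON."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    cohort.microarray.values.to_csv(out / "microarray.tsv", sep="\t")
    cohort.rnaseq.values.to_csv(out / "rnaseq.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
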