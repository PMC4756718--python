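# Methods

`routesurv` implements a biomarker-discovery analysis for two-arm
chemotherapy cohorts — intraperitoneal (IP, meaning any intraperitoneal
administration, almost always alongside IV) versus intravenous-only (IV)
adjuvant treatment — with censored progression-free survival (PFS) and
overall survival (OS) endpoints in months and bulk tumor mRNA expression
on two platforms ("microarray" covering the cohort, "rnaseq" covering a
subset). This note records the models, the defaults and why, what the
synthetic generator does and does not emulate, and the design choices
that were genuinely open.

## Cohort handling

- **Route assignment.** A case is IP if any administered regimen was
  intraperitoneal, else IV; neoadjuvant cases are excluded at load time.
- **Truncation.** Both endpoints are administratively censored at the
  horizon (default 60 months): times are clipped and events after the
  horizon become censorings at the horizon. This matches the restriction
  time τ = 60 used for all restricted-mean calculations and is
  idempotent.
- **Missing data.** Listwise deletion per analysis: each model drops the
  cases missing any variable it uses, and the omitted count is logged and
  carried into the run manifest. No imputation anywhere.
- **Descriptive comparisons.** Continuous variables: Welch two-sample
  t-test; ordered categoricals (stage, grade): Kruskal–Wallis with tie
  correction; unordered categoricals (race, cytoreduction): Fisher's
  exact. For 2×k tables with k > 2 no exact routine exists in scipy, so
  the package enumerates all fixed-margin tables (probability-ordering
  two-sided rule) when the table space is small, and falls back to seeded
  Monte-Carlo sampling via `scipy.stats.random_table` otherwise.

## Survival core

Kaplan–Meier, log-rank and Cox proportional-hazards fitting are delegated
to lifelines (Efron tie correction, Newton–Raphson, Breslow-type baseline
cumulative hazard; 95% Wald intervals). KM medians are read as the first
time the curve reaches 0.5 or below, no interpolation. Covariate
encoding: age continuous; stage (IIA/B/C < IIIA/B < IIIC < IV) and grade
(G2 < G3) as ordered integer scores; cytoreduction binary (suboptimal =
1, optimal ⇔ residual ≤ 10 mm); race one-hot against a White reference.
Constant columns are dropped so degenerate subsets remain fittable.

Restricted mean survival (RMS) is the exact area under a right-continuous
survival step function on [0, τ]: S = 1 before the first event time, the
last value extended to τ. On a fine grid this converges to the continuous
integral (for exponential survival with mean 30 and τ = 60, to the closed
form 30(1 − e⁻²) ≈ 25.94 within 10⁻³ by ~60k grid points).

A streamlined Newton solver (`_coxfast`) re-implements the same partial
likelihood for the permutation inner loop, where thousands of refits per
gene are needed; it is validated against the lifelines path to ~10⁻⁵ in
the coefficients (the reference fitter's own convergence precision) and
supports warm starts. It is an optimization of the identical estimator,
not a different model.

## Discovery and validation

Within each arm, cases are stratified at 12 months of PFS (early
progression marks likely chemoresistance; PFS = 12.0 falls in the ≥ 12
stratum). Per-gene two-sample t-tests between strata use the Welch
variant by default — the strata are typically very unbalanced (~10% early
progressors in an IP arm) — with the pooled-variance test available by
flag. Benjamini–Hochberg adjustment is applied within arm; genes at
adjusted p < 0.05 are the discovery list. Fold change is the ratio of
arithmetic means (≥12-month over <12-month stratum) on the provided
expression scale.

Validation fits, per arm and per platform, a Cox model of each endpoint
on the gene's expression (continuous, scaled to unit SD on the analysis
subset, so HRs read "per 1 SD of expression" and are invariant to linear
rescaling of the raw values) plus age, stage and grade. The significance
gate uses raw p < 0.05 — no further multiplicity adjustment at this step.
A gene significant for OS and/or PFS on *both* platforms is a positive
discovery; an endpoint-matched variant of the gate is available by flag.

## RMS curves and the window permutation test

Expression is rank-normalized per platform over the pooled analyzed
IP+IV cohort: qᵢ = (rankᵢ − 1)/(n − 1) with average ranks for ties, so q
is the tumor's relative position in [0, 1] and invariant to monotone
transforms. RMS curves fit a univariate Cox of the endpoint on q within
an arm and integrate predicted survival to τ at each grid q; pointwise
95% bands come from a case-resampling bootstrap (percentile method,
B = 200 default, seeded) because the estimator is a composition (Cox →
predicted survival → integral) for which a delta-method band would be
needlessly intricate.

For testing, a multivariate Cox on (q, age, stage, grade) within each arm
yields a per-case adjusted RMS (the area under that case's predicted
survival). Cases with q inside a closed quantile window (defaults: the
bottom and top deciles, ties at the boundary included) are compared:
Δ = mean RMS of IP members − mean RMS of IV members, in months.

**Permutation scheme.** The default test permutes arm labels over the
whole analyzed cohort and *refits both arm models under every
relabeling* before recomputing the window members' RMS and Δ\*; the
two-tailed p is (1 + #{|Δ\*| ≥ |Δ̂|})/(B + 1). Two cheaper variants are
retained behind flags, and the choice matters:

- Holding the observed per-case RMS fixed and shuffling labels
  (`refit=False`) treats the sampling noise of the two arm fits as
  treatment signal: on null cohorts (100/arm) it rejects at ≈ 0.35
  instead of 0.05. It is provided only for sensitivity analysis.
- Refitting but shuffling labels only among window members
  (`shuffle="window"`) is calibrated but nearly powerless, because the
  route effect embedded in the arm baselines survives a window-local
  relabeling: it cannot demonstrate an IP benefit and therefore
  over-flags prognostic genes.
- The default (`shuffle="cohort"`) tests exchangeability of the route
  label given expression — i.e. the null that IP confers no survival
  difference at any expression level, which is the decision-relevant
  hypothesis here — and is both calibrated and powered. Measured on
  seeded synthetic nulls the rejection rate at α = 0.05 is slightly
  conservative (the +1 correction and refit-failure skipping can only
  raise p).

For small windows the fixed-value test switches to exact enumeration of
all C(n, n_IP) label assignments (p is then the exact tail proportion and
can never be zero).

**Candidate logic.** A platform flags a gene/endpoint/window when IP
members show either a significant survival *decrease* (Δ < 0, p < α) or
no significant difference (p ≥ α) — i.e. no demonstrated IP benefit. A
gene flagged on both platforms for the same endpoint and window is a
candidate biomarker. Note the asymmetry is deliberate and inherited from
the study design: absence of evidence of benefit is treated as a flag,
so low-powered strata flag liberally; the dual-platform requirement and
the demand that the *benefit* be demonstrable elsewhere are what keep
the false-call rate down.

## Synthetic cohorts

`simulate.generate` draws survival by inverse-transform sampling from a
Weibull (default exponential) cumulative hazard scaled by
exp(linear predictor), giving exact proportional hazards so generating
coefficients are recoverable by Cox fits. The linear predictor sums the
route effect (default ln 0.45 for IP), per-gene effects — prognostic
(both arms) or route-specific (separate IP/IV log-HRs) — and clinical
covariate effects (age 0.02/yr, stage 0.30/level, grade 0.15, suboptimal
cytoreduction 0.50; magnitudes in the range reported for ovarian-cancer
prognostic factors). Expression is marginally standard normal, so gene
log-HRs are per SD. Baseline rates put the IV-arm medians near 16 months
(PFS) and 38 months (OS); censoring is independent exponential
(0.012/month); per-field missingness mirrors registry-style reporting
(heaviest for OS, ~20%). The rnaseq platform is the microarray values
plus Gaussian noise on a per-arm subset of cases. A single root seed
streams per-component seeds (clinical, expression, survival, censoring,
missingness, platform), so any stage is reproducible in isolation.

What the generator does *not* emulate: microarray normalization
artifacts, RNA-Seq count distributions (only a noise model), correlation
between genes, correlation between PFS and OS beyond shared covariates
(the endpoints are drawn independently given the linear predictor), or
informative censoring. Passing tests therefore show the machinery is
correct and calibrated under clean proportional-hazards data, not that
real cohorts satisfy those assumptions.

Fixtures: `tcga_like` (90 IP / 398 IV, rnaseq covering 34 and 187 cases
per arm, a few planted genes), `null_cohort` (no route or gene effects),
`predictive_gene_demo` (one IV-arm-only gene, one prognostic gene,
200/arm).

## Operating-characteristic studies

`experiments.null_calibration` measures the permutation test's type-I
error over seeded null cohorts (defaults 200 cohorts, 100/arm, 500
permutations, both decile windows). `experiments.planted_recovery`
measures candidate-call rates for a planted route-specific gene
(IV-arm log-HR 0.5/SD — at the bottom decile its IV-arm hazard reduction
roughly cancels the IP route benefit, the pattern the pipeline should
flag) versus a prognostic-only gene of the same magnitude (50 cohorts,
200/arm, 1000 permutations, bottom-decile window, PFS, platforms gated
jointly). These sizes keep each study to a few minutes on one core while
leaving Monte-Carlo error around one percentage point for the
calibration rate and ~5 points for the recovery rates; the prognostic
false-call rate is the tightest of these margins, since it depends on
demonstrating the IP benefit inside a ~40-member window on both
platforms.

## Numerical choices and degenerate inputs

- Cox convergence: gradient-norm tolerance 10⁻⁸ (lifelines path) / 10⁻⁹
  (fast path), Newton with step-halving; non-convergence raises,
  near-separation attaches a warning to the fit.
- Zero-variance genes: t-test returns t = 0, p = 1, flagged; per-SD
  scaling refuses constant vectors; constant covariate columns are
  dropped with a log message.
- All-identical expression cannot be rank-normalized (error), ties get
  average ranks.
- Windows are closed intervals; boundary ties are all included.
- Permutation p-values use the +1 correction (sampled) or exact tail
  proportions (enumeration); both are strictly positive.
- Every stochastic stage receives a seed derived from the root seed via
  `numpy.random.SeedSequence(root, spawn_key=(counter,))`, kept below
  2³¹; identical configuration and seed reproduce outputs byte for byte.

## Known limitations

- The RMS-vs-q model is linear in q on the log-hazard scale; strongly
  nonlinear expression effects are flattened at the extremes of q, which
  shrinks window deltas for extreme-expression subsets.
- Refit permutations cost two Cox fits each; genome-scale runs at
  B = 10,000 are expensive (the fast solver mitigates but does not
  remove this).
- The dual-platform gate requires the gene on both platforms; cases or
  genes absent from the second platform make a gene untestable rather
  than positive.
- The candidate logic treats *absence of demonstrated benefit* as a flag,
  so its specificity against purely prognostic genes is limited by the
  power of the window comparison: at the operating-characteristic study
  sizes (200/arm, decile windows, half rnaseq coverage) the per-platform
  power to demonstrate the IP benefit is well below 1, and
  `planted_recovery` reports a substantial prognostic false-candidate
  rate alongside the high route-specific recovery rate. Larger cohorts,
  wider windows, or full dual-platform coverage raise that specificity;
  the rates for any condition of interest can be recomputed directly
  with `experiments.planted_recovery`.
- Proportional-hazards diagnostics, frailty, and time-varying covariates
  are out of scope.
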