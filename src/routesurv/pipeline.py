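"""End-to-end pipeline: cohort -> route survival -> discovery -> validation
-> window permutation -> candidate calls, with seeded stages and
publication-style table outputs (TSV + full-precision JSON + run manifest)."""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import discovery, rms_perm, simulate, survival, validation
from .cohort import (
    analysis_subset,
    encode_covariates,
    load_clinical,
    load_expression,
    summarize_cohort,
    truncate_survival,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_tables"]


@dataclass
class PipelineConfig:
    # either a fixture name, or explicit input paths
    fixture: str | None = "tcga_like"
    clinical_path: str | None = None
    microarray_path: str | None = None
    rnaseq_path: str | None = None
    gene_universe: list[str] | None = None  # None = all genes in the matrix
    horizon: float = 60.0
    pfs_cutoff: float = 12.0
    alpha: float = 0.05
    windows: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 0.1), (0.9, 1.0)])
    n_perm: int = 10_000
    n_bootstrap: int = 200
    seed: int = 0
    route_covariates: list[str] = field(
        default_factory=lambda: ["age", "stage", "grade", "cytoreduction", "race"]
    )
    gene_covariates: list[str] = field(default_factory=lambda: ["age", "stage", "grade"])
    outdir: str = "routesurv_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.windows = [tuple(w) for w in cfg.windows]
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["windows"] = [list(w) for w in self.windows]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def stage_seed(self, stage: int) -> int:
        """Derived per-stage seed: root seed + stage counter, kept < 2^31."""
        return int(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,)).generate_state(1)[0]
            % 2**31
        )


def _load_inputs(config: PipelineConfig):
    if config.fixture:
        cohort = simulate.make_fixture(config.fixture, seed=config.stage_seed(0))
        return cohort.clinical, cohort.microarray, cohort.rnaseq
    clinical = load_clinical(config.clinical_path)
    micro = load_expression(config.microarray_path, "microarray").matched_to(clinical)
    rnaseq = (
        load_expression(config.rnaseq_path, "rnaseq").matched_to(clinical)
        if config.rnaseq_path
        else None
    )
    return clinical, micro, rnaseq


def _route_survival(clinical: pd.DataFrame, config: PipelineConfig) -> dict:
    """Fig-1-style comparison: KM medians + log-rank, and adjusted Cox HR."""
    out = {}
    for endpoint, (tcol, ecol) in (("PFS", ("pfs_months", "pfs_event")),
                                   ("OS", ("os_months", "os_event"))):
        km_sub = analysis_subset(clinical, [tcol, ecol])
        entry = {"n_km": len(km_sub), "n_km_omitted": len(clinical) - len(km_sub)}
        medians = {}
        for arm in ("IP", "IV"):
            a = km_sub[km_sub["route"] == arm]
            curve = survival.km_fit(a[tcol].to_numpy(float), a[ecol].to_numpy(bool))
            medians[arm] = curve.median
        stat, p = survival.logrank(
            km_sub[tcol].to_numpy(float),
            km_sub[ecol].to_numpy(bool),
            km_sub["route"].to_numpy(),
        )
        entry.update(median_ip=medians["IP"], median_iv=medians["IV"],
                     logrank_stat=stat, logrank_p=p)

        cox_sub = analysis_subset(clinical, [tcol, ecol, *config.route_covariates])
        X = encode_covariates(cox_sub, config.route_covariates)
        X.insert(0, "route_ip", (cox_sub["route"] == "IP").astype(float))
        try:
            fit = survival.cox_fit(cox_sub[tcol].to_numpy(float),
                                   cox_sub[ecol].to_numpy(bool), X)
            entry.update(
                cox_hr=float(fit.hr["route_ip"]),
                cox_ci=[float(fit.ci_lower["route_ip"]), float(fit.ci_upper["route_ip"])],
                cox_p=float(fit.p["route_ip"]),
                n_cox=fit.n_used,
                n_cox_omitted=len(clinical) - fit.n_used,
            )
        except (ValueError, RuntimeError) as err:
            logger.warning("route Cox (%s) failed: %s", endpoint, err)
            entry["cox_error"] = str(err)
        out[endpoint] = entry
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write tables, manifest, and logs to outdir.

    Returns a dict bundle with all in-memory results.
    """
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    clinical, micro, rnaseq = _load_inputs(config)
    clinical = truncate_survival(clinical, config.horizon)

    bundle: dict = {"config": asdict(config)}
    manifest: dict = {
        "n_cases": int(len(clinical)),
        "n_ip": int((clinical["route"] == "IP").sum()),
        "n_iv": int((clinical["route"] == "IV").sum()),
        "seed": config.seed,
        "stage_seeds": {k: config.stage_seed(i) for i, k in
                        enumerate(["fixture", "discovery", "rms_micro", "rms_rnaseq"])},
    }

    # Table 1 analogue
    bundle["summary"] = summarize_cohort(clinical)

    # Fig 1 analogue
    bundle["route_survival"] = _route_survival(clinical, config)

    # discovery (microarray only, per arm)
    strat = discovery.stratify_pfs(clinical, config.pfs_cutoff)
    de_frames = []
    de_genes: dict[str, list[str]] = {}
    for arm in ("IP", "IV"):
        arm_ids = set(clinical.loc[clinical["route"] == arm, "case_id"])
        arm_strat = discovery.PfsStratification(
            strat.strata[strat.strata.index.isin(arm_ids)], strat.cutoff
        )
        try:
            de = discovery.gene_ttest(micro, arm_strat, config.gene_universe, arm=arm)
        except ValueError as err:
            logger.warning("discovery in arm %s skipped: %s", arm, err)
            de_genes[arm] = []
            continue
        de_frames.append(de)
        de_genes[arm] = discovery.call_de(de, config.alpha)
    bundle["de_results"] = pd.concat(de_frames, ignore_index=True) if de_frames else pd.DataFrame()
    bundle["de_genes"] = de_genes
    manifest["n_de_genes"] = {arm: len(g) for arm, g in de_genes.items()}

    # validation Cox per arm on both platforms, then the dual gate
    all_de = sorted(set(de_genes.get("IP", [])) | set(de_genes.get("IV", [])))
    verdicts = []
    assoc_frames = []
    for arm in ("IP", "IV"):
        arm_records = clinical[clinical["route"] == arm]
        genes_arm = de_genes.get(arm, [])
        if not genes_arm:
            continue
        assoc_m = validation.validate_genes(arm_records, micro, genes_arm,
                                            tuple(config.gene_covariates))
        assoc_m["arm"] = arm
        assoc_frames.append(assoc_m)
        if rnaseq is not None:
            assoc_r = validation.validate_genes(arm_records, rnaseq, genes_arm,
                                                tuple(config.gene_covariates))
            assoc_r["arm"] = arm
            assoc_frames.append(assoc_r)
            verdict = validation.dual_validate(assoc_m, assoc_r, config.alpha)
            verdict["arm"] = arm
            verdicts.append(verdict)
    bundle["associations"] = (
        pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame()
    )
    bundle["verdicts"] = pd.concat(verdicts, ignore_index=True) if verdicts else pd.DataFrame()

    # window permutation on both platforms for all DE genes
    perm_micro = rms_perm.window_permutation_analysis(
        clinical, micro, all_de,
        windows=[tuple(w) for w in config.windows],
        covariates=tuple(config.gene_covariates),
        n_perm=config.n_perm,
        seed=config.stage_seed(2),
    )
    if rnaseq is not None:
        perm_rnaseq = rms_perm.window_permutation_analysis(
            clinical, rnaseq, all_de,
            windows=[tuple(w) for w in config.windows],
            covariates=tuple(config.gene_covariates),
            n_perm=config.n_perm,
            seed=config.stage_seed(3),
        )
        bundle["candidates"] = rms_perm.call_candidates(perm_micro, perm_rnaseq, config.alpha)
    else:
        perm_rnaseq = []
        bundle["candidates"] = rms_perm.call_candidates(perm_micro, [], config.alpha)
    bundle["perm_results"] = {"microarray": perm_micro, "rnaseq": perm_rnaseq}
    manifest["n_candidates"] = int(bundle["candidates"]["candidate"].sum()) if len(
        bundle["candidates"]
    ) else 0

    bundle["manifest"] = manifest
    render_tables(bundle, outdir)
    logger.info("pipeline complete: %s", manifest)
    return bundle


def _fmt(df: pd.DataFrame, digits: int = 4) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: f"{v:.{digits}g}" if pd.notna(v) else "")
    return out


def render_tables(bundle: dict, outdir) -> None:
    """Write TSV tables (printed precision) and JSON (full precision)."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    _fmt(bundle["summary"]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    if len(bundle["de_results"]):
        cols = ["gene", "arm", "p_adj", "fold_change", "t", "p"]
        _fmt(bundle["de_results"][cols]).to_csv(outdir / "discovery.tsv",
                                                sep="\t", index=False)
    else:
        pd.DataFrame(columns=["gene", "arm", "p_adj", "fold_change", "t", "p"]).to_csv(
            outdir / "discovery.tsv", sep="\t", index=False
        )
    if len(bundle["associations"]):
        _fmt(bundle["associations"]).to_csv(outdir / "validation.tsv",
                                            sep="\t", index=False)
    _fmt(bundle["candidates"]).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    full = {
        "route_survival": bundle["route_survival"],
        "manifest": bundle["manifest"],
        "de_genes": bundle["de_genes"],
        "candidates": bundle["candidates"].to_dict(orient="records"),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(full, fh, indent=2, default=_json_default)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({**bundle["manifest"], "config": bundle["config"]}, fh, indent=2,
                  default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
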