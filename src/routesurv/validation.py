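"""Dual-platform Cox validation of discovered genes.

Each discovered gene is entered as a continuous covariate (scaled to unit
standard deviation, so hazard ratios read "per 1 SD of expression") in a
Cox model of PFS and OS with clinical covariates, separately per platform.
A gene significantly associated with OS and/or PFS on *both* platforms is
a positive discovery — the stringent dual-validation gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival
from .cohort import ExpressionMatrix, analysis_subset, encode_covariates

logger = logging.getLogger(__name__)

__all__ = ["scale_per_sd", "gene_cox", "dual_validate", "validate_genes"]

ENDPOINT_COLS = {"PFS": ("pfs_months", "pfs_event"), "OS": ("os_months", "os_event")}


def scale_per_sd(values) -> np.ndarray:
    """Divide by the sample standard deviation (ddof=1); result has SD 1.

    Cox partial likelihood is location-invariant, so no centering is needed:
    exp(beta) on the scaled values is the hazard ratio per 1 SD of raw
    expression.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >=2 distinct values to scale per SD")
    return x / np.std(x, ddof=1)


@dataclass
class GeneSurvivalAssociation:
    gene: str
    platform: str
    endpoint: str  # "PFS" or "OS"
    hr_per_sd: float
    ci_lower: float
    ci_upper: float
    p: float
    n_used: int
    n_omitted: int


def gene_cox(
    records: pd.DataFrame,
    expr: ExpressionMatrix,
    gene: str,
    endpoint: str,
    covariates: tuple[str, ...] = ("age", "stage", "grade"),
) -> GeneSurvivalAssociation:
    """Cox model of one endpoint on one gene's expression plus covariates.

    ``records`` is typically a single chemotherapy arm.  Listwise deletion
    on the endpoint and covariates is applied here; expression is scaled
    per SD on the resulting analysis subset, so the reported HR is per
    1 SD of expression among the modeled cases.
    """
    tcol, ecol = ENDPOINT_COLS[endpoint]
    sub = records[records["case_id"].isin(expr.samples)]
    n_start = len(sub)
    sub = analysis_subset(sub, [tcol, ecol, *covariates])
    if sub.empty:
        raise ValueError("empty analysis subset")
    raw = expr.values.loc[gene, sub["case_id"]].to_numpy(dtype=float)
    X = encode_covariates(sub, list(covariates))
    X.insert(0, "expr_sd", scale_per_sd(raw))
    fit = survival.cox_fit(sub[tcol].to_numpy(float), sub[ecol].to_numpy(bool), X)
    return GeneSurvivalAssociation(
        gene=gene,
        platform=expr.platform,
        endpoint=endpoint,
        hr_per_sd=float(fit.hr["expr_sd"]),
        ci_lower=float(fit.ci_lower["expr_sd"]),
        ci_upper=float(fit.ci_upper["expr_sd"]),
        p=float(fit.p["expr_sd"]),
        n_used=len(sub),
        n_omitted=n_start - len(sub),
    )


def validate_genes(
    records: pd.DataFrame,
    expr: ExpressionMatrix,
    genes: list[str],
    covariates: tuple[str, ...] = ("age", "stage", "grade"),
) -> pd.DataFrame:
    """Per-gene PFS and OS Cox associations on one platform (long format)."""
    rows = []
    for gene in genes:
        if gene not in set(expr.genes):
            logger.info("gene %s absent from %s matrix", gene, expr.platform)
            continue
        for endpoint in ("PFS", "OS"):
            try:
                assoc = gene_cox(records, expr, gene, endpoint, covariates)
            except (ValueError, RuntimeError) as err:
                logger.warning("%s %s %s: %s", gene, expr.platform, endpoint, err)
                continue
            rows.append(vars(assoc))
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "platform",
            "endpoint",
            "hr_per_sd",
            "ci_lower",
            "ci_upper",
            "p",
            "n_used",
            "n_omitted",
        ],
    )


def dual_validate(
    micro: pd.DataFrame,
    rnaseq: pd.DataFrame,
    alpha: float = 0.05,
    *,
    endpoint_matched: bool = False,
) -> pd.DataFrame:
    """Positive-discovery gate across platforms.

    A platform "passes" a gene when its Cox p < alpha for OS and/or PFS on
    that platform; a positive discovery passes on both.  With
    ``endpoint_matched=True`` the same endpoint must be significant on both
    platforms.  Genes absent from a platform are flagged untestable and
    cannot be positive.
    """
    def per_gene(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=["gene", "sig_pfs", "sig_os"]).set_index("gene")
        wide = df.pivot_table(index="gene", columns="endpoint", values="p", aggfunc="first")
        out = pd.DataFrame(index=wide.index)
        out["sig_pfs"] = wide.get("PFS", pd.Series(index=wide.index)) < alpha
        out["sig_os"] = wide.get("OS", pd.Series(index=wide.index)) < alpha
        return out

    m = per_gene(micro)
    r = per_gene(rnaseq)
    genes = sorted(set(m.index) | set(r.index))
    rows = []
    for g in genes:
        in_m, in_r = g in m.index, g in r.index
        if endpoint_matched:
            passed_m = passed_r = False
            both = False
            if in_m and in_r:
                for ep in ("sig_pfs", "sig_os"):
                    if bool(m.loc[g, ep]) and bool(r.loc[g, ep]):
                        both = True
                passed_m = bool(m.loc[g, ["sig_pfs", "sig_os"]].any()) if in_m else False
                passed_r = bool(r.loc[g, ["sig_pfs", "sig_os"]].any()) if in_r else False
            positive = both
        else:
            passed_m = bool(m.loc[g, ["sig_pfs", "sig_os"]].any()) if in_m else False
            passed_r = bool(r.loc[g, ["sig_pfs", "sig_os"]].any()) if in_r else False
            positive = passed_m and passed_r
        rows.append(
            {
                "gene": g,
                "passed_microarray": passed_m,
                "passed_rnaseq": passed_r,
                "untestable": not (in_m and in_r),
                "positive_discovery": positive and in_m and in_r,
            }
        )
    return pd.DataFrame(rows)
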