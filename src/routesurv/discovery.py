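"""PFS-stratified differential expression within each chemotherapy arm.

Cases in an arm are split at 12 months of progression-free survival
(early progression marks likely chemoresistance); per-gene two-sample
t-tests between the strata, Benjamini-Hochberg FDR adjustment, and
fold changes (mean expression in the >=12-month stratum over the
<12-month stratum) yield the differentially-expressed gene lists that
feed the validation and RMS stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PfsStratification", "stratify_pfs", "gene_ttest", "fdr_adjust", "call_de"]


@dataclass
class PfsStratification:
    """case_id -> stratum ("lt12" / "ge12"); unassigned cases have null PFS."""

    strata: pd.Series  # index case_id, values "lt12"/"ge12"
    cutoff: float

    def counts(self) -> dict[str, int]:
        return self.strata.value_counts().to_dict()

    def cases(self, stratum: str) -> list[str]:
        return list(self.strata.index[self.strata == stratum])


def stratify_pfs(records: pd.DataFrame, cutoff: float = 12.0) -> PfsStratification:
    """Assign each case with non-null PFS to lt12 (< cutoff) or ge12 (>= cutoff)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    has = records["pfs_months"].notna()
    sub = records.loc[has]
    strata = pd.Series(
        np.where(sub["pfs_months"].astype(float) < cutoff, "lt12", "ge12"),
        index=sub["case_id"].to_numpy(),
        name="stratum",
    )
    return PfsStratification(strata=strata, cutoff=float(cutoff))


def _welch(a: np.ndarray, b: np.ndarray, *, equal_var: bool = False) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0:
        # zero-variance gene in both strata: no evidence either way
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def gene_ttest(
    expr: ExpressionMatrix,
    strat: PfsStratification,
    gene_universe: list[str] | None = None,
    *,
    arm: str = "",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between PFS strata.

    Welch (unequal-variance) by default since the strata are typically very
    unbalanced; set ``equal_var=True`` for the pooled-variance variant.
    Returns one row per gene with t, raw p, BH-adjusted p, fold change
    (mean ge12 / mean lt12) and group means/sizes.
    """
    universe = list(gene_universe) if gene_universe is not None else expr.genes
    missing = [g for g in universe if g not in set(expr.genes)]
    if missing:
        logger.info("%d universe gene(s) absent from %s matrix; skipped", len(missing), expr.platform)
    genes = [g for g in universe if g in set(expr.genes)]

    cols = set(expr.samples)
    ge_ids = [c for c in strat.cases("ge12") if c in cols]
    lt_ids = [c for c in strat.cases("lt12") if c in cols]
    if len(ge_ids) < 2 or len(lt_ids) < 2:
        raise ValueError("each PFS stratum needs >=2 samples with expression")

    ge = expr.values.loc[genes, ge_ids].to_numpy(dtype=float)
    lt = expr.values.loc[genes, lt_ids].to_numpy(dtype=float)

    rows = []
    for i, g in enumerate(genes):
        t, p = _welch(ge[i], lt[i], equal_var=equal_var)
        m_ge, m_lt = float(ge[i].mean()), float(lt[i].mean())
        fc = m_ge / m_lt if m_lt != 0 else np.nan
        rows.append(
            {
                "gene": g,
                "arm": arm,
                "t": t,
                "p": p,
                "fold_change": fc,
                "mean_ge12": m_ge,
                "mean_lt12": m_lt,
                "n_ge12": ge.shape[1],
                "n_lt12": lt.shape[1],
                "zero_variance": bool(np.var(ge[i]) == 0 and np.var(lt[i]) == 0),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = fdr_adjust(out["p"].to_numpy())
    return out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes differentially expressed at BH-adjusted p < alpha."""
    if results.empty:
        raise ValueError("empty results")
    hits = results.loc[results["p_adj"] < alpha]
    return list(hits["gene"])
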