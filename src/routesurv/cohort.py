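"""Clinical/expression input handling, truncation, listwise deletion, summaries.

The clinical table is carried as a pandas DataFrame with one row per case
and the canonical columns in :data:`CLINICAL_COLUMNS`.  Chemotherapy route
is the two-arm exposure: ``IP`` means any intraperitoneal administration
(almost always alongside IV), ``IV`` means intravenous only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CLINICAL_COLUMNS",
    "STAGE_ORDER",
    "GRADE_ORDER",
    "ExpressionMatrix",
    "load_clinical",
    "load_expression",
    "truncate_survival",
    "analysis_subset",
    "encode_covariates",
    "summarize_cohort",
    "fisher_exact_2xk",
]

STAGE_ORDER = ["IIA/B/C", "IIIA/B", "IIIC", "IV"]
GRADE_ORDER = ["G2", "G3"]
RACE_LEVELS = ["White", "Black", "Asian", "Other"]

CLINICAL_COLUMNS = [
    "case_id",
    "route",
    "age",
    "stage",
    "grade",
    "cytoreduction",
    "race",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
]

#: continuous vs ordered vs unordered classification used by summarize_cohort
_VARIABLE_KIND = {
    "age": "continuous",
    "stage": "ordered",
    "grade": "ordered",
    "race": "categorical",
    "cytoreduction": "categorical",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one platform."""

    platform: str  # "microarray" or "rnaseq"
    values: pd.DataFrame  # index = gene symbols, columns = case_ids

    def __post_init__(self) -> None:
        if self.platform not in ("microarray", "rnaseq"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate case_ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def matched_to(self, clinical: pd.DataFrame) -> "ExpressionMatrix":
        """Restrict columns to samples present in the clinical table."""
        keep = [c for c in self.values.columns if c in set(clinical["case_id"])]
        unmatched = self.values.shape[1] - len(keep)
        if unmatched:
            logger.info(
                "%s: %d expression samples without clinical record dropped",
                self.platform,
                unmatched,
            )
        return ExpressionMatrix(self.platform, self.values[keep])


def _coerce_bool(x):
    if pd.isna(x):
        return np.nan
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("1", "true", "yes", "y", "event"):
            return True
        if s in ("0", "false", "no", "n", "censored"):
            return False
        return np.nan
    return bool(x)


def load_clinical(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical TSV/CSV into the canonical clinical frame.

    ``schema`` maps canonical column names to file column names; identity
    is assumed for omitted entries.  Rows lacking ``case_id`` or ``route``
    are rejected (with a logged reason), as are rows flagged neoadjuvant.
    Unparseable optional fields become null.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    schema = schema or {}
    colmap = {schema.get(c, c): c for c in CLINICAL_COLUMNS + ["neoadjuvant"]}
    present = {src: dst for src, dst in colmap.items() if src in raw.columns}
    df = raw.rename(columns=present)

    for required in ("case_id", "route"):
        if required not in df.columns:
            raise KeyError(f"required column {required!r} missing from {path}")

    n0 = len(df)
    rejected = df["case_id"].isna() | (df["case_id"].astype(str).str.strip() == "")
    route = df["route"].astype(str).str.strip().str.upper()
    route = route.where(route.isin(["IP", "IV"]))
    rejected |= route.isna()
    if "neoadjuvant" in df.columns:
        neo = df["neoadjuvant"].map(_coerce_bool).fillna(False).astype(bool)
        if neo.any():
            logger.info("excluding %d neoadjuvant case(s)", int(neo.sum()))
        rejected |= neo
    if rejected.any():
        logger.info("rejected %d of %d rows (missing id/route or excluded)", int(rejected.sum()), n0)
    df = df.loc[~rejected].copy()
    df["route"] = route.loc[df.index]

    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_id(s): {dupes[:5]}")

    out = pd.DataFrame({"case_id": df["case_id"].astype(str), "route": df["route"]})
    for col in ("age", "pfs_months", "os_months"):
        out[col] = pd.to_numeric(df.get(col), errors="coerce")
    for col, levels in (("stage", STAGE_ORDER), ("grade", GRADE_ORDER)):
        vals = df.get(col, pd.Series(index=df.index, dtype=object))
        out[col] = vals.where(vals.isin(levels))
    cyto = df.get("cytoreduction", pd.Series(index=df.index, dtype=object))
    if cyto is not None:
        cyto = cyto.astype(str).str.strip().str.lower().where(lambda s: s.isin(["optimal", "suboptimal"]))
    out["cytoreduction"] = cyto
    race = df.get("race", pd.Series(index=df.index, dtype=object))
    out["race"] = race.astype(str).str.strip().str.title().where(lambda s: s.isin(RACE_LEVELS))
    for col in ("pfs_event", "os_event"):
        out[col] = df.get(col, pd.Series(index=df.index, dtype=object)).map(_coerce_bool)

    for col in ("pfs_months", "os_months"):
        neg = out[col] < 0
        if neg.any():
            raise ValueError(f"negative {col} for {out.loc[neg, 'case_id'].tolist()[:5]}")

    out = out.reset_index(drop=True)
    for col in CLINICAL_COLUMNS:
        missing = out[col].isna().sum()
        if missing:
            logger.debug("%s: %d missing", col, missing)
    logger.info("loaded %d clinical records from %s", len(out), path)
    return out[CLINICAL_COLUMNS]


def load_expression(path, platform: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(platform, df.astype(float))


def truncate_survival(records: pd.DataFrame, horizon: float = 60.0) -> pd.DataFrame:
    """Administratively censor both endpoints at ``horizon`` months.

    Times are clipped to the horizon; an event strictly after the horizon
    becomes a censoring at the horizon.  Events at t <= horizon are kept.
    Idempotent.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = records.copy()
    for tcol, ecol in (("pfs_months", "pfs_event"), ("os_months", "os_event")):
        t = out[tcol]
        if (t < 0).any():
            raise ValueError(f"negative {tcol}")
        over = t > horizon
        out.loc[over, ecol] = False
        out[tcol] = t.clip(upper=horizon)
    return out


def analysis_subset(records: pd.DataFrame, required_fields: list[str]) -> pd.DataFrame:
    """Listwise deletion: keep rows with all ``required_fields`` non-null.

    The omitted count is logged, mirroring per-model omission reporting.
    """
    unknown = set(required_fields) - set(records.columns)
    if unknown:
        raise KeyError(f"unknown fields: {sorted(unknown)}")
    if not required_fields:
        return records.copy()
    keep = records[list(required_fields)].notna().all(axis=1)
    omitted = int((~keep).sum())
    if omitted:
        logger.info("analysis_subset: %d case(s) omitted for missing %s", omitted, required_fields)
    return records.loc[keep].copy()


def encode_covariates(
    records: pd.DataFrame,
    covariates: list[str],
) -> pd.DataFrame:
    """Numeric design matrix for Cox models.

    Encoding: age continuous; stage/grade as ordered integer scores;
    cytoreduction as binary (1 = suboptimal); race one-hot against a
    White reference.  Constant columns are dropped (with a log message)
    so degenerate subsets remain fittable.
    """
    parts = {}
    for cov in covariates:
        if cov == "age":
            parts["age"] = records["age"].astype(float)
        elif cov == "stage":
            parts["stage_score"] = records["stage"].map({s: i for i, s in enumerate(STAGE_ORDER)}).astype(float)
        elif cov == "grade":
            parts["grade_score"] = records["grade"].map({g: i for i, g in enumerate(GRADE_ORDER)}).astype(float)
        elif cov == "cytoreduction":
            parts["suboptimal"] = (records["cytoreduction"] == "suboptimal").astype(float)
        elif cov == "race":
            for level in RACE_LEVELS[1:]:
                parts[f"race_{level.lower()}"] = (records["race"] == level).astype(float)
        else:
            parts[cov] = records[cov].astype(float)
    X = pd.DataFrame(parts, index=records.index)
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        logger.info("dropping constant covariate column(s): %s", constant)
        X = X.drop(columns=constant)
    return X


def _fisher_table_logp(table: np.ndarray) -> float:
    """log P(table) under the fixed-margin hypergeometric model."""
    table = np.asarray(table)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(math.lgamma(r + 1) for r in row)
        + sum(math.lgamma(c + 1) for c in col)
        - math.lgamma(n + 1)
        - sum(math.lgamma(v + 1) for v in table.ravel())
    )
    return lp


def fisher_exact_2xk(
    table,
    *,
    max_enumeration: int = 2_000_000,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Two-sided Fisher's exact test for a 2 x k contingency table.

    The p-value is the total probability, under the fixed-margin null, of
    tables no more probable than the observed one.  Exact enumeration over
    first-row compositions when the table space is small enough, otherwise
    seeded Monte-Carlo sampling of fixed-margin tables.

    Returns (p, method) with method in {"exact", "monte-carlo"}.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (obs < 0).any():
        raise ValueError("negative cell count")
    col = obs.sum(axis=0)
    row = obs.sum(axis=1)
    if row.min() == 0 or (col == 0).all():
        return 1.0, "exact"
    keep = col > 0
    obs = obs[:, keep]
    col = col[keep]
    k = obs.shape[1]

    lp_obs = _fisher_table_logp(obs)
    space = int(np.prod([min(row[0], c) + 1 for c in col]))
    if space <= max_enumeration:
        total = 0.0
        extreme = 0.0
        ranges = [range(min(row[0], c) + 1) for c in col[:-1]]
        for first in itertools.product(*ranges):
            last = row[0] - sum(first)
            if last < 0 or last > col[-1]:
                continue
            r1 = np.array(list(first) + [last])
            cand = np.vstack([r1, col - r1])
            lp = _fisher_table_logp(cand)
            p = math.exp(lp)
            total += p
            if lp <= lp_obs + 1e-9:
                extreme += p
        return min(1.0, extreme / total), "exact"

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row, col, seed=rng)
    draws = sampler.rvs(n_monte_carlo)
    lps = np.array([_fisher_table_logp(d) for d in draws])
    hits = int(np.sum(lps <= lp_obs + 1e-9))
    return (hits + 1) / (n_monte_carlo + 1), "monte-carlo"


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive by-route comparison of baseline variables.

    Continuous variables use a two-sample Welch t-test, ordered categorical
    variables Kruskal-Wallis (with tie correction), unordered categorical
    variables Fisher's exact (2 x k).  Missing values are excluded from
    each comparison, so denominators are per-variable.
    """
    rows = []
    ip = records[records["route"] == "IP"]
    iv = records[records["route"] == "IV"]
    for var, kind in _VARIABLE_KIND.items():
        a = ip[var].dropna()
        b = iv[var].dropna()
        entry = {
            "variable": var,
            "kind": kind,
            "n_ip": len(a),
            "n_iv": len(b),
        }
        if len(a) < 2 or len(b) < 2:
            entry.update(test="none", statistic=np.nan, p=np.nan, computable=False)
            rows.append(entry)
            continue
        entry["computable"] = True
        if kind == "continuous":
            stat, p = stats.ttest_ind(a.astype(float), b.astype(float), equal_var=False)
            entry.update(
                test="t-test",
                statistic=float(stat),
                p=float(p),
                mean_ip=float(a.mean()),
                mean_iv=float(b.mean()),
            )
        elif kind == "ordered":
            order = STAGE_ORDER if var == "stage" else GRADE_ORDER
            score = {s: i for i, s in enumerate(order)}
            xa = a.map(score).astype(float)
            xb = b.map(score).astype(float)
            if xa.nunique() == 1 and xb.nunique() == 1 and xa.iloc[0] == xb.iloc[0]:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.kruskal(xa, xb)
            entry.update(test="kruskal-wallis", statistic=float(stat), p=float(p))
        else:
            levels = sorted(set(a) | set(b))
            tab = np.array(
                [[int((a == l).sum()) for l in levels], [int((b == l).sum()) for l in levels]]
            )
            p, method = fisher_exact_2xk(tab)
            entry.update(test=f"fisher-{method}", statistic=np.nan, p=float(p))
            for l, ca, cb in zip(levels, tab[0], tab[1]):
                entry[f"ip_{l}"] = int(ca)
                entry[f"iv_{l}"] = int(cb)
            entry[f"pct_ip_{levels[0]}"] = 100.0 * tab[0, 0] / tab[0].sum()
            entry[f"pct_iv_{levels[0]}"] = 100.0 * tab[1, 0] / tab[1].sum()
        rows.append(entry)
    return pd.DataFrame(rows)
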