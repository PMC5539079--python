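"""Subject-level scoring, exclusion rules, and the correlation battery.

Executive function is scored as the Trail Making Test switching cost
(Trail B minus Trail A, seconds).  Subjects scoring more than 2.5 SD above
the cohort mean are excluded (one-sided upper rule, applied once to the
full non-missing set).  Associations are residual-based partial
correlations controlling for age and sex; two-group sex differences are
one-way ANOVA F tests, identical to the squared pooled-variance t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "tmt_score",
    "exclude_outliers",
    "partial_correlation",
    "sex_difference",
    "summarize_cohort",
    "TMT_OUTLIER_SD",
]

TMT_OUTLIER_SD = 2.5

TABLE1_COLUMNS = ["age", "rhi", "cluster_fa", "tmt_a_s", "tmt_b_s", "tmt_diff_s"]


@dataclass(frozen=True)
class StatResult:
    """A single inferential result: estimate, degrees of freedom, p-value."""

    kind: str  # partial_r | pearson_r | anova_F
    estimate: float
    df: tuple[int, ...]
    p: float
    n: int
    controlled: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self):
        if self.kind in ("partial_r", "pearson_r") and np.isfinite(self.estimate):
            if abs(self.estimate) > 1 + 1e-12:
                raise ValueError(f"|r| must be <= 1, got {self.estimate}")
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0,1], got {self.p}")

    def as_dict(self) -> dict:
        return {
            "kind": self.kind, "estimate": self.estimate, "df": list(self.df),
            "p": self.p, "n": self.n, "controlled": list(self.controlled),
            "note": self.note,
        }


def tmt_score(tmt_a_s, tmt_b_s):
    """Trail B minus Trail A, seconds.  NaN inputs propagate to NaN output
    (the subject then drops out of TMT analyses).  Negative costs are legal
    but unusual; callers may flag them."""
    a = np.asarray(tmt_a_s, dtype=float)
    b = np.asarray(tmt_b_s, dtype=float)
    if np.any(a[np.isfinite(a)] <= 0) or np.any(b[np.isfinite(b)] <= 0):
        raise ValueError("TMT times must be > 0")
    return b - a


def exclude_outliers(scores, sd_cutoff: float = TMT_OUTLIER_SD) -> np.ndarray:
    """Inclusion flags for the upper-tail outlier rule.

    A score is excluded when it is strictly greater than mean + sd_cutoff *
    SD, with mean and SD computed once over all non-missing scores (single
    pass: the rule is not re-applied to the filtered set).  Missing scores
    are returned as included (they drop out of analyses on their own); a
    zero-SD set excludes nobody.
    """
    x = np.asarray(scores, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing scores")
    m = float(x[finite].mean())
    sd = float(x[finite].std(ddof=1))
    include = np.ones(x.shape, dtype=bool)
    if sd > 0:
        include[finite] = x[finite] <= m + sd_cutoff * sd
    return include


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, covariates]."""
    X = np.column_stack([np.ones(len(y)), covariates]) if covariates.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(x, y, covariates=None, names: tuple[str, ...] = ()) -> StatResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] by OLS and
    the residuals correlated; df = n - 2 - #covariates and the two-sided p
    comes from the t transform r * sqrt(df / (1 - r^2)).  With no
    covariates this is the plain Pearson correlation with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    n = len(x)
    if n <= k + 2:
        raise ValueError(f"need n > #covariates + 2, got n={n}, k={k}")

    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sx = float(np.sqrt(np.sum(rx ** 2)))
    sy = float(np.sqrt(np.sum(ry ** 2)))
    # scale-aware degeneracy check: a variable that is (numerically) a
    # linear function of the covariates has no residual variation left
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(x - x.mean())))
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(y - y.mean())))
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("constant variable after residualization; correlation undefined")
    r = float(np.dot(rx, ry) / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    kind = "partial_r" if k else "pearson_r"
    return StatResult(kind=kind, estimate=r, df=(df,), p=p, n=n, controlled=names)


def sex_difference(values, sex) -> StatResult:
    """One-way two-group ANOVA for a variable by sex.

    F with df (1, n - 2); numerically identical to the squared
    pooled-variance two-sample t statistic.
    """
    v = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    groups = [v[sex == g] for g in pd.unique(sex)]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) != 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need exactly 2 groups with >= 2 observations each")
    g1, g2 = groups
    n = len(g1) + len(g2)
    ss_within = float(np.sum((g1 - g1.mean()) ** 2) + np.sum((g2 - g2.mean()) ** 2))
    grand = float(np.concatenate([g1, g2]).mean())
    ss_between = len(g1) * (g1.mean() - grand) ** 2 + len(g2) * (g2.mean() - grand) ** 2
    df1, df2 = 1, n - 2
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = float(ss_between / df1 / (ss_within / df2))
        p = float(stats.f.sf(F, df1, df2))
    return StatResult(kind="anova_F", estimate=F, df=(df1, df2), p=p, n=n)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Demographics-table-style summary: mean (SD) per column, overall and
    by sex.  Missing values are excluded columnwise with n reported; for a
    single observation the SD is reported as NaN."""
    if table.empty:
        raise ValueError("empty cohort table")
    df = table.copy()
    if "tmt_diff_s" not in df.columns and {"tmt_a_s", "tmt_b_s"} <= set(df.columns):
        df["tmt_diff_s"] = tmt_score(df["tmt_a_s"], df["tmt_b_s"])
    cols = [c for c in TABLE1_COLUMNS if c in df.columns]

    def block(sub: pd.DataFrame, label: str) -> dict:
        row: dict = {"group": label, "n": len(sub)}
        for c in cols:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{c}_n"] = len(vals)
        return row

    rows = [block(df, "overall")]
    if "sex" in df.columns:
        for g in ("F", "M"):
            sub = df[df["sex"] == g]
            if len(sub):
                rows.append(block(sub, g))
    return pd.DataFrame(rows)
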