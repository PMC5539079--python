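"""Connectivity-based hard segmentation of a seed white-matter cluster.

Each seed voxel is assigned to the cortical target with which it shares
the strictly largest streamline count (ties and sub-floor counts are
UNASSIGNED by default); per-target voxel tallies are normalized by target
mask size, 100 * (voxels assigned to target) / (target mask voxels), to
control for cortical region size.  Across subjects, target percentages
are compared with a repeated-measures one-way ANOVA (subjects as blocks,
df = (T-1, (T-1)(n-1))) followed by Bonferroni-corrected paired
comparisons; a between-subjects error model is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import StatResult
from .synthetic import SeedConnectivity

__all__ = [
    "UNASSIGNED",
    "SegmentationResult",
    "hard_segment",
    "normalize_counts",
    "compare_targets",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class SegmentationResult:
    """Hard-segmentation assignment and per-target tallies."""

    assignment: pd.Series  # voxel_id -> target name or UNASSIGNED
    per_target_voxels: dict[str, int]
    unassigned: int
    target_sizes: dict[str, int]
    normalized_pct: dict[str, float] | None = None

    @property
    def n_seed_voxels(self) -> int:
        return len(self.assignment)


def hard_segment(
    conn: SeedConnectivity,
    min_count: int = 1,
    tie_break: str = "unassigned",
) -> SegmentationResult:
    """Assign each seed voxel to its strongest target.

    A voxel is assigned to the target with the strictly largest streamline
    count, provided that count reaches ``min_count``; all-zero voxels and
    exact ties are UNASSIGNED (``tie_break='first'`` instead awards ties to
    the first tied target in column order).
    """
    counts = conn.counts
    if counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("need >= 1 seed voxel and >= 2 targets")
    if counts.isna().any().any():
        bad = counts.index[counts.isna().any(axis=1)][0]
        raise ValueError(f"voxel {bad} has missing counts")
    if tie_break not in ("unassigned", "first"):
        raise ValueError(f"unknown tie_break {tie_break!r}")

    arr = counts.to_numpy()
    names = np.asarray(counts.columns, dtype=object)
    best = arr.max(axis=1)
    winner_idx = arr.argmax(axis=1)  # first max in column order
    n_at_max = (arr == best[:, None]).sum(axis=1)

    assigned = names[winner_idx].copy()
    below_floor = best < min_count
    tied = n_at_max > 1
    if tie_break == "unassigned":
        assigned[tied] = UNASSIGNED
    assigned[below_floor] = UNASSIGNED

    assignment = pd.Series(assigned, index=counts.index, name="target")
    per_target = {str(t): int((assignment == t).sum()) for t in counts.columns}
    unassigned = int((assignment == UNASSIGNED).sum())
    assert sum(per_target.values()) + unassigned == len(assignment)
    return SegmentationResult(
        assignment=assignment,
        per_target_voxels=per_target,
        unassigned=unassigned,
        target_sizes=dict(conn.target_sizes),
    )


def normalize_counts(seg: SegmentationResult) -> dict[str, float]:
    """Per-target percentage of the target mask occupied by seed voxels:
    100 * assigned_voxels / mask_voxel_count."""
    pct = {}
    for name, n_assigned in seg.per_target_voxels.items():
        size = seg.target_sizes.get(name, 0)
        if size <= 0:
            raise ValueError(f"target {name!r} has non-positive mask size {size}")
        pct[name] = 100.0 * n_assigned / size
    seg.normalized_pct = pct
    return pct


def compare_targets(
    per_subject: list[dict[str, float]] | pd.DataFrame,
    alpha: float = 0.05,
    error_model: str = "within",
) -> dict:
    """Omnibus ANOVA over targets plus Bonferroni pairwise table.

    ``per_subject`` holds one normalized-percentage vector per subject
    (rows) over a common set of targets (columns).  ``error_model='within'``
    (default) is the repeated-measures one-way ANOVA: subject effects are
    removed and F = MS_target / MS_residual with df (T-1, (T-1)(n-1)).
    ``'between'`` ignores the subject blocking, df (T-1, T(n-1)).

    Pairwise paired-t comparisons with Bonferroni-adjusted p = min(1, p *
    n_pairs) are returned only when the omnibus p < alpha.
    """
    df = pd.DataFrame(per_subject) if not isinstance(per_subject, pd.DataFrame) else per_subject.copy()
    if df.isna().any().any():
        raise ValueError("per-subject vectors have unequal targets / missing values")
    n, T = df.shape
    if n < 2 or T < 2:
        raise ValueError("need >= 2 subjects and >= 2 targets")
    X = df.to_numpy(dtype=float)

    grand = X.mean()
    target_means = X.mean(axis=0)
    subject_means = X.mean(axis=1)
    ss_target = n * float(np.sum((target_means - grand) ** 2))
    ss_subject = T * float(np.sum((subject_means - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))

    if error_model == "within":
        ss_err = ss_total - ss_target - ss_subject
        df1, df2 = T - 1, (T - 1) * (n - 1)
    elif error_model == "between":
        ss_err = ss_total - ss_target
        df1, df2 = T - 1, T * (n - 1)
    else:
        raise ValueError(f"unknown error_model {error_model!r}")

    ss_err = max(ss_err, 0.0)
    if ss_err == 0.0:
        if ss_target == 0.0:
            omnibus = StatResult(
                kind="anova_F", estimate=0.0, df=(df1, df2), p=1.0, n=n,
                note="zero variance: no difference",
            )
            return {"omnibus": omnibus, "pairwise": None, "target_means": dict(zip(df.columns, target_means))}
        F, p = np.inf, 0.0
    else:
        F = float((ss_target / df1) / (ss_err / df2))
        p = float(stats.f.sf(F, df1, df2))
    omnibus = StatResult(kind="anova_F", estimate=F, df=(df1, df2), p=p, n=n)

    pairwise = None
    if omnibus.p < alpha:
        cols = list(df.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
        rows = []
        for a, b in pairs:
            t, praw = stats.ttest_rel(df[a], df[b])
            praw = float(praw) if np.isfinite(praw) else 1.0
            rows.append({
                "target_a": a, "target_b": b,
                "mean_diff": float(df[a].mean() - df[b].mean()),
                "t": float(t), "p_raw": praw,
                "p_bonferroni": min(1.0, praw * len(pairs)),
            })
        pairwise = pd.DataFrame(rows)

    return {
        "omnibus": omnibus,
        "pairwise": pairwise,
        "target_means": dict(zip(df.columns, target_means)),
    }
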