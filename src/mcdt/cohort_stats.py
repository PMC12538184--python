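"""Descriptive and inferential cohort statistics.

Group comparability is checked the way small clinical cohorts usually
are: Pearson chi-square (no continuity correction) for sex and education
by group, Kruskal-Wallis for age and neuropsychological scores, post hoc
Mann-Whitney with a Bonferroni-corrected critical p, and a
median-(IQR)-styled summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUPS, EDUCATION_LEVELS


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("need at least a 2x2 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


def chi_square_independence(t: ContingencyTable) -> tuple[float, int]:
    """Pearson X^2 and df for an RxC table, expecteds from the margins."""
    if t.counts.sum() == 0:
        raise ValueError("empty table")
    if (t.counts.sum(axis=0) == 0).any() or (t.counts.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, _, df, _ = stats.chi2_contingency(t.counts, correction=False)
    return float(stat), int(df)


def kruskal_wallis(groups: list) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H and df = K - 1."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; H degenerates to 0")
        return 0.0, len(groups) - 1
    h, _ = stats.kruskal(*groups)
    return float(h), len(groups) - 1


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (x-oriented statistic) and p.

    Exact p below 20 per group without ties; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni_critical(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-corrected critical p value: alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def describe_cohort(participants: pd.DataFrame) -> dict:
    """Demographic summary by group plus the omnibus test statistics.

    IQRs use linear-interpolation quartiles.  Returns a dict with per-
    group counts, sex and education breakdowns, age and FAB medians
    (IQR), and chi-square / Kruskal-Wallis results.
    """
    if participants.empty:
        raise ValueError("empty cohort")
    p = participants
    groups_present = [g for g in GROUPS if (p["group"] == g).any()]
    out: dict = {"n_total": int(len(p)), "groups": {}}
    for g in groups_present:
        sub = p[p["group"] == g]
        q1, q3 = np.percentile(sub["age"], [25, 75])
        fq1, fq3 = np.percentile(sub["fab"], [25, 75])
        out["groups"][g] = dict(
            n=int(len(sub)),
            female=int((sub["sex"] == "F").sum()),
            age_median=float(np.median(sub["age"])),
            age_iqr=float(q3 - q1),
            fab_median=float(np.median(sub["fab"])),
            fab_iqr=float(fq3 - fq1),
            education={
                lvl: int((sub["education"] == lvl).sum()) for lvl in EDUCATION_LEVELS
            },
        )
    if len(groups_present) >= 2:
        sex_counts = np.array(
            [
                [int(((p["group"] == g) & (p["sex"] == s)).sum()) for g in groups_present]
                for s in ("F", "M")
            ]
        )
        if (sex_counts.sum(axis=1) > 0).all():
            stat, df = chi_square_independence(
                ContingencyTable(sex_counts, ("F", "M"), tuple(groups_present))
            )
            out["sex_chi2"] = dict(statistic=stat, df=df)
        edu_counts = np.array(
            [
                [int(((p["group"] == g) & (p["education"] == lvl)).sum()) for g in groups_present]
                for lvl in EDUCATION_LEVELS
            ]
        )
        edu_counts = edu_counts[edu_counts.sum(axis=1) > 0]
        if edu_counts.shape[0] >= 2:
            stat, df = chi_square_independence(
                ContingencyTable(edu_counts, ("edu",) * edu_counts.shape[0], tuple(groups_present))
            )
            out["education_chi2"] = dict(statistic=stat, df=df)
        age_groups = [p.loc[p["group"] == g, "age"].to_numpy() for g in groups_present]
        h, df = kruskal_wallis(age_groups)
        out["age_kruskal"] = dict(H=h, df=df)
        fab_groups = [p.loc[p["group"] == g, "fab"].to_numpy() for g in groups_present]
        h, df = kruskal_wallis(fab_groups)
        out["fab_kruskal"] = dict(H=h, df=df)
        out["bonferroni_critical_p"] = bonferroni_critical(
            0.05, m=len(groups_present) * (len(groups_present) - 1) // 2
        )
    return out
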