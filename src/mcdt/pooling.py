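"""Per-exercise pooled indices from weighted dual-task-cost columns.

With tens of correlated cost columns and a small sample, each exercise is
reduced to one composite score per participant: redundant columns are
screened out by an iterative deletion procedure until no pair of
survivors correlates strongly and at most six components remain, then the
survivors are oriented so that higher always means better functioning,
min-max normalised to [0, 1], and averaged.

Deletion procedure (per exercise, candidate pool = every (feature, CL1-3)
weighted-cost column):
  1. count, per column, the partners with |Spearman rho| at or above the
     threshold (default 0.4); delete the column with the most;
  2. on a tie, delete the tied column with the smaller |Cohen's d| on the
     MCI-vs-OA contrast;
  3. on a residual tie, fall back to a fixed priority list of feature
     names (theoretical preference).
The loop repeats until no pair reaches the threshold; if more than
max_components uncorrelated columns remain, the max_components with the
largest |d| are kept.  Every deletion is recorded in an auditable trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dual_task import DT_LEVELS
from .kinematics import GAIT_FEATURES, TAPPING_FEATURES

#: +1 when a larger weighted-cost value signals better functioning, -1 when
#: worse.  The starred cost is 100*(Zc*f_DT - f_ST)/f_ST — cognitively
#: discounted retention of motor output — and its motivating limit case
#: (unchanged motor output, zero counting) drives it strongly negative for
#: *every* nonnegative feature, so the default orients all weighted-cost
#: columns as higher-is-better.  The map stays overridable, e.g. for
#: pooling unweighted costs, where variability and time features flip.
DEFAULT_ORIENTATION = {
    "tap": +1, "exc": +1, "wo": +1, "wc": +1,
    "exc_sd": +1, "wo_sd": +1, "wc_sd": +1, "iav": +1,
    "gvel": +1, "gstrd_l": +1, "gexc": +1,
    "gt": +1, "gstrd": +1, "gstrd_t": +1, "gstrd_t_sd": +1,
    "gswt": +1, "gswt_sd": +1, "gstt": +1, "gstt_sd": +1,
    "grs": +1, "gexc_sd": +1,
}
#: step-3 theoretical preference: plain magnitude features first, then
#: speeds, then variability; earlier entries are kept, later ones dropped.
DEFAULT_PRIORITY = (
    "tap", "exc", "wo", "wc", "iav", "exc_sd", "wo_sd", "wc_sd",
    "gvel", "gstrd_l", "gt", "gstrd_t", "gswt", "gstt", "grs", "gexc",
    "gstrd", "gstrd_t_sd", "gswt_sd", "gstt_sd", "gexc_sd",
)


@dataclass(frozen=True)
class EffectSize:
    d: float
    contrast: tuple[str, str]


@dataclass
class ScreeningConfig:
    rho_threshold: float = 0.4
    max_components: int = 6
    orientation_map: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    priority_list: tuple = DEFAULT_PRIORITY
    effect_contrast: tuple[str, str] = ("MCI", "OA")

    def __post_init__(self) -> None:
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho_threshold must lie in (0, 1)")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


def spearman_matrix(columns: pd.DataFrame, min_valid: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rho among cost columns, pairwise-deleting NaNs.

    Columns with fewer than ``min_valid`` non-missing values are excluded
    with a warning.
    """
    if columns.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    valid = columns.columns[columns.notna().sum() >= min_valid]
    dropped = set(columns.columns) - set(valid)
    if dropped:
        warnings.warn(f"excluding near-empty columns from correlation: {sorted(dropped)}")
    rho = columns[valid].corr(method="spearman")
    np.fill_diagonal(rho.values, 1.0)
    return rho


def cohens_d(x, groups, contrast: tuple[str, str] = ("MCI", "OA")) -> EffectSize:
    """Cohen's d between two labelled groups, pooled-SD denominator."""
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    a = x[(groups == contrast[0]) & np.isfinite(x)]
    b = x[(groups == contrast[1]) & np.isfinite(x)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both contrast groups need at least 2 members")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    d = float("inf") if pooled == 0 else float((a.mean() - b.mean()) / pooled)
    if pooled == 0 and a.mean() == b.mean():
        d = 0.0
    return EffectSize(d=d, contrast=contrast)


def _column_priority(col: str, priority_list) -> int:
    """Rank of a column's feature name in the priority list (worse = larger)."""
    feature = col.rsplit("_", 1)[0]
    try:
        return priority_list.index(feature)
    except ValueError:
        return len(priority_list)


def screen_features(
    dtc_columns: pd.DataFrame,
    labels,
    cfg: ScreeningConfig | None = None,
) -> tuple[list[str], list[dict]]:
    """Iterative redundancy screening of one exercise's cost columns.

    ``dtc_columns``: participants x columns (column names ``<feature>_<CL>``);
    ``labels``: per-participant diagnosis, aligned with the rows.
    Returns (surviving column names, deletion trace).
    """
    cfg = cfg or ScreeningConfig()
    if dtc_columns.shape[1] == 0:
        raise ValueError("empty candidate pool")
    labels = np.asarray(labels)
    cols = dtc_columns.copy()

    def abs_d(col: str) -> float:
        try:
            return abs(cohens_d(cols[col].to_numpy(), labels, cfg.effect_contrast).d)
        except ValueError:
            return 0.0

    trace: list[dict] = []
    while cols.shape[1] > 1:
        rho = spearman_matrix(cols)
        above = (rho.abs() >= cfg.rho_threshold) & ~np.eye(len(rho), dtype=bool)
        counts = above.sum(axis=1)
        if counts.max() == 0:
            break
        tied = list(counts[counts == counts.max()].index)
        rule = "max_high_rho_count"
        if len(tied) > 1:
            ds = {c: abs_d(c) for c in tied}
            lo = min(ds.values())
            tied = [c for c in tied if ds[c] == lo]
            rule = "lower_effect_size"
        if len(tied) > 1:
            tied.sort(key=lambda c: (_column_priority(c, cfg.priority_list), c))
            tied = [tied[-1]]
            rule = "priority_list"
        victim = tied[0]
        trace.append(
            dict(deleted=victim, rule=rule, high_rho_partners=int(counts[victim]))
        )
        cols = cols.drop(columns=[victim])
    if cols.shape[1] > cfg.max_components:
        ds = pd.Series({c: abs_d(c) for c in cols.columns})
        keep = ds.sort_values(ascending=False).index[: cfg.max_components]
        for c in cols.columns:
            if c not in set(keep):
                trace.append(dict(deleted=c, rule="max_components_by_effect_size",
                                  high_rho_partners=0))
        cols = cols[[c for c in cols.columns if c in set(keep)]]
    return list(cols.columns), trace


def orient_higher_better(column: pd.Series, feature: str, cfg: ScreeningConfig | None = None) -> pd.Series:
    """Flip a cost column, where needed, so larger values mean better
    functioning.  Unmapped features are an error — no silent default."""
    cfg = cfg or ScreeningConfig()
    if feature not in cfg.orientation_map:
        raise KeyError(f"feature {feature!r} missing from orientation map")
    return column * cfg.orientation_map[feature]


def pooled_score(selected: pd.DataFrame) -> pd.Series:
    """One composite score per participant in [0, 1].

    Each (already oriented) column is min-max normalised across
    participants, then averaged per participant ignoring missing
    components; a participant missing every component scores NaN.
    """
    if selected.shape[1] < 1:
        raise ValueError("need at least one selected column")
    normed = selected.apply(
        lambda c: (c - c.min()) / (c.max() - c.min()) if c.max() > c.min() else c * 0 + 0.5
    )
    score = normed.mean(axis=1, skipna=True)
    if score.isna().any():
        warnings.warn("participants missing all pooled-index components scored NaN")
    return score


def build_pooled_indices(
    dtc_table: pd.DataFrame,
    participants: pd.DataFrame,
    cfg: ScreeningConfig | None = None,
):
    """Screen, orient, normalise and average per exercise.

    ``dtc_table``: tidy costs (participant_id, exercise, cl, feature,
    dtc_star); ``participants``: table with id and group columns.
    Returns (scores, report): scores is a participants x exercises
    DataFrame of pooled indices; report maps exercise -> dict with the
    surviving columns and the deletion trace.
    """
    cfg = cfg or ScreeningConfig()
    label_map = participants.set_index("id")["group"]
    scores = {}
    report = {}
    for ex, grp in dtc_table.groupby("exercise"):
        wide = grp.pivot_table(
            index="participant_id", columns=["feature", "cl"], values="dtc_star",
            aggfunc="first", dropna=False,
        )
        wide.columns = [f"{f}_{cl}" for f, cl in wide.columns]
        wide = wide.loc[:, [c for c in wide.columns if c.rsplit("_", 1)[1] in DT_LEVELS]]
        labels = label_map.reindex(wide.index).to_numpy()
        selected, trace = screen_features(wide, labels, cfg)
        oriented = pd.DataFrame(
            {c: orient_higher_better(wide[c], c.rsplit("_", 1)[0], cfg) for c in selected}
        )
        scores[ex] = pooled_score(oriented)
        report[ex] = dict(selected=selected, trace=trace)
    return pd.DataFrame(scores), report
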