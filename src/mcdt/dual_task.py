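"""Dual-task cost (DTC) and its cognitively weighted variant (DTC*).

The standard dual-task cost of a kinematic feature f is the percent change
from the single-task baseline:

    DTC = 100 * (f_DT - f_ST) / f_ST

It ignores the cognitive half of the dual task: a participant who simply
stops counting keeps f_DT near f_ST and scores a deceptively normal DTC of
0%.  The weighted variant multiplies the dual-task feature by a weight
Zc in [0.01, 1] derived from the participant's correct counting responses
Nc — z-scored across the sample, then affinely rescaled so the sample
minimum maps to 0.01 (avoiding exact zeros) and the maximum to 1:

    DTC* = 100 * (f_DT * Zc - f_ST) / f_ST

With full cognitive engagement (Zc = 1) DTC* reduces to DTC; with no
correct answers the motor feature is heavily discounted and DTC* turns
strongly negative, exposing the trade-off the standard cost misses.
Weights exist only under dual task (CL1-CL3), never at baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DT_LEVELS = ("CL1", "CL2", "CL3")


@dataclass(frozen=True)
class RescaleBounds:
    a: float = 0.01
    b: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.a < self.b:
            raise ValueError("bounds must satisfy 0 < a < b")


def dtc(f_dt: float, f_st: float, zero_tol: float = 1e-9) -> float:
    """Percent change of a feature from its single-task baseline.

    A (numerically) zero baseline makes the cost undefined (NaN, logged),
    not an exception: cohort runs proceed past degenerate trials.
    """
    if not np.isfinite(f_st) or not np.isfinite(f_dt):
        return float("nan")
    if abs(f_st) < zero_tol:
        log.warning("zero single-task baseline: dual-task cost undefined")
        return float("nan")
    return 100.0 * (f_dt - f_st) / f_st


def rescale_unit(x, bounds: RescaleBounds = RescaleBounds()) -> np.ndarray:
    """Order-preserving affine map sending min(x) -> a and max(x) -> b.

    A spread-free vector (all values equal) maps to all-b: without spread
    there is no evidence of differential engagement, and a weight of 1
    reproduces the unweighted cost.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    finite = x[np.isfinite(x)]
    out = np.full_like(x, np.nan, dtype=float)
    if finite.size == 0:
        return out
    lo, hi = finite.min(), finite.max()
    m = np.isfinite(x)
    if hi == lo:
        out[m] = bounds.b
        return out
    out[m] = bounds.a + (x[m] - lo) * (bounds.b - bounds.a) / (hi - lo)
    return out


def zc_scores(nc, bounds: RescaleBounds = RescaleBounds()) -> np.ndarray:
    """Engagement weights for one (exercise, CL): z-score Nc across the
    sample, then rescale to [a, b].

    Since z-scoring is itself affine, the composition equals a direct
    min-max rescale; the z-step is kept to mirror the defined procedure.
    A single participant or zero spread yields all-1 weights with a
    warning.
    """
    nc = np.asarray(nc, dtype=float)
    finite = nc[np.isfinite(nc)]
    if finite.size <= 1 or np.std(finite) == 0:
        warnings.warn("degenerate correct-response spread: all weights set to 1")
        out = np.full_like(nc, np.nan, dtype=float)
        out[np.isfinite(nc)] = bounds.b
        return out
    z = (nc - finite.mean()) / finite.std()
    return rescale_unit(z, bounds)


def weighted_feature(f: float, zc: float, cl: str = "CL1") -> float:
    """Dual-task feature discounted by the engagement weight: f * Zc."""
    if cl == "CL0":
        raise ValueError("weighting is possible only under dual task (k > 0), not at baseline")
    return f * zc


def weighted_dtc_table(features: pd.DataFrame, nc_table: pd.DataFrame) -> pd.DataFrame:
    """Standard and weighted dual-task costs for a whole cohort.

    ``features`` is the tidy feature table (participant_id, exercise, cl,
    feature, value); ``nc_table`` is tidy correct-response counts
    (participant_id, exercise, cl, nc).  Weights are computed per
    (exercise, CL) across the whole analysed sample.  Output is tidy:
    participant_id, exercise, cl, feature, dtc, dtc_star, for CL1-CL3;
    cells without a finite nonzero baseline are NaN with a warning.
    """
    base = (
        features[features["cl"] == "CL0"]
        .set_index(["participant_id", "exercise", "feature"])["value"]
    )
    # per-(exercise, CL) weights, indexed by participant
    zc_map: dict[tuple[str, str], pd.Series] = {}
    for (ex, cl), grp in nc_table.groupby(["exercise", "cl"]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zc_map[(ex, cl)] = pd.Series(
                zc_scores(grp["nc"].to_numpy()), index=grp["participant_id"].to_numpy()
            )
    rows = []
    n_missing_baseline = 0
    dt = features[features["cl"].isin(DT_LEVELS)]
    for row in dt.itertuples(index=False):
        key = (row.participant_id, row.exercise, row.feature)
        f_st = base.get(key, float("nan"))
        zc_series = zc_map.get((row.exercise, row.cl))
        zc = float(zc_series.get(row.participant_id, float("nan"))) if zc_series is not None else float("nan")
        if not (np.isfinite(f_st) and abs(f_st) >= 1e-9):
            n_missing_baseline += 1
            d = d_star = float("nan")
        else:
            d = dtc(row.value, f_st)
            d_star = dtc(weighted_feature(row.value, zc, row.cl), f_st)
        rows.append(
            dict(
                participant_id=row.participant_id, exercise=row.exercise, cl=row.cl,
                feature=row.feature, dtc=d, dtc_star=d_star,
            )
        )
    if n_missing_baseline:
        warnings.warn(
            f"{n_missing_baseline} dual-task cells lacked a finite nonzero baseline; left missing"
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "exercise", "cl", "feature", "dtc", "dtc_star"]
    )
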