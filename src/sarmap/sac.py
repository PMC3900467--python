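"""Shared-active-compound (SAC) diagnostics of bioactivity trees.

For a "common" target, every other ("variable") target contributes one point:
the percentage of shared active compound instances (normalized by the common
target's actives, the variable target's actives, or the union of both) against
the inter-target bioactivity distance.  Each series is rescaled
multiplicatively so its mean distance is 0.5 and its mean percentage is 50
(the rescaled percentage is the SAC score; values above 200 arise when a raw
percentage far exceeds its series mean).  A quadratic is fitted to each
scaled series; a series shows *neighborhood behavior* — SAR similarity
decaying with distance — when the fitted slope is negative at distances 0.40
and 0.67 and R^2 exceeds 0.2; otherwise the target is an outlier.

Targets whose actives are shared with too few other targets yield unreliable
series; the exclusion filter drops targets with shared_total at or below a
threshold (default 16) in a single pass over the unfiltered panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ActivityCalls
from .distances import DistanceMatrix

__all__ = [
    "SharedActivityStats",
    "shared_activity_stats",
    "sac_raw_percentage",
    "SACSeries",
    "build_sac_series",
    "scale_series",
    "OutlierCall",
    "classify_series",
    "exclusion_filter",
    "SACAnalysis",
    "run_sac_analysis",
]

SLOPE_POINTS = (0.40, 0.67)
R_SQUARED_MIN = 0.2
DEFAULT_EXCLUSION_THRESHOLD = 16


@dataclass
class SharedActivityStats:
    """Pairwise shared-active counts and per-target sharing summaries.

    ``shared_total`` counts a target's active instances that are active on at
    least one other target (each instance once, regardless of how many
    partners).  ``mean_partners`` is the average number of other targets those
    shared actives are active on.
    """

    shared_counts: pd.DataFrame      # targets × targets, diagonal 0
    total_active: pd.Series
    shared_total: pd.Series
    mean_partners: pd.Series

    @property
    def target_ids(self) -> list[str]:
        return list(self.total_active.index)


def shared_activity_stats(calls: ActivityCalls) -> SharedActivityStats:
    a = calls.values.astype(np.int64)
    targets = list(calls.target_ids)
    pair = a @ a.T
    np.fill_diagonal(pair, 0)
    col_sums = a.sum(axis=0)                  # targets active per instance
    shared_mask = a.astype(bool) & (col_sums >= 2)[None, :]
    shared_total = shared_mask.sum(axis=1)
    partners = col_sums - 1                   # other targets per instance
    with np.errstate(invalid="ignore"):
        mean_partners = np.where(
            shared_total > 0,
            (shared_mask * partners[None, :]).sum(axis=1)
            / np.where(shared_total > 0, shared_total, 1),
            0.0,
        )
    return SharedActivityStats(
        shared_counts=pd.DataFrame(pair, index=targets, columns=targets),
        total_active=pd.Series(a.sum(axis=1), index=targets, name="total_active"),
        shared_total=pd.Series(shared_total, index=targets, name="shared_total"),
        mean_partners=pd.Series(mean_partners, index=targets, name="mean_partners"),
    )


def sac_raw_percentage(
    common: str, variable: str, stats: SharedActivityStats, mode: str = "variable"
) -> float | None:
    """Shared-active percentage for one target pair under a normalization mode.

    ``common``: shared / actives of the common target; ``variable``: shared /
    actives of the variable target; ``both``: shared / size of the union of
    the two active sets.  A zero denominator returns None (the point is
    dropped from the series with a warning).
    """
    shared = int(stats.shared_counts.loc[common, variable])
    tot_c = int(stats.total_active[common])
    tot_v = int(stats.total_active[variable])
    if mode == "common":
        denom = tot_c
    elif mode == "variable":
        denom = tot_v
    elif mode == "both":
        denom = tot_c + tot_v - shared
    elif mode == "both_sum":
        denom = tot_c + tot_v
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        return None
    return 100.0 * shared / denom


@dataclass
class SACSeries:
    """One common target's SAC-vs-distance series (raw, optionally scaled)."""

    common_target: str
    mode: str
    points: pd.DataFrame  # variable_target, raw_percentage, raw_distance [+ scaled]
    scaled: bool = False

    def __len__(self) -> int:
        return len(self.points)


def build_sac_series(
    common: str,
    stats: SharedActivityStats,
    distances: DistanceMatrix,
    mode: str = "variable",
) -> SACSeries:
    """One point per other target with a defined percentage and a distance."""
    if common not in stats.total_active.index:
        raise KeyError(f"unknown target {common!r}")
    if stats.total_active[common] == 0:
        raise ValueError(
            f"target {common!r} has no active compounds; no SAC series is defined"
        )
    rows = []
    dropped = 0
    didx = distances.index
    for variable in stats.target_ids:
        if variable == common or variable not in didx:
            continue
        pct = sac_raw_percentage(common, variable, stats, mode)
        if pct is None:
            dropped += 1
            continue
        rows.append((variable, pct, distances.loc(common, variable)))
    if dropped:
        warnings.warn(
            f"series for {common!r}: dropped {dropped} pair(s) with zero "
            f"denominator under mode {mode!r}",
            stacklevel=2,
        )
    points = pd.DataFrame(rows, columns=["variable_target", "raw_percentage",
                                         "raw_distance"])
    return SACSeries(common, mode, points)


def scale_series(series: SACSeries) -> SACSeries:
    """Rescale a series so mean distance is 0.5 and mean percentage is 50.

    The rescaling is multiplicative (distance × 0.5/mean, percentage ×
    50/mean): an additive shift could never push a percentage bounded by 100
    to SAC scores above 200, which the scaled series can and do reach.
    Idempotent on an already-scaled series.
    """
    if len(series) == 0:
        raise ValueError(f"series for {series.common_target!r} is empty")
    pts = series.points.copy()
    x = pts["scaled_distance"] if series.scaled else pts["raw_distance"]
    y = pts["scaled_sac_score"] if series.scaled else pts["raw_percentage"]
    mean_d, mean_p = float(np.mean(x)), float(np.mean(y))
    if mean_d <= 0 or mean_p <= 0:
        raise ValueError(
            f"series for {series.common_target!r}: non-positive mean "
            f"(distance {mean_d}, percentage {mean_p}); cannot rescale"
        )
    pts["scaled_distance"] = np.asarray(x) * (0.5 / mean_d)
    pts["scaled_sac_score"] = np.asarray(y) * (50.0 / mean_p)
    return SACSeries(series.common_target, series.mode, pts, scaled=True)


@dataclass
class OutlierCall:
    """Quadratic-fit verdict for one target's scaled SAC series."""

    target_id: str
    a: float = np.nan
    b: float = np.nan
    c: float = np.nan
    slope_at_040: float = np.nan
    slope_at_067: float = np.nan
    r_squared: float = np.nan
    verdict: str = "outlier"
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id, "a": self.a, "b": self.b, "c": self.c,
            "slope_at_040": self.slope_at_040, "slope_at_067": self.slope_at_067,
            "r_squared": self.r_squared, "verdict": self.verdict,
            "reason": self.reason,
        }


def classify_series(series: SACSeries) -> OutlierCall:
    """Fit y = a·x² + b·x + c by OLS and apply the neighborhood rule.

    Neighborhood iff slope (2a·x + b) < 0 at x = 0.40 and x = 0.67 and
    R² > 0.2.  Degenerate series (< 3 points, or all x identical) are called
    outliers with a reason flag.
    """
    if not series.scaled:
        raise ValueError("classify_series expects a scaled series")
    n = len(series)
    if n < 3:
        return OutlierCall(series.common_target, reason="fewer than 3 points")
    x = series.points["scaled_distance"].to_numpy()
    y = series.points["scaled_sac_score"].to_numpy()
    if np.ptp(x) == 0:
        return OutlierCall(series.common_target, reason="degenerate x values")
    a, b, c = np.polyfit(x, y, 2)
    fitted = np.polyval((a, b, c), x)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    s040 = 2 * a * SLOPE_POINTS[0] + b
    s067 = 2 * a * SLOPE_POINTS[1] + b
    verdict = (
        "neighborhood"
        if (s040 < 0 and s067 < 0 and r2 > R_SQUARED_MIN)
        else "outlier"
    )
    return OutlierCall(series.common_target, float(a), float(b), float(c),
                       float(s040), float(s067), float(r2), verdict)


def exclusion_filter(
    stats: SharedActivityStats, threshold: int = DEFAULT_EXCLUSION_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split targets into (kept, excluded): excluded iff shared_total <= threshold.

    A single pass on the unfiltered panel; the boundary case (shared_total
    exactly at the threshold) is excluded.  Zero-active targets always fall
    below any non-negative threshold and are excluded.
    """
    excluded = [t for t in stats.target_ids if stats.shared_total[t] <= threshold]
    kept = [t for t in stats.target_ids if stats.shared_total[t] > threshold]
    return kept, excluded


@dataclass
class SACAnalysis:
    """Result of classifying every eligible series of a panel."""

    calls_table: pd.DataFrame         # one row per classified series
    neighborhood_fraction: float
    outliers: list[str]
    excluded: list[str] = field(default_factory=list)
    zero_active: list[str] = field(default_factory=list)
    mode: str = "variable"
    series: dict[str, SACSeries] = field(default_factory=dict)

    @property
    def n_series(self) -> int:
        return len(self.calls_table)


def run_sac_analysis(
    calls: ActivityCalls,
    distances: DistanceMatrix,
    mode: str = "variable",
    exclusion_threshold: int | None = None,
    keep_series: bool = False,
) -> SACAnalysis:
    """Build, scale and classify a SAC series for every eligible target.

    Zero-active targets never yield a series.  When ``exclusion_threshold``
    is given, the filter is computed once on the full panel and both the
    series and the candidate variable targets are restricted to the kept set
    (the distance matrix is subset accordingly).
    """
    stats = shared_activity_stats(calls)
    zero_active = [t for t in stats.target_ids if stats.total_active[t] == 0]
    excluded: list[str] = []
    eligible_calls = calls
    if exclusion_threshold is not None:
        kept, excluded = exclusion_filter(stats, exclusion_threshold)
        eligible_calls = calls.subset_targets(kept)
        distances = distances.subset(kept)
        stats = shared_activity_stats(eligible_calls)
    commons = [
        t for t in eligible_calls.target_ids
        if stats.total_active[t] > 0 and t in distances.index
    ]
    rows, outliers, series_store = [], [], {}
    for common in commons:
        raw = build_sac_series(common, stats, distances, mode)
        try:
            series = scale_series(raw)
        except ValueError:
            # flat-zero series (no shared actives): unscalable, trivially an outlier
            call = OutlierCall(common, reason="zero-mean series; cannot rescale")
            rows.append(call.to_dict())
            outliers.append(common)
            continue
        call = classify_series(series)
        rows.append(call.to_dict())
        if call.verdict == "outlier":
            outliers.append(common)
        if keep_series:
            series_store[common] = series
    table = pd.DataFrame(rows)
    frac = (
        float((table["verdict"] == "neighborhood").mean()) if len(table) else 0.0
    )
    return SACAnalysis(
        calls_table=table,
        neighborhood_fraction=frac,
        outliers=outliers,
        excluded=excluded,
        zero_active=zero_active,
        mode=mode,
        series=series_store,
    )
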