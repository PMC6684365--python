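"""PM-based exposure statistics.

Per-series summaries (mean, SD, maximum, observed duration), the fraction of
1-minute measurements exceeding benchmark concentrations, day/night medians
split on the elevated smoking window, cross-prison pooling by column-wise
medians, and the pooled location/activity summaries of short mobile
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from .pm import PMSeries
from .stats import geometric_stats

__all__ = [
    "MOBILE_CATEGORIES",
    "AreaSummary",
    "MobileMeasurement",
    "summarize_series",
    "exceedance_fractions",
    "day_night_medians",
    "summarize_area",
    "pool_across_prisons",
    "summarize_mobile",
]

MOBILE_CATEGORIES = frozenset(
    {
        "reception",
        "teaching",
        "healthcare_gym",
        "outdoor",
        "staff_office",
        "workshop",
        "corridor_landing",
        "cell_unlock",
        "cell_search",
        "recreation",
        "cell_maintenance",
    }
)


@dataclass(frozen=True)
class AreaSummary:
    """Summary of one prison's 6-day area PM2.5 measurement.

    ``exceedance_fractions`` holds the % of observed minutes strictly above
    each configured benchmark, in threshold order; day/night medians split the
    clock on the elevated smoking window and may be None when a class is
    unobserved.
    """

    prison_id: str
    duration_minutes: int
    mean: float
    sd: float
    maximum: float
    exceedance_fractions: tuple[float, ...] = ()
    day_median: float | None = None
    night_median: float | None = None


@dataclass(frozen=True)
class MobileMeasurement:
    """One short mobile/activity PM2.5 measurement."""

    prison_id: str
    category: str
    duration_minutes: float
    mean_pm25: float

    def __post_init__(self) -> None:
        if self.category not in MOBILE_CATEGORIES:
            raise ValueError(f"unknown location/activity category {self.category!r}")
        if self.duration_minutes <= 0:
            raise ValueError("duration must be positive")


def summarize_series(pm: PMSeries) -> AreaSummary:
    """Arithmetic mean, sample SD (n−1), maximum and observed-minute count."""
    obs = pm.observed()
    if len(obs) == 0:
        raise ValueError("no observed minutes in series")
    return AreaSummary(
        prison_id=pm.source_id,
        duration_minutes=int(len(obs)),
        mean=float(obs.mean()),
        sd=float(obs.std(ddof=1)) if len(obs) > 1 else 0.0,
        maximum=float(obs.max()),
    )


def exceedance_fractions(pm: PMSeries, thresholds) -> tuple[float, ...]:
    """% of observed 1-minute measurements strictly above each benchmark.

    Missing minutes are excluded from the denominator.  Thresholds must be
    strictly increasing, so the fractions are non-increasing.
    """
    th = np.asarray(thresholds, dtype=float)
    if len(th) == 0 or np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    obs = pm.observed().to_numpy()
    if len(obs) == 0:
        raise ValueError("no observed minutes in series")
    return tuple(float(100.0 * (obs > t).mean()) for t in th)


def day_night_medians(
    pm: PMSeries, window: tuple[time, time] = (time(7), time(23))
) -> tuple[float | None, float | None]:
    """Medians of observed minutes inside vs. outside the daytime window.

    A minute belongs to "day" when its clock time lies in [start, end); the
    half-open convention tiles the 24-h clock exactly once.  A class with no
    observed minutes yields None.
    """
    start, end = window
    if not start < end:
        raise ValueError("day window start must precede end")
    obs = pm.observed()
    clock = obs.index.time
    is_day = (clock >= start) & (clock < end)
    day = obs[is_day]
    night = obs[~is_day]
    return (
        float(day.median()) if len(day) else None,
        float(night.median()) if len(night) else None,
    )


def summarize_area(
    pm: PMSeries,
    thresholds=(10.0, 25.0, 246.0),
    window: tuple[time, time] = (time(7), time(23)),
) -> AreaSummary:
    """Full per-prison area summary: core stats, exceedances, day/night medians."""
    core = summarize_series(pm)
    day, night = day_night_medians(pm, window)
    return AreaSummary(
        prison_id=core.prison_id,
        duration_minutes=core.duration_minutes,
        mean=core.mean,
        sd=core.sd,
        maximum=core.maximum,
        exceedance_fractions=exceedance_fractions(pm, thresholds),
        day_median=day,
        night_median=night,
    )


def pool_across_prisons(summaries: list[AreaSummary]) -> dict[str, float]:
    """Column-wise cross-prison medians of the per-prison summaries.

    Even counts use the mean of the two central order statistics.  Exceedance
    columns are keyed ``exceedance_0``, ``exceedance_1``, ... in threshold
    order.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    out = {
        "mean": float(np.median([s.mean for s in summaries])),
        "maximum": float(np.median([s.maximum for s in summaries])),
        "duration_minutes": float(np.median([s.duration_minutes for s in summaries])),
    }
    n_th = len(summaries[0].exceedance_fractions)
    for i in range(n_th):
        out[f"exceedance_{i}"] = float(
            np.median([s.exceedance_fractions[i] for s in summaries])
        )
    days = [s.day_median for s in summaries if s.day_median is not None]
    nights = [s.night_median for s in summaries if s.night_median is not None]
    if days:
        out["day_median"] = float(np.median(days))
    if nights:
        out["night_median"] = float(np.median(nights))
    return out


def summarize_mobile(
    measurements: list[MobileMeasurement],
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Pooled location/activity table plus cohort geometric statistics.

    Per category: n, min, max, mean, SD, median and inter-quartile range of
    the measurement means, with rows ordered by increasing median (smoke-free
    locations first).  The geometric mean and GSD pool every measurement
    across categories; any non-positive mean makes the GM undefined and
    raises.
    """
    if not measurements:
        raise ValueError("no mobile measurements")
    df = pd.DataFrame(
        {
            "category": [m.category for m in measurements],
            "mean_pm25": [m.mean_pm25 for m in measurements],
        }
    )
    rows = []
    for cat, g in df.groupby("category"):
        v = g["mean_pm25"]
        rows.append(
            {
                "category": cat,
                "n": len(v),
                "min": float(v.min()),
                "max": float(v.max()),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": float(v.median()),
                "p25": float(v.quantile(0.25)),
                "p75": float(v.quantile(0.75)),
            }
        )
    table = (
        pd.DataFrame(rows).sort_values("median", kind="stable").reset_index(drop=True)
    )
    gm_gsd = geometric_stats(df["mean_pm25"].to_numpy())
    return table, gm_gsd
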