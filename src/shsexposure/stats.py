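"""Shared statistics for the exposure pipeline.

Geometric mean/GSD (the occupational-hygiene summary for right-skewed
exposure distributions), the coefficient of determination for the PM–nicotine
agreement check, and the comparison of in-prison PM with matched ambient
monitoring-station data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedPrisonData",
    "r_squared",
    "geometric_stats",
    "ambient_comparison",
]


@dataclass(frozen=True)
class PairedPrisonData:
    """One prison's co-located 6-day PM mean and processed nicotine value.

    ``nicotine`` must already be duplicate-merged and ½-LOD imputed;
    ``contemporaneous`` marks whether the two monitors ran over the same
    interval (required for the paired comparison).
    """

    prison_id: str
    pm_mean: float
    nicotine: float
    contemporaneous: bool = True


def r_squared(x, y) -> float:
    """Coefficient of determination of the ordinary least-squares fit of y on x.

    Equivalently the squared Pearson correlation.  Requires at least three
    pairs and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; R² undefined")
    fit = sps.linregress(x, y)
    return float(fit.rvalue**2)


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric standard deviation of positive values.

    GM = exp(mean of ln values); GSD = exp(sample SD, n−1, of ln values).
    For a single value the GSD is NaN (no spread estimate).
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no values")
    if np.any(v <= 0):
        raise ValueError("geometric statistics require strictly positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if len(v) > 1 else float("nan")
    return gm, gsd


def ambient_comparison(prison_series: dict, ambient_series: dict):
    """Compare each prison's PM series with its matched ambient station.

    For every prison the ambient series is restricted to the wall-clock span
    of the in-prison measurement before averaging (no interpolation; the
    station's native resolution is kept).  Returns a per-prison table of
    (prison mean, ambient mean) and the cross-prison medians of both columns.

    ``prison_series`` and ``ambient_series`` map prison id → PMSeries; a
    prison whose ambient series has zero temporal overlap raises.
    """
    rows = []
    for prison, pm in prison_series.items():
        if prison not in ambient_series:
            raise KeyError(f"no ambient series for prison {prison!r}")
        amb = ambient_series[prison]
        start, end = pm.pm25.index[0], pm.pm25.index[-1]
        window = amb.pm25.loc[start:end].dropna()
        if len(window) == 0:
            raise ValueError(
                f"ambient series for {prison!r} has no overlap with the "
                "prison measurement window"
            )
        rows.append(
            {
                "prison": prison,
                "prison_mean": float(pm.observed().mean()),
                "ambient_mean": float(window.mean()),
            }
        )
    table = pd.DataFrame(rows)
    medians = {
        "prison_median": float(table["prison_mean"].median()),
        "ambient_median": float(table["ambient_mean"].median()),
    }
    return table, medians
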