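"""Two-channel particle counts and their conversion to SHS-PM2.5 mass.

Low-cost optical particle counters of the Dylos DC1700 class report particle
number concentrations in two size channels (>0.5 µm and >2.5 µm diameter) per
0.01 cubic foot of sampled air, once a minute.  The number of particles in the
0.5–2.5 µm band — the size range dominated by second-hand tobacco smoke (SHS)
aerosol — is estimated by channel subtraction, and converted to a PM2.5 mass
concentration through a calibrated monotone mapping with an additional
per-device chamber calibration factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("shsexposure")

__all__ = [
    "ParticleCountSeries",
    "CalibrationModel",
    "PMSeries",
    "bin_difference",
    "counts_to_pm25",
]


@dataclass(frozen=True)
class ParticleCountSeries:
    """Minute-resolution two-channel particle counts from one device.

    Parameters
    ----------
    device_id :
        Identifier of the logging device.
    counts :
        DataFrame indexed by timestamp with integer columns ``small``
        (particles >0.5 µm per 0.01 ft³) and ``large`` (particles >2.5 µm
        per 0.01 ft³).  Timestamps must be strictly increasing; gaps are
        simply absent rows, never interpolated.
    interval_seconds :
        Nominal sampling interval (60 s for the DC1700 logger).
    """

    device_id: str
    counts: pd.DataFrame
    interval_seconds: int = 60

    def __post_init__(self) -> None:
        df = self.counts
        if not {"small", "large"}.issubset(df.columns):
            raise ValueError("counts needs 'small' and 'large' columns")
        if len(df) == 0:
            raise ValueError("empty particle-count series")
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if (df[["small", "large"]].to_numpy() < 0).any():
            raise ValueError("particle counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class CalibrationModel:
    """Monotone piecewise-linear counts-difference → mass mapping.

    The mapping sends a per-minute count difference (0.5–2.5 µm particles per
    0.01 ft³) to a PM2.5 mass concentration in µg/m³, anchored at 0 → 0, with
    a dimensionless per-device multiplier derived from a chamber comparison
    against a reference photometer configured for SHS aerosol.

    ``breakpoints`` are count values starting at 0, strictly increasing;
    ``slopes`` (µg/m³ per count) apply segment-wise, the last one extending to
    infinity.  Slopes must be non-negative (positive where the inverse mapping
    is needed, e.g. by the simulator).
    """

    breakpoints: tuple[float, ...] = (0.0, 10_000.0)
    slopes: tuple[float, ...] = (0.010, 0.008)
    device_factor: float = 1.0
    provenance_note: str = (
        "default SHS-aerosol count-to-mass mapping; per-device factors from "
        "chamber comparison against a photometer set to an SHS correction "
        "factor of 0.295"
    )

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        if len(bp) != len(sl):
            raise ValueError("one slope per breakpoint segment required")
        if bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must start at 0 and strictly increase")
        if np.any(sl < 0):
            raise ValueError("non-monotone calibration: negative slope")
        if self.device_factor <= 0:
            raise ValueError("device_factor must be positive")

    def _heights(self) -> np.ndarray:
        bp = np.asarray(self.breakpoints, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        seg = np.diff(bp) * sl[:-1]
        return np.concatenate([[0.0], np.cumsum(seg)])

    def mass(self, diff) -> np.ndarray:
        """Evaluate the mapping (without the device factor) at count differences."""
        d = np.asarray(diff, dtype=float)
        if np.any(d < 0):
            raise ValueError("count differences must be non-negative")
        bp = np.asarray(self.breakpoints, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        h = self._heights()
        idx = np.clip(np.searchsorted(bp, d, side="right") - 1, 0, len(bp) - 1)
        return h[idx] + sl[idx] * (d - bp[idx])

    def inverse(self, mass) -> np.ndarray:
        """Count difference producing a given mass (requires strictly positive slopes)."""
        m = np.asarray(mass, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        if np.any(sl <= 0):
            raise ValueError("inverse undefined for zero-slope segments")
        if np.any(m < 0):
            raise ValueError("mass must be non-negative")
        bp = np.asarray(self.breakpoints, dtype=float)
        h = self._heights()
        idx = np.clip(np.searchsorted(h, m, side="right") - 1, 0, len(h) - 1)
        return bp[idx] + (m - h[idx]) / sl[idx]


@dataclass(frozen=True)
class PMSeries:
    """Minute-resolution PM2.5 mass concentrations from one source.

    ``pm25`` is a float Series (µg/m³) indexed by timestamp; NaN marks a
    missing minute.  ``calibration_ref`` records which calibration produced
    the values ("none" for e.g. ambient monitoring-station data).
    """

    source_id: str
    pm25: pd.Series
    calibration_ref: str = "none"

    def __post_init__(self) -> None:
        s = self.pm25
        if len(s) == 0:
            raise ValueError("empty PM series")
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if (s.dropna() < 0).any():
            raise ValueError("PM2.5 concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.pm25)

    def observed(self) -> pd.Series:
        """The non-missing minutes."""
        return self.pm25.dropna()


def bin_difference(series: ParticleCountSeries) -> pd.Series:
    """Per-minute counts of particles in the 0.5–2.5 µm band.

    Computed as the small-channel minus the large-channel count, clamped at
    zero; channel inversions (large > small, possible at very clean-air
    counts) are clamped and logged.
    """
    diff = series.counts["small"] - series.counts["large"]
    n_inverted = int((diff < 0).sum())
    if n_inverted:
        logger.warning(
            "%s: %d minute(s) with large-channel count exceeding the small "
            "channel; clamped to 0",
            series.device_id,
            n_inverted,
        )
    return diff.clip(lower=0)


def counts_to_pm25(series: ParticleCountSeries, calib: CalibrationModel) -> PMSeries:
    """Convert a two-channel count series to an SHS-PM2.5 mass series.

    ``pm25[t] = device_factor × mapping(small[t] − large[t])``; zero counts
    map to zero mass and the output is monotone in the count difference.
    """
    diff = bin_difference(series)
    mass = calib.device_factor * calib.mass(diff.to_numpy())
    pm = pd.Series(mass, index=series.counts.index, name="pm25")
    return PMSeries(source_id=series.device_id, pm25=pm, calibration_ref="calibrated")
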