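"""Study configuration: every cross-module constant in one auditable place.

Defaults reproduce the baseline-study conventions: WHO indoor-air PM2.5
benchmarks (annual 10 and 24-h 25 µg/m³) plus the pre-legislation Scottish
bar average (246 µg/m³); the 07:00–23:00 elevated smoking window; passive
nicotine LOD 0.031 µg/m³ (½ LOD 0.016 as printed, i.e. rounded to the assay's
reporting precision); salivary cotinine LOD 0.1 ng/ml with ½-LOD substitution
at 0.05; the 5 ng/ml smoker cut-off; and the calibration, toxicokinetic and
cotinine→air conversion constants.  Everything is overridable from a YAML
file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import time
from pathlib import Path

import yaml

from .cotinine import RosettaParams, TKParams
from .pm import CalibrationModel

__all__ = ["StudyConfig", "load_config"]


@dataclass(frozen=True)
class StudyConfig:
    pm_thresholds: tuple[float, ...] = (10.0, 25.0, 246.0)
    day_window: tuple[time, time] = (time(7, 0), time(23, 0))
    nicotine_lod: float = 0.031
    nicotine_half_lod: float = 0.016
    cotinine_lod: float = 0.1
    cotinine_half_lod: float = 0.05
    smoker_cutoff: float = 5.0
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    tk: TKParams = field(default_factory=TKParams)
    rosetta: RosettaParams = field(default_factory=RosettaParams)
    seed: int = 0

    def __post_init__(self) -> None:
        th = self.pm_thresholds
        if len(th) == 0 or any(t <= 0 for t in th):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        # half-LOD must equal half the LOD up to the assay's printed rounding
        # (the nicotine assay reports 0.016 for 0.031/2)
        for lod, half in (
            (self.nicotine_lod, self.nicotine_half_lod),
            (self.cotinine_lod, self.cotinine_half_lod),
        ):
            if lod <= 0 or half <= 0:
                raise ValueError("LODs must be positive")
            if abs(half - lod / 2.0) > 5e-4 + 1e-12:
                raise ValueError("half-LOD must be one-half the LOD")
        start, end = self.day_window
        if not (isinstance(start, time) and isinstance(end, time)):
            raise ValueError("day_window must be clock times")
        if not start < end:
            raise ValueError("day_window start must precede end")
        if self.smoker_cutoff <= 0:
            raise ValueError("smoker_cutoff must be positive")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["day_window"] = [t.strftime("%H:%M") for t in self.day_window]
        d["pm_thresholds"] = list(self.pm_thresholds)
        d["calibration"]["breakpoints"] = list(self.calibration.breakpoints)
        d["calibration"]["slopes"] = list(self.calibration.slopes)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kw = dict(d)
        if "day_window" in kw:
            kw["day_window"] = tuple(
                time(*map(int, s.split(":"))) for s in kw["day_window"]
            )
        if "pm_thresholds" in kw:
            kw["pm_thresholds"] = tuple(kw["pm_thresholds"])
        if isinstance(kw.get("calibration"), dict):
            c = dict(kw["calibration"])
            c["breakpoints"] = tuple(c.get("breakpoints", (0.0, 10_000.0)))
            c["slopes"] = tuple(c.get("slopes", (0.010, 0.008)))
            kw["calibration"] = CalibrationModel(**c)
        if isinstance(kw.get("tk"), dict):
            kw["tk"] = TKParams(**kw["tk"])
        if isinstance(kw.get("rosetta"), dict):
            kw["rosetta"] = RosettaParams(**kw["rosetta"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_config(path=None) -> StudyConfig:
    """Load a configuration file, or the defaults when no path is given."""
    return StudyConfig() if path is None else StudyConfig.from_yaml(path)
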