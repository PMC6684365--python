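"""Salivary-cotinine biomarker pipeline.

Cotinine, the primary metabolite of nicotine, is measured in saliva (ng/ml)
before and after a work shift.  Under first-order elimination the pre-shift
value projects forward to a hypothetical post-shift value that would have
occurred with zero nicotine intake; the excess of the measured post-shift
value over that projection (the shift increment) quantifies intake during the
shift.  A toxicokinetic conversion chain then expresses the increment as the
average airborne nicotine concentration over the shift and, via the ~10:1
PM:nicotine ratio of second-hand smoke, as an SHS-PM2.5 shift equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .stats import geometric_stats

__all__ = [
    "CotinineRecord",
    "TKParams",
    "RosettaParams",
    "ExposureEstimate",
    "eligibility_filter",
    "impute_cotinine_lod",
    "predict_post_shift",
    "cotinine_delta",
    "estimate_exposures",
    "select_subsample",
    "delta_to_pm_equivalent",
    "cohort_summaries",
]


@dataclass(frozen=True)
class CotinineRecord:
    """One worker's paired pre/post-shift salivary cotinine measurement.

    ``pre_value``/``post_value`` are ng/ml and are ``None`` when the assay
    reported below its limit of detection (the matching ``*_censored`` flag is
    then set).  Questionnaire flags record self-reported smoking, use of any
    nicotine product, living with a smoker and travelling in a vehicle where
    smoking occurs — any of which makes the worker ineligible as a workplace
    SHS sentinel.
    """

    participant_id: str
    prison_id: str
    pre_time: datetime | None
    post_time: datetime | None
    pre_value: float | None
    post_value: float | None
    pre_censored: bool = False
    post_censored: bool = False
    smoker: bool = False
    nicotine_product_user: bool = False
    smoking_cohabitant: bool = False
    smoking_vehicle: bool = False
    valid_pre: bool = True
    valid_post: bool = True

    def __post_init__(self) -> None:
        if self.pre_censored and self.pre_value is not None:
            raise ValueError("censored pre value must not carry a number")
        if self.post_censored and self.post_value is not None:
            raise ValueError("censored post value must not carry a number")

    @property
    def questionnaire_eligible(self) -> bool:
        return not (
            self.smoker
            or self.nicotine_product_user
            or self.smoking_cohabitant
            or self.smoking_vehicle
        )

    @property
    def samples_valid(self) -> bool:
        """Both samples valid with post collection strictly after pre."""
        return bool(
            self.valid_pre
            and self.valid_post
            and self.pre_time is not None
            and self.post_time is not None
            and self.post_time > self.pre_time
        )

    @property
    def elapsed_hours(self) -> float:
        if self.pre_time is None or self.post_time is None:
            raise ValueError("record lacks sample timestamps")
        return (self.post_time - self.pre_time).total_seconds() / 3600.0


@dataclass(frozen=True)
class TKParams:
    """Population toxicokinetics of salivary-cotinine elimination."""

    half_life: float = 16.0  # hours
    source_note: str = "population salivary-cotinine elimination kinetics"

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")


@dataclass(frozen=True)
class RosettaParams:
    """Constants linking a shift cotinine increment to air concentrations.

    The chain assumes the increment ΔC (ng/ml saliva) arises from inhaling
    air at nicotine concentration N (µg/m³) for ``elapsed`` hours:

        ΔC = N · BR · t · f_abs · f_conv · ρ / V_d

    with BR the breathing rate at light occupational activity (m³/h), f_abs
    the fraction of inhaled nicotine absorbed, f_conv the fraction of absorbed
    nicotine metabolised to cotinine, V_d the cotinine distribution volume
    (l, 0.88 l/kg × 70 kg) and ρ the saliva:plasma cotinine ratio.  The SHS
    PM2.5:nicotine mass ratio (~10) converts airborne nicotine to an SHS-PM2.5
    equivalent.  ``representative_shift_h`` is the shift duration used for
    cohort-level (median-increment) conversions.
    """

    breathing_rate_m3_h: float = 0.77
    absorbed_fraction: float = 0.71
    conversion_fraction: float = 0.78
    distribution_volume_l: float = 61.6
    saliva_plasma_ratio: float = 1.0
    pm_to_nicotine_ratio: float = 10.0
    representative_shift_h: float = 8.0

    def __post_init__(self) -> None:
        for name in (
            "breathing_rate_m3_h",
            "absorbed_fraction",
            "conversion_fraction",
            "distribution_volume_l",
            "saliva_plasma_ratio",
            "pm_to_nicotine_ratio",
            "representative_shift_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def uptake_slope(self) -> float:
        """ng/ml of salivary cotinine per (µg/m³ airborne nicotine × hour)."""
        return (
            self.breathing_rate_m3_h
            * self.absorbed_fraction
            * self.conversion_fraction
            * self.saliva_plasma_ratio
            / self.distribution_volume_l
        )


@dataclass(frozen=True)
class ExposureEstimate:
    """Derived per-worker shift-exposure quantities.

    ``delta`` (measured post − elimination-projected post) may be negative;
    ``pm_equivalent`` is filled only for sub-sample members.
    """

    participant_id: str
    predicted_post: float
    delta: float
    elapsed: float
    pre_censored: bool
    pm_equivalent: float | None = None


def eligibility_filter(
    records: list[CotinineRecord], smoker_cutoff: float = 5.0
) -> tuple[list[CotinineRecord], dict[str, int]]:
    """Apply the cohort inclusion rules and tally each exclusion reason.

    Drops, in order: questionnaire-ineligible workers; records without a
    valid pre and post sample (including non-increasing timestamps); records
    with a pre- or post-shift value strictly above the smoker cut-off
    (boundary equality is retained).  Each record is tallied under the first
    rule it fails, so retained + tallies always sums to the input count.
    """
    kept: list[CotinineRecord] = []
    tallies = {"questionnaire": 0, "invalid_sample": 0, "over_cutoff": 0}
    for rec in records:
        if not rec.questionnaire_eligible:
            tallies["questionnaire"] += 1
        elif not rec.samples_valid:
            tallies["invalid_sample"] += 1
        elif (rec.pre_value is not None and rec.pre_value > smoker_cutoff) or (
            rec.post_value is not None and rec.post_value > smoker_cutoff
        ):
            tallies["over_cutoff"] += 1
        else:
            kept.append(rec)
    return kept, tallies


def impute_cotinine_lod(values, half_lod: float = 0.05) -> np.ndarray:
    """Replace below-LOD (``None``) entries by one-half the LOD; detects pass through."""
    if half_lod <= 0:
        raise ValueError("half_lod must be positive")
    return np.array([half_lod if v is None else float(v) for v in values])


def predict_post_shift(pre: float, elapsed: float, tk: TKParams) -> float:
    """Project a pre-shift value forward under first-order elimination.

    The hypothetical post-shift value with zero nicotine intake is
    ``pre × 2^(−elapsed / half_life)``.
    """
    if pre < 0:
        raise ValueError("pre-shift value must be non-negative")
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    return pre * 2.0 ** (-elapsed / tk.half_life)


def cotinine_delta(measured_post: float, predicted_post: float) -> float:
    """Shift increment: measured post minus the zero-intake projection (sign kept)."""
    return measured_post - predicted_post


def estimate_exposures(
    records: list[CotinineRecord],
    tk: TKParams,
    half_lod: float = 0.05,
) -> list[ExposureEstimate]:
    """Compute the elimination projection and increment for each record.

    Censored values enter through the study's ½-LOD substitution.  Elapsed
    time is taken per participant from the recorded sample times.
    """
    if half_lod <= 0:
        raise ValueError("half_lod must be positive")
    out = []
    for rec in records:
        pre = half_lod if rec.pre_value is None else rec.pre_value
        post = half_lod if rec.post_value is None else rec.post_value
        elapsed = rec.elapsed_hours
        predicted = predict_post_shift(pre, elapsed, tk)
        out.append(
            ExposureEstimate(
                participant_id=rec.participant_id,
                predicted_post=predicted,
                delta=cotinine_delta(post, predicted),
                elapsed=elapsed,
                pre_censored=rec.pre_censored,
            )
        )
    return out


def select_subsample(
    estimates: list[ExposureEstimate], cotinine_lod: float = 0.1
) -> list[ExposureEstimate]:
    """Restrict to workers for whom an increment is actually measurable.

    Keeps estimates whose pre-shift sample was above the LOD and whose
    zero-intake projected post-shift value is also above the LOD (otherwise a
    change between samples cannot be resolved by the assay).
    """
    return [
        e
        for e in estimates
        if not e.pre_censored and e.predicted_post > cotinine_lod
    ]


def delta_to_pm_equivalent(
    delta: float, elapsed: float, rosetta: RosettaParams
) -> float:
    """Convert a shift cotinine increment to an SHS-PM2.5 shift equivalent.

    The increment is first mapped to the average airborne nicotine
    concentration over the shift (see :class:`RosettaParams`), then scaled by
    the SHS PM:nicotine ratio.  Linear in ``delta``; zero increment maps to
    zero.
    """
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    nicotine = delta / (rosetta.uptake_slope * elapsed)
    return nicotine * rosetta.pm_to_nicotine_ratio


def cohort_summaries(
    records: list[CotinineRecord], half_lod: float = 0.05
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-prison and overall post-shift cotinine distribution summaries.

    Returns a table with one row per prison plus an ``All`` row — n, n (and %)
    below the LOD, 25th/75th percentiles and median of the ½-LOD-imputed
    post-shift values — together with the cohort geometric mean and geometric
    standard deviation.
    """
    if not records:
        raise ValueError("no records to summarise")
    df = pd.DataFrame(
        {
            "prison": [r.prison_id for r in records],
            "post": impute_cotinine_lod([r.post_value for r in records], half_lod),
            "censored": [r.post_censored for r in records],
        }
    )

    def _row(label: str, g: pd.DataFrame) -> dict:
        return {
            "prison": label,
            "n": len(g),
            "n_below_lod": int(g["censored"].sum()),
            "p25": float(g["post"].quantile(0.25)),
            "p75": float(g["post"].quantile(0.75)),
            "median": float(g["post"].median()),
        }

    rows = [_row(p, g) for p, g in df.groupby("prison", sort=True)]
    rows.append(_row("All", df))
    table = pd.DataFrame(rows)
    gm, gsd = geometric_stats(df["post"].to_numpy())
    return table, (gm, gsd)
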