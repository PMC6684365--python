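"""Synthetic-data generators with the statistical structure the study assumes.

No raw measurement data from the survey are deposited anywhere, so every
pipeline stage is exercised against simulated inputs that carry the features
the study describes: diurnal smoking-driven PM over an ambient baseline
(Poisson smoking events in a 07:00–23:00 elevated window, each decaying
exponentially with air exchange), two-channel count quantisation through the
configured calibration, passive nicotine proportional to the SHS-PM mean at
the ~10:1 PM:nicotine ratio with LOD censoring, and pre/post-shift cotinine
pairs produced by first-order elimination plus exposure-driven uptake whose
coefficient is the exact inverse of the configured conversion chain — so
pipeline parameter recovery is well-posed by construction.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import signal

from .cotinine import CotinineRecord, RosettaParams, TKParams
from .nicotine import NicotineMeasurement
from .pm import CalibrationModel, ParticleCountSeries, PMSeries

__all__ = [
    "CohortScenario",
    "SimScenario",
    "simulate_area_pm",
    "simulate_nicotine",
    "simulate_cotinine_cohort",
]


@dataclass(frozen=True)
class CohortScenario:
    """Worker-cohort generator settings.

    Pre-shift cotinine is log-normal (GM/GSD in ng/ml, scaled to the reported
    post-shift distribution); ``uptake_coefficient`` (ng/ml per µg/m³·h of
    SHS-PM) defaults to the inverse of the configured conversion chain;
    ``assay_noise_sd`` is the absolute LC-MS/MS measurement noise.
    ``n_invalid`` and ``n_smokers`` append records that fail the validity and
    smoker-cut-off rules, mirroring the study's recruitment layout
    (422 volunteers = 407 analysable + 3 invalid + 12 over cut-off).
    """

    n_workers: int = 407
    pre_gm: float = 0.16
    pre_gsd: float = 2.5
    uptake_coefficient: float | None = None
    assay_noise_sd: float = 0.02
    shift_hours: float = 8.0
    half_life: float = 16.0
    n_invalid: int = 3
    n_smokers: int = 12


@dataclass(frozen=True)
class SimScenario:
    """Study-condition parameters for one simulated prison.

    Smoking events arrive as a Poisson process with separate day
    (07:00–23:00) and night rates; each event adds a log-normal peak
    increment that decays exponentially (air-exchange removal).  Defaults put
    the simulated 6-day mean inside the survey's reported ~10–140 µg/m³
    per-prison range.
    """

    n_days: int = 6
    ambient_baseline: float = 6.6
    day_event_rate: float = 2.0  # events per hour
    night_event_rate: float = 0.2
    event_mass_gm: float = 17.0  # µg/m³ peak increment, geometric mean
    event_mass_gsd: float = 2.0
    decay_rate: float = 1.0  # per hour
    obs_noise_sd: float = 2.0  # µg/m³
    nicotine_ratio: float = 10.0  # PM : nicotine
    nicotine_noise_sd: float = 0.02  # µg/m³
    nicotine_lod: float = 0.031
    cohort: CohortScenario = field(default_factory=CohortScenario)
    start: datetime = datetime(2016, 10, 3, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.day_event_rate, self.night_event_rate) < 0:
            raise ValueError("event rates must be non-negative")
        if self.event_mass_gm <= 0 or self.decay_rate <= 0:
            raise ValueError("event mass and decay rate must be positive")


def _default_uptake(rosetta: RosettaParams) -> float:
    # ng/ml per (µg/m³ SHS-PM × hour): the nicotine-side uptake slope divided
    # by the PM:nicotine ratio, i.e. the exact inverse of the pipeline chain.
    return rosetta.uptake_slope / rosetta.pm_to_nicotine_ratio


def simulate_area_pm(
    scenario: SimScenario,
    seed: int | None = None,
    device_id: str = "SIM1",
    calibration: CalibrationModel | None = None,
) -> tuple[PMSeries, ParticleCountSeries]:
    """Simulate one prison's minute-resolution area measurement.

    Returns the true PM series (ambient baseline + decaying smoking events +
    observation noise, floored at 0) together with the two-channel count log
    a Dylos-class device would record for it, obtained by inverting the
    calibration mapping and quantising to integer counts.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    calib = calibration or CalibrationModel()
    n = scenario.n_days * 1440
    idx = pd.date_range(scenario.start, periods=n, freq="min")
    hours = idx.hour.to_numpy()
    is_day = (hours >= 7) & (hours < 23)
    rate_per_min = np.where(
        is_day, scenario.day_event_rate, scenario.night_event_rate
    ) / 60.0
    n_events = rng.poisson(rate_per_min)
    total = int(n_events.sum())
    impulses = np.zeros(n)
    if total:
        mass = rng.lognormal(
            mean=np.log(scenario.event_mass_gm),
            sigma=np.log(scenario.event_mass_gsd),
            size=total,
        )
        np.add.at(impulses, np.repeat(np.arange(n), n_events), mass)
    # recursive exponential decay: each impulse contributes mass·exp(-k Δt)
    a = np.exp(-scenario.decay_rate / 60.0)
    shs = signal.lfilter([1.0], [1.0, -a], impulses)
    pm_vals = scenario.ambient_baseline + shs
    if scenario.obs_noise_sd > 0:
        pm_vals = pm_vals + rng.normal(0.0, scenario.obs_noise_sd, n)
    pm_vals = np.clip(pm_vals, 0.0, None)
    pm = PMSeries(
        source_id=device_id,
        pm25=pd.Series(pm_vals, index=idx, name="pm25"),
        calibration_ref="simulated-true",
    )
    diff = np.rint(calib.inverse(pm_vals / calib.device_factor)).astype(int)
    large = rng.poisson(2.0, n)
    counts = pd.DataFrame({"small": diff + large, "large": large}, index=idx)
    return pm, ParticleCountSeries(device_id=device_id, counts=counts)


def simulate_nicotine(
    pm: PMSeries,
    scenario: SimScenario,
    seed: int | None = None,
    monitor_id: str = "SIMN1",
) -> NicotineMeasurement:
    """Passive-monitor nicotine result for a simulated PM series.

    The time-averaged SHS-PM (series mean minus the ambient baseline) divides
    by the PM:nicotine ratio, plus assay noise; results below the LOD are
    censored, as the laboratory would report them.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    shs_mean = max(float(pm.observed().mean()) - scenario.ambient_baseline, 0.0)
    conc = shs_mean / scenario.nicotine_ratio
    if scenario.nicotine_noise_sd > 0:
        conc += rng.normal(0.0, scenario.nicotine_noise_sd)
    censored = conc < scenario.nicotine_lod
    return NicotineMeasurement(
        prison_id=pm.source_id,
        monitor_id=monitor_id,
        concentration=None if censored else float(conc),
        duration_minutes=float(len(pm)),
        censored=censored,
    )


def simulate_cotinine_cohort(
    scenario: SimScenario,
    exposure: float,
    seed: int | None = None,
    rosetta: RosettaParams | None = None,
    prison_id: str = "SIM1",
) -> list[CotinineRecord]:
    """Simulate a pre/post-shift cotinine cohort at a constant SHS-PM exposure.

    Measured post = pre·2^(−shift/half-life) + uptake·exposure·shift + assay
    noise, floored at 0; values below the 0.1 ng/ml assay LOD are censored.
    Appends ``n_invalid`` records without a valid post sample and
    ``n_smokers`` records above the smoker cut-off, so the eligibility filter
    sees the full recruitment layout.
    """
    c = scenario.cohort
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    rosetta = rosetta or RosettaParams()
    uptake = c.uptake_coefficient
    if uptake is None:
        uptake = _default_uptake(rosetta)
    n = c.n_workers
    pre = rng.lognormal(np.log(c.pre_gm), np.log(c.pre_gsd), n)
    decayed = pre * 2.0 ** (-c.shift_hours / c.half_life)
    post = decayed + uptake * exposure * c.shift_hours
    if c.assay_noise_sd > 0:
        post = post + rng.normal(0.0, c.assay_noise_sd, n)
    post = np.clip(post, 0.0, None)
    day = datetime(2016, 11, 7)
    pre_t = day + timedelta(hours=7, minutes=30)
    post_t = pre_t + timedelta(hours=c.shift_hours)
    lod = 0.1

    def _rec(i: int, pre_v: float, post_v: float, **kw) -> CotinineRecord:
        pre_cens = pre_v < lod
        post_cens = post_v < lod
        return CotinineRecord(
            participant_id=f"W{i:04d}",
            prison_id=prison_id,
            pre_time=pre_t,
            post_time=post_t,
            pre_value=None if pre_cens else float(pre_v),
            post_value=None if post_cens else float(post_v),
            pre_censored=pre_cens,
            post_censored=post_cens,
            **kw,
        )

    records = [_rec(i, pre[i], post[i]) for i in range(n)]
    for j in range(c.n_invalid):
        records.append(
            replace(_rec(n + j, float(pre[j % n]), float(post[j % n])), valid_post=False)
        )
    for j in range(c.n_smokers):
        high = float(rng.uniform(6.0, 40.0))
        records.append(_rec(n + c.n_invalid + j, high, high * 1.1))
    return records
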