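"""Passive-sampler airborne nicotine processing.

Sodium-bisulfate-treated filters in passive diffusion monitors accumulate
airborne nicotine over the 6-day area-measurement period; laboratory analysis
yields one time-averaged concentration (µg/m³) per monitor.  This module
applies the study QC rules — tamper exclusion, field-blank contamination
checks, duplicate-pair averaging and ½-LOD substitution for non-detects —
and produces the per-prison values and their cross-prison median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NicotineMeasurement",
    "MergedDuplicate",
    "QCResult",
    "impute_below_lod",
    "merge_duplicates",
    "qc_exclude",
    "prison_values",
    "nicotine_median",
]


@dataclass(frozen=True)
class NicotineMeasurement:
    """One passive-monitor result.

    ``concentration`` is µg/m³, or ``None`` with ``censored=True`` when below
    the analytical LOD.  ``duplicate_of`` links the second member of a
    duplicate pair to the first; field blanks travel with the samples but are
    never exposed, so they carry no prison-level interpretation.
    """

    prison_id: str
    monitor_id: str
    concentration: float | None
    duration_minutes: float = 8640.0
    censored: bool = False
    field_blank: bool = False
    duplicate_of: str | None = None
    tampered: bool = False
    contemporaneous: bool = True

    def __post_init__(self) -> None:
        if self.censored and self.concentration is not None:
            raise ValueError("censored measurement must not carry a number")
        if not self.censored and not self.tampered and self.concentration is None:
            raise ValueError("uncensored measurement requires a concentration")


@dataclass(frozen=True)
class MergedDuplicate:
    """Arithmetic mean of a duplicate pair and each member's % deviation from it."""

    mean: float
    deviations_pct: tuple[float, float]


@dataclass(frozen=True)
class QCResult:
    analysis: list
    excluded: list  # (measurement, reason) pairs
    blanks: list
    contaminated_blanks: list


def impute_below_lod(values, half_lod: float = 0.016) -> np.ndarray:
    """Replace below-LOD (``None``) entries by one-half the LOD; detects pass through."""
    if half_lod <= 0:
        raise ValueError("half_lod must be positive")
    return np.array([half_lod if v is None else float(v) for v in values])


def merge_duplicates(
    pair: tuple[NicotineMeasurement, NicotineMeasurement],
) -> MergedDuplicate:
    """Average a co-located duplicate pair and report the pair's agreement.

    Both members must be uncensored and from the same prison; agreement is
    each member's absolute deviation from the arithmetic mean, as a
    percentage of that mean.
    """
    a, b = pair
    if a.prison_id != b.prison_id:
        raise ValueError("duplicate pair must come from the same prison")
    if a.censored or b.censored:
        raise ValueError("duplicate merging is defined for detected pairs only")
    mean = (a.concentration + b.concentration) / 2.0
    dev = tuple(abs(m.concentration - mean) / mean * 100.0 for m in (a, b))
    return MergedDuplicate(mean=mean, deviations_pct=dev)


def qc_exclude(measurements: list[NicotineMeasurement]) -> QCResult:
    """Partition monitors into the analysis set, exclusions and blanks.

    Tampered monitors (e.g. a holed outer membrane) are excluded with a
    logged reason; field blanks are routed to a blank report, and any blank
    with a detectable concentration is flagged as evidence of contamination
    in transport or storage.
    """
    analysis, excluded, blanks, contaminated = [], [], [], []
    for m in measurements:
        if m.field_blank:
            blanks.append(m)
            if not m.censored:
                contaminated.append(m)
        elif m.tampered:
            excluded.append((m, "tampered"))
        else:
            analysis.append(m)
    return QCResult(
        analysis=analysis,
        excluded=excluded,
        blanks=blanks,
        contaminated_blanks=contaminated,
    )


def prison_values(
    analysis: list[NicotineMeasurement], half_lod: float = 0.016
) -> dict[str, float]:
    """One processed concentration per prison.

    Duplicate pairs are averaged; censored monitors enter at ½ LOD.  More
    than two monitors at one prison is undefined for the pairing rule and
    raises.
    """
    by_prison: dict[str, list[NicotineMeasurement]] = {}
    for m in analysis:
        by_prison.setdefault(m.prison_id, []).append(m)
    out: dict[str, float] = {}
    for prison, ms in by_prison.items():
        if len(ms) == 1:
            out[prison] = float(impute_below_lod([ms[0].concentration], half_lod)[0])
        elif len(ms) == 2:
            out[prison] = merge_duplicates((ms[0], ms[1])).mean
        else:
            raise ValueError(
                f"{prison}: {len(ms)} monitors at one site; only duplicate "
                "pairs are defined"
            )
    return out


def nicotine_median(values) -> float:
    """Cross-prison median of the processed per-prison concentrations."""
    if isinstance(values, dict):
        values = list(values.values())
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no values")
    return float(np.median(v))
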