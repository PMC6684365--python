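"""Readers and writers for the pipeline's external text formats.

Dylos logger exports (timestamp + two particle-count channels), ambient
monitoring-station CSVs, passive-nicotine result tables and pre/post-shift
cotinine tables.  Readers validate rather than coerce: a malformed row fails
with its line number, duplicate timestamps and negative values are rejected,
and below-LOD tokens are preserved as censored status instead of being turned
into numbers.  Write∘read is the identity on every format.

All timestamps are naive local clock time ("YYYY-MM-DD HH:MM"); the study's
statistics compare within-site clock-time windows only.
"""

from __future__ import annotations

import csv
import math
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .cotinine import CotinineRecord
from .nicotine import NicotineMeasurement
from .pm import ParticleCountSeries, PMSeries

__all__ = [
    "TIMESTAMP_FORMAT",
    "read_dylos_log",
    "write_dylos_log",
    "read_ambient_csv",
    "write_ambient_csv",
    "read_nicotine_csv",
    "write_nicotine_csv",
    "read_cotinine_table",
    "write_cotinine_table",
]

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M"
BELOW_LOD_TOKEN = "<LOD"
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "null"}


def _parse_time(token: str, lineno: int, fmt: str) -> datetime:
    try:
        return datetime.strptime(token.strip(), fmt)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable timestamp {token!r}") from exc


def _rows(path) -> list[tuple[int, list[str]]]:
    text = Path(path).read_text()
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            out.append((lineno, next(csv.reader([line]))))
    return out


def _bool(token: str, lineno: int) -> bool:
    t = token.strip().lower()
    if t in {"1", "true", "yes"}:
        return True
    if t in {"0", "false", "no", ""}:
        return False
    raise ValueError(f"line {lineno}: unparseable boolean {token!r}")


# -- Dylos particle-count logs -------------------------------------------


def read_dylos_log(
    path, device_id: str, timestamp_format: str = TIMESTAMP_FORMAT
) -> ParticleCountSeries:
    """Read a Dylos logger CSV export (timestamp, >0.5 µm, >2.5 µm counts).

    A header line is optional.  Rows may appear out of order and are sorted;
    duplicate timestamps, negative counts and unparseable rows are rejected
    with the offending line number.  Gaps stay as missing rows.
    """
    rows = _rows(path)
    if rows and rows[0][1][0].strip().lower() in {"timestamp", "time", "date"}:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    times, small, large = [], [], []
    for lineno, fields in rows:
        if len(fields) != 3:
            raise ValueError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        times.append(_parse_time(fields[0], lineno, timestamp_format))
        for name, tok, dest in (("small", fields[1], small), ("large", fields[2], large)):
            try:
                v = int(tok)
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: unparseable {name}-channel count {tok!r}"
                ) from exc
            if v < 0:
                raise ValueError(f"line {lineno}: negative {name}-channel count {v}")
            dest.append(v)
    df = pd.DataFrame(
        {"small": small, "large": large}, index=pd.DatetimeIndex(times)
    ).sort_index()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate timestamp {dup}")
    interval = 60
    if len(df) > 1:
        interval = int(
            pd.Series(df.index).diff().dropna().min().total_seconds()
        )
    return ParticleCountSeries(device_id=device_id, counts=df, interval_seconds=interval)


def write_dylos_log(series: ParticleCountSeries, path) -> None:
    lines = ["timestamp,small,large"]
    for ts, row in series.counts.iterrows():
        lines.append(
            f"{ts.strftime(TIMESTAMP_FORMAT)},{int(row['small'])},{int(row['large'])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- ambient monitoring-station series -----------------------------------


def read_ambient_csv(path, source_id: str = "ambient") -> PMSeries:
    """Read a monitoring-station CSV of (timestamp, PM2.5 µg/m³).

    Missing-value tokens become missing minutes (never zero); negative
    concentrations are rejected.
    """
    rows = _rows(path)
    if rows and rows[0][1][0].strip().lower() in {"timestamp", "time", "date"}:
        rows = rows[1:]
    times, values = [], []
    for lineno, fields in rows:
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected 2 fields, got {len(fields)}")
        times.append(_parse_time(fields[0], lineno, TIMESTAMP_FORMAT))
        tok = fields[1].strip()
        if tok in _MISSING_TOKENS:
            values.append(math.nan)
            continue
        try:
            v = float(tok)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparseable concentration {tok!r}") from exc
        if v < 0:
            raise ValueError(f"line {lineno}: negative concentration {v}")
        values.append(v)
    if not times:
        raise ValueError(f"{path}: no parseable rows")
    s = pd.Series(values, index=pd.DatetimeIndex(times), name="pm25").sort_index()
    return PMSeries(source_id=source_id, pm25=s, calibration_ref="none")


def write_ambient_csv(series: PMSeries, path) -> None:
    lines = ["timestamp,pm25"]
    for ts, v in series.pm25.items():
        tok = "" if pd.isna(v) else repr(float(v))
        lines.append(f"{ts.strftime(TIMESTAMP_FORMAT)},{tok}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- passive nicotine results --------------------------------------------

_NICOTINE_HEADER = [
    "prison",
    "monitor",
    "concentration",
    "duration_minutes",
    "field_blank",
    "duplicate_of",
    "tampered",
    "contemporaneous",
]


def read_nicotine_csv(path) -> list[NicotineMeasurement]:
    """Read per-monitor passive-nicotine results with QC flags.

    The concentration field holds a number, the below-LOD token ``<LOD``, or
    is empty for a tampered (unanalysable) monitor.
    """
    rows = _rows(path)
    if rows and rows[0][1][0].strip().lower() == "prison":
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    out = []
    for lineno, fields in rows:
        if len(fields) != len(_NICOTINE_HEADER):
            raise ValueError(
                f"line {lineno}: expected {len(_NICOTINE_HEADER)} fields, "
                f"got {len(fields)}"
            )
        (prison, monitor, conc_tok, dur, blank, dup, tamper, contemp) = fields
        conc_tok = conc_tok.strip()
        censored = conc_tok == BELOW_LOD_TOKEN
        if censored or conc_tok == "":
            conc = None
        else:
            try:
                conc = float(conc_tok)
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: unparseable concentration {conc_tok!r}"
                ) from exc
        out.append(
            NicotineMeasurement(
                prison_id=prison.strip(),
                monitor_id=monitor.strip(),
                concentration=conc,
                duration_minutes=float(dur),
                censored=censored,
                field_blank=_bool(blank, lineno),
                duplicate_of=dup.strip() or None,
                tampered=_bool(tamper, lineno),
                contemporaneous=_bool(contemp, lineno),
            )
        )
    return out


def write_nicotine_csv(measurements: list[NicotineMeasurement], path) -> None:
    lines = [",".join(_NICOTINE_HEADER)]
    for m in measurements:
        conc = (
            BELOW_LOD_TOKEN
            if m.censored
            else ("" if m.concentration is None else repr(float(m.concentration)))
        )
        lines.append(
            ",".join(
                [
                    m.prison_id,
                    m.monitor_id,
                    conc,
                    repr(float(m.duration_minutes)),
                    str(int(m.field_blank)),
                    m.duplicate_of or "",
                    str(int(m.tampered)),
                    str(int(m.contemporaneous)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- salivary cotinine tables --------------------------------------------

_COTININE_HEADER = [
    "participant",
    "prison",
    "pre_time",
    "pre_value",
    "post_time",
    "post_value",
    "smoker",
    "nicotine_product_user",
    "smoking_cohabitant",
    "smoking_vehicle",
    "valid_pre",
    "valid_post",
]


def _cotinine_value(tok: str, lineno: int) -> tuple[float | None, bool]:
    tok = tok.strip()
    if tok == BELOW_LOD_TOKEN:
        return None, True
    try:
        return float(tok), False
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable cotinine value {tok!r}") from exc


def read_cotinine_table(path) -> list[CotinineRecord]:
    """Read pre/post-shift cotinine records with questionnaire and QC flags.

    Below-LOD tokens are kept as censored status.  A record whose post time
    is not after its pre time is loaded with its validity flag cleared rather
    than dropped silently.
    """
    rows = _rows(path)
    if rows and rows[0][1][0].strip().lower() == "participant":
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    out = []
    for lineno, fields in rows:
        if len(fields) != len(_COTININE_HEADER):
            raise ValueError(
                f"line {lineno}: expected {len(_COTININE_HEADER)} fields, "
                f"got {len(fields)}"
            )
        pre_v, pre_cens = _cotinine_value(fields[3], lineno)
        post_v, post_cens = _cotinine_value(fields[5], lineno)
        valid_post = _bool(fields[11], lineno)
        pre_t = _parse_time(fields[2], lineno, TIMESTAMP_FORMAT) if fields[2].strip() else None
        post_t = _parse_time(fields[4], lineno, TIMESTAMP_FORMAT) if fields[4].strip() else None
        if pre_t is not None and post_t is not None and post_t <= pre_t:
            valid_post = False  # temporal ordering violated: flag, don't drop
        out.append(
            CotinineRecord(
                participant_id=fields[0].strip(),
                prison_id=fields[1].strip(),
                pre_time=pre_t,
                post_time=post_t,
                pre_value=pre_v,
                post_value=post_v,
                pre_censored=pre_cens,
                post_censored=post_cens,
                smoker=_bool(fields[6], lineno),
                nicotine_product_user=_bool(fields[7], lineno),
                smoking_cohabitant=_bool(fields[8], lineno),
                smoking_vehicle=_bool(fields[9], lineno),
                valid_pre=_bool(fields[10], lineno),
                valid_post=valid_post,
            )
        )
    return out


def write_cotinine_table(records: list[CotinineRecord], path) -> None:
    lines = [",".join(_COTININE_HEADER)]
    for r in records:
        def _val(v, censored):
            if censored:
                return BELOW_LOD_TOKEN
            return "" if v is None else repr(float(v))

        lines.append(
            ",".join(
                [
                    r.participant_id,
                    r.prison_id,
                    r.pre_time.strftime(TIMESTAMP_FORMAT) if r.pre_time else "",
                    _val(r.pre_value, r.pre_censored),
                    r.post_time.strftime(TIMESTAMP_FORMAT) if r.post_time else "",
                    _val(r.post_value, r.post_censored),
                    str(int(r.smoker)),
                    str(int(r.nicotine_product_user)),
                    str(int(r.smoking_cohabitant)),
                    str(int(r.smoking_vehicle)),
                    str(int(r.valid_pre)),
                    str(int(r.valid_post)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
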