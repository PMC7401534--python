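"""On-disk formats and time alignment for keel-mounted accelerometer data.

Trace files are delimited text with a small ``# key: value`` header (sampling
rate, unit, start time) followed by ``time,ax,ay,az`` rows, acceleration in G
units sampled at 800 Hz. Event annotations carry the six video-derived
timestamps per jump at millisecond resolution plus the balancing flag and a
per-session clock offset between the video and logger clocks.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "EventAnnotation",
    "HenRecord",
    "FormatError",
    "AlignmentError",
    "PHASES",
    "EVENT_FIELDS",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_roster",
    "write_roster",
    "read_metrics",
    "write_metrics",
    "window_to_samples",
]

DEFAULT_RATE_HZ = 800.0

#: The six video events, in temporal order (ms since session start).
EVENT_FIELDS = [
    "signal_ms",
    "takeoff_start_ms",
    "takeoff_end_ms",
    "landing_start_ms",
    "landing_end_ms",
    "first_peck_ms",
]

#: Phase name -> (start event, end event); half-open windows [start, end).
PHASES = {
    "prejump": ("signal_ms", "takeoff_start_ms"),
    "takeoff": ("takeoff_start_ms", "takeoff_end_ms"),
    "flight": ("takeoff_end_ms", "landing_start_ms"),
    "landing": ("landing_start_ms", "landing_end_ms"),
    "peck": ("landing_end_ms", "first_peck_ms"),
}


class FormatError(ValueError):
    """A file does not conform to the documented on-disk format."""


class AlignmentError(ValueError):
    """An annotation window falls outside the span of its trace."""


@dataclass
class AccelTrace:
    """Triaxial acceleration stream in G units."""

    start_s: float
    rate_hz: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis arrays must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        for arr in (self.ax, self.ay, self.az):
            if not np.all(np.isfinite(arr)):
                raise ValueError("acceleration values must be finite")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(len(self)) / self.rate_hz


@dataclass
class EventAnnotation:
    """Video timestamps and balancing flag for one jump.

    Timestamps are milliseconds on the video clock; ``clock_offset_ms`` is the
    video-minus-logger offset, subtracted before mapping onto trace samples.
    ``first_peck_ms`` may be None (censored).
    """

    session_id: int
    jump: int
    signal_ms: float
    takeoff_start_ms: float
    takeoff_end_ms: float
    landing_start_ms: float
    landing_end_ms: float
    first_peck_ms: float | None = None
    balancing: bool = False
    clock_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        seq = [getattr(self, f) for f in EVENT_FIELDS]
        present = [t for t in seq if t is not None and not (isinstance(t, float) and math.isnan(t))]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(
                f"event timestamps must be nondecreasing (session {self.session_id} "
                f"jump {self.jump}): {seq}"
            )

    def event(self, name: str) -> float | None:
        val = getattr(self, name)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        return val


@dataclass
class HenRecord:
    hen_id: str
    pen: str
    hybrid: str
    body_mass_pre_kg: float | None
    body_mass_post_kg: float | None

    def __post_init__(self) -> None:
        for m in (self.body_mass_pre_kg, self.body_mass_post_kg):
            if m is not None and not (isinstance(m, float) and math.isnan(m)) and m <= 0:
                raise ValueError(f"body mass must be positive, got {m} for hen {self.hen_id}")


# ---------------------------------------------------------------------------
# trace files


def write_trace(trace: AccelTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz: {trace.rate_hz:g}\n")
        fh.write("# unit: G\n")
        fh.write(f"# start_s: {trace.start_s:.6f}\n")
        fh.write("time_s,ax,ay,az\n")
        arr = np.column_stack([trace.times_s, trace.ax, trace.ay, trace.az])
        np.savetxt(fh, arr, fmt=["%.6f", "%.6g", "%.6g", "%.6g"], delimiter=",")


def read_trace(path) -> AccelTrace:
    """Read a delimited trace file, validating header and row structure."""
    path = Path(path)
    header: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            header[key.strip()] = val.strip()
        else:
            body_start = i
            break
    unit = header.get("unit", "")
    if unit != "G":
        raise FormatError(f"{path}: acceleration unit must be 'G', found {unit!r}")
    try:
        rate = float(header["rate_hz"])
        start = float(header.get("start_s", "0"))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad or missing header fields: {exc}") from None

    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    except Exception as exc:
        raise FormatError(f"{path}: unparseable data block: {exc}") from None
    needed = {"time_s", "ax", "ay", "az"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    bad = df[df[["time_s", "ax", "ay", "az"]].isna().any(axis=1)]
    if len(bad):
        raise FormatError(f"{path}: malformed rows at data lines {list(bad.index + 1)}")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        first = int(np.argmax(np.diff(t) <= 0)) + 2
        raise FormatError(f"{path}: non-monotone time at data line {first}")
    return AccelTrace(start_s=start, rate_hz=rate,
                      ax=df["ax"].to_numpy(float), ay=df["ay"].to_numpy(float),
                      az=df["az"].to_numpy(float))


# ---------------------------------------------------------------------------
# event tables

_EVENT_COLUMNS = ["session_id", "jump", *EVENT_FIELDS, "balancing", "clock_offset_ms"]


def write_events(annotations: Sequence[EventAnnotation], path) -> None:
    rows = []
    for a in annotations:
        row = {f: getattr(a, f) for f in _EVENT_COLUMNS if f not in ("balancing",)}
        row["balancing"] = int(a.balancing)
        rows.append(row)
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[EventAnnotation]:
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: event table missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        peck = r["first_peck_ms"]
        out.append(
            EventAnnotation(
                session_id=int(r["session_id"]),
                jump=int(r["jump"]),
                signal_ms=float(r["signal_ms"]),
                takeoff_start_ms=float(r["takeoff_start_ms"]),
                takeoff_end_ms=float(r["takeoff_end_ms"]),
                landing_start_ms=float(r["landing_start_ms"]),
                landing_end_ms=float(r["landing_end_ms"]),
                first_peck_ms=None if pd.isna(peck) else float(peck),
                balancing=bool(int(r["balancing"])),
                clock_offset_ms=float(r["clock_offset_ms"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# roster

_ROSTER_COLUMNS = ["hen_id", "pen", "hybrid", "body_mass_pre_kg", "body_mass_post_kg"]


def write_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, index=False)


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: roster missing columns {sorted(missing)}")
    bad = df[(df["body_mass_pre_kg"] <= 0) | (df["body_mass_post_kg"] <= 0)]
    if len(bad):
        raise FormatError(f"{path}: nonpositive body mass for hens {list(bad['hen_id'])}")
    return df


# ---------------------------------------------------------------------------
# metrics tables

METRICS_SCHEMA_VERSION = 1

METRICS_COLUMNS = [
    "session_id",
    "jump",
    "hen_id",
    "pen",
    "hybrid",
    "direction",
    "angle_class",
    "distance_cm",
    "date",
    "peak_force_takeoff",
    "peak_force_flight",
    "peak_force_landing",
    "impulse_takeoff",
    "impulse_flight",
    "impulse_landing",
    "latency_to_jump",
    "duration_takeoff",
    "duration_flight",
    "duration_landing",
    "latency_to_peck",
    "balancing",
    "body_mass_kg",
    "units_mode",
]


def write_metrics(records: pd.DataFrame, path) -> None:
    """Write a per-jump metrics table, prefixed with a schema-version header."""
    for col in METRICS_COLUMNS:
        if col not in records.columns:
            raise FormatError(f"metrics table missing column {col!r}")
    with open(path, "w") as fh:
        fh.write(f"# keeljump-metrics-v{METRICS_SCHEMA_VERSION}\n")
        records[METRICS_COLUMNS].to_csv(fh, index=False)


def read_metrics(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        tag = fh.readline().strip()
        if tag != f"# keeljump-metrics-v{METRICS_SCHEMA_VERSION}":
            raise FormatError(f"{path}: unknown metrics schema tag {tag!r}")
        df = pd.read_csv(fh)
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metrics table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# alignment


def _ms_to_index(t_ms: float, offset_ms: float, trace: AccelTrace) -> int:
    # nearest sample, ties toward the earlier sample
    x = ((t_ms - offset_ms) / 1000.0 - trace.start_s) * trace.rate_hz
    return int(math.ceil(x - 0.5))


def window_to_samples(annotation: EventAnnotation, phase: str, trace: AccelTrace) -> tuple[int, int]:
    """Map a phase of an annotated jump onto a half-open sample range.

    Millisecond event times are corrected by the annotation's clock offset and
    rounded to the nearest sample (ties toward the earlier sample).
    """
    try:
        start_ev, end_ev = PHASES[phase]
    except KeyError:
        raise ValueError(f"unknown phase {phase!r}; expected one of {sorted(PHASES)}") from None
    t0, t1 = annotation.event(start_ev), annotation.event(end_ev)
    if t0 is None or t1 is None:
        raise AlignmentError(f"phase {phase!r}: boundary event missing "
                             f"(session {annotation.session_id} jump {annotation.jump})")
    i0 = _ms_to_index(t0, annotation.clock_offset_ms, trace)
    i1 = _ms_to_index(t1, annotation.clock_offset_ms, trace)
    if i0 < 0 or i1 > len(trace):
        raise AlignmentError(
            f"phase {phase!r} window [{i0}, {i1}) outside trace of {len(trace)} samples "
            f"(session {annotation.session_id} jump {annotation.jump})"
        )
    if i0 >= i1:
        raise AlignmentError(f"phase {phase!r}: empty window [{i0}, {i1})")
    return i0, i1
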