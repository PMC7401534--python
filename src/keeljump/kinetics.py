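"""Per-jump kinetics at the keel: acceleration magnitude, force, peak force,
impulse, durations and latencies.

The combined acceleration magnitude is sqrt(ax^2 + ay^2 + az^2) computed on
the raw axes — no gravity subtraction, so a resting sensor reads about 1 G and
forces include the static component. Force follows Newton's second law,
F = m * a, with the hen's mean body mass (average of pre- and post-study
weighings).

Two unit conventions are supported. In ``paper`` mode (the default) the
acceleration stays in G units, so F = m[kg] * a[G]; this reproduces the
convention behind the study's worked arithmetic (1.5 kg at 100 G -> "150 N")
and its reported keel forces of a few N. In ``si`` mode the magnitude is
converted to m/s^2 (x 9.80665), giving physically correct newtons. The two
modes differ by exactly the factor 9.80665 everywhere and are never mixed
within a table.

The phase impulse is the literal average-force-times-duration definition:
(sample mean of force over the phase window) x (window duration), which
agrees with trapezoidal integration to O(1/n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AccelTrace, AlignmentError, EventAnnotation, HenRecord, window_to_samples

__all__ = [
    "G_TO_MS2",
    "PhaseMetrics",
    "magnitude",
    "force",
    "mean_mass",
    "peak_force",
    "impulse",
    "derive_metrics",
]

#: Standard gravity, m/s^2 per G.
G_TO_MS2 = 9.80665

_UNIT_FACTOR = {"paper": 1.0, "si": G_TO_MS2}


@dataclass
class PhaseMetrics:
    """Derived outcomes for one jump."""

    session_id: int
    jump: int
    peak_force_takeoff: float
    peak_force_flight: float
    peak_force_landing: float
    impulse_takeoff: float
    impulse_flight: float
    impulse_landing: float
    latency_to_jump: float
    duration_takeoff: float
    duration_flight: float
    duration_landing: float
    latency_to_peck: float | None
    balancing: bool
    body_mass_kg: float
    units_mode: str


def magnitude(ax, ay, az) -> np.ndarray:
    """Elementwise combined acceleration magnitude, in the units of the axes."""
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError(f"axis arrays must have equal shape, got {ax.shape}, {ay.shape}, {az.shape}")
    return np.sqrt(ax * ax + ay * ay + az * az)


def force(a_g, mass_kg: float, units_mode: str = "paper") -> np.ndarray:
    """Force from acceleration magnitude in G units and body mass in kg."""
    if mass_kg <= 0:
        raise ValueError(f"body mass must be positive, got {mass_kg}")
    try:
        factor = _UNIT_FACTOR[units_mode]
    except KeyError:
        raise ValueError(f"units_mode must be 'paper' or 'si', got {units_mode!r}") from None
    return np.asarray(a_g, dtype=float) * mass_kg * factor


def mean_mass(hen: HenRecord) -> float:
    """Mean of pre- and post-study body mass; falls back to the one present."""
    pre, post = hen.body_mass_pre_kg, hen.body_mass_post_kg
    pre = None if pre is None or np.isnan(pre) else float(pre)
    post = None if post is None or np.isnan(post) else float(post)
    if pre is None and post is None:
        raise ValueError(f"hen {hen.hen_id}: no body mass recorded")
    if pre is None or post is None:
        present = pre if pre is not None else post
        warnings.warn(
            f"hen {hen.hen_id}: only one body mass recorded, using {present} kg",
            stacklevel=2,
        )
        return present
    return 0.5 * (pre + post)


def _window_force(trace: AccelTrace, window: tuple[int, int], mass_kg: float,
                  units_mode: str, phase: str = "?") -> np.ndarray:
    i0, i1 = window
    if i0 >= i1:
        raise ValueError(f"empty window for phase {phase!r}: [{i0}, {i1})")
    mag = magnitude(trace.ax[i0:i1], trace.ay[i0:i1], trace.az[i0:i1])
    return force(mag, mass_kg, units_mode)


def peak_force(trace: AccelTrace, window: tuple[int, int], mass_kg: float,
               units_mode: str = "paper", phase: str = "?") -> float:
    """Maximum force over the sample window."""
    return float(np.max(_window_force(trace, window, mass_kg, units_mode, phase)))


def impulse(trace: AccelTrace, window: tuple[int, int], mass_kg: float,
            units_mode: str = "paper", phase: str = "?") -> float:
    """Average force over the window times the window duration (N.s)."""
    f = _window_force(trace, window, mass_kg, units_mode, phase)
    duration_s = (window[1] - window[0]) / trace.rate_hz
    return float(np.mean(f) * duration_s)


def derive_metrics(trace: AccelTrace, annotation: EventAnnotation, hen: HenRecord,
                   units_mode: str = "paper") -> PhaseMetrics:
    """All per-jump outcomes from one aligned trace + annotation.

    Durations and latencies come from the annotation's millisecond timestamps;
    forces and impulses from the trace samples inside each half-open phase
    window. ``latency_to_peck`` is None when the first peck is censored.
    """
    mass = mean_mass(hen)
    try:
        windows = {p: window_to_samples(annotation, p, trace)
                   for p in ("takeoff", "flight", "landing")}
    except AlignmentError as exc:
        raise AlignmentError(
            f"session {annotation.session_id} jump {annotation.jump}: {exc}") from exc

    peaks = {p: peak_force(trace, w, mass, units_mode, phase=p) for p, w in windows.items()}
    imps = {p: impulse(trace, w, mass, units_mode, phase=p) for p, w in windows.items()}

    ev = annotation
    peck = ev.event("first_peck_ms")
    return PhaseMetrics(
        session_id=ev.session_id,
        jump=ev.jump,
        peak_force_takeoff=peaks["takeoff"],
        peak_force_flight=peaks["flight"],
        peak_force_landing=peaks["landing"],
        impulse_takeoff=imps["takeoff"],
        impulse_flight=imps["flight"],
        impulse_landing=imps["landing"],
        latency_to_jump=(ev.takeoff_start_ms - ev.signal_ms) / 1000.0,
        duration_takeoff=(ev.takeoff_end_ms - ev.takeoff_start_ms) / 1000.0,
        duration_flight=(ev.landing_start_ms - ev.takeoff_end_ms) / 1000.0,
        duration_landing=(ev.landing_end_ms - ev.landing_start_ms) / 1000.0,
        latency_to_peck=None if peck is None else (peck - ev.landing_end_ms) / 1000.0,
        balancing=ev.balancing,
        body_mass_kg=mass,
        units_mode=units_mode,
    )
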