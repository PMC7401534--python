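"""Ground-truth simulator for the perch-transition study.

Generates a complete synthetic study — roster, counterbalanced schedule,
per-jump latent outcomes drawn from a known mixed-model structure, and
accelerometer traces with matching event annotations — so the whole pipeline
can be exercised against known truth.

Outcomes are drawn on the analysis (transformed) scale as

    value = X beta + b_pen + b_hen + b_condition(hen) + b_date + eps

and back-transformed; the balancing indicator is Bernoulli with the same
random structure on the logit scale. Default fixed-effect coefficients are
anchored to the magnitudes such an experiment reports (peak
forces around 3-4 N in the mass-times-G convention, take-off impulses around
0.3-0.5 N.s, landing impulses 1.4-2.3 N.s, latencies 1-4 s, balancing rates
17-58%); body-mass distributions are invented plumbing (the study reports no
masses) and configurable.

Traces are built truth-first: each phase gets an analytically tractable pulse
(half-sine thrust for take-off, sinusoidal flapping in flight, exponential
impact decay for landing) riding on a 1 G standing baseline, with amplitudes
and pulse widths solved so that the windowed peak force and impulse equal the
drawn truth. True phase boundaries are snapped to a 5 ms grid — a common
multiple of the 1 ms annotation resolution and the 1.25 ms sample period — so
millisecond annotations map exactly onto samples.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import design as _design
from . import io as _io
from .inference import default_transform, back_transform

__all__ = [
    "SimConfig",
    "TraceShapeConfig",
    "JumpTruth",
    "simulate_roster",
    "draw_outcomes",
    "render_trace",
    "emit_dataset",
    "truth_table",
]

_GRID_S = 0.005  # truth boundaries snap to this (4 samples at 800 Hz, 5 ms)

#: Modeled continuous responses (balancing handled separately).
_CONTINUOUS = [
    "peak_force_takeoff",
    "peak_force_flight",
    "peak_force_landing",
    "impulse_takeoff",
    "impulse_landing",
    "latency_to_jump",
    "latency_to_peck",
]

_COMPONENTS = ("pen", "hen", "hen_condition", "date", "residual")


def _default_effects() -> dict:
    """Fixed-effect coefficients per (response, direction) on the transformed
    scale: keys intercept / distance / angle / hybrid / interactions.
    Reference cell: 50 cm, flat, nick_chick."""
    return {
        ("peak_force_takeoff", "up"): {"intercept": 0.316, "distance": -0.038},
        ("peak_force_takeoff", "down"): {"intercept": 0.295, "hybrid": -0.047},
        ("peak_force_flight", "up"): {"intercept": 0.312, "angle": 0.056,
                                      "distance": -0.019, "angle * distance": -0.064},
        ("peak_force_flight", "down"): {"intercept": 0.330, "angle": 0.012,
                                        "distance": -0.011, "hybrid": -0.057,
                                        "angle * distance": -0.069},
        ("peak_force_landing", "up"): {"intercept": 0.341, "distance": -0.031},
        ("peak_force_landing", "down"): {"intercept": 0.352, "angle": -0.006,
                                         "hybrid": -0.042, "distance": -0.032},
        # up take-off impulse untransformed (N.s); down log
        ("impulse_takeoff", "up"): {"intercept": 0.30, "angle": -0.03,
                                    "distance": -0.01, "angle * distance": 0.01},
        ("impulse_takeoff", "down"): {"intercept": np.log(0.42), "hybrid": 0.26,
                                      "angle": 0.04, "distance": -0.18,
                                      "angle * distance": 0.30},
        ("impulse_landing", "up"): {"intercept": 0.344, "angle": 0.007,
                                    "distance": 0.126, "angle * distance": 0.365},
        ("impulse_landing", "down"): {"intercept": 0.464, "distance": 0.249},
        ("latency_to_jump", "up"): {"intercept": 0.10, "hybrid": 0.70,
                                    "distance": 0.59, "angle": -0.04,
                                    "angle * distance": 0.28},
        ("latency_to_jump", "down"): {"intercept": 0.70, "distance": 0.52,
                                      "angle": 0.28},
        ("latency_to_peck", "up"): {"intercept": -0.03, "angle": 0.04,
                                    "distance": 0.08, "angle * distance": 0.18},
        ("latency_to_peck", "down"): {"intercept": 0.0, "hybrid": -0.08,
                                      "distance": 0.05, "angle": 0.02,
                                      "angle * distance": 0.15},
        ("balancing", "up"): {"intercept": -1.20, "angle": -0.39,
                              "distance": -0.10, "angle * distance": 2.01},
        ("balancing", "down"): {"intercept": -0.60, "distance": 0.75},
    }


def _default_sds() -> dict:
    """Random-effect and residual SDs per response on the transformed scale,
    ordered pen / hen / hen_condition / date / residual."""
    inv = {"pen": 0.012, "hen": 0.030, "hen_condition": 0.018, "date": 0.008,
           "residual": 0.055}
    logn = {"pen": 0.05, "hen": 0.14, "hen_condition": 0.08, "date": 0.04,
            "residual": 0.28}
    return {
        "peak_force_takeoff": dict(inv),
        "peak_force_flight": dict(inv),
        "peak_force_landing": dict(inv),
        "impulse_takeoff": {"pen": 0.02, "hen": 0.05, "hen_condition": 0.03,
                            "date": 0.015, "residual": 0.08},
        "impulse_landing": dict(logn),
        "latency_to_jump": {"pen": 0.08, "hen": 0.28, "hen_condition": 0.14,
                            "date": 0.06, "residual": 0.45},
        "latency_to_peck": {"pen": 0.04, "hen": 0.10, "hen_condition": 0.06,
                            "date": 0.03, "residual": 0.20},
        "balancing": {"pen": 0.20, "hen": 0.55, "hen_condition": 0.30,
                      "date": 0.20, "residual": 0.0},
    }


@dataclass
class TraceShapeConfig:
    rate_hz: float = 800.0
    max_g: float = 200.0
    noise_sd_g: float = 0.02
    pre_signal_s: float = 0.5
    post_end_s: float = 0.4
    flap_freq_hz: float = 6.0
    # duration location/scale (lognormal on the natural scale) and hard bounds
    takeoff_duration_s: float = 0.12
    takeoff_duration_sigma: float = 0.15
    takeoff_duration_bounds: tuple = (0.05, 0.50)
    flight_duration_s: dict = field(default_factory=lambda: {50.0: 0.28, 100.0: 0.42})
    flight_duration_sigma: float = 0.10
    landing_duration_s: float = 0.70
    landing_duration_sigma: float = 0.15
    landing_duration_bounds: tuple = (0.30, 2.50)


@dataclass
class SimConfig:
    """Generative configuration of the synthetic study."""

    seed: int = 0
    n_hens_per_hybrid: int = 20
    n_pens: int = 8
    n_days: int = 16
    n_jumps: int = 5
    #: per-hybrid body mass (mean, sd) in kg; invented plumbing, configurable
    body_mass_kg: dict = field(default_factory=lambda: {
        "nick_chick": (1.6, 0.12), "brown_nick": (2.0, 0.15)})
    effects: dict = field(default_factory=_default_effects)
    sds: dict = field(default_factory=_default_sds)
    trace: TraceShapeConfig = field(default_factory=TraceShapeConfig)
    peck_censor_prob: float = 0.02
    clock_offset_ms: float = 0.0
    #: draw only these continuous responses (None = all); undrawn responses
    #: are set to their back-transformed intercepts
    responses: tuple | None = None

    def __post_init__(self) -> None:
        for resp, comps in self.sds.items():
            for name, sd in comps.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {resp}/{name}")
        if self.trace.noise_sd_g < 0:
            raise ValueError("noise sd must be nonnegative")

    def digest(self) -> str:
        return hashlib.sha256(repr(asdict(self)).encode()).hexdigest()[:16]


@dataclass
class JumpTruth:
    """Latent ground truth for one jump (times in seconds from trace start)."""

    session_id: int
    jump: int
    hen_id: str
    pen: str
    hybrid: str
    direction: str
    angle_class: str
    distance_cm: float
    date: str
    body_mass_kg: float
    signal_s: float
    takeoff_start_s: float
    takeoff_end_s: float
    landing_start_s: float
    landing_end_s: float
    first_peck_s: float | None
    peak_force_takeoff: float
    peak_force_flight: float
    peak_force_landing: float
    impulse_takeoff: float
    impulse_landing: float
    latency_to_jump: float
    latency_to_peck: float | None
    balancing: bool
    acclimation: bool

    def phase_times(self) -> list[float]:
        t = [self.signal_s, self.takeoff_start_s, self.takeoff_end_s,
             self.landing_start_s, self.landing_end_s]
        if self.first_peck_s is not None:
            t.append(self.first_peck_s)
        return t


def _snap(t: float) -> float:
    return round(round(t / _GRID_S) * _GRID_S, 3)


def simulate_roster(config: SimConfig) -> pd.DataFrame:
    """Roster of hens blocked by hybrid into pens (4-7 hens per pen by default)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.n_pens % 2:
        raise ValueError("n_pens must be even (half per hybrid)")
    pens_per_hybrid = config.n_pens // 2
    n = config.n_hens_per_hybrid
    base, extra = divmod(n, pens_per_hybrid)
    rows = []
    pen_no = 0
    for hybrid, tag in (("nick_chick", "NC"), ("brown_nick", "BN")):
        counts = np.array([base + (1 if i < extra else 0) for i in range(pens_per_hybrid)])
        # vary counts within [4, 7] while keeping the total, when room allows
        if pens_per_hybrid >= 2 and base - 1 >= 4 and base + 1 <= 7:
            k = rng.integers(0, pens_per_hybrid // 2 + 1)
            for i in range(k):
                counts[i] += 1
                counts[-1 - i] -= 1
        counts = rng.permutation(counts)
        if counts.min() < 4 or counts.max() > 7:
            raise ValueError(
                f"infeasible pen sizes {counts.tolist()} for {n} {hybrid} hens in "
                f"{pens_per_hybrid} pens (need 4-7 per pen)")
        mean, sd = config.body_mass_kg[hybrid]
        idx = 0
        for c in counts:
            pen_no += 1
            for _ in range(c):
                idx += 1
                rows.append({
                    "hen_id": f"{tag}{idx:02d}",
                    "pen": f"P{pen_no}",
                    "hybrid": hybrid,
                    "body_mass_pre_kg": round(max(0.8, rng.normal(mean, sd)), 3),
                    "body_mass_post_kg": round(max(0.8, rng.normal(mean, sd)), 3),
                })
    return pd.DataFrame(rows)


def _term_value(coefs: dict, dist: float, angle: str, hybrid: str) -> float:
    xd = 1.0 if dist == 100.0 else 0.0
    xa = 1.0 if angle == "steep" else 0.0
    xh = 1.0 if hybrid == "brown_nick" else 0.0
    x = {"intercept": 1.0, "distance": xd, "angle": xa, "hybrid": xh,
         "angle * distance": xa * xd, "distance * hybrid": xd * xh,
         "angle * hybrid": xa * xh, "angle * distance * hybrid": xa * xd * xh}
    bad = set(coefs) - set(x)
    if bad:
        raise ValueError(f"unknown effect terms {sorted(bad)}")
    return sum(b * x[t] for t, b in coefs.items())


def draw_outcomes(schedule: _design.Schedule, roster: pd.DataFrame,
                  config: SimConfig) -> list[JumpTruth]:
    """Draw latent per-jump outcomes for every session of the schedule."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    roster_idx = roster.set_index("hen_id")
    shape = config.trace

    responses = _CONTINUOUS + ["balancing"]
    # random-effect draws, lazily created per (response, level-key)
    re_draws: dict = {r: {c: {} for c in _COMPONENTS[:-1]} for r in responses}

    def rand_effect(resp: str, comp: str, key) -> float:
        sd = config.sds[resp][comp]
        if sd == 0.0:
            return 0.0
        store = re_draws[resp][comp]
        if key not in store:
            store[key] = rng.normal(0.0, sd)
        return store[key]

    truths: list[JumpTruth] = []
    for _, sess in schedule.sessions.iterrows():
        hen = roster_idx.loc[sess["hen_id"]]
        mass = 0.5 * (hen["body_mass_pre_kg"] + hen["body_mass_post_kg"])
        date = f"day{int(sess['day']):02d}"
        dist = float(sess["distance_cm"])
        angle, hybrid, direction = sess["angle_class"], hen["hybrid"], sess["direction"]
        cond_key = (sess["hen_id"], direction, dist, angle)
        drawn = set(_CONTINUOUS if config.responses is None else config.responses)
        drawn.add("balancing")
        for j in range(1, config.n_jumps + 1):
            vals = {}
            for resp in responses:
                coefs = config.effects[(resp, direction)]
                if resp not in drawn:
                    kind = default_transform(resp, direction)
                    vals[resp] = max(float(back_transform(coefs["intercept"], kind)), 0.05)
                    continue
                eta = _term_value(coefs, dist, angle, hybrid)
                eta += rand_effect(resp, "pen", sess["pen"])
                eta += rand_effect(resp, "hen", sess["hen_id"])
                eta += rand_effect(resp, "hen_condition", cond_key)
                eta += rand_effect(resp, "date", date)
                if resp == "balancing":
                    vals[resp] = bool(rng.random() < special.expit(eta))
                else:
                    eta += rng.normal(0.0, config.sds[resp]["residual"])
                    kind = default_transform(resp, direction)
                    # guard the far tail: the inverse transform blows up near
                    # eta = 0, so cap outcomes at plausible physical ranges
                    if kind == "inverse":
                        eta = max(eta, 0.08)
                    v = float(back_transform(eta, kind))
                    if resp.startswith("latency"):
                        v = min(v, 30.0)
                    vals[resp] = max(v, 0.05)

            # durations (seconds), lognormal jitter then snapped to the grid
            def _dur(mean, sigma, bounds):
                d = float(np.exp(rng.normal(np.log(mean), sigma)))
                return min(max(d, bounds[0]), bounds[1])

            t_takeoff = _dur(shape.takeoff_duration_s, shape.takeoff_duration_sigma,
                             shape.takeoff_duration_bounds)
            t_flight = _dur(shape.flight_duration_s[dist], shape.flight_duration_sigma,
                            (0.10, 1.0))
            t_landing = _dur(shape.landing_duration_s, shape.landing_duration_sigma,
                             shape.landing_duration_bounds)
            if vals["balancing"]:
                t_landing = min(t_landing * 1.3, shape.landing_duration_bounds[1])

            # Pull phase durations into the feasibility window of the trace
            # model: with a 1 G baseline plus a nonnegative pulse of amplitude
            # A, the phase impulse I satisfies m*T < I < m*T*(1 + c_shape*A),
            # so T must lie in (I / (m*(1+c_shape*A)), I/m).
            def _feasible(T, I, peak, bounds):
                # lower bound only: the renderer drops the phase baseline when
                # the impulse target is small, so short durations stay feasible
                b, A = _phase_baseline(peak / mass)
                lo = max(bounds[0], 1.05 * (I / mass) / (b + 0.95 * A))
                return min(max(T, lo), max(lo, bounds[1]))

            t_takeoff = _feasible(t_takeoff, vals["impulse_takeoff"],
                                  vals["peak_force_takeoff"],
                                  shape.takeoff_duration_bounds)
            t_landing = _feasible(t_landing, vals["impulse_landing"],
                                  vals["peak_force_landing"],
                                  shape.landing_duration_bounds)

            latency = max(_snap(vals["latency_to_jump"]), _GRID_S)
            signal_s = shape.pre_signal_s
            takeoff_start = _snap(signal_s + latency)
            takeoff_end = _snap(takeoff_start + max(t_takeoff, 0.05))
            landing_start = _snap(takeoff_end + max(t_flight, 0.10))
            landing_end = _snap(landing_start + max(t_landing, 0.10))
            censored = rng.random() < config.peck_censor_prob
            peck_lat = max(_snap(vals["latency_to_peck"]), _GRID_S)
            first_peck = None if censored else _snap(landing_end + peck_lat)

            truths.append(JumpTruth(
                session_id=int(sess["session_id"]),
                jump=j,
                hen_id=sess["hen_id"],
                pen=sess["pen"],
                hybrid=hybrid,
                direction=direction,
                angle_class=angle,
                distance_cm=dist,
                date=date,
                body_mass_kg=float(mass),
                signal_s=_snap(signal_s),
                takeoff_start_s=takeoff_start,
                takeoff_end_s=takeoff_end,
                landing_start_s=landing_start,
                landing_end_s=landing_end,
                first_peck_s=first_peck,
                peak_force_takeoff=vals["peak_force_takeoff"],
                peak_force_flight=vals["peak_force_flight"],
                peak_force_landing=vals["peak_force_landing"],
                impulse_takeoff=vals["impulse_takeoff"],
                impulse_landing=vals["impulse_landing"],
                latency_to_jump=latency,
                latency_to_peck=None if censored else peck_lat,
                balancing=vals["balancing"],
                acclimation=(j == 1),
            ))
    return truths


# ---------------------------------------------------------------------------
# trace rendering


_RAMP_EFF = 1.0 - 2.0 / np.pi  # area lost per unit ramp length vs a plateau


def _phase_baseline(peak_over_mass: float) -> tuple[float, float]:
    """Baseline load b (in G) and pulse amplitude A for a target peak.

    Peaks above the standing 1 G force ride on a 1 G baseline; smaller peaks
    are encoded by unloading the whole phase window to b < 1 (push-off or
    flight can genuinely dip below 1 G)."""
    if peak_over_mass >= 1.05:
        return 1.0, peak_over_mass - 1.0
    b = peak_over_mass / 1.05
    return b, peak_over_mass - b


def _thrust_pulse(t_rel: np.ndarray, c: float, A: float, T: float
                  ) -> tuple[np.ndarray, float]:
    """Flat-topped thrust pulse with quarter-sine ramps, amplitude A, target
    area c, fitted into [0, T]. Returns sampled values and achieved area."""
    if A <= 0 or c <= 0:
        return np.zeros_like(t_rel), 0.0
    if c >= 2.0 / np.pi * A * T:
        w = T
        r = min(max((A * T - c) / (2.0 * A * _RAMP_EFF), 1e-4), T / 2.0)
    else:
        w = min(max(c * np.pi / (2.0 * A), 0.005), T)
        r = w / 2.0
    area = A * (w - 2.0 * r * _RAMP_EFF)
    t0 = (T - w) / 2.0
    s = t_rel - t0
    out = np.zeros_like(t_rel)
    rise = (s >= 0) & (s < r)
    out[rise] = A * np.sin(np.pi * s[rise] / (2.0 * r))
    out[(s >= r) & (s < w - r)] = A
    fall = (s >= w - r) & (s <= w)
    out[fall] = A * np.sin(np.pi * (w - s[fall]) / (2.0 * r))
    return out, area


def _solve_exp_tau(c: float, A: float, T: float) -> tuple[float, float]:
    """Decay time of A*exp(-t/tau) on [0, T] with target area c."""
    if A <= 0 or c <= 0:
        return 1e-4, 0.0

    def area(tau):
        return A * tau * (1.0 - np.exp(-T / tau))

    lo, hi = 1e-4, 50.0
    c = min(max(c, area(lo) * 1.001), area(hi) * 0.999)
    tau = optimize.brentq(lambda t: area(t) - c, lo, hi, xtol=1e-10)
    return tau, area(tau)


def render_trace(truth: JumpTruth, config: SimConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[_io.AccelTrace, _io.EventAnnotation, dict]:
    """Render one jump as a triaxial trace plus its event annotation.

    Returns ``(trace, annotation, encoded)`` where ``encoded`` holds the peak
    forces and impulses the noiseless trace actually encodes (closed-form
    values; they can differ from the drawn truth when a pulse had to be
    clipped to stay within the phase window or the sensor range).
    """
    shape = config.trace
    rate = shape.rate_hz
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 3, truth.session_id, truth.jump]))
    m = truth.body_mass_kg

    t_end = truth.first_peck_s if truth.first_peck_s is not None else truth.landing_end_s
    n = int(round((t_end + shape.post_end_s) * rate)) + 1
    t = np.arange(n) / rate
    z = np.ones(n)  # standing baseline: gravity, 1 G

    encoded: dict[str, float] = {}
    clip_warn = False

    # take-off: flat-topped thrust pulse centred in the phase window
    T_to = truth.takeoff_end_s - truth.takeoff_start_s
    pk_om = truth.peak_force_takeoff / m
    I_om = truth.impulse_takeoff / m
    b, A = _phase_baseline(pk_om)
    w_spike = 0.005  # narrowest pulse: 4 samples, peak lands on the grid
    k = 2.0 / np.pi * w_spike
    if I_om - b * T_to < A * k:
        # small impulse target: unload the baseline and carry the peak on a
        # narrow grid-aligned spike whose area is solved exactly
        b = max((I_om - pk_om * k) / (T_to - k), 1e-3)
        A = pk_om - b
    c = I_om - b * T_to  # required pulse area
    sel = (t >= truth.takeoff_start_s) & (t < truth.takeoff_end_s)
    pulse, area = _thrust_pulse(t[sel] - truth.takeoff_start_s, max(c, 1e-9), A, T_to)
    z[sel] = b + pulse
    encoded["peak_force_takeoff"] = m * (b + A)
    encoded["impulse_takeoff"] = m * (b * T_to + area)

    # flight: wing-flap loading, squared sine so loading stays >= baseline
    T_fl = truth.landing_start_s - truth.takeoff_end_s
    bf, Af = _phase_baseline(truth.peak_force_flight / m)
    f = shape.flap_freq_hz
    sel = (t >= truth.takeoff_end_s) & (t < truth.landing_start_s)
    z[sel] = bf + Af * np.sin(np.pi * f * (t[sel] - truth.takeoff_end_s)) ** 2
    area_fl = Af * (T_fl / 2.0 - np.sin(2 * np.pi * f * T_fl) / (4 * np.pi * f))
    encoded["peak_force_flight"] = m * (bf + Af) if T_fl * f >= 0.5 else float("nan")
    encoded["impulse_flight"] = m * (bf * T_fl + area_fl)

    # landing: impact pulse with exponential decay from first perch contact
    T_la = truth.landing_end_s - truth.landing_start_s
    pk_om = truth.peak_force_landing / m
    I_om = truth.impulse_landing / m
    bl, Al = _phase_baseline(pk_om)
    tau0 = 0.004  # narrowest impact spike the solver may need
    if I_om - bl * T_la < Al * tau0:
        bl = max((I_om - pk_om * tau0) / (T_la - tau0), 1e-3)
        Al = pk_om - bl
    c = I_om - bl * T_la
    tau, area = _solve_exp_tau(max(c, 1e-6), Al, T_la)
    sel = (t >= truth.landing_start_s) & (t < truth.landing_end_s)
    z[sel] = bl + Al * np.exp(-(t[sel] - truth.landing_start_s) / tau)
    encoded["peak_force_landing"] = m * (bl + Al)
    encoded["impulse_landing"] = m * (bl * T_la + area)

    if 1.0 + max(A, Af, Al) > shape.max_g:
        warnings.warn(
            f"session {truth.session_id} jump {truth.jump}: requested peak exceeds "
            f"the ±{shape.max_g:g} G sensor range; trace will clip", stacklevel=2)
        clip_warn = True

    if shape.noise_sd_g > 0:
        ax = rng.normal(0.0, shape.noise_sd_g, n)
        ay = rng.normal(0.0, shape.noise_sd_g, n)
        z = z + rng.normal(0.0, shape.noise_sd_g, n)
    else:
        ax = np.zeros(n)
        ay = np.zeros(n)
    clipped = clip_warn or bool(np.any(np.abs(z) > shape.max_g))
    z = np.clip(z, -shape.max_g, shape.max_g)

    trace = _io.AccelTrace(start_s=0.0, rate_hz=rate, ax=ax, ay=ay, az=z,
                           clipped=clipped)
    ann = _io.EventAnnotation(
        session_id=truth.session_id,
        jump=truth.jump,
        signal_ms=round(truth.signal_s * 1000.0 + config.clock_offset_ms, 3),
        takeoff_start_ms=round(truth.takeoff_start_s * 1000.0 + config.clock_offset_ms, 3),
        takeoff_end_ms=round(truth.takeoff_end_s * 1000.0 + config.clock_offset_ms, 3),
        landing_start_ms=round(truth.landing_start_s * 1000.0 + config.clock_offset_ms, 3),
        landing_end_ms=round(truth.landing_end_s * 1000.0 + config.clock_offset_ms, 3),
        first_peck_ms=None if truth.first_peck_s is None else
            round(truth.first_peck_s * 1000.0 + config.clock_offset_ms, 3),
        balancing=truth.balancing,
        clock_offset_ms=config.clock_offset_ms,
    )
    return trace, ann, encoded


# ---------------------------------------------------------------------------
# dataset emission


def truth_table(truths: list[JumpTruth]) -> pd.DataFrame:
    rows = []
    for tr in truths:
        d = {k: v for k, v in tr.__dict__.items()}
        d["balancing"] = int(tr.balancing)
        d["acclimation"] = int(tr.acclimation)
        rows.append(d)
    return pd.DataFrame(rows)


def truth_metrics_frame(truths: list[JumpTruth],
                        exclude_acclimation: bool = True) -> pd.DataFrame:
    """Per-jump metrics table built directly from the latent truth.

    Bypasses trace rendering and extraction — the fast path for exercising
    the inference stage against known generative parameters.
    """
    rows = []
    for tr in truths:
        if exclude_acclimation and tr.acclimation:
            continue
        rows.append({
            "session_id": tr.session_id, "jump": tr.jump, "hen_id": tr.hen_id,
            "pen": tr.pen, "hybrid": tr.hybrid, "direction": tr.direction,
            "angle_class": tr.angle_class, "distance_cm": tr.distance_cm,
            "date": tr.date,
            "peak_force_takeoff": tr.peak_force_takeoff,
            "peak_force_flight": tr.peak_force_flight,
            "peak_force_landing": tr.peak_force_landing,
            "impulse_takeoff": tr.impulse_takeoff,
            "impulse_flight": np.nan,
            "impulse_landing": tr.impulse_landing,
            "latency_to_jump": tr.latency_to_jump,
            "duration_takeoff": tr.takeoff_end_s - tr.takeoff_start_s,
            "duration_flight": tr.landing_start_s - tr.takeoff_end_s,
            "duration_landing": tr.landing_end_s - tr.landing_start_s,
            "latency_to_peck": tr.latency_to_peck,
            "balancing": int(tr.balancing),
            "body_mass_kg": tr.body_mass_kg,
            "units_mode": "paper",
        })
    return pd.DataFrame(rows, columns=_io.METRICS_COLUMNS)


def emit_dataset(config: SimConfig, out_dir) -> dict:
    """Write the full synthetic study to ``out_dir``.

    Layout: roster.csv, schedule.csv, truth.csv, manifest.txt, and one trace +
    one event table per session under traces/ and events/. Sessions are
    rendered jump by jump and concatenated on a common session clock.
    Re-running with the same config is byte-identical.
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "events").mkdir(parents=True, exist_ok=True)

    roster = simulate_roster(config)
    schedule = _design.make_schedule(roster, n_days=config.n_days, seed=config.seed,
                                     n_jumps=config.n_jumps)
    truths = draw_outcomes(schedule, roster, config)
    _io.write_roster(roster, out / "roster.csv")
    _design.write_schedule(schedule, out / "schedule.csv")

    by_session: dict[int, list[JumpTruth]] = {}
    for tr in truths:
        by_session.setdefault(tr.session_id, []).append(tr)

    n_traces = 0
    for sid, jumps in sorted(by_session.items()):
        arrs, anns = [], []
        offset = 0.0
        rate = config.trace.rate_hz
        for tr in sorted(jumps, key=lambda j: j.jump):
            trace, ann, _ = render_trace(tr, config)
            arrs.append(np.column_stack([trace.ax, trace.ay, trace.az]))
            shift = offset * 1000.0
            anns.append(_io.EventAnnotation(
                session_id=ann.session_id, jump=ann.jump,
                signal_ms=ann.signal_ms + shift,
                takeoff_start_ms=ann.takeoff_start_ms + shift,
                takeoff_end_ms=ann.takeoff_end_ms + shift,
                landing_start_ms=ann.landing_start_ms + shift,
                landing_end_ms=ann.landing_end_ms + shift,
                first_peck_ms=None if ann.first_peck_ms is None else ann.first_peck_ms + shift,
                balancing=ann.balancing, clock_offset_ms=ann.clock_offset_ms))
            offset += len(trace) / rate
        stacked = np.vstack(arrs)
        session_trace = _io.AccelTrace(start_s=0.0, rate_hz=rate,
                                       ax=stacked[:, 0], ay=stacked[:, 1],
                                       az=stacked[:, 2])
        _io.write_trace(session_trace, out / "traces" / f"session_{sid:04d}.csv")
        _io.write_events(anns, out / "events" / f"session_{sid:04d}.csv")
        n_traces += 1

    truth_table(truths).to_csv(out / "truth.csv", index=False)
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_sessions": len(by_session),
        "n_jumps": len(truths),
        "n_hens": len(roster),
    }
    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k} = {v}\n")
    return manifest
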