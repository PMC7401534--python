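"""Pipeline stages: simulate -> extract -> analyze -> report.

Each stage is a plain function over a :class:`RunConfig`; the click command
line in :mod:`keeljump.cli` is a thin wrapper. The run configuration is a
flat ``key = value`` text file (see :func:`read_config`); every stage derives
all randomness from the single configured seed, so a config file fully
determines every output byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as _design
from . import io as _io
from . import kinetics as _kin
from . import simulate as _sim
from .inference import (
    FACTORS,
    RESPONSES,
    backward_reduce,
    estimate_effects,
    full_model_spec,
    term_label,
)

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "cmd_simulate",
    "cmd_extract",
    "cmd_analyze",
    "cmd_report",
]

log = logging.getLogger("keeljump")


@dataclass
class RunConfig:
    """Flat run configuration shared by all pipeline stages."""

    seed: int = 0
    dataset_dir: str = "dataset"
    metrics_path: str = "metrics.csv"
    analysis_dir: str = "analysis"
    units_mode: str = "paper"
    exclude_acclimation: bool = True
    alpha: float = 0.05
    n_sim: int = 1000
    n_hens_per_hybrid: int = 20
    n_pens: int = 8
    n_days: int = 16
    n_jumps: int = 5
    noise_sd_g: float = 0.02
    responses: tuple = tuple(RESPONSES)
    directions: tuple = ("up", "down")
    balancing_jump_level: bool = True
    force: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.units_mode not in ("paper", "si"):
            raise ValueError("units_mode must be 'paper' or 'si'")

    def sim_config(self) -> _sim.SimConfig:
        cfg = _sim.SimConfig(seed=self.seed,
                             n_hens_per_hybrid=self.n_hens_per_hybrid,
                             n_pens=self.n_pens, n_days=self.n_days,
                             n_jumps=self.n_jumps)
        cfg.trace.noise_sd_g = self.noise_sd_g
        return cfg


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file (``#`` starts a comment)."""
    kwargs = {}
    ftypes = {f.name: f for f in fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in ftypes:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        default = getattr(RunConfig, key, None)
        if isinstance(default, bool):
            kwargs[key] = _BOOL[val.lower()]
        elif isinstance(default, int):
            kwargs[key] = int(val)
        elif isinstance(default, float):
            kwargs[key] = float(val)
        elif isinstance(default, tuple):
            kwargs[key] = tuple(s.strip() for s in val.split(",") if s.strip())
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for f in fields(RunConfig):
            v = getattr(config, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            fh.write(f"{f.name} = {v}\n")


def cmd_simulate(config: RunConfig) -> dict:
    """Generate the synthetic study dataset (wraps the truth-first generator)."""
    out = Path(config.dataset_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force to overwrite")
    manifest = _sim.emit_dataset(config.sim_config(), out)
    log.info("simulated %d sessions (%d jumps) into %s",
             manifest["n_sessions"], manifest["n_jumps"], out)
    return manifest


def cmd_extract(config: RunConfig) -> pd.DataFrame:
    """Derive the per-jump metrics table from traces + annotations.

    The first (acclimation) jump of each session is excluded by default.
    Per-jump failures are logged and skipped; the run fails only if no jump
    survives.
    """
    root = Path(config.dataset_dir)
    roster = _io.read_roster(root / "roster.csv")
    schedule = _design.read_schedule(root / "schedule.csv")
    sess_info = schedule.sessions.set_index("session_id")
    hens = {r.hen_id: _io.HenRecord(r.hen_id, r.pen, r.hybrid,
                                    r.body_mass_pre_kg, r.body_mass_post_kg)
            for r in roster.itertuples()}

    rows = []
    n_failed = 0
    for events_path in sorted((root / "events").glob("session_*.csv")):
        sid = int(events_path.stem.split("_")[1])
        trace_path = root / "traces" / f"session_{sid:04d}.csv"
        try:
            trace = _io.read_trace(trace_path)
            annotations = _io.read_events(events_path)
        except (_io.FormatError, OSError) as exc:
            log.warning("session %d skipped: %s", sid, exc)
            n_failed += 1
            continue
        info = sess_info.loc[sid]
        hen = hens[info["hen_id"]]
        for ann in annotations:
            if config.exclude_acclimation and ann.jump == 1:
                continue
            try:
                pm = _kin.derive_metrics(trace, ann, hen, units_mode=config.units_mode)
            except (ValueError, _io.AlignmentError) as exc:
                log.warning("session %d jump %d skipped: %s", sid, ann.jump, exc)
                n_failed += 1
                continue
            rows.append({
                "session_id": sid,
                "jump": ann.jump,
                "hen_id": info["hen_id"],
                "pen": info["pen"],
                "hybrid": info["hybrid"],
                "direction": info["direction"],
                "angle_class": info["angle_class"],
                "distance_cm": info["distance_cm"],
                "date": f"day{int(info['day']):02d}",
                "peak_force_takeoff": pm.peak_force_takeoff,
                "peak_force_flight": pm.peak_force_flight,
                "peak_force_landing": pm.peak_force_landing,
                "impulse_takeoff": pm.impulse_takeoff,
                "impulse_flight": pm.impulse_flight,
                "impulse_landing": pm.impulse_landing,
                "latency_to_jump": pm.latency_to_jump,
                "duration_takeoff": pm.duration_takeoff,
                "duration_flight": pm.duration_flight,
                "duration_landing": pm.duration_landing,
                "latency_to_peck": pm.latency_to_peck,
                "balancing": int(pm.balancing),
                "body_mass_kg": pm.body_mass_kg,
                "units_mode": pm.units_mode,
            })
    if not rows:
        raise RuntimeError("extraction produced no usable jumps")
    log.info("extracted %d jumps (%d failures skipped)", len(rows), n_failed)
    metrics = pd.DataFrame(rows, columns=_io.METRICS_COLUMNS)
    _io.write_metrics(metrics, config.metrics_path)
    return metrics


_LEVEL_NAMES = {
    "distance": {"50": "50 cm", "100": "100 cm"},
    "angle": {"flat": "flat", "steep": "steep"},
    "hybrid": {"nick_chick": "Nick Chick", "brown_nick": "Brown Nick"},
}


def _pattern(results, term: tuple[str, ...]) -> str:
    """Human-readable direction-of-effect pattern for a retained term."""
    if len(term) == 3:
        return "three-way interaction"
    eff = estimate_effects(results, list(term))
    names = _LEVEL_NAMES

    def cmp(a_mean, b_mean, a_lab, b_lab):
        if abs(a_mean - b_mean) < 0.02 * max(abs(a_mean), abs(b_mean), 1e-9):
            return f"{a_lab} = {b_lab}"
        return f"{a_lab} > {b_lab}" if a_mean > b_mean else f"{b_lab} > {a_lab}"

    if len(term) == 1:
        f = term[0]
        lo, hi = FACTORS[f]
        m = eff.set_index(f)["mean"]
        return cmp(m[hi], m[lo], names[f][hi], names[f][lo])
    f1, f2 = term
    lines = []
    for lev in FACTORS[f1]:
        sub = eff[eff[f1] == lev].set_index(f2)["mean"]
        lo, hi = FACTORS[f2]
        lines.append(f"{names[f1][lev]}: "
                     + cmp(sub[hi], sub[lo], names[f2][hi], names[f2][lo]))
    return "; ".join(lines)


def cmd_analyze(config: RunConfig) -> pd.DataFrame:
    """Backward-reduce and report every response x direction model.

    Writes, per model, a text report (reduction trace, final REML/Laplace fit,
    back-transformed effect table) plus an overview table across models in the
    layout outcome / direction / retained effects / p / pattern. Per-model
    failures are isolated; the overview records them.
    """
    metrics = _io.read_metrics(config.metrics_path)
    out = Path(config.analysis_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([config.seed, 1000])

    overview_rows = []
    any_failed = False
    for response in config.responses:
        for direction in config.directions:
            seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            tag = f"{response}_{direction}"
            try:
                spec = full_model_spec(
                    response, direction,
                    include_jump_level=config.balancing_jump_level)
                final_spec, trace, final = backward_reduce(
                    metrics, spec, alpha=config.alpha, n_sim=config.n_sim,
                    seed=seed)
            except Exception as exc:  # isolate per-model failures
                log.error("model %s failed: %s", tag, exc)
                overview_rows.append({"response": response, "direction": direction,
                                      "effects": "FAILED", "p_value": np.nan,
                                      "pattern": str(exc)})
                any_failed = True
                continue

            lines = [f"=== {response} ({direction}ward jumps) ===", "",
                     "Reduction trace (parametric bootstrap, "
                     f"n_sim={config.n_sim}, alpha={config.alpha}):"]
            for s in trace.steps:
                lines.append(f"  {s.term:<28} T={s.stat:8.3f}  p={s.p_value:.4f}"
                             f"  -> {s.decision}")
            lines += ["", final.summary(), ""]
            final_p = {s.term: s.p_value for s in trace.steps}
            if final_spec.fixed_terms:
                lines.append("Effect estimates, response scale, mean (lower, upper):")
                for t in final_spec.fixed_terms:
                    eff = estimate_effects(final, list(t))
                    lines.append(f"  {term_label(t)}:")
                    for _, r in eff.iterrows():
                        levs = ", ".join(_LEVEL_NAMES[f][r[f]] for f in t)
                        lines.append(f"    {levs:<24} {r['mean']:.3f} "
                                     f"({r['lower']:.3f}, {r['upper']:.3f})")
                    overview_rows.append({
                        "response": response, "direction": direction,
                        "effects": term_label(t),
                        "p_value": final_p.get(term_label(t), np.nan),
                        "pattern": _pattern(final, t)})
            else:
                lines.append("No fixed effects retained (intercept-only model).")
                overview_rows.append({"response": response, "direction": direction,
                                      "effects": "none", "p_value": np.nan,
                                      "pattern": ""})
            (out / f"{tag}.txt").write_text("\n".join(lines) + "\n")

    overview = pd.DataFrame(overview_rows,
                            columns=["response", "direction", "effects",
                                     "p_value", "pattern"])
    overview.to_csv(out / "overview.csv", index=False)
    if any_failed:
        raise RuntimeError("one or more models failed; see analysis overview")
    return overview


def cmd_report(config: RunConfig) -> str:
    """Combine per-model outputs into one plain-text study report."""
    out = Path(config.analysis_dir)
    overview = pd.read_csv(out / "overview.csv")
    lines = ["Perch-transition outcome models: overview", ""]
    lines.append(f"{'response':<22}{'dir':<6}{'effects':<28}{'p':>8}  pattern")
    for _, r in overview.iterrows():
        p = "" if pd.isna(r["p_value"]) else f"{r['p_value']:.4f}"
        lines.append(f"{r['response']:<22}{r['direction']:<6}{r['effects']:<28}"
                     f"{p:>8}  {r['pattern'] if isinstance(r['pattern'], str) else ''}")
    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    return report
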