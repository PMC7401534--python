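"""Ground-truth generator: roster, outcomes, traces, dataset emission."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import keeljump as kj
from keeljump import io as kio
from keeljump.simulate import truth_metrics_frame, _phase_baseline
from conftest import small_config, simulate_metrics


class TestRoster:
    def test_default_counts(self):
        roster = kj.simulate_roster(kj.SimConfig(seed=0))
        assert len(roster) == 40
        assert roster["pen"].nunique() == 8
        assert roster.groupby("hybrid").size().eq(20).all()
        assert roster.groupby("pen").size().between(4, 7).all()
        assert roster.groupby("pen")["hybrid"].nunique().eq(1).all()

    def test_deterministic(self):
        a = kj.simulate_roster(kj.SimConfig(seed=9))
        b = kj.simulate_roster(kj.SimConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_pen_counts_rejected(self):
        with pytest.raises(ValueError, match="4-7"):
            kj.simulate_roster(kj.SimConfig(seed=0, n_hens_per_hybrid=40, n_pens=8))


class TestDrawOutcomes:
    def _truths(self, config):
        roster = kj.simulate_roster(config)
        schedule = kj.make_schedule(roster, n_days=config.n_days,
                                    seed=config.seed, n_jumps=config.n_jumps)
        return kj.draw_outcomes(schedule, roster, config)

    def test_degenerate_config_returns_intercepts(self):
        """With all coefficients and variances zero, every response is the
        back-transformed intercept."""
        cfg = small_config(1)
        for key in cfg.effects:
            cfg.effects[key] = {"intercept": cfg.effects[key]["intercept"]}
        for resp in cfg.sds:
            cfg.sds[resp] = {c: 0.0 for c in cfg.sds[resp]}
        truths = self._truths(cfg)
        for direction, resp in (("up", "peak_force_landing"),
                                ("down", "impulse_landing")):
            vals = np.array([getattr(t, resp) for t in truths
                             if t.direction == direction])
            kind = kj.inference.default_transform(resp, direction)
            expected = float(kj.inference.back_transform(
                cfg.effects[(resp, direction)]["intercept"], kind))
            np.testing.assert_allclose(vals, expected, rtol=1e-12)

    def test_distance_effect_recovered_by_averaging(self):
        """The simulated distance coefficient shows up as the difference of
        empirical means on the transformed scale (Monte-Carlo oracle)."""
        cfg = kj.SimConfig(seed=4, n_jumps=32,
                           responses=("impulse_landing",))
        beta = 0.40
        cfg.effects[("impulse_landing", "down")] = {"intercept": 0.46,
                                                    "distance": beta}
        for c in cfg.sds["impulse_landing"]:
            cfg.sds["impulse_landing"][c] = 0.0 if c != "residual" else 0.25
        truths = [t for t in self._truths(cfg) if t.direction == "down"]
        assert len(truths) >= 10_000 / 2
        logv = {d: np.log([t.impulse_landing for t in truths
                           if t.distance_cm == d]) for d in (50.0, 100.0)}
        diff = logv[100.0].mean() - logv[50.0].mean()
        mc_err = 3 * 0.25 * np.sqrt(1 / len(logv[100.0]) + 1 / len(logv[50.0]))
        assert diff == pytest.approx(beta, abs=mc_err)

    def test_balancing_rate_half_at_zero_logit(self):
        cfg = small_config(6, n_jumps=8)
        for d in ("up", "down"):
            cfg.effects[("balancing", d)] = {"intercept": 0.0}
        cfg.sds["balancing"] = {c: 0.0 for c in cfg.sds["balancing"]}
        truths = self._truths(cfg)
        rate = np.mean([t.balancing for t in truths])
        assert rate == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(truths)))

    def test_phase_boundaries_strictly_ordered(self, small_metrics):
        cfg = small_config(31)
        truths = self._truths(cfg)
        for t in truths:
            seq = t.phase_times()
            assert all(b > a for a, b in zip(seq[1:], seq[2:]))
            assert seq[1] >= seq[0]


class TestRenderTrace:
    def _one(self, seed=3, noise=0.0):
        cfg = small_config(seed)
        cfg.trace.noise_sd_g = noise
        roster = kj.simulate_roster(cfg)
        schedule = kj.make_schedule(roster, seed=seed, n_jumps=cfg.n_jumps)
        truths = kj.draw_outcomes(schedule, roster, cfg)
        return cfg, roster, truths

    def test_zero_noise_recovers_truth(self):
        """Noiseless traces reproduce the drawn peak forces and impulses to
        within one-sample quantization."""
        cfg, roster, truths = self._one()
        henmap = roster.set_index("hen_id")
        dt = 1.0 / cfg.trace.rate_hz
        for tr in truths[:120]:
            trace, ann, encoded = kj.render_trace(tr, cfg)
            hen = kio.HenRecord(tr.hen_id, tr.pen, tr.hybrid,
                                *henmap.loc[tr.hen_id,
                                            ["body_mass_pre_kg", "body_mass_post_kg"]])
            pm = kj.derive_metrics(trace, ann, hen)
            for ph in ("takeoff", "flight", "landing"):
                truth_pk = getattr(tr, f"peak_force_{ph}")
                assert getattr(pm, f"peak_force_{ph}") == pytest.approx(
                    truth_pk, rel=1e-3, abs=1e-6)
            for ph in ("takeoff", "landing"):
                truth_imp = getattr(tr, f"impulse_{ph}")
                tol = getattr(tr, f"peak_force_{ph}") * dt + 1e-6 * truth_imp
                assert abs(getattr(pm, f"impulse_{ph}") - truth_imp) <= tol

    def test_trace_length_arithmetic(self):
        cfg, _, truths = self._one()
        tr = truths[0]
        trace, _, _ = kj.render_trace(tr, cfg)
        t_end = tr.first_peck_s if tr.first_peck_s is not None else tr.landing_end_s
        expected = (t_end + cfg.trace.post_end_s) * cfg.trace.rate_hz
        assert abs(len(trace) - expected) <= 1

    def test_annotation_consistent_with_truth(self):
        cfg, _, truths = self._one()
        for tr in truths[:20]:
            _, ann, _ = kj.render_trace(tr, cfg)
            assert ann.takeoff_start_ms - ann.signal_ms == pytest.approx(
                tr.latency_to_jump * 1000.0, abs=0.5)
            assert ann.landing_end_ms - ann.landing_start_ms == pytest.approx(
                (tr.landing_end_s - tr.landing_start_s) * 1000.0, abs=0.5)

    def test_sensor_range_clip_flag(self):
        cfg, _, truths = self._one()
        tr = truths[0]
        tr.peak_force_takeoff = tr.body_mass_kg * 500.0  # 500 G, beyond range
        tr.impulse_takeoff = tr.peak_force_takeoff * 0.05
        with pytest.warns(UserWarning, match="sensor range"):
            trace, _, _ = kj.render_trace(tr, cfg)
        assert trace.clipped
        assert np.max(np.abs(trace.az)) <= cfg.trace.max_g

    def test_traces_respect_sensor_range(self):
        cfg, _, truths = self._one(noise=0.02)
        for tr in truths[:40]:
            trace, _, _ = kj.render_trace(tr, cfg)
            assert trace.clipped or np.max(np.abs(trace.az)) <= cfg.trace.max_g


class TestEmitDataset:
    def _digest(self, root: Path) -> str:
        h = hashlib.sha256()
        for p in sorted(root.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    def test_counts_and_determinism(self, tmp_path):
        cfg = small_config(12, n_hens_per_hybrid=4, n_jumps=2)
        m1 = kj.emit_dataset(cfg, tmp_path / "a")
        assert m1["n_sessions"] == 8 * 8
        assert m1["n_jumps"] == 8 * 8 * 2
        assert len(list((tmp_path / "a" / "events").glob("*.csv"))) == 64
        m2 = kj.emit_dataset(cfg, tmp_path / "b")
        assert m1 == m2
        assert self._digest(tmp_path / "a") == self._digest(tmp_path / "b")

    def test_different_seed_changes_bytes(self, tmp_path):
        kj.emit_dataset(small_config(13, n_hens_per_hybrid=4, n_jumps=2),
                        tmp_path / "a")
        kj.emit_dataset(small_config(14, n_hens_per_hybrid=4, n_jumps=2),
                        tmp_path / "b")
        assert self._digest(tmp_path / "a") != self._digest(tmp_path / "b")


def test_truth_metrics_frame_excludes_acclimation(small_metrics):
    assert (small_metrics["jump"] > 1).all()
    # 12 hens x 8 conditions x (3 - 1) jumps
    assert len(small_metrics) == 12 * 8 * 2
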