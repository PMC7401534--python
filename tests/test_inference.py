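"""Outcome models: transforms, bootstrap comparison, reduction, effects,
residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import keeljump as kj
from keeljump.inference import (
    FULL_TERMS,
    JumpOutcomeModel,
    ModelSpec,
    back_transform,
    back_transform_interval,
    backward_reduce,
    default_transform,
    estimate_effects,
    full_model_spec,
    pb_modcomp,
    simulate_quantile_residuals,
    transform,
)
from conftest import simulate_metrics, small_config


class TestTransforms:
    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=20))
    def test_round_trips(self, values):
        for kind in ("identity", "log", "inverse"):
            back = back_transform(transform(values, kind), kind)
            np.testing.assert_allclose(back, values, rtol=1e-12)

    def test_inverse_examples(self):
        assert transform([4.0], "inverse")[0] == 0.25
        assert back_transform([0.25], "inverse")[0] == 4.0

    def test_interval_endpoints_swap_under_inverse(self):
        lo, hi = back_transform_interval(0.2, 0.5, "inverse")
        assert (lo, hi) == (2.0, 5.0)

    def test_nonpositive_inputs_name_rows(self):
        with pytest.raises(ValueError, match="rows"):
            transform([1.0, -2.0, 3.0], "log")

    def test_default_transform_table(self):
        """Peak forces inverse; impulses/latencies log except upward take-off
        impulse (identity); balancing binomial."""
        for d in ("up", "down"):
            for r in ("peak_force_takeoff", "peak_force_flight",
                      "peak_force_landing"):
                assert default_transform(r, d) == "inverse"
            assert default_transform("impulse_landing", d) == "log"
            assert default_transform("latency_to_jump", d) == "log"
            assert default_transform("latency_to_peck", d) == "log"
        assert default_transform("impulse_takeoff", "up") == "identity"
        assert default_transform("impulse_takeoff", "down") == "log"


class TestModelSpec:
    def test_marginality_enforced_on_construction(self):
        with pytest.raises(ValueError, match="marginal"):
            ModelSpec("latency_to_jump", "up",
                      fixed_terms=(("angle", "distance"),))

    def test_droppable_terms_of_full_model(self):
        spec = full_model_spec("latency_to_jump", "up")
        assert spec.droppable_terms() == [("angle", "distance", "hybrid")]
        reduced = spec.drop(("angle", "distance", "hybrid"))
        assert set(reduced.droppable_terms()) == {
            ("angle", "distance"), ("distance", "hybrid"), ("angle", "hybrid")}

    def test_cannot_drop_marginal_term(self):
        spec = full_model_spec("latency_to_jump", "up")
        with pytest.raises(ValueError, match="droppable"):
            spec.drop(("distance",))

    def test_binomial_takes_no_transformation(self):
        with pytest.raises(ValueError, match="transformation"):
            ModelSpec("balancing", "up", family="binomial", transformation="log")


class TestModelFitting:
    def test_directions_never_pooled(self, small_metrics):
        m = JumpOutcomeModel.from_dataframe(small_metrics, "latency_to_jump", "up")
        assert set(m.data["direction"]) == {"up"}
        m2 = JumpOutcomeModel.from_dataframe(small_metrics, "latency_to_jump", "down")
        assert len(m.data) + len(m2.data) == len(small_metrics)

    def test_summary_mentions_model_and_transform(self, small_metrics):
        res = JumpOutcomeModel.from_dataframe(
            small_metrics, "peak_force_landing", "down").fit()
        s = res.summary()
        assert "inverse" in s and "downward" in s and "intercept" in s

    def test_balancing_is_binomial_with_probabilities(self, small_metrics):
        res = JumpOutcomeModel.from_dataframe(small_metrics, "balancing", "up").fit()
        eff = estimate_effects(res, ["distance"])
        assert ((eff["mean"] > 0) & (eff["mean"] < 1)).all()
        assert ((eff["lower"] < eff["mean"]) & (eff["mean"] < eff["upper"])).all()

    def test_identity_effects_equal_cell_means_of_fitted_values(self):
        """With an identity response and a saturated fixed part, the effect
        table reproduces plain cell means of the fitted values."""
        cfg = small_config(21, n_jumps=4, responses=("impulse_takeoff",))
        metrics = simulate_metrics(cfg)
        res = JumpOutcomeModel.from_dataframe(metrics, "impulse_takeoff", "up").fit()
        eff = estimate_effects(res, ["distance", "angle", "hybrid"])
        sub = res.model.data
        beta = res.params
        # saturated model: cell prediction equals the sum of its active terms
        for _, r in eff.iterrows():
            x = {"distance": r["distance"] == "100", "angle": r["angle"] == "steep",
                 "hybrid": r["hybrid"] == "brown_nick"}
            pred = beta["intercept"]
            for term in res.spec.fixed_terms:
                if all(x[f] for f in term):
                    pred += beta[" * ".join(term)]
            assert r["mean"] == pytest.approx(pred, rel=1e-9)

    def test_unfitted_factor_rejected_in_effect_table(self, small_metrics):
        spec = ModelSpec("latency_to_jump", "up", transformation="log",
                         fixed_terms=(("distance",),), random=("hen",))
        res = JumpOutcomeModel(spec, small_metrics).fit()
        with pytest.raises(ValueError, match="not in the fitted model"):
            estimate_effects(res, ["hybrid"])

    def test_variance_components_recovered_and_consistent(self):
        """Hen-level variance is estimated within 50% relative error at the
        study's hen count and tightens when the hen count grows tenfold."""
        truth = 0.28 ** 2

        def hen_vc(n_per_hybrid, n_pens, seed):
            cfg = kj.SimConfig(seed=seed, n_hens_per_hybrid=n_per_hybrid,
                               n_pens=n_pens, n_jumps=3,
                               responses=("latency_to_jump",))
            cfg.sds["latency_to_jump"] = {"pen": 0.0, "hen": 0.28,
                                          "hen_condition": 0.0, "date": 0.0,
                                          "residual": 0.45}
            metrics = simulate_metrics(cfg)
            spec = ModelSpec("latency_to_jump", "up", transformation="log",
                             random=("hen",))
            return JumpOutcomeModel(spec, metrics).fit().vcomps["hen"]

        small = hen_vc(20, 8, seed=3)
        big = hen_vc(200, 80, seed=3)
        assert abs(small - truth) / truth < 0.5
        assert abs(big - truth) / truth < 0.35

    def test_back_transformed_interval_ordering(self, small_metrics):
        res = JumpOutcomeModel.from_dataframe(
            small_metrics, "peak_force_takeoff", "up").fit()
        eff = estimate_effects(res, ["distance"])
        assert ((eff["lower"] < eff["mean"]) & (eff["mean"] < eff["upper"])).all()
        assert (eff["mean"] > 0).all()


@pytest.fixture(scope="module")
def metrics():
    cfg = small_config(41, responses=("latency_to_jump",))
    return simulate_metrics(cfg)


class TestParametricBootstrap:
    def _models(self, metrics, random=("hen",)):
        spec = ModelSpec("latency_to_jump", "down", transformation="log",
                         fixed_terms=(("distance",), ("angle",)), random=random)
        full = JumpOutcomeModel(spec, metrics)
        reduced = JumpOutcomeModel(spec.drop(("angle",)), metrics)
        return full, reduced

    def test_identical_models_give_p_one(self, metrics):
        full, _ = self._models(metrics)
        res = pb_modcomp(full, full, n_sim=50, seed=1)
        assert res.stat == 0.0
        assert res.p_value == 1.0

    def test_p_value_definition_and_determinism(self, metrics):
        full, reduced = self._models(metrics)
        r1 = pb_modcomp(full, reduced, n_sim=99, seed=7)
        r2 = pb_modcomp(full, reduced, n_sim=99, seed=7)
        assert r1.p_value == (r1.count_ge + 1) / (r1.n_sim - r1.n_failed + 1)
        assert (r1.p_value, r1.stat) == (r2.p_value, r2.stat)
        assert 0 < r1.p_value <= 1

    def test_invariant_to_relabeled_grouping_levels(self, metrics):
        full, reduced = self._models(metrics)
        renamed = metrics.copy()
        renamed["hen_id"] = "zz_" + renamed["hen_id"].str[::-1]
        full2, reduced2 = self._models(renamed)
        a = pb_modcomp(full, reduced, n_sim=60, seed=3)
        b = pb_modcomp(full2, reduced2, n_sim=60, seed=3)
        assert a.p_value == b.p_value
        assert a.stat == pytest.approx(b.stat, rel=1e-8)

    def test_non_nested_rejected(self, metrics):
        full, reduced = self._models(metrics)
        with pytest.raises(ValueError, match="nested"):
            pb_modcomp(reduced, full, n_sim=10, seed=0)

    def test_strong_effect_attains_minimum_p(self):
        cfg = small_config(43, responses=("latency_to_jump",))
        cfg.effects[("latency_to_jump", "down")] = {"intercept": 0.7,
                                                    "distance": 2.0}
        metrics = simulate_metrics(cfg)
        spec = ModelSpec("latency_to_jump", "down", transformation="log",
                         fixed_terms=(("distance",),), random=("hen",))
        full = JumpOutcomeModel(spec, metrics)
        reduced = JumpOutcomeModel(
            ModelSpec("latency_to_jump", "down", transformation="log",
                      fixed_terms=(), random=("hen",)), metrics)
        res = pb_modcomp(full, reduced, n_sim=99, seed=5)
        assert res.p_value == 1.0 / (res.n_sim - res.n_failed + 1)


class TestBackwardReduction:
    def test_interaction_keeps_marginal_main_effects(self):
        """Simulated distance-by-angle interaction: both main effects stay by
        marginality even if their own tests would drop them."""
        cfg = small_config(51, responses=("impulse_landing",))
        cfg.effects[("impulse_landing", "down")] = {
            "intercept": 0.46, "distance": 0.0, "angle": 0.0,
            "angle * distance": 1.5}
        metrics = simulate_metrics(cfg)
        spec = ModelSpec("impulse_landing", "down", transformation="log",
                         fixed_terms=FULL_TERMS, random=("hen",))
        final, trace, fit = backward_reduce(metrics, spec, alpha=0.05,
                                            n_sim=60, seed=2)
        assert ("angle", "distance") in final.fixed_terms
        assert ("distance",) in final.fixed_terms
        assert ("angle",) in final.fixed_terms
        assert fit.converged

    def test_trace_records_every_test(self):
        cfg = small_config(52, responses=("latency_to_jump",))
        metrics = simulate_metrics(cfg)
        spec = ModelSpec("latency_to_jump", "up", transformation="log",
                         fixed_terms=(("distance",), ("hybrid",)),
                         random=("hen",))
        final, trace, _ = backward_reduce(metrics, spec, alpha=0.05,
                                          n_sim=40, seed=9)
        df = trace.to_frame()
        assert {"term", "stat", "p_value", "decision"} <= set(df.columns)
        assert len(df) >= len(final.fixed_terms)
        assert set(df["decision"]) <= {"dropped", "retained"}


class TestQuantileResiduals:
    def test_deterministic_and_uniformish_when_well_specified(self, small_metrics):
        res = JumpOutcomeModel.from_dataframe(
            small_metrics, "latency_to_jump", "up").fit()
        q1 = simulate_quantile_residuals(res, n_sim=120, seed=4)
        q2 = simulate_quantile_residuals(res, n_sim=120, seed=4)
        np.testing.assert_array_equal(q1.quantiles, q2.quantiles)
        assert q1.ks_pvalue > 0.01
        assert ((q1.quantiles >= 0) & (q1.quantiles <= 1)).all()

    def test_outlier_hits_quantile_bound(self, small_metrics):
        data = small_metrics.copy()
        idx = data.index[data["direction"] == "up"][0]
        data.loc[idx, "latency_to_jump"] = 1e5
        res = JumpOutcomeModel.from_dataframe(data, "latency_to_jump", "up").fit()
        q = simulate_quantile_residuals(res, n_sim=60, seed=0)
        assert q.quantiles[0] == 1.0

    def test_calibrated_over_replicates(self):
        """Well-specified Gaussian fits give KS p > 0.01 in nearly all
        replicates."""
        ok = 0
        for rep in range(20):
            cfg = small_config(600 + rep, responses=("latency_to_jump",))
            metrics = simulate_metrics(cfg)
            res = JumpOutcomeModel(
                ModelSpec("latency_to_jump", "up", transformation="log",
                          fixed_terms=(("distance",),), random=("hen",)),
                metrics).fit()
            q = simulate_quantile_residuals(res, n_sim=150, seed=rep)
            ok += q.ks_pvalue > 0.01
        assert ok >= 19
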