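"""Mixed-model inference for perch-transition outcomes.

Each outcome (peak forces and impulses per phase, latencies, balancing) is
analyzed separately for upward and downward jumps with the fixed effects
distance (50 vs 100 cm), angle (flat vs steep), hybrid (Nick Chick vs Brown
Nick) and all their interactions, and random intercepts for pen, hen within
pen, condition within hen (the four distance-by-angle cells of one direction)
and calendar date as a crossed factor. The jump index within a session is the
finest level: it is absorbed into the residual for Gaussian responses and kept
as an explicit observation-level intercept for the binomial balancing model
(configurable).

Continuous responses are transformed before fitting (inverse for the peak
forces, log for most impulses and latencies, identity for upward take-off
impulse) and effect estimates are reported back-transformed, with interval
endpoints swapped where the transformation is order-reversing.

Model comparison uses parametric-bootstrap likelihood-ratio tests: responses
are simulated from the reduced ML fit (drawing new random effects and
residuals), both models are refitted on each draw, and the p-value is
(1 + #{T* >= T_obs}) / (n_sim + 1). The final model is found by stepwise
backward reduction under marginality (a term is only droppable while no
retained higher-order term contains it), removing the largest p > alpha one
term at a time. Comparisons use ML; the final reported fit uses REML for
Gaussian responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._mixed import FitError, GLMMDesign, GLMMFit, LMMDesign, LMMFit

__all__ = [
    "FACTORS",
    "FULL_TERMS",
    "RESPONSES",
    "ModelSpec",
    "JumpOutcomeModel",
    "JumpOutcomeResults",
    "PBTestResult",
    "ReductionStep",
    "ReductionTrace",
    "QuantileResiduals",
    "default_transform",
    "transform",
    "back_transform",
    "back_transform_interval",
    "full_model_spec",
    "pb_modcomp",
    "backward_reduce",
    "estimate_effects",
    "simulate_quantile_residuals",
]

#: Experimental factors and their (reference, treatment) levels.
FACTORS = {
    "distance": ("50", "100"),
    "angle": ("flat", "steep"),
    "hybrid": ("nick_chick", "brown_nick"),
}

#: All fixed-effect terms of the full three-way interaction model.
FULL_TERMS: tuple[tuple[str, ...], ...] = (
    ("distance",),
    ("angle",),
    ("hybrid",),
    ("angle", "distance"),
    ("distance", "hybrid"),
    ("angle", "hybrid"),
    ("angle", "distance", "hybrid"),
)

#: Analyzed responses and their default family.
RESPONSES = [
    "peak_force_takeoff",
    "peak_force_flight",
    "peak_force_landing",
    "impulse_takeoff",
    "impulse_landing",
    "latency_to_jump",
    "latency_to_peck",
    "balancing",
]

_DEFAULT_RANDOM = ("pen", "hen", "hen_condition", "date")


def default_transform(response: str, direction: str) -> str:
    """The per-response transformation used for analysis.

    Peak forces are inverse-transformed; impulses and latencies log-transformed
    except upward take-off impulse (untransformed); balancing is binomial.
    """
    if response == "balancing":
        return "identity"
    if response.startswith("peak_force"):
        return "inverse"
    if response == "impulse_takeoff":
        return "identity" if direction == "up" else "log"
    return "log"


def transform(values, kind: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if kind == "identity":
        return values
    bad = np.nonzero(values <= 0)[0]
    if bad.size:
        raise ValueError(f"{kind} transform needs positive values; "
                         f"offending rows: {bad[:10].tolist()}")
    if kind == "log":
        return np.log(values)
    if kind == "inverse":
        return 1.0 / values
    raise ValueError(f"unknown transformation {kind!r}")


def back_transform(values, kind: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if kind == "identity":
        return values
    if kind == "log":
        return np.exp(values)
    if kind == "inverse":
        return 1.0 / values
    raise ValueError(f"unknown transformation {kind!r}")


def back_transform_interval(lo, hi, kind: str) -> tuple:
    """Back-transform a transformed-scale interval, swapping endpoints when the
    back-transformation is order-reversing (the inverse transform)."""
    a, b = back_transform(lo, kind), back_transform(hi, kind)
    if kind == "inverse":
        a, b = b, a
    return a, b


def _canon_term(term: Iterable[str]) -> tuple[str, ...]:
    t = tuple(sorted(term))
    for f in t:
        if f not in FACTORS:
            raise ValueError(f"unknown factor {f!r} in term {t}")
    return t


def term_label(term: tuple[str, ...]) -> str:
    return " * ".join(term)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one outcome model."""

    response: str
    direction: str
    family: str = "gaussian"
    transformation: str = "identity"
    fixed_terms: tuple[tuple[str, ...], ...] = FULL_TERMS
    random: tuple[str, ...] = _DEFAULT_RANDOM
    obs_level: bool = True  # explicit jump-level intercept (binomial only)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and self.transformation != "identity":
            raise ValueError("binomial models take no response transformation")
        terms = tuple(_canon_term(t) for t in self.fixed_terms)
        object.__setattr__(self, "fixed_terms", terms)
        self._check_marginality(terms)

    @staticmethod
    def _check_marginality(terms: Sequence[tuple[str, ...]]) -> None:
        present = set(terms)
        for t in terms:
            for f in t:
                sub = tuple(sorted(set(t) - {f}))
                if sub and sub not in present:
                    raise ValueError(
                        f"term {term_label(t)} requires its marginal term {term_label(sub)}")

    def droppable_terms(self) -> list[tuple[str, ...]]:
        """Terms not contained in any retained higher-order term."""
        out = []
        for t in self.fixed_terms:
            if not any(set(t) < set(o) for o in self.fixed_terms):
                out.append(t)
        return out

    def drop(self, term) -> "ModelSpec":
        t = _canon_term(term)
        if t not in self.droppable_terms():
            raise ValueError(f"term {term_label(t)} is not droppable (marginality)")
        return replace(self, fixed_terms=tuple(x for x in self.fixed_terms if x != t))

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.fixed_terms) <= set(other.fixed_terms)


def full_model_spec(response: str, direction: str, include_jump_level: bool = True,
                    transformation: str | None = None) -> ModelSpec:
    """The full three-way-interaction model for one response and direction."""
    family = "binomial" if response == "balancing" else "gaussian"
    if transformation is None:
        transformation = "identity" if family == "binomial" else default_transform(
            response, direction)
    return ModelSpec(response=response, direction=direction, family=family,
                     transformation=transformation, obs_level=include_jump_level)


# ---------------------------------------------------------------------------
# design construction


def _indicator(data: pd.DataFrame, factor: str) -> np.ndarray:
    ref, alt = FACTORS[factor]
    if factor == "distance":
        col = data["distance_cm"].astype(float).map(lambda v: f"{v:g}")
    elif factor == "angle":
        col = data["angle_class"].astype(str)
    else:
        col = data["hybrid"].astype(str).str.lower().str.replace(" ", "_")
    vals = set(col.unique())
    if not vals <= {ref, alt}:
        raise ValueError(f"factor {factor!r} has unexpected levels {sorted(vals)}")
    return (col == alt).to_numpy(float)


def build_fixed_design(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    ind = {f: _indicator(data, f) for f in FACTORS}
    for t in spec.fixed_terms:
        x = np.ones(len(data))
        for f in t:
            x = x * ind[f]
        cols.append(x)
        names.append(term_label(t))
    return np.column_stack(cols), names


def _random_factors(spec: ModelSpec, data: pd.DataFrame) -> dict:
    hen = data["hen_id"].astype(str)
    cond = data["distance_cm"].astype(float).map(lambda v: f"{v:g}") + "_" + \
        data["angle_class"].astype(str)
    available = {
        "pen": data["pen"].astype(str).to_numpy(),
        "hen": hen.to_numpy(),
        "hen_condition": (hen + ":" + cond).to_numpy(),
        "date": data["date"].astype(str).to_numpy(),
    }
    out = {}
    for name in spec.random:
        if name not in available:
            raise ValueError(f"unknown random grouping {name!r}")
        fac = available[name]
        if len(np.unique(fac)) >= 2:
            out[name] = fac
    return out


class JumpOutcomeModel:
    """One outcome model (statsmodels-style): construct from data, then fit.

    Parameters
    ----------
    spec : ModelSpec
    data : per-jump metrics table with columns direction, distance_cm,
        angle_class, hybrid, pen, hen_id, date and the response column.
        Rows of the other direction are dropped automatically.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        sub = data[data["direction"] == spec.direction]
        sub = sub[sub[spec.response].notna()].reset_index(drop=True)
        if not len(sub):
            raise ValueError(f"no usable rows for {spec.response} ({spec.direction})")
        self.data = sub
        y_raw = sub[spec.response].to_numpy(float)
        X, names = build_fixed_design(spec, sub)
        factors = _random_factors(spec, sub)
        if spec.family == "gaussian":
            self.endog = transform(y_raw, spec.transformation)
            self.design = LMMDesign(X, factors, beta_names=names)
        else:
            bad = set(np.unique(y_raw)) - {0.0, 1.0}
            if bad:
                raise ValueError(f"binomial response must be 0/1, found {sorted(bad)}")
            self.endog = y_raw
            self.design = GLMMDesign(X, factors, beta_names=names,
                                     obs_level=spec.obs_level)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, direction: str,
                       **spec_kwargs) -> "JumpOutcomeModel":
        return cls(full_model_spec(response, direction, **spec_kwargs), data)

    def fit(self, reml: bool | None = None) -> "JumpOutcomeResults":
        """Fit the model. Gaussian models default to REML for reporting; pass
        ``reml=False`` for likelihood-ratio work. Binomial fits are Laplace ML."""
        if self.spec.family == "gaussian":
            if reml is None:
                reml = True
            raw = self.design.fit(self.endog, reml=reml)
        else:
            raw = self.design.fit(self.endog)
        return JumpOutcomeResults(self, raw)


class JumpOutcomeResults:
    """Fitted outcome model: estimates, uncertainties, diagnostics."""

    def __init__(self, model: JumpOutcomeModel, raw: LMMFit | GLMMFit):
        self.model = model
        self.spec = model.spec
        self._raw = raw

    # -- basic accessors -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._raw.beta, index=self._raw.beta_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._raw.bse, index=self._raw.beta_names)

    @property
    def vcomps(self) -> pd.Series:
        v = dict(self._raw.vcomp)
        if self.spec.family == "gaussian":
            v["residual"] = self._raw.sigma2
        return pd.Series(v)

    @property
    def llf(self) -> float:
        return self._raw.llf

    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def singular(self) -> bool:
        return self._raw.singular

    @property
    def nobs(self) -> int:
        return self._raw.n

    def _tcrit(self, alpha: float) -> float:
        return float(stats.t.ppf(1 - alpha / 2, max(self._raw.df_resid, 1)))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        c = self._tcrit(alpha)
        lo = self._raw.beta - c * self._raw.bse
        hi = self._raw.beta + c * self._raw.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self._raw.beta_names)

    def simulate(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Simulate responses on the model (transformed / linear) scale."""
        return self._raw.simulate(rng, size)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        s = self.spec
        head = (
            f"{'Binomial-logit' if s.family == 'binomial' else 'Gaussian'} mixed model: "
            f"{s.response} ({s.direction}ward jumps)\n"
            f"transformation: {s.transformation}   n = {self.nobs}   "
            f"{'REML' if getattr(self._raw, 'reml', False) else 'ML'}   "
            f"logLik = {self.llf:.3f}\n"
            f"converged: {self.converged}   singular: {self.singular}\n"
        )
        ci = self.conf_int()
        rows = [f"{'term':<28}{'estimate':>10}{'se':>10}{'lower':>10}{'upper':>10}"]
        for name, b, se, lo, hi in zip(self._raw.beta_names, self._raw.beta,
                                       self._raw.bse, ci["lower"], ci["upper"]):
            rows.append(f"{name:<28}{b:>10.4f}{se:>10.4f}{lo:>10.4f}{hi:>10.4f}")
        vrows = ["variance components:"]
        for name, v in self.vcomps.items():
            vrows.append(f"  {name:<20}{v:>12.6f}")
        return head + "\n".join(rows) + "\n" + "\n".join(vrows)

    def estimate_effects(self, factors: Sequence[str], alpha: float = 0.05) -> pd.DataFrame:
        return estimate_effects(self, factors, alpha=alpha)


# ---------------------------------------------------------------------------
# parametric bootstrap


@dataclass
class PBTestResult:
    """Parametric-bootstrap likelihood-ratio test of reduced vs full model."""

    term: str
    stat: float
    n_sim: int
    count_ge: int
    n_failed: int
    seed: int
    valid: bool

    @property
    def p_value(self) -> float:
        n_ok = self.n_sim - self.n_failed
        return (self.count_ge + 1) / (n_ok + 1)


def _fit_ml(model: JumpOutcomeModel):
    if model.spec.family == "gaussian":
        return model.design.fit(model.endog, reml=False)
    return model.design.fit(model.endog)


def pb_modcomp(full: JumpOutcomeModel, reduced: JumpOutcomeModel,
               n_sim: int = 1000, seed: int = 0, term: str = "") -> PBTestResult:
    """Parametric-bootstrap model comparison (reduced nested in full).

    Simulates ``n_sim`` responses from the reduced ML fit, refits both models
    on each, and compares the observed LR statistic against the simulated
    ones: p = (1 + #{T* >= T_obs}) / (n_ok + 1). Refit failures are counted;
    more than 10% invalidates the test.
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("reduced model must be nested in the full model")
    fit_f = _fit_ml(full)
    fit_r = _fit_ml(reduced)
    t_obs = max(0.0, 2.0 * (fit_f.llf - fit_r.llf))
    rng = np.random.default_rng(seed)
    ystars = fit_r.simulate(rng, n_sim)
    count_ge = 0
    n_failed = 0
    for i in range(n_sim):
        y = ystars[i]
        try:
            lf = full.design.fit(y) if full.spec.family == "binomial" else \
                full.design.fit(y, reml=False)
            lr = reduced.design.fit(y) if reduced.spec.family == "binomial" else \
                reduced.design.fit(y, reml=False)
            t = 2.0 * (lf.llf - lr.llf)
            if not np.isfinite(t):
                raise FitError("non-finite bootstrap statistic")
        except (FitError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if max(t, 0.0) >= t_obs:
            count_ge += 1
    valid = n_failed <= 0.1 * n_sim
    return PBTestResult(term=term, stat=t_obs, n_sim=n_sim, count_ge=count_ge,
                        n_failed=n_failed, seed=seed, valid=valid)


@dataclass
class ReductionStep:
    term: str
    stat: float
    n_sim: int
    p_value: float
    decision: str  # "dropped" | "retained"


@dataclass
class ReductionTrace:
    steps: list[ReductionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def backward_reduce(data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05,
                    n_sim: int = 1000, seed: int = 0
                    ) -> tuple[ModelSpec, ReductionTrace, JumpOutcomeResults]:
    """Stepwise-backwards reduction under marginality.

    At each iteration every currently droppable term is tested by parametric
    bootstrap against the model without it; the term with the largest p-value
    above ``alpha`` is removed and the procedure repeats until no droppable
    term exceeds ``alpha``. Returns the final spec, the full test trace, and
    the final fit (REML for Gaussian responses).
    """
    ss = np.random.SeedSequence(seed)
    trace = ReductionTrace()
    current = spec
    while True:
        droppable = current.droppable_terms()
        if not droppable:
            break
        full_model = JumpOutcomeModel(current, data)
        results = []
        for t in droppable:
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            reduced = JumpOutcomeModel(current.drop(t), data)
            res = pb_modcomp(full_model, reduced, n_sim=n_sim, seed=child_seed,
                             term=term_label(t))
            if not res.valid:
                raise FitError(
                    f"bootstrap test of {term_label(t)} invalid: "
                    f"{res.n_failed}/{res.n_sim} refit failures")
            results.append((t, res))
        worst_term, worst = max(results, key=lambda tr: (tr[1].p_value, tr[0]))
        if worst.p_value > alpha:
            for t, r in results:
                trace.steps.append(ReductionStep(r.term, r.stat, r.n_sim, r.p_value,
                                                 "dropped" if t == worst_term else "retained"))
            current = current.drop(worst_term)
        else:
            for t, r in results:
                trace.steps.append(ReductionStep(r.term, r.stat, r.n_sim, r.p_value,
                                                 "retained"))
            break
    final = JumpOutcomeModel(current, data).fit()
    return current, trace, final


# ---------------------------------------------------------------------------
# effect estimates


def estimate_effects(results: JumpOutcomeResults, factors: Sequence[str],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Model-based means per combination of the named factors.

    Predictions are formed on the transformed (linear) scale for every cell of
    the 2x2x2 factor space restricted to the retained terms, averaged equally
    over the factors not named, given Wald intervals, and back-transformed to
    the response scale (probabilities for binomial fits). Both scales are
    reported; interval endpoints are swapped for the order-reversing inverse
    transformation.
    """
    spec = results.spec
    for f in factors:
        if f not in FACTORS:
            raise ValueError(f"unknown factor {f!r}")
        if not any(f in t for t in spec.fixed_terms):
            raise ValueError(f"factor {f!r} is not in the fitted model")
    beta = results.params.to_numpy()
    cov = results._raw.cov_beta
    crit = results._tcrit(alpha)

    cells = [
        {"distance": d, "angle": a, "hybrid": h}
        for d in FACTORS["distance"] for a in FACTORS["angle"] for h in FACTORS["hybrid"]
    ]

    def cell_row(cell: dict) -> np.ndarray:
        row = [1.0]
        for t in spec.fixed_terms:
            v = 1.0
            for f in t:
                v *= 1.0 if cell[f] == FACTORS[f][1] else 0.0
            row.append(v)
        return np.array(row)

    combos = [{}]
    for f in factors:
        combos = [dict(c, **{f: lev}) for c in combos for lev in FACTORS[f]]

    rows = []
    for combo in combos:
        match = [cell_row(c) for c in cells if all(c[f] == v for f, v in combo.items())]
        x = np.mean(match, axis=0)
        eta = float(x @ beta)
        se = math.sqrt(float(x @ cov @ x))
        lo_t, hi_t = eta - crit * se, eta + crit * se
        if spec.family == "binomial":
            mean = float(special.expit(eta))
            lo, hi = float(special.expit(lo_t)), float(special.expit(hi_t))
        else:
            mean = float(back_transform(eta, spec.transformation))
            lo, hi = back_transform_interval(lo_t, hi_t, spec.transformation)
            lo, hi = float(lo), float(hi)
        rows.append({**combo, "mean": mean, "lower": lo, "upper": hi,
                     "eta": eta, "eta_se": se, "eta_lower": lo_t, "eta_upper": hi_t})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulated quantile residuals


@dataclass
class QuantileResiduals:
    """DHARMa-style posterior-predictive quantile residuals."""

    quantiles: np.ndarray
    ks_stat: float
    ks_pvalue: float
    n_sim: int
    seed: int


def simulate_quantile_residuals(results: JumpOutcomeResults, n_sim: int = 250,
                                seed: int = 0) -> QuantileResiduals:
    """Per-observation quantile of the observed response within ``n_sim``
    simulations from the fitted model (new random effects each draw), with a
    uniform(0,1) Kolmogorov-Smirnov summary. Ties — which occur for the
    discrete binomial response — are broken by seeded uniform randomization.
    """
    rng = np.random.default_rng(seed)
    sims = results.simulate(rng, n_sim)  # (n_sim, n)
    obs = results.model.endog
    less = (sims < obs).sum(axis=0)
    equal = (sims == obs).sum(axis=0)
    u = rng.random(len(obs))
    q = (less + u * equal) / n_sim
    ks = stats.kstest(q, "uniform")
    return QuantileResiduals(quantiles=q, ks_stat=float(ks.statistic),
                             ks_pvalue=float(ks.pvalue), n_sim=n_sim, seed=seed)
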