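"""The mixed-model core against independent oracles.

Oracles: statsmodels OLS/GLM for the zero-variance limits, closed-form ANOVA
method-of-moments for a balanced one-way layout, and R's lme4 (via Rscript)
for the full nested + crossed likelihoods.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from keeljump._mixed import GLMMDesign, LMMDesign


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestGaussian:
    def test_zero_variance_matches_ols(self, rng):
        """No simulated group variance, balanced grouping: the ML mixed fit
        reproduces ordinary least squares."""
        n = 240
        g = np.repeat(np.arange(12), n // 12)
        x = np.tile(np.r_[np.zeros(10), np.ones(10)], 12)
        X = np.column_stack([np.ones(n), x])
        y = X @ [1.0, 0.5] + rng.normal(0, 1.2, n)
        fit = LMMDesign(X, {"g": g}).fit(y, reml=False)
        ols = sm.OLS(y, X).fit()
        assert np.abs(fit.beta - np.asarray(ols.params)).max() < 1e-4

    def test_balanced_one_way_matches_anova_moments(self, rng):
        """REML on a balanced one-way layout equals the ANOVA mean-squares
        estimator (exact in this balanced case)."""
        k, m = 20, 10
        groups = np.repeat(np.arange(k), m)
        y = 1.0 + rng.normal(0, 1.5, k)[groups] + rng.normal(0, 1.0, k * m)
        fit = LMMDesign(np.ones((k * m, 1)), {"g": groups}).fit(y, reml=True)
        ybar = np.array([y[groups == i].mean() for i in range(k)])
        msb = m * ((ybar - y.mean()) ** 2).sum() / (k - 1)
        msw = sum(((y[groups == i] - ybar[i]) ** 2).sum()
                  for i in range(k)) / (k * m - k)
        assert fit.sigma2 == pytest.approx(msw, rel=1e-5)
        assert fit.vcomp["g"] == pytest.approx((msb - msw) / m, rel=1e-5)

    def test_duplicating_rows_preserves_ml_point_estimates(self, rng):
        """In a balanced layout (where GLS reduces to OLS for the fixed part),
        duplicating every row leaves the ML fixed-effect estimates unchanged."""
        n = 120
        g = np.repeat(np.arange(12), 10)
        x = np.tile(np.r_[np.zeros(5), np.ones(5)], 12)
        X = np.column_stack([np.ones(n), x])
        y = X @ [1.0, 0.7] + rng.normal(0, 0.8, 12)[g] + rng.normal(0, 1, n)
        f1 = LMMDesign(X, {"g": g}).fit(y, reml=False)
        f2 = LMMDesign(np.vstack([X, X]), {"g": np.r_[g, g]}).fit(
            np.r_[y, y], reml=False)
        assert np.abs(f1.beta - f2.beta).max() < 1e-5

    def test_simulate_reproduces_variance_structure(self, rng):
        n, k = 400, 20
        g = np.repeat(np.arange(k), n // k)
        d = LMMDesign(np.ones((n, 1)), {"g": g})
        fit = d.fit(rng.normal(size=n))
        fit.vcomp["g"] = 4.0
        fit.sigma2 = 1.0
        fit.beta = np.array([0.0])
        sims = fit.simulate(np.random.default_rng(0), 400)
        total_var = sims.var(axis=1).mean()
        assert total_var == pytest.approx(5.0, rel=0.1)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(Exception, match="rank"):
            LMMDesign(X, {})


class TestBinomial:
    def test_zero_variance_matches_glm_logit(self, rng):
        n = 400
        g = np.repeat(np.arange(10), n // 10)
        x = np.tile(np.r_[np.zeros(20), np.ones(20)], 10)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ [0.3, 0.9])))).astype(float)
        fit = GLMMDesign(X, {"g": g}).fit(y)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(fit.beta - np.asarray(glm.params)).max() < 1e-3
        assert np.abs(fit.bse - np.asarray(glm.bse)).max() < 1e-3
        assert fit.llf == pytest.approx(glm.llf, abs=1e-3)

    def test_balanced_intercept_near_zero(self, rng):
        n = 200
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        fit = GLMMDesign(np.ones((n, 1)), {"g": np.arange(n) % 10}).fit(y)
        assert abs(fit.beta[0]) < 1e-3

    def test_separation_flagged(self):
        n = 60
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([np.ones(n), x])
        fit = GLMMDesign(X, {"g": np.arange(n) % 6}).fit(x.copy())
        assert fit.separation

    def test_distance_effect_ci_coverage(self):
        """A simulated within-group log-odds effect is covered by its Wald 95%
        CI in nearly all of 50 replicates."""
        n, k, beta = 320, 16, 1.0
        g = np.repeat(np.arange(k), n // k)
        x = np.tile(np.r_[np.zeros(n // k // 2), np.ones(n // k // 2)], k)
        X = np.column_stack([np.ones(n), x])
        design = GLMMDesign(X, {"g": g}, obs_level=True)
        covered = 0
        for rep in range(50):
            r = np.random.default_rng(100 + rep)
            eta = -0.4 + beta * x + r.normal(0, 0.7, k)[g]
            y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = design.fit(y)
            lo = fit.beta[1] - 1.96 * fit.bse[1]
            hi = fit.beta[1] + 1.96 * fit.bse[1]
            covered += lo <= beta <= hi
        assert covered >= 45  # >= 90% of 50


@pytest.fixture(scope="module")
def lme4_fits(tmp_path_factory):
    """Fit one nested + crossed dataset with our code and with lme4."""
    rng = np.random.default_rng(42)
    n_hen, n_per = 12, 8
    hen = np.repeat(np.arange(n_hen), n_per)
    pen = hen // 3
    date = np.tile(np.arange(4), n_hen * n_per // 4)
    x = rng.integers(0, 2, n_hen * n_per).astype(float)
    X = np.column_stack([np.ones(len(x)), x])
    y = (1.0 + 0.8 * x + rng.normal(0, 0.5, n_hen)[hen]
         + rng.normal(0, 0.3, 4)[pen] + rng.normal(0, 0.2, 4)[date]
         + rng.normal(0, 1.0, len(x)))
    yb = (rng.random(len(x)) <
          1 / (1 + np.exp(-(-0.5 + 1.0 * x + rng.normal(0, 0.8, n_hen)[hen])))
          ).astype(float)
    d = LMMDesign(X, {"pen": pen, "hen": hen, "date": date})
    ours = {
        "ml": d.fit(y, reml=False),
        "reml": d.fit(y, reml=True),
        "glmer": GLMMDesign(X, {"hen": hen}).fit(yb),
    }
    root = tmp_path_factory.mktemp("lme4")
    pd.DataFrame({"y": y, "yb": yb, "x": x, "hen": hen, "pen": pen,
                  "date": date}).to_csv(root / "d.csv", index=False)
    script = root / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{root}/d.csv')\n"
        "m <- lmer(y ~ x + (1|pen) + (1|hen) + (1|date), data=d, REML=FALSE)\n"
        "r <- lmer(y ~ x + (1|pen) + (1|hen) + (1|date), data=d, REML=TRUE)\n"
        "g <- glmer(yb ~ x + (1|hen), data=d, family=binomial)\n"
        "cat(logLik(m), fixef(m), logLik(r), fixef(r), logLik(g), fixef(g),"
        " sep='\\n')\n")
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    vals = [float(v) for v in out.stdout.split()]
    return ours, vals


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstLme4:
    """Dual-route check: our likelihoods vs lme4 on one small dataset."""

    def test_gaussian_ml_agrees(self, lme4_fits):
        ours, r = lme4_fits
        assert ours["ml"].llf == pytest.approx(r[0], abs=1e-4)
        assert ours["ml"].beta == pytest.approx(np.array(r[1:3]), abs=1e-4)

    def test_gaussian_reml_agrees(self, lme4_fits):
        ours, r = lme4_fits
        assert ours["reml"].llf == pytest.approx(r[3], abs=1e-4)
        assert ours["reml"].beta == pytest.approx(np.array(r[4:6]), abs=1e-4)

    def test_binomial_laplace_agrees(self, lme4_fits):
        ours, r = lme4_fits
        assert ours["glmer"].llf == pytest.approx(r[6], abs=1e-3)
        assert ours["glmer"].beta == pytest.approx(np.array(r[7:9]), abs=5e-3)
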