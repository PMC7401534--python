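"""Random-intercept mixed models: Gaussian (profiled ML/REML) and binomial
(Laplace approximation).

Both models share the structure

    y = X beta + sum_k Z_k b_k (+ eps),   b_k ~ N(0, sigma_k^2 I)

with every Z_k an indicator (one column per level of a grouping factor). The
Gaussian likelihood is profiled over beta and the residual variance, leaving
an optimization over the variance ratios gamma_k = sigma_k^2 / sigma_e^2
only; all linear algebra runs through a q x q Woodbury factorization
(q = total number of random levels), so refitting the same design on new
responses — the inner loop of a parametric bootstrap — is cheap.

The binomial-logit model is fitted by Laplace approximation: penalized IRLS
finds the joint mode of (beta, u) given the variance parameters, and the
Laplace-approximate log-likelihood is optimized over log sigma_k^2. An
optional observation-level intercept (one level per row) is handled by Schur
complement against its diagonal block so it costs O(n), not O(n^3).

This module is deliberately self-contained and oblivious to the study; the
study-facing model classes live in :mod:`keeljump.inference`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special

__all__ = ["LMMDesign", "LMMFit", "GLMMDesign", "GLMMFit", "FitError"]

_LOG2PI = np.log(2.0 * np.pi)
_GAMMA_FLOOR = 1e-10  # variance ratios below this are reported as zero
_SINGULAR_TOL = 1e-6


class FitError(RuntimeError):
    """A model fit failed outright (not merely flagged non-converged)."""


def _codes(factor) -> tuple[np.ndarray, int]:
    """Integer codes 0..q-1 for a grouping factor, numbered by first appearance.

    First-appearance order (rather than sorted labels) makes every downstream
    seeded simulation invariant to relabeling of the factor levels."""
    vals, first, codes = np.unique(np.asarray(factor), return_index=True,
                                   return_inverse=True)
    rank = np.empty(len(vals), dtype=np.intp)
    rank[np.argsort(first, kind="stable")] = np.arange(len(vals))
    return rank[codes.ravel()].astype(np.intp), len(vals)


@dataclass
class LMMFit:
    """Fitted Gaussian random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    beta_names: list[str]
    sigma2: float
    vcomp: dict[str, float]  # per-factor variance components sigma_k^2
    llf: float
    reml: bool
    converged: bool
    singular: bool
    n: int
    rank: int
    _design: "LMMDesign" = field(repr=False, default=None)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    def simulate(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw response vectors from the fitted model (new random effects
        and residuals every draw). Shape (size, n)."""
        d = self._design
        mean = d.X @ self.beta
        out = np.tile(mean, (size, 1))
        for name, codes, q in d.factors:
            sd = np.sqrt(max(self.vcomp[name], 0.0))
            if sd > 0:
                b = rng.normal(0.0, sd, size=(size, q))
                out += b[:, codes]
        out += rng.normal(0.0, np.sqrt(self.sigma2), size=(size, d.n))
        return out


class LMMDesign:
    """Immutable design (X + grouping factors) with precomputed cross-products.

    ``fit(y)`` may be called many times with different responses; everything
    that depends only on the design is computed once here.
    """

    def __init__(self, X: np.ndarray, factors: dict, beta_names: list[str] | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.X = X
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise FitError("fixed-effect design matrix is rank deficient")
        self.beta_names = beta_names or [f"x{j}" for j in range(self.p)]
        self.factors: list[tuple[str, np.ndarray, int]] = []
        for name, fac in factors.items():
            codes, q = _codes(fac)
            if len(codes) != self.n:
                raise ValueError(f"factor {name!r} has length {len(codes)}, expected {self.n}")
            self.factors.append((name, codes, q))
        self.K = len(self.factors)
        self.q_total = sum(q for _, _, q in self.factors)
        # column slice of each factor inside the stacked Z
        self._slices = []
        off = 0
        for _, _, q in self.factors:
            self._slices.append(slice(off, off + q))
            off += q

        # stacked sparse-free cross products
        self.XtX = X.T @ X
        if self.K:
            ZtX = np.zeros((self.q_total, self.p))
            ZtZ = np.zeros((self.q_total, self.q_total))
            for (_, ci, qi), si in zip(self.factors, self._slices):
                np.add.at(ZtX[si], ci, X)
            for a, ((_, ca, qa), sa) in enumerate(zip(self.factors, self._slices)):
                for b, ((_, cb, qb), sb) in enumerate(zip(self.factors, self._slices)):
                    if b < a:
                        continue
                    blk = np.zeros((qa, qb))
                    np.add.at(blk, (ca, cb), 1.0)
                    ZtZ[sa, sb] = blk
                    if b != a:
                        ZtZ[sb, sa] = blk.T
            self.ZtX = ZtX
            self.ZtZ = ZtZ

    def _zty(self, y: np.ndarray) -> np.ndarray:
        zty = np.zeros(self.q_total)
        for (_, ci, qi), si in zip(self.factors, self._slices):
            np.add.at(zty[si], ci, y)
        return zty

    def _gamma_cols(self, gamma: np.ndarray) -> np.ndarray:
        s = np.empty(self.q_total)
        for g, si in zip(gamma, self._slices):
            s[si] = g
        return s

    def _profile(self, gamma: np.ndarray, y: np.ndarray, zty: np.ndarray,
                 xty: np.ndarray, yty: float, reml: bool, grad: bool = False):
        """Profiled -2 log-likelihood at variance ratios gamma, plus byproducts.

        With ``grad=True`` also returns the analytic gradient with respect to
        gamma (envelope theorem: beta and sigma^2 are at their optima, so only
        the explicit dependence on V matters)."""
        n, p = self.n, self.p
        if self.K:
            s = np.sqrt(self._gamma_cols(gamma))
            M = self.ZtZ * np.outer(s, s)
            M[np.diag_indices_from(M)] += 1.0
            cM, _ = linalg.cho_factor(M, lower=True, check_finite=False)
            WX = linalg.solve_triangular(cM, s[:, None] * self.ZtX, lower=True,
                                         check_finite=False)
            wy = linalg.solve_triangular(cM, s * zty, lower=True, check_finite=False)
            XtVX = self.XtX - WX.T @ WX
            XtVy = xty - WX.T @ wy
            yVy = yty - wy @ wy
            logdetV = 2.0 * np.sum(np.log(np.diag(cM)))
        else:
            XtVX, XtVy, yVy, logdetV = self.XtX, xty, yty, 0.0
        cX = linalg.cho_factor(XtVX, lower=True, check_finite=False)
        beta = linalg.cho_solve(cX, XtVy, check_finite=False)
        rss = max(yVy - XtVy @ beta, 1e-300)
        logdetXtVX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        if reml:
            dof = n - p
            sigma2 = rss / dof
            dev = dof * (_LOG2PI + np.log(sigma2)) + logdetV + logdetXtVX + dof
        else:
            sigma2 = rss / n
            dev = n * (_LOG2PI + np.log(sigma2)) + logdetV + n
        if not grad:
            return dev, beta, sigma2, XtVX
        # gradient wrt gamma_k: tr(Zk' V^-1 Zk) - |Zk' V^-1 r|^2 / sigma2
        # (+ REML term -tr[(X'V^-1X)^-1 X'V^-1 Zk Zk' V^-1 X])
        U = linalg.solve_triangular(cM, s[:, None] * self.ZtZ, lower=True,
                                    check_finite=False)
        ZVZ_diag = np.diag(self.ZtZ) - np.einsum("ij,ij->j", U, U)
        t1 = linalg.solve_triangular(cM.T, wy, lower=False, check_finite=False)
        ZVy = zty - (self.ZtZ * s[None, :]) @ t1
        TX = linalg.solve_triangular(cM.T, WX, lower=False, check_finite=False)
        ZVX = self.ZtX - (self.ZtZ * s[None, :]) @ TX
        ZVr = ZVy - ZVX @ beta
        g = np.empty(self.K)
        if reml:
            XtVXinv_ZVX = linalg.cho_solve(cX, ZVX.T, check_finite=False)  # p x q
        for k, sk in enumerate(self._slices):
            gk = np.sum(ZVZ_diag[sk]) - float(ZVr[sk] @ ZVr[sk]) / sigma2
            if reml:
                gk -= np.einsum("ij,ji->", ZVX[sk], XtVXinv_ZVX[:, sk])
            g[k] = gk
        return dev, beta, sigma2, XtVX, g

    def fit(self, y: np.ndarray, reml: bool = False) -> LMMFit:
        """Fit by ML (default) or REML; variance ratios optimized on log scale."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"response has shape {y.shape}, expected ({self.n},)")
        zty = self._zty(y) if self.K else None
        xty = self.X.T @ y
        yty = float(y @ y)

        def obj(theta):
            try:
                dev, *_ = self._profile(np.exp(theta), y, zty, xty, yty, reml)
            except linalg.LinAlgError:
                return np.inf
            return dev

        converged = True
        if self.K == 0:
            gamma = np.empty(0)
        elif self.K == 1:
            res = optimize.minimize_scalar(lambda t: obj(np.array([t])),
                                           bounds=(np.log(_GAMMA_FLOOR), 12.0),
                                           method="bounded",
                                           options={"xatol": 1e-6})
            gamma = np.exp([res.x])
            converged = bool(res.success)
        else:
            def obj_grad(theta):
                g_ = np.exp(theta)
                try:
                    out = self._profile(g_, y, zty, xty, yty, reml, grad=True)
                except linalg.LinAlgError:
                    return np.inf, np.zeros_like(theta)
                return out[0], out[4] * g_  # chain rule for theta = log gamma

            bounds = [(np.log(_GAMMA_FLOOR), 12.0)] * self.K
            best = None
            for start in (np.full(self.K, np.log(0.5)), np.full(self.K, -4.0)):
                res = optimize.minimize(obj_grad, start, jac=True,
                                        method="L-BFGS-B", bounds=bounds,
                                        options={"ftol": 1e-12, "gtol": 1e-7,
                                                 "maxiter": 200})
                if best is None or res.fun < best.fun:
                    best = res
            if not best.success:  # fall back to a derivative-free polish
                res = optimize.minimize(obj, best.x, method="Nelder-Mead",
                                        options={"xatol": 1e-6, "fatol": 1e-9,
                                                 "maxiter": 400 * self.K})
                if res.fun <= best.fun:
                    best = res
            gamma = np.minimum(np.exp(best.x), 1e12)
            converged = bool(best.success)

        dev, beta, sigma2, XtVX = self._profile(gamma, y, zty, xty, yty, reml)
        gamma = np.where(gamma < _SINGULAR_TOL, 0.0, gamma)
        cov_beta = sigma2 * linalg.inv(XtVX)
        vcomp = {name: float(g * sigma2) for (name, _, _), g in zip(self.factors, gamma)}
        return LMMFit(
            beta=beta,
            cov_beta=cov_beta,
            beta_names=list(self.beta_names),
            sigma2=float(sigma2),
            vcomp=vcomp,
            llf=-0.5 * float(dev),
            reml=reml,
            converged=converged,
            singular=bool(np.any(gamma == 0.0)),
            n=self.n,
            rank=self.p,
            _design=self,
        )


# ---------------------------------------------------------------------------
# binomial-logit GLMM, Laplace approximation


@dataclass
class GLMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    beta_names: list[str]
    vcomp: dict[str, float]
    llf: float
    converged: bool
    singular: bool
    separation: bool
    n: int
    rank: int
    _design: "GLMMDesign" = field(repr=False, default=None)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    @property
    def sigma2(self) -> float:  # parity with LMMFit; Bernoulli has no scale
        return 1.0

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    def simulate(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        d = self._design
        eta = np.tile(d.X @ self.beta, (size, 1))
        for name, codes, q in d.factors:
            sd = np.sqrt(max(self.vcomp[name], 0.0))
            if sd > 0:
                eta += rng.normal(0.0, sd, size=(size, q))[:, codes]
        if d.obs_level:
            sd = np.sqrt(max(self.vcomp["_obs"], 0.0))
            if sd > 0:
                eta += rng.normal(0.0, sd, size=(size, d.n))
        return (rng.random((size, d.n)) < special.expit(eta)).astype(float)


class GLMMDesign:
    """Binomial-logit design with grouping factors and optional per-row level."""

    def __init__(self, X, factors: dict, beta_names=None, obs_level: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.X = X
        self.n, self.p = X.shape
        self.beta_names = beta_names or [f"x{j}" for j in range(self.p)]
        self.obs_level = obs_level
        self.factors = []
        for name, fac in factors.items():
            codes, q = _codes(fac)
            self.factors.append((name, codes, q))
        self.K = len(self.factors)
        self.q_small = sum(q for _, _, q in self.factors)
        self._slices = []
        off = 0
        for _, _, q in self.factors:
            self._slices.append(slice(off, off + q))
            off += q

    # -- helpers over the small random-effect block ---------------------
    def _Zu(self, u: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        for (_, ci, _), si in zip(self.factors, self._slices):
            out += u[si][ci]
        return out

    def _Zt(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros(self.q_small)
        for (_, ci, _), si in zip(self.factors, self._slices):
            np.add.at(out[si], ci, v)
        return out

    def _ZtWZ(self, w: np.ndarray) -> np.ndarray:
        M = np.zeros((self.q_small, self.q_small))
        for a, ((_, ca, qa), sa) in enumerate(zip(self.factors, self._slices)):
            for b, ((_, cb, qb), sb) in enumerate(zip(self.factors, self._slices)):
                if b < a:
                    continue
                blk = np.zeros((qa, qb))
                np.add.at(blk, (ca, cb), w)
                M[sa, sb] = blk
                if b != a:
                    M[sb, sa] = blk.T
        return M

    def _ZtW_X(self, w: np.ndarray) -> np.ndarray:
        out = np.zeros((self.q_small, self.p))
        for (_, ci, _), si in zip(self.factors, self._slices):
            np.add.at(out[si], ci, self.X * w[:, None])
        return out

    def _pirls(self, sig2: np.ndarray, sig2_obs: float, y: np.ndarray,
               maxiter: int = 80, tol: float = 1e-9):
        """Joint penalized-likelihood mode over (beta, u_small, u_obs)."""
        n, p, qs = self.n, self.p, self.q_small
        beta = np.zeros(p)
        # start intercept-ish: empirical logit if an all-ones column exists
        u = np.zeros(qs)
        v = np.zeros(n) if self.obs_level else None
        inv_small = np.empty(qs)
        for s2, si in zip(sig2, self._slices):
            inv_small[si] = 1.0 / max(s2, _GAMMA_FLOOR)

        def pen_ll(beta, u, v):
            eta = self.X @ beta + self._Zu(u)
            if v is not None:
                eta = eta + v
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            ll -= 0.5 * float(u @ (inv_small * u))
            if v is not None:
                ll -= 0.5 * float(v @ v) / max(sig2_obs, _GAMMA_FLOOR)
            return ll, eta

        ll_old, eta = pen_ll(beta, u, v)
        for _ in range(maxiter):
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            r = y - mu
            gb = self.X.T @ r
            gu = self._Zt(r) - inv_small * u
            if self.obs_level:
                d = w + 1.0 / max(sig2_obs, _GAMMA_FLOOR)
                gv = r - v / max(sig2_obs, _GAMMA_FLOOR)
                # Schur complement of the diagonal obs block
                Wd = w * w / d
                XtWX = self.X.T @ ((w - Wd)[:, None] * self.X)
                ZtWZ = self._ZtWZ(w - Wd)
                ZtWX = self._ZtW_X(w - Wd)
                H = np.block([[XtWX, ZtWX.T], [ZtWX, ZtWZ]])
                H[p:, p:][np.diag_indices(qs)] += inv_small
                rhs = np.concatenate([
                    gb - self.X.T @ (w / d * gv),
                    gu - self._Zt(w / d * gv),
                ])
            else:
                XtWX = self.X.T @ (w[:, None] * self.X)
                ZtWZ = self._ZtWZ(w)
                ZtWX = self._ZtW_X(w)
                H = np.block([[XtWX, ZtWX.T], [ZtWX, ZtWZ]])
                H[p:, p:][np.diag_indices(qs)] += inv_small
                rhs = np.concatenate([gb, gu])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    step = linalg.solve(H, rhs, assume_a="pos", check_finite=False)
            except linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = linalg.solve(H, rhs, check_finite=False)
            if self.obs_level:
                dv = (gv - w * (self.X @ step[:p] + self._Zu(step[p:]))) / d
            # step halving on the penalized likelihood
            t = 1.0
            for _ in range(30):
                nb = beta + t * step[:p]
                nu = u + t * step[p:]
                nv = v + t * dv if self.obs_level else None
                ll_new, eta_new = pen_ll(nb, nu, nv)
                if ll_new >= ll_old - 1e-12:
                    break
                t *= 0.5
            beta, u = nb, nu
            if self.obs_level:
                v = nv
            gained = ll_new - ll_old
            ll_old, eta = ll_new, eta_new
            if abs(gained) < tol:
                return beta, u, v, eta, True
        return beta, u, v, eta, False

    def _laplace_dev(self, log_s2: np.ndarray, y: np.ndarray):
        Ks = self.K
        sig2 = np.exp(log_s2[:Ks])
        sig2_obs = float(np.exp(log_s2[Ks])) if self.obs_level else 0.0
        beta, u, v, eta, ok = self._pirls(sig2, sig2_obs, y)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        inv_small = np.empty(self.q_small)
        s2_cols = np.empty(self.q_small)
        for s2, si in zip(sig2, self._slices):
            inv_small[si] = 1.0 / max(s2, _GAMMA_FLOOR)
            s2_cols[si] = s2
        ll -= 0.5 * float(u @ (inv_small * u))
        # log det(Sigma^1/2 Z'WZ Sigma^1/2 + I), obs block eliminated by Schur
        if self.obs_level:
            ll -= 0.5 * float(v @ v) / max(sig2_obs, _GAMMA_FLOOR)
            d_oo = sig2_obs * w + 1.0
            frac = sig2_obs * w * w / d_oo
            B = self._ZtWZ(w - frac) * np.sqrt(np.outer(s2_cols, s2_cols))
            B[np.diag_indices_from(B)] += 1.0
            sign, ld_small = np.linalg.slogdet(B)
            logdet = float(np.sum(np.log(d_oo))) + ld_small
        else:
            B = self._ZtWZ(w) * np.sqrt(np.outer(s2_cols, s2_cols))
            B[np.diag_indices_from(B)] += 1.0
            sign, logdet = np.linalg.slogdet(B)
        ll -= 0.5 * logdet
        return -2.0 * ll, beta, u, v, eta, w, ok

    def fit(self, y: np.ndarray) -> GLMMFit:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"response has shape {y.shape}, expected ({self.n},)")
        ntheta = self.K + (1 if self.obs_level else 0)

        def obj(theta):
            try:
                return self._laplace_dev(theta, y)[0]
            except (linalg.LinAlgError, FloatingPointError):
                return np.inf

        converged = True
        if ntheta == 0:
            theta = np.empty(0)
        elif ntheta == 1:
            res = optimize.minimize_scalar(lambda t: obj(np.array([t])),
                                           bounds=(np.log(_GAMMA_FLOOR), 8.0),
                                           method="bounded",
                                           options={"xatol": 1e-6})
            theta = np.array([res.x])
            converged = bool(res.success)
        else:
            res = optimize.minimize(obj, np.full(ntheta, np.log(0.25)),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-6,
                                             "maxiter": 300 * ntheta})
            theta = res.x
            converged = bool(res.success)

        dev, beta, u, v, eta, w, inner_ok = self._laplace_dev(theta, y)
        converged = converged and inner_ok
        separation = bool(np.max(np.abs(eta)) > 15.0)
        sig2 = np.exp(theta)
        sig2 = np.where(sig2 < _SINGULAR_TOL, 0.0, sig2)
        vcomp = {name: float(s2) for (name, _, _), s2 in zip(self.factors, sig2)}
        if self.obs_level:
            vcomp["_obs"] = float(sig2[self.K])

        # cov(beta): inverse of the Hessian block for beta after eliminating u
        inv_small = np.empty(self.q_small)
        for s2, si in zip(np.maximum(np.exp(theta[: self.K]), _GAMMA_FLOOR), self._slices):
            inv_small[si] = 1.0 / s2
        if self.obs_level:
            d = w + 1.0 / max(np.exp(theta[self.K]), _GAMMA_FLOOR)
            weff = w - w * w / d
        else:
            weff = w
        XtWX = self.X.T @ (weff[:, None] * self.X)
        if self.q_small:
            ZtWZ = self._ZtWZ(weff)
            ZtWZ[np.diag_indices_from(ZtWZ)] += inv_small
            ZtWX = self._ZtW_X(weff)
            try:
                S = XtWX - ZtWX.T @ linalg.solve(ZtWZ, ZtWX, assume_a="pos",
                                                 check_finite=False)
            except linalg.LinAlgError:
                S = XtWX
        else:
            S = XtWX
        try:
            cov_beta = linalg.inv(S)
        except linalg.LinAlgError:
            cov_beta = np.full((self.p, self.p), np.nan)
            converged = False

        return GLMMFit(
            beta=beta,
            cov_beta=cov_beta,
            beta_names=list(self.beta_names),
            vcomp=vcomp,
            llf=-0.5 * float(dev),
            converged=converged,
            singular=bool(np.any(sig2 == 0.0)),
            separation=separation,
            n=self.n,
            rank=self.p,
            _design=self,
        )
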