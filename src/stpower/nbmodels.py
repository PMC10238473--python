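"""Count models for group-difference testing on ROI data.

Implements

* TMM (trimmed mean of M-values) effective library sizes, used as the
  natural-log offset of every count model;
* a negative-binomial GLM with log link and maximum-likelihood dispersion
  (theta profiled out), used for paired pseudobulk fold changes and as the
  boundary (sigma = 0) reference of the mixed model;
* a negative-binomial GLMM with one Gaussian patient random intercept,
  ``count ~ offset(log effective library size) + group + (1|patient)``,
  fitted by maximizing the marginal likelihood with adaptive Gauss-Hermite
  quadrature (mode-centred, Hessian-scaled nodes);
* Wald and likelihood-ratio tests of the group fixed effect, and a dense
  trapezoid-grid likelihood oracle used to validate the quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

LN2 = np.log(2.0)

_LOG_THETA_BOUNDS = (-7.0, 15.0)
_LOG_SIGMA_FLOOR = -10.0  # sigma below exp(-10) is treated as 0


# ---------------------------------------------------------------------------
# TMM effective library sizes


@dataclass
class EffectiveLibSizes:
    raw_libsize: np.ndarray
    tmm_factor: np.ndarray
    effective: np.ndarray
    reference_index: int


def tmm_effective_libsize(
    counts: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05
) -> EffectiveLibSizes:
    """Trimmed-mean-of-M-values normalization factors and effective sizes.

    The reference column is the one whose upper-quartile/library-size ratio
    is closest to the mean such ratio.  For each column, M-values (log2
    expression ratios to the reference) are trimmed by ``trim_m`` on M and
    ``trim_a`` on average log expression A, then averaged with
    inverse-asymptotic-variance weights.  Factors are rescaled so their
    geometric mean is 1; effective size = raw library size x factor.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x columns matrix with >= 2 columns")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every column must have a nonzero library size")

    q75 = np.quantile(counts, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    nR = lib[ref]
    yR = counts[:, ref]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yj = counts[:, j]
        nj = lib[j]
        pos = (yj > 0) & (yR > 0)
        if not pos.any():
            warnings.warn(f"column {j} shares no expressed genes with the "
                          "reference; TMM factor set to 1")
            continue
        o, r = yj[pos], yR[pos]
        M = np.log2((o / nj) / (r / nR))
        A = 0.5 * np.log2((o / nj) * (r / nR))
        v = (nj - o) / (nj * o) + (nR - r) / (nR * r)
        n = M.size
        # rank-window trimming as in the standard TMM recipe
        loM = np.floor(n * trim_m) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_a) + 1
        hiA = n + 1 - loA
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any() or np.sum(1.0 / v[keep]) == 0:
            warnings.warn(f"column {j}: no genes survive TMM trimming; "
                          "factor set to 1")
            continue
        f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
        if not np.isfinite(f):
            f = 0.0
        log_factors[j] = f

    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return EffectiveLibSizes(
        raw_libsize=lib, tmm_factor=factors, effective=lib * factors,
        reference_index=ref,
    )


# ---------------------------------------------------------------------------
# NB log-likelihood primitives


def _nb_loglik(y, mu, theta):
    """Elementwise NB log-pmf with mean mu and size theta."""
    return (
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def nb_loglik_total(y, mu, theta) -> float:
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-12)
    return float(_nb_loglik(y, mu, theta).sum())


# ---------------------------------------------------------------------------
# NB GLM with profiled dispersion


@dataclass
class NBGLMFit:
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    theta: float
    loglik: float
    converged: bool
    n_iter: int


def _irls(y, X, offset, theta, beta0=None, max_iter=100, tol=1e-10):
    """IRLS for an NB GLM with log link at fixed theta."""
    n, p = X.shape
    if beta0 is None:
        z0 = np.log(y + 0.5) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    else:
        beta = beta0.copy()
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        w = mu * theta / (theta + mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        # step-halving if the likelihood decreases
        for _ in range(12):
            cand = beta + step
            ll = nb_loglik_total(y, np.exp(np.clip(X @ cand + offset, -30, 30)), theta)
            if ll >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return beta, ll_old, converged, it


def fit_nb_glm(
    y,
    X,
    offset=None,
    theta: Optional[float] = None,
    max_iter: int = 100,
) -> NBGLMFit:
    """ML fit of an NB GLM with log link.

    The dispersion (NB size theta) is profiled out by 1-D optimization over
    log theta unless a fixed ``theta`` is supplied; Wald SEs come from the
    observed information at the optimum.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, float)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if np.all(y == 0):
        raise ValueError("all counts are zero; NB GLM is undefined")

    cache = {}

    def prof_nll(log_theta):
        th = np.exp(log_theta)
        beta, ll, conv, it = _irls(y, X, offset, th, max_iter=max_iter)
        cache[log_theta] = (beta, ll, conv, it)
        return -ll

    if theta is None:
        res = optimize.minimize_scalar(
            prof_nll, bounds=_LOG_THETA_BOUNDS, method="bounded",
            options={"xatol": 1e-6},
        )
        log_theta = float(res.x)
    else:
        log_theta = float(np.log(theta))
    if log_theta not in cache:
        prof_nll(log_theta)
    beta, ll, conv, it = cache[log_theta]
    th = np.exp(log_theta)

    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w_obs = mu * th * (th + y) / (th + mu) ** 2
    info = X.T @ (X * w_obs[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.diag(cov))
    return NBGLMFit(coef=beta, se=se, cov=cov, theta=th, loglik=ll,
                    converged=bool(conv), n_iter=it)


# ---------------------------------------------------------------------------
# NB GLMM with patient random intercept (adaptive Gauss-Hermite quadrature)


@dataclass
class NBGLMMFit:
    beta0: float
    beta_group: Optional[float]  # None for the null (no-group) model
    se_group: Optional[float]
    sigma_b: float
    theta: float
    loglik: float
    converged: bool
    n_iter: int
    n_quadrature: int

    @property
    def lfc(self) -> Optional[float]:
        return None if self.beta_group is None else self.beta_group / LN2


def _prepare_grouping(patient):
    """Sort order and reduceat boundaries for per-patient sums."""
    codes, _ = pd.factorize(np.asarray(patient))
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) > 0])
    return order, sorted_codes, starts


class _GLMMWork:
    """Pre-sorted data and scratch for marginal-likelihood evaluations."""

    def __init__(self, y, group, patient, offset, n_quadrature):
        y = np.asarray(y, float)
        offset = np.asarray(offset, float)
        order, codes, starts = _prepare_grouping(patient)
        self.y = y[order]
        self.offset = offset[order]
        self.group = None if group is None else np.asarray(group, float)[order]
        self.codes = codes
        self.starts = starts
        self.n_patients = starts.size
        z, w = np.polynomial.hermite.hermgauss(n_quadrature)
        self.z = z
        self.logw = np.log(w)
        self.K = n_quadrature

    def eta_fixed(self, beta0, beta_group):
        eta = self.offset + beta0
        if self.group is not None and beta_group is not None:
            eta = eta + beta_group * self.group
        return eta

    def _conditional_modes(self, eta, theta, sigma2):
        """Vectorized Newton for the per-patient posterior modes of b."""
        b = np.zeros(self.n_patients)
        for _ in range(50):
            mu = np.exp(np.clip(eta + b[self.codes], -30, 30))
            g_terms = (self.y - mu) * theta / (theta + mu)
            grad = np.add.reduceat(g_terms, self.starts) - b / sigma2
            h_terms = mu * theta * (theta + self.y) / (theta + mu) ** 2
            hess = -np.add.reduceat(h_terms, self.starts) - 1.0 / sigma2
            step = -grad / hess
            step = np.clip(step, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = np.exp(np.clip(eta + b[self.codes], -30, 30))
        h_terms = mu * theta * (theta + self.y) / (theta + mu) ** 2
        hess = -np.add.reduceat(h_terms, self.starts) - 1.0 / sigma2
        return b, hess

    def marginal_loglik(self, beta0, beta_group, theta, sigma):
        """AGQ approximation of the marginal log-likelihood."""
        sigma2 = sigma * sigma
        eta = self.eta_fixed(beta0, beta_group)
        b_hat, hess = self._conditional_modes(eta, theta, sigma2)
        s = 1.0 / np.sqrt(-hess)  # (J,)
        nodes = b_hat[:, None] + np.sqrt(2.0) * s[:, None] * self.z[None, :]  # J x K
        mu = np.exp(np.clip(eta[:, None] + nodes[self.codes, :], -30, 30))  # N x K
        ll_terms = _nb_loglik(self.y[:, None], mu, theta)
        h = np.add.reduceat(ll_terms, self.starts, axis=0)  # J x K
        h += (
            -0.5 * nodes**2 / sigma2
            - 0.5 * np.log(2 * np.pi * sigma2)
        )
        per_patient = (
            0.5 * np.log(2.0) + np.log(s)
            + logsumexp(self.logw[None, :] + self.z[None, :] ** 2 + h, axis=1)
        )
        return float(per_patient.sum())


def fit_nb_glmm(
    y,
    group,
    patient,
    offset,
    n_quadrature: int = 15,
    max_iter: int = 200,
    sigma: Optional[float] = None,
) -> NBGLMMFit:
    """Fit the NB mixed model by maximizing the AGQ marginal likelihood.

    ``group`` may be None for the null (intercept-only) model.  ``sigma``
    pins the random-intercept SD (``sigma=0`` reduces exactly to the GLM).
    When the free fit drives sigma to its lower boundary the model is
    refitted as a GLM and reported with ``sigma_b = 0``.
    """
    y = np.asarray(y, float)
    has_group = group is not None
    X = (
        np.column_stack([np.ones(y.size), np.asarray(group, float)])
        if has_group
        else np.ones((y.size, 1))
    )

    if sigma is not None and sigma == 0:
        glm = fit_nb_glm(y, X, offset=offset)
        return NBGLMMFit(
            beta0=glm.coef[0],
            beta_group=glm.coef[1] if has_group else None,
            se_group=glm.se[1] if has_group else None,
            sigma_b=0.0, theta=glm.theta, loglik=glm.loglik,
            converged=glm.converged, n_iter=glm.n_iter,
            n_quadrature=n_quadrature,
        )

    glm = fit_nb_glm(y, X, offset=offset)
    work = _GLMMWork(y, group if has_group else None, patient, offset, n_quadrature)

    fixed_sigma = sigma is not None

    def unpack(params):
        if has_group:
            b0, b1 = params[0], params[1]
            rest = params[2:]
        else:
            b0, b1 = params[0], None
            rest = params[1:]
        theta = np.exp(rest[0])
        sig = sigma if fixed_sigma else np.exp(rest[1])
        return b0, b1, theta, sig

    def nll(params):
        b0, b1, theta, sig = unpack(params)
        try:
            return -work.marginal_loglik(b0, b1, theta, sig)
        except FloatingPointError:
            return 1e12

    p0 = [glm.coef[0]] + ([glm.coef[1]] if has_group else [])
    p0 += [np.log(glm.theta)]
    if not fixed_sigma:
        p0 += [np.log(0.3)]
    p0 = np.asarray(p0, float)

    bounds = [(None, None)] * (2 if has_group else 1)
    bounds += [list(_LOG_THETA_BOUNDS)]
    if not fixed_sigma:
        bounds += [(_LOG_SIGMA_FLOOR, 3.0)]

    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(
            nll, p0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
        )
    b0, b1, theta, sig = unpack(res.x)

    at_floor = (not fixed_sigma) and np.log(max(sig, 1e-300)) <= _LOG_SIGMA_FLOOR + 1e-6
    if at_floor or (fixed_sigma and sigma <= np.exp(_LOG_SIGMA_FLOOR)):
        # boundary: the random intercept vanishes; report the exact GLM fit
        return NBGLMMFit(
            beta0=glm.coef[0],
            beta_group=glm.coef[1] if has_group else None,
            se_group=glm.se[1] if has_group else None,
            sigma_b=0.0, theta=glm.theta, loglik=glm.loglik,
            converged=glm.converged and bool(res.success),
            n_iter=int(res.nit), n_quadrature=n_quadrature,
        )

    se_group = None
    if has_group:
        # SE of the group effect from the fixed-effects block of the observed
        # information at the variance-parameter estimates (lme4 convention)
        def nll_beta(beta):
            return -work.marginal_loglik(beta[0], beta[1], theta, sig)

        hess = _numeric_hessian(nll_beta, np.array([b0, b1]))
        try:
            cov = np.linalg.inv(hess)
            se_group = float(np.sqrt(cov[1, 1]))
        except (np.linalg.LinAlgError, ValueError):
            se_group = np.nan

    return NBGLMMFit(
        beta0=float(b0),
        beta_group=None if b1 is None else float(b1),
        se_group=se_group,
        sigma_b=float(sig), theta=float(theta),
        loglik=float(-res.fun), converged=bool(res.success),
        n_iter=int(res.nit), n_quadrature=n_quadrature,
    )


def _numeric_hessian(f, x, h=1e-4):
    """Central-difference Hessian of a scalar function."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


# ---------------------------------------------------------------------------
# tests


@dataclass
class TestResult:
    method: str
    lfc: float
    p: float
    converged: bool
    fit: Optional[NBGLMMFit] = None


def wald_test(fit: NBGLMMFit) -> TestResult:
    """Two-sided Wald test of the group fixed effect."""
    if fit.beta_group is None:
        raise ValueError("fit has no group effect to test")
    if not fit.converged or fit.se_group is None or not np.isfinite(fit.se_group):
        return TestResult("wald_glmm", fit.lfc if fit.beta_group is not None else np.nan,
                          np.nan, False, fit)
    z = fit.beta_group / fit.se_group
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult("wald_glmm", fit.lfc, float(p), True, fit)


def lrt_test(y, group, patient, offset, n_quadrature: int = 15) -> TestResult:
    """Likelihood-ratio test: full (group + random intercept) vs null
    (random intercept only), chi-square with 1 df."""
    full = fit_nb_glmm(y, group, patient, offset, n_quadrature=n_quadrature)
    null = fit_nb_glmm(y, None, patient, offset, n_quadrature=n_quadrature)
    converged = full.converged and null.converged
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < 0:
        if stat > -1e-6:
            stat = 0.0
        else:
            converged = False
    p = float(stats.chi2.sf(stat, df=1)) if converged else np.nan
    return TestResult("lrt_glmm", full.lfc, p, converged, full)


def marginal_loglik_oracle(
    beta0, beta_group, theta, sigma, y, group, patient, offset,
    grid_halfwidth: float = 8.0, grid_points: int = 2001,
) -> float:
    """Brute-force marginal log-likelihood by trapezoid integration over the
    random intercept on a dense grid of half-width ``grid_halfwidth`` x sigma.
    Independent of the quadrature path; used only for validation."""
    if sigma <= 0:
        raise ValueError("oracle requires sigma > 0")
    y = np.asarray(y, float)
    offset = np.asarray(offset, float)
    order, codes, starts = _prepare_grouping(patient)
    y = y[order]
    offset = offset[order]
    eta = offset + beta0
    if group is not None and beta_group is not None:
        eta = eta + beta_group * np.asarray(group, float)[order]

    b = np.linspace(-grid_halfwidth * sigma, grid_halfwidth * sigma, grid_points)
    db = b[1] - b[0]
    mu = np.exp(np.clip(eta[:, None] + b[None, :], -30, 30))
    ll = _nb_loglik(y[:, None], mu, theta)
    h = np.add.reduceat(ll, starts, axis=0)  # J x B
    h += stats.norm.logpdf(b, scale=sigma)[None, :]
    # log-trapezoid: endpoints weighted 1/2
    logw = np.full(grid_points, np.log(db))
    logw[0] += np.log(0.5)
    logw[-1] += np.log(0.5)
    return float(logsumexp(h + logw[None, :], axis=1).sum())
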