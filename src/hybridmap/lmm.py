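"""Restricted maximum likelihood machinery for linear mixed models.

Model: y = X beta + sum_k u_k + e with u_k ~ N(0, sigma2_k K_k) for each
random term (a dense PSD kernel, or Z Z' from a grouping factor) and
e ~ N(0, sigma2_e I).

The restricted log-likelihood is, up to the stated constant,

    l_R = -1/2 [ q log 2pi + log|V| + log|X' V^-1 X| - log|X' X| + y' P y ]

with q = n - rank(X) and P the REML projection; including -log|X'X| makes
l_R exactly invariant to invertible reparameterisations of X.  Ordinary ML
uses the profiled GLS beta.

Fitting strategy: variance components are profiled on the residual scale
(gamma_k = sigma2_k / sigma2_e, optimised in log space).  Models with a
single random term are solved by an exact one-dimensional eigen-rotation
profile; multi-component models use Nelder-Mead restarts from three fixed
initialisations followed by an L-BFGS-B polish.

The restricted likelihood-ratio test for a variance component on the
boundary is computed against a parametric-bootstrap null: traits are
simulated from the fitted null model and both models refitted (a vectorised
eigen-rotation path covers the common case of no nuisance random terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RandomTerm", "LMMFit", "reml_fit", "lrt", "rlrt_test",
           "restricted_loglik", "ml_loglik"]

_LOG2PI = np.log(2.0 * np.pi)
_BOUND = 16.0  # bounds on log variance ratios
_BOUNDARY_TOL = 1e-5  # gamma below this is reported as a zero component


@dataclass
class RandomTerm:
    """One random effect: a PSD kernel or a grouping factor.

    ``kind='kernel'`` requires ``matrix`` (n x n PSD); ``kind='grouping'``
    requires ``labels`` (length-n factor), expanded to Z Z'.
    """

    name: str
    kind: str = "kernel"
    matrix: np.ndarray | None = None
    labels: np.ndarray | None = None

    def covariance(self, n: int | None = None) -> np.ndarray:
        if self.kind == "kernel":
            k = np.asarray(self.matrix, dtype=float)
            if k.shape[0] != k.shape[1]:
                raise ValueError(f"kernel {self.name!r} is not square")
            if n is not None and k.shape[0] != n:
                raise ValueError(f"kernel {self.name!r} has wrong dimension")
            return k
        if self.kind == "grouping":
            codes, _ = pd.factorize(np.asarray(self.labels))
            z = np.zeros((len(codes), codes.max() + 1))
            z[np.arange(len(codes)), codes] = 1.0
            return z @ z.T
        raise ValueError(f"unknown random-term kind {self.kind!r}")


@dataclass
class LMMFit:
    variance_components: dict
    beta: np.ndarray
    beta_se: np.ndarray
    fixed_names: list[str]
    loglik_reml: float
    loglik_ml: float
    method: str
    converged: bool
    n_iter: int
    n: int
    rank_x: int
    boundary: list = field(default_factory=list)
    term_names: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_reml if self.method == "reml" else self.loglik_ml


def _check_design(y, X):
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response dimensions differ")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    if n < p + 2:
        raise ValueError("need n >= number of fixed effects + 2")
    return y, X


def restricted_loglik(y, X, V) -> float:
    """Dense evaluation of the restricted log-likelihood at covariance V."""
    y, X = _check_design(y, X)
    n, p = X.shape
    q = n - p
    c = cho_factor(V, lower=True)
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    _, ld_xvx = np.linalg.slogdet(XtViX)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (q * _LOG2PI + logdet_v + ld_xvx - ld_xx + ypy)


def ml_loglik(y, X, V) -> float:
    """Ordinary log-likelihood at covariance V with GLS-profiled beta."""
    y, X = _check_design(y, X)
    n = len(y)
    c = cho_factor(V, lower=True)
    Vi_y = cho_solve(c, y)
    Vi_X = cho_solve(c, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    return -0.5 * (n * _LOG2PI + logdet_v + ypy)


def _profiled_criterion(psi, y, X, kernels, method, ld_xx=None, yX=None):
    """Negative profiled (restricted) log-likelihood at log-ratios psi."""
    n, p = X.shape
    q = n - p
    if ld_xx is None:
        _, ld_xx = np.linalg.slogdet(X.T @ X)
    if yX is None:
        yX = np.column_stack([y, X])
    psi = np.clip(psi, -_BOUND, _BOUND)  # keep evaluated == reported points
    W = np.eye(n)
    for g, K in zip(np.exp(psi), kernels):
        W += g * K
    try:
        c = cho_factor(W, lower=True, overwrite_a=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12
    sol = cho_solve(c, yX, check_finite=False)
    Wi_y, Wi_X = sol[:, 0], sol[:, 1:]
    XtWiX = X.T @ Wi_X
    XtWiy = X.T @ Wi_y
    beta = np.linalg.solve(XtWiX, XtWiy)
    ypy = float(y @ Wi_y - XtWiy @ beta)
    if ypy <= 0:
        return 1e12
    logdet_w = 2.0 * np.sum(np.log(np.diag(c[0])))
    if method == "reml":
        s2 = ypy / q
        _, ld_xwx = np.linalg.slogdet(XtWiX)
        ll = -0.5 * (q * (_LOG2PI + np.log(s2) + 1.0) + logdet_w + ld_xwx - ld_xx)
    else:
        s2 = ypy / n
        ll = -0.5 * (n * (_LOG2PI + np.log(s2) + 1.0) + logdet_w)
    return -ll


def _finalise(y, X, kernels, term_names, gammas, method, converged, n_iter,
              fixed_names):
    """Build the LMMFit at the optimised variance ratios."""
    n, p = X.shape
    q = n - p
    W = np.eye(n)
    for g, K in zip(gammas, kernels):
        W += g * K
    c = cho_factor(W, lower=True)
    Wi_y = cho_solve(c, y)
    Wi_X = cho_solve(c, X)
    XtWiX = X.T @ Wi_X
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    ypy = float(y @ Wi_y - (X.T @ Wi_y) @ beta)
    s2e = ypy / q if method == "reml" else ypy / n
    comps = {}
    boundary = []
    for name, g in zip(term_names, gammas):
        if g <= _BOUNDARY_TOL:
            comps[name] = 0.0
            boundary.append(name)
        else:
            comps[name] = g * s2e
    comps["residual"] = s2e
    # report the likelihood at the *reported* (clamped) components so the
    # stored value equals a dense evaluation at those components exactly
    V = s2e * np.eye(n)
    for name, K in zip(term_names, kernels):
        V += comps[name] * K
    if boundary:
        c = cho_factor(s2e ** -1 * V, lower=True)
        Wi_y = cho_solve(c, y)
        Wi_X = cho_solve(c, X)
        XtWiX = X.T @ Wi_X
        beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    se = np.sqrt(np.diag(np.linalg.inv(XtWiX)) * s2e)
    return LMMFit(
        variance_components=comps,
        beta=beta,
        beta_se=se,
        fixed_names=fixed_names,
        loglik_reml=restricted_loglik(y, X, V),
        loglik_ml=ml_loglik(y, X, V),
        method=method,
        converged=converged,
        n_iter=n_iter,
        n=n,
        rank_x=p,
        boundary=boundary,
        term_names=list(term_names),
    )


# -- exact one-dimensional profile for a single random term -----------------

def _single_term_rotation(X, K):
    """Eigen-rotation of one kernel restricted to the complement of col(X).

    Returns (xi, U, lam): eigenvalues/vectors of B' K B where B is an
    orthonormal basis of the orthogonal complement of col(X) (so U = B E
    spans that complement even when K is singular), plus the eigenvalues of
    K itself (needed for the ML log-determinant).
    """
    n, p = X.shape
    qfull, _ = np.linalg.qr(X, mode="complete")
    B = qfull[:, p:]  # n x (n - p)
    M = B.T @ K @ B
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    xi = np.clip(vals, 0.0, None)
    U = B @ vecs
    lam = np.clip(np.linalg.eigvalsh((K + K.T) / 2.0), 0.0, None)
    return xi, U, lam


def _profile_ll_single(eta2, xi, lam, n, q, gamma, method):
    """Profiled (restricted) ll at variance ratio gamma = sigma2_k/sigma2_e."""
    denom = gamma * xi + 1.0
    quad = float(np.sum(eta2 / denom))
    if method == "reml":
        s2 = quad / q
        return -0.5 * (q * (_LOG2PI + np.log(s2) + 1.0) + np.sum(np.log(denom)))
    s2 = quad / n
    return -0.5 * (n * (_LOG2PI + np.log(s2) + 1.0) + np.sum(np.log(gamma * lam + 1.0)))


def _fit_single_term(y, X, K, method):
    n, p = X.shape
    q = n - p
    xi, U, lam = _single_term_rotation(X, K)
    eta2 = (U.T @ y) ** 2

    def neg(psi):
        return -_profile_ll_single(eta2, xi, lam, n, q, np.exp(psi), method)

    grid = np.linspace(-_BOUND, _BOUND, 97)
    vals = np.array([neg(t) for t in grid])
    k = int(vals.argmin())
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    psi = float(res.x) if res.fun <= vals[k] else grid[k]
    return [np.exp(psi)], True, int(getattr(res, "nfev", 0)) + len(grid)


def reml_fit(y, fixed_design, random_terms=(), method: str = "reml") -> LMMFit:
    """Fit a Gaussian LMM by REML (or ML) over non-negative components.

    Parameters
    ----------
    y : response vector.
    fixed_design : n x p full-rank fixed-effect design (include intercept).
    random_terms : sequence of RandomTerm; the residual is implicit.
    method : 'reml' (default) or 'ml'; both log-likelihoods are evaluated
        at the optimum and stored on the fit either way.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    y, X = _check_design(y, fixed_design)
    n, p = X.shape
    fixed_names = [f"b{i}" for i in range(p)]
    terms = list(random_terms)
    term_names = [t.name for t in terms]

    if not terms:  # degenerate case: OLS
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        s2 = sse / (n - p) if method == "reml" else sse / n
        return _finalise(y, X, [], [], [], method, True, 0, fixed_names)

    kernels = [t.covariance(n) for t in terms]

    if len(kernels) == 1:
        gammas, ok, nit = _fit_single_term(y, X, kernels[0], method)
        return _finalise(y, X, kernels, term_names, gammas, method, ok, nit,
                         fixed_names)

    _, ld_xx = np.linalg.slogdet(X.T @ X)
    yX = np.column_stack([y, X])
    args = (y, X, kernels, method, ld_xx, yX)
    starts = [np.full(len(kernels), np.log(g)) for g in (0.1, 1.0, 10.0)]
    best = None
    n_iter = 0
    converged = False
    for s in starts:
        res = optimize.minimize(
            _profiled_criterion, s, args=args,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 80},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    polish = optimize.minimize(
        _profiled_criterion, np.clip(best.x, -_BOUND, _BOUND),
        args=args, method="L-BFGS-B",
        bounds=[(-_BOUND, _BOUND)] * len(kernels),
        options={"ftol": 1e-12, "gtol": 1e-9},
    )
    n_iter += polish.nit
    if polish.fun <= best.fun + 1e-12:
        best = polish
        converged = converged or bool(polish.success)
    gammas = np.exp(np.clip(best.x, -_BOUND, _BOUND))
    gammas = np.where(gammas <= np.exp(-_BOUND) * 1.01, 0.0, gammas)
    return _finalise(y, X, kernels, term_names, gammas, method, converged,
                     n_iter, fixed_names)


def lrt(full: LMMFit, null: LMMFit, df: int) -> float:
    """Chi-square LRT p-value for nested fixed effects (ML likelihoods)."""
    ll_f, ll_0 = full.loglik_ml, null.loglik_ml
    if ll_f < ll_0 - 1e-6:
        raise ValueError(
            f"full-model log-likelihood {ll_f:.6f} below null {ll_0:.6f}: "
            "optimizer failure"
        )
    stat = max(0.0, 2.0 * (ll_f - ll_0))
    return float(stats.chi2.sf(stat, df))


def _rlrt_stats_fast(Y, X, K):
    """RLRT statistics for each column of Y (single tested kernel, no nuisance).

    Grid-profiled over the variance ratio; the same grid is used for the
    observed trait and the bootstrap samples so comparisons are exchangeable.
    """
    n, p = X.shape
    q = n - p
    xi, U, _ = _single_term_rotation(X, K)
    H2 = (U.T @ Y) ** 2  # q x B
    gammas = np.concatenate([[0.0], np.logspace(-8, 8, 321)])
    denom = gammas[None, :] * xi[:, None] + 1.0  # q x G
    quad = H2.T @ (1.0 / denom)  # B x G
    logdet = np.log(denom).sum(axis=0)  # G
    rll = -0.5 * (q * (_LOG2PI + np.log(quad / q) + 1.0) + logdet[None, :])
    rll_full = rll.max(axis=1)
    rll_null = rll[:, 0]  # gamma = 0
    return np.maximum(0.0, 2.0 * (rll_full - rll_null))


def rlrt_test(
    y,
    fixed_design,
    tested_term: RandomTerm,
    nuisance_terms=(),
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap restricted likelihood-ratio test.

    Tests sigma2 = 0 for ``tested_term``.  The null distribution is obtained
    by simulating ``n_sim`` traits from the REML-fitted null model (nuisance
    terms + residual) and refitting both models; the returned p-value is
    (1 + #{sim >= observed}) / (n_sim + 1).

    Returns (statistic, p).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    y, X = _check_design(y, fixed_design)
    n = len(y)
    nuisance = list(nuisance_terms)
    rng = np.random.default_rng(seed)

    full = reml_fit(y, X, nuisance + [tested_term], method="reml")
    null = reml_fit(y, X, nuisance, method="reml")
    stat = max(0.0, 2.0 * (full.loglik_reml - null.loglik_reml))

    if not nuisance:
        K = tested_term.covariance(n)
        obs = float(_rlrt_stats_fast(y[:, None], X, K)[0])
        mean0 = X @ null.beta
        s0 = np.sqrt(null.variance_components["residual"])
        Y = mean0[:, None] + s0 * rng.standard_normal((n, n_sim))
        sims = _rlrt_stats_fast(Y, X, K)
        p = (1.0 + np.sum(sims >= obs - 1e-12)) / (n_sim + 1.0)
        return stat, float(p)

    # general nested case: per-simulation refits
    V0 = null.variance_components["residual"] * np.eye(n)
    for t in nuisance:
        V0 += null.variance_components.get(t.name, 0.0) * t.covariance(n)
    L0 = np.linalg.cholesky(V0 + 1e-10 * np.eye(n))
    mean0 = X @ null.beta
    sims = np.empty(n_sim)
    for b in range(n_sim):
        yb = mean0 + L0 @ rng.standard_normal(n)
        fb = reml_fit(yb, X, nuisance + [tested_term], method="reml")
        nb = reml_fit(yb, X, nuisance, method="reml")
        sims[b] = max(0.0, 2.0 * (fb.loglik_reml - nb.loglik_reml))
    p = (1.0 + np.sum(sims >= stat - 1e-12)) / (n_sim + 1.0)
    return stat, float(p)
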