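"""EM estimation of Gaussian mixtures with BIC selection of K.

Two covariance regimes are supported:

* ``SHARED_SPHERICAL`` — all components share one spherical covariance
  ``sigma^2 I`` (the latent-profile-analysis structure used throughout the
  main study); a single variance parameter is pooled across components and
  variables.
* ``FULL_UNCONSTRAINED`` — each component has its own full SPD covariance.

Fits that collapse (a covariance with smallest eigenvalue below 1e-10, or a
diverging log-likelihood) are recorded as *failed* rather than raised: when
ordinal data with very few categories concentrate on a handful of grid
points, EM can drive component variances to zero, and model selection must
be able to observe and exclude those degenerate candidates.  No variance
prior or ridge is applied, precisely so that this failure mode can occur.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import linalg
from scipy.cluster.vq import kmeans2
from scipy.special import logsumexp

__all__ = [
    "ModelFamily",
    "EMConfig",
    "FittedMixture",
    "SelectionResult",
    "fit_em",
    "n_params",
    "bic",
    "select_k",
]

_EIG_FLOOR = 1e-10  # smallest admissible covariance eigenvalue


class ModelFamily(str, Enum):
    """Covariance structure imposed during estimation.

    ``SHARED_SPHERICAL`` pools a single spherical variance across all
    components; ``COMPONENT_SPHERICAL`` gives each component its own
    spherical variance ``sigma_k^2 I`` (the latent-profile structure whose
    parameter count is K(p+1) + (K-1) and whose per-component variances can
    collapse individually on coarse ordinal grids); ``FULL_UNCONSTRAINED``
    estimates a full SPD covariance per component.
    """

    SHARED_SPHERICAL = "shared_spherical"
    COMPONENT_SPHERICAL = "component_spherical"
    FULL_UNCONSTRAINED = "full_unconstrained"


@dataclass(frozen=True)
class EMConfig:
    """Engine options for a single EM fit.

    n_init random restarts are run in a short first stage (at most
    ``short_iters`` iterations at tolerance ``short_tol``) and only the
    highest-likelihood survivor is then refined to convergence — a relative
    log-likelihood change below ``tol``, or ``max_iter`` total iterations.
    ``variance_count`` switches the parameter count used in the BIC penalty
    for the shared-spherical family between the pooled count (one shared
    variance) and the per-component-spherical count K(p+1) + (K-1); only
    the penalty is affected, never the fit.
    """

    n_init: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    short_iters: int = 100
    short_tol: float = 1e-6
    variance_count: str = "shared"  # "shared" | "per_component"


@dataclass(frozen=True)
class FittedMixture:
    """One EM solution for a fixed K (or a recorded failure)."""

    K: int
    family: ModelFamily
    weights: np.ndarray | None
    means: np.ndarray | None
    covariances: np.ndarray | None
    loglik: float
    n_params: int
    bic: float
    N: int
    converged: bool = False
    failed: bool = False
    fail_reason: str = ""
    loglik_trace: tuple = ()


@dataclass(frozen=True)
class SelectionResult:
    """BIC model selection over K = 1..K_max."""

    fits: tuple            # FittedMixture per K, index 0 -> K=1
    selected: FittedMixture
    K_hat: int

    @property
    def bic_table(self) -> dict:
        return {f.K: (None if f.failed else f.bic) for f in self.fits}


def n_params(K: int, p: int, family: ModelFamily,
             variance_count: str = "shared") -> int:
    """Number of free parameters of the mixture.

    Shared spherical: K*p means + 1 pooled variance + (K-1) weights (the
    ``per_component`` variant counts one spherical variance per component,
    K(p+1) + (K-1)).  Component spherical: K*p + K + (K-1).  Full: K*p
    means + K*p(p+1)/2 covariance entries + (K-1) weights.
    """
    if K < 1 or p < 1:
        raise ValueError("K and p must be >= 1")
    family = ModelFamily(family)
    if family is ModelFamily.SHARED_SPHERICAL:
        n_var = K if variance_count == "per_component" else 1
        return K * p + n_var + (K - 1)
    if family is ModelFamily.COMPONENT_SPHERICAL:
        return K * p + K + (K - 1)
    return K * p + K * p * (p + 1) // 2 + (K - 1)


def bic(loglik: float, m: int, N: int) -> float:
    """``2*loglik - m*ln(N)``; larger is better."""
    return 2.0 * loglik - m * math.log(N)


# ---------------------------------------------------------------------------
# log densities
# ---------------------------------------------------------------------------

def _log_dens_spherical(X: np.ndarray, means: np.ndarray,
                        sigma2: float) -> np.ndarray:
    """N x K log N(x | mu_k, sigma2 I)."""
    p = X.shape[1]
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ means.T
        + np.sum(means * means, axis=1)[None, :]
    )
    return -0.5 * (p * math.log(2.0 * math.pi * sigma2) + d2 / sigma2)


def _log_dens_comp_spherical(X: np.ndarray, means: np.ndarray,
                             sigma2s: np.ndarray) -> np.ndarray:
    """N x K log N(x | mu_k, sigma_k^2 I)."""
    p = X.shape[1]
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ means.T
        + np.sum(means * means, axis=1)[None, :]
    )
    return -0.5 * (
        p * np.log(2.0 * math.pi * sigma2s)[None, :] + d2 / sigma2s[None, :]
    )


def _log_dens_full(X: np.ndarray, means: np.ndarray,
                   covs: np.ndarray) -> np.ndarray:
    N, p = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        chol = linalg.cholesky(covs[k], lower=True)
        diff = X - means[k]
        sol = linalg.solve_triangular(chol, diff.T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (
            p * math.log(2.0 * math.pi) + logdet + np.sum(sol * sol, axis=0)
        )
    return out


class _Degenerate(Exception):
    pass


def _m_step(X, resp, family):
    N, p = X.shape
    nk = resp.sum(axis=0)
    if np.any(nk < 1e-12):
        raise _Degenerate("empty component")
    weights = nk / N
    means = (resp.T @ X) / nk[:, None]
    if family in (ModelFamily.SHARED_SPHERICAL,
                  ModelFamily.COMPONENT_SPHERICAL):
        d2 = (
            np.sum(X * X, axis=1)[:, None]
            - 2.0 * X @ means.T
            + np.sum(means * means, axis=1)[None, :]
        )
        if family is ModelFamily.SHARED_SPHERICAL:
            sigma2 = float(np.sum(resp * d2) / (N * p))
            if sigma2 < _EIG_FLOOR:
                raise _Degenerate("pooled variance collapsed to zero")
            return weights, means, sigma2
        sigma2s = np.sum(resp * d2, axis=0) / (nk * p)
        if np.any(sigma2s < _EIG_FLOOR):
            k = int(np.argmin(sigma2s))
            raise _Degenerate(f"singular covariance in component {k}")
        return weights, means, sigma2s
    covs = np.empty((means.shape[0], p, p))
    for k in range(means.shape[0]):
        diff = X - means[k]
        covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
        covs[k] = 0.5 * (covs[k] + covs[k].T)
        if np.linalg.eigvalsh(covs[k])[0] < _EIG_FLOOR:
            raise _Degenerate(f"singular covariance in component {k}")
    return weights, means, covs


def _log_dens(X, means, cov_param, family):
    if family is ModelFamily.SHARED_SPHERICAL:
        return _log_dens_spherical(X, means, cov_param)
    if family is ModelFamily.COMPONENT_SPHERICAL:
        return _log_dens_comp_spherical(X, means, cov_param)
    return _log_dens_full(X, means, cov_param)


def _init_means(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means-style initial centres (k-means++ seeding plus a few Lloyd
    iterations); falls back to random distinct rows on degenerate data."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seed_state = np.random.default_rng(rng.integers(2**31))
            centres, _ = kmeans2(X, K, minit="++", iter=10, seed=seed_state)
        if np.all(np.isfinite(centres)) and (
            K == 1 or np.unique(centres, axis=0).shape[0] == K
        ):
            return centres
    except Exception:
        pass
    idx = rng.choice(X.shape[0], size=K, replace=False)
    return X[idx] + 1e-6 * rng.standard_normal((K, X.shape[1]))


def _em_loop(X, K, family, weights, means, cov_param, max_iter, tol,
             trace=None):
    """Iterate EM from the given parameters; raises _Degenerate on collapse.

    Continuing a run from its own parameters extends its (non-decreasing)
    log-likelihood trace, so the two-stage schedule preserves EM ascent.
    """
    loglik = -np.inf
    trace = [] if trace is None else list(trace)
    converged = False
    for _ in range(max_iter):
        log_comp = _log_dens(X, means, cov_param, family) + np.log(weights)
        log_norm = logsumexp(log_comp, axis=1)
        new_loglik = float(np.sum(log_norm))
        if not np.isfinite(new_loglik):
            raise _Degenerate("log-likelihood diverged")
        trace.append(new_loglik)
        if np.isfinite(loglik):
            if abs(new_loglik - loglik) / (1.0 + abs(loglik)) < tol:
                loglik = new_loglik
                converged = True
                break
        loglik = new_loglik
        resp = np.exp(log_comp - log_norm[:, None])
        weights, means, cov_param = _m_step(X, resp, family)
    return weights, means, cov_param, loglik, converged, trace


def _run_em_once(X, K, family, config, rng):
    """One initialised short-stage EM run; raises _Degenerate on collapse."""
    N, p = X.shape
    means = _init_means(X, K, rng)
    # initial responsibilities: hard assignment to the nearest centre
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ means.T
        + np.sum(means * means, axis=1)[None, :]
    )
    resp = np.zeros((N, K))
    resp[np.arange(N), np.argmin(d2, axis=1)] = 1.0
    weights, means, cov_param = _m_step(X, resp, family)
    return _em_loop(
        X, K, family, weights, means, cov_param,
        max_iter=min(config.short_iters, config.max_iter),
        tol=max(config.short_tol, config.tol),
    )


def _fit_k1(X: np.ndarray, family: ModelFamily, config: EMConfig,
            N: int, p: int) -> FittedMixture:
    """Closed-form MLE for a single Gaussian; never fails."""
    mean = X.mean(axis=0, keepdims=True)
    diff = X - mean
    if family in (ModelFamily.SHARED_SPHERICAL,
                  ModelFamily.COMPONENT_SPHERICAL):
        sigma2 = max(float(np.sum(diff * diff) / (N * p)), _EIG_FLOOR)
        covs = sigma2 * np.eye(p)[None]
        ll = float(np.sum(_log_dens_spherical(X, mean, sigma2)))
    else:
        cov = diff.T @ diff / N
        cov = 0.5 * (cov + cov.T)
        if np.linalg.eigvalsh(cov)[0] < _EIG_FLOOR:
            cov = cov + _EIG_FLOOR * np.eye(p)
        covs = cov[None]
        ll = float(np.sum(_log_dens_full(X, mean, covs)))
    m = n_params(1, p, family, config.variance_count)
    return FittedMixture(
        K=1, family=family, weights=np.array([1.0]), means=mean,
        covariances=covs, loglik=ll, n_params=m, bic=bic(ll, m, N), N=N,
        converged=True, loglik_trace=(ll,),
    )


def fit_em(X: np.ndarray, K: int, family: ModelFamily,
           config: EMConfig | None = None) -> FittedMixture:
    """Fit a K-component mixture by EM, best of ``config.n_init`` restarts.

    Returns a FittedMixture with ``failed=True`` (never raises) when every
    restart degenerates — e.g. when a covariance collapses onto a grid point
    of heavily discretised data.
    """
    config = config or EMConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be an N x p matrix")
    N, p = X.shape
    if N <= K:
        raise ValueError("need more observations than components")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    family = ModelFamily(family)
    if K == 1:
        return _fit_k1(X, family, config, N, p)

    rng = np.random.default_rng(config.seed)
    candidates = []
    reasons = []
    for _ in range(config.n_init):
        try:
            candidates.append(_run_em_once(X, K, family, config, rng))
        except _Degenerate as exc:
            reasons.append(str(exc))
    candidates.sort(key=lambda c: c[3], reverse=True)

    # refine the best short run to full convergence; if refinement itself
    # degenerates, fall through to the next-best survivor
    best = None
    for w, mu, covp, ll, conv, trace in candidates:
        try:
            best = _em_loop(
                X, K, family, w, mu, covp,
                max_iter=max(config.max_iter - len(trace), 2),
                tol=config.tol, trace=trace,
            )
            break
        except _Degenerate as exc:
            reasons.append(str(exc))
    m = n_params(K, p, family, config.variance_count)
    if best is None:
        reason = "; ".join(sorted(set(reasons))) or "no run converged"
        return FittedMixture(
            K=K, family=family, weights=None, means=None, covariances=None,
            loglik=-np.inf, n_params=m, bic=-np.inf, N=N,
            failed=True, fail_reason=reason,
        )
    w, mu, covp, ll, conv, trace = best
    if family is ModelFamily.SHARED_SPHERICAL:
        covs = np.broadcast_to(covp * np.eye(p), (K, p, p)).copy()
    elif family is ModelFamily.COMPONENT_SPHERICAL:
        covs = covp[:, None, None] * np.eye(p)[None]
    else:
        covs = covp
    return FittedMixture(
        K=K, family=family, weights=w, means=mu, covariances=covs,
        loglik=ll, n_params=m, bic=bic(ll, m, N), N=N, converged=conv,
        loglik_trace=tuple(trace),
    )


def select_k(X: np.ndarray, family: ModelFamily, K_max: int = 7,
             config: EMConfig | None = None) -> SelectionResult:
    """Fit K = 1..K_max and select the maximum-BIC non-failed fit.

    Failed (degenerate) fits are excluded from the comparison; ties in BIC
    break toward smaller K; K = 1 has a closed form and never fails, so a
    selection always exists.
    """
    config = config or EMConfig()
    fits = []
    for K in range(1, K_max + 1):
        cfg = replace(config, seed=config.seed + 7919 * K)
        fits.append(fit_em(X, K, family, cfg))
    survivors = [f for f in fits if not f.failed]
    selected = max(survivors, key=lambda f: (f.bic, -f.K))
    return SelectionResult(fits=tuple(fits), selected=selected,
                           K_hat=selected.K)
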