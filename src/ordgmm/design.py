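"""Construction of data-generating Gaussian mixture designs.

A *design* is a K-component multivariate Gaussian mixture with equal mixing
weights 1/K whose components are pairwise equidistant in Kullback-Leibler
divergence.  For every supported condition except (K=4, p=2) the components
share the spherical covariance ``sigma2 * I`` and equidistance is achieved by
placing the means on a regular (K-1)-simplex; for K=4 in two dimensions no
such mean arrangement exists, so the means sit on a square and the component
covariances are optimised numerically to equalise the six pairwise
(symmetrised) divergences.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "DEFAULT_VARIANCE",
    "GaussianComponent",
    "MixtureDesign",
    "Condition",
    "kl_mvn",
    "symmetrized_kl",
    "place_equidistant_means",
    "solve_k4p2_design",
    "build_design",
    "random_rotation",
]

#: Shared spherical variance of the data-generating components, sigma^2 = sqrt(0.25).
DEFAULT_VARIANCE: float = math.sqrt(0.25)

#: The mean configuration is centred on this coordinate so that individual
#: means fall roughly in [-0.5, 1.5] for the separations studied here.
_CENTROID_COORD: float = 0.5


class DesignError(ValueError):
    """Invalid or infeasible design specification."""


def _as_spd(cov: np.ndarray, name: str) -> np.ndarray:
    """Validate symmetric positive-definiteness and return a float array."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise DesignError(f"{name} must be a square matrix, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise DesignError(f"{name} must be symmetric")
    try:
        linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise DesignError(f"{name} must be positive definite") from exc
    return cov


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: mean vector, SPD covariance and mixing weight."""

    mean: np.ndarray
    covariance: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).ravel()
        cov = _as_spd(self.covariance, "covariance")
        if cov.shape[0] != mean.size:
            raise DesignError("mean and covariance dimensions differ")
        if not (0.0 < self.weight <= 1.0):
            raise DesignError(f"weight must lie in (0, 1], got {self.weight}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def p(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class MixtureDesign:
    """A K-component Gaussian mixture with pairwise-equidistant components.

    Attributes
    ----------
    K, p : int
        Number of components and number of variables.
    components : tuple of GaussianComponent
        The mixture components; weights sum to one.
    target_kl : float
        The common pairwise (symmetrised) KL divergence, in nats.
    kl_tolerance : float
        The tolerance within which all pairwise divergences match the target.
    """

    K: int
    p: int
    components: tuple
    target_kl: float
    kl_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if len(self.components) != self.K:
            raise DesignError("number of components does not match K")
        for comp in self.components:
            if comp.p != self.p:
                raise DesignError("component dimension does not match p")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-10:
            raise DesignError(f"component weights sum to {total}, expected 1")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def means(self) -> np.ndarray:
        """K x p array of component means."""
        return np.array([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        """K x p x p array of component covariances."""
        return np.array([c.covariance for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def pairwise_kl_matrix(self) -> np.ndarray:
        """K x K matrix of pairwise symmetrised KL divergences."""
        out = np.zeros((self.K, self.K))
        for i, j in itertools.combinations(range(self.K), 2):
            ci, cj = self.components[i], self.components[j]
            out[i, j] = out[j, i] = symmetrized_kl(
                ci.mean, ci.covariance, cj.mean, cj.covariance
            )
        return out

    def validate(self) -> None:
        """Raise DesignError if any pairwise divergence misses the target."""
        kls = self.pairwise_kl_matrix()
        off = kls[~np.eye(self.K, dtype=bool)]
        resid = np.max(np.abs(off - self.target_kl)) if off.size else 0.0
        if resid > self.kl_tolerance:
            raise DesignError(
                f"pairwise KL residual {resid:.3g} exceeds tolerance "
                f"{self.kl_tolerance:.3g}"
            )

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "K": self.K,
            "p": self.p,
            "target_kl": self.target_kl,
            "kl_tolerance": self.kl_tolerance,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MixtureDesign":
        d = json.loads(text)
        comps = tuple(
            GaussianComponent(np.array(m), np.array(c), w)
            for m, c, w in zip(d["means"], d["covariances"], d["weights"])
        )
        return cls(
            K=d["K"],
            p=d["p"],
            components=comps,
            target_kl=d["target_kl"],
            kl_tolerance=d.get("kl_tolerance", 1e-8),
        )


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation grid.

    ``n_categories`` is either an integer >= 2 (ordinal data with that many
    categories) or the string ``"continuous"`` (no discretisation).
    """

    K: int
    p: int
    target_kl: float
    N: int
    n_categories: object = "continuous"
    family: str = "shared_spherical"
    reps: int = 100
    base_seed: int = 0

    _GRID_K = (2, 3, 4)
    _GRID_P = tuple(range(2, 11))
    _GRID_KL = (2.0, 3.5, 5.0)
    _GRID_N = (1000, 2500, 10000)

    def __post_init__(self) -> None:
        if self.K < 1 or self.p < 1:
            raise DesignError("K and p must be positive")
        if self.reps < 1:
            raise DesignError("reps must be >= 1")
        c = self.n_categories
        if not (c == "continuous" or (isinstance(c, (int, np.integer)) and c >= 2)):
            raise DesignError(
                "n_categories must be an integer >= 2 or 'continuous', "
                f"got {c!r}"
            )

    @property
    def is_continuous(self) -> bool:
        return self.n_categories == "continuous"

    def in_supported_grid(self) -> bool:
        """Whether this cell lies on the validated study grid."""
        return (
            self.K in self._GRID_K
            and self.p in self._GRID_P
            and float(self.target_kl) in self._GRID_KL
            and self.N in self._GRID_N
            and (self.is_continuous or 2 <= int(self.n_categories) <= 12)
        )


# ---------------------------------------------------------------------------
# Kullback-Leibler divergence between multivariate Gaussians
# ---------------------------------------------------------------------------

def kl_mvn(
    mean0: Sequence[float],
    cov0: np.ndarray,
    mean1: Sequence[float],
    cov1: np.ndarray,
) -> float:
    """KL( N(mean0, cov0) || N(mean1, cov1) ) in nats.

    Closed form
    ``0.5 * [tr(S1^-1 S0) + d' S1^-1 d - p + ln(det S1 / det S0)]``
    with ``d = mean1 - mean0``.
    """
    m0 = np.asarray(mean0, dtype=float).ravel()
    m1 = np.asarray(mean1, dtype=float).ravel()
    c0 = _as_spd(cov0, "cov0")
    c1 = _as_spd(cov1, "cov1")
    p = m0.size
    if m1.size != p or c0.shape[0] != p or c1.shape[0] != p:
        raise DesignError("dimension mismatch between means and covariances")
    chol1 = linalg.cho_factor(c1, lower=True)
    trace = np.trace(linalg.cho_solve(chol1, c0))
    diff = m1 - m0
    maha = diff @ linalg.cho_solve(chol1, diff)
    _, logdet0 = np.linalg.slogdet(c0)
    _, logdet1 = np.linalg.slogdet(c1)
    return max(0.0, 0.5 * (trace + maha - p + logdet1 - logdet0))


def symmetrized_kl(mean0, cov0, mean1, cov1) -> float:
    """Symmetrised KL divergence, ``(KL(0||1) + KL(1||0)) / 2``.

    Coincides with the one-directional divergence whenever the two
    covariances are equal, which is the case for every design here except
    (K=4, p=2).
    """
    return 0.5 * (
        kl_mvn(mean0, cov0, mean1, cov1) + kl_mvn(mean1, cov1, mean0, cov0)
    )


# ---------------------------------------------------------------------------
# Mean placement
# ---------------------------------------------------------------------------

def random_rotation(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random rotation matrix (orthogonal, determinant +1) via QR of a
    standard-Gaussian matrix with the usual sign fix."""
    g = rng.standard_normal((p, p))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _regular_simplex(K: int, edge: float) -> np.ndarray:
    """K vertices of a regular simplex with the given edge length, centred at
    the origin, as a K x (K-1) array (K=1 yields a single zero vertex)."""
    if K == 1:
        return np.zeros((1, 0))
    # Rows of I - J/K are pairwise sqrt(2) apart and span a (K-1)-dim space.
    v = np.eye(K) - np.full((K, K), 1.0 / K)
    # Orthonormal basis of the span via SVD; coordinates in that basis.
    u, s, _ = np.linalg.svd(v, full_matrices=False)
    coords = (u * s)[:, : K - 1]
    return coords * (edge / math.sqrt(2.0))


def place_equidistant_means(
    K: int,
    p: int,
    target_kl: float,
    variance: float = DEFAULT_VARIANCE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Means of K components with shared covariance ``variance * I`` whose
    pairwise (symmetrised) KL divergences all equal ``target_kl``.

    For equal spherical covariances KL = ||d||^2 / (2 sigma^2), so the means
    form a regular (K-1)-simplex with edge ``sqrt(2 * variance * target_kl)``.
    The simplex is randomly rotated (a draw from SO(p) using ``rng``) and
    translated so its centroid sits at (0.5, ..., 0.5).

    Returns a K x p array.
    """
    if K - 1 > p:
        msg = f"a regular {K - 1}-simplex does not fit in {p} dimensions"
        if K == 4 and p == 2:
            msg += " (the K=4, p=2 case requires solve_k4p2_design)"
        raise DesignError(msg)
    if target_kl <= 0 or variance <= 0:
        raise DesignError("target_kl and variance must be positive")
    rng = np.random.default_rng() if rng is None else rng
    edge = math.sqrt(2.0 * variance * target_kl)
    simplex = _regular_simplex(K, edge)  # K x (K-1)
    means = np.zeros((K, p))
    means[:, : K - 1] = simplex
    means = means @ random_rotation(p, rng).T
    return means + _CENTROID_COORD


# ---------------------------------------------------------------------------
# K = 4, p = 2: equalise divergences by varying covariances
# ---------------------------------------------------------------------------

def _chol_from_params(params3: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor from (log l11, log l22, l21)."""
    l11, l22, l21 = math.exp(params3[0]), math.exp(params3[1]), params3[2]
    return np.array([[l11, 0.0], [l21, l22]])


def _k4p2_unpack(x: np.ndarray):
    side = math.exp(x[0])
    half = side / 2.0
    means = np.array(
        [[-half, -half], [half, -half], [half, half], [-half, half]]
    )
    covs = np.array(
        [_chol_from_params(x[1 + 3 * k : 4 + 3 * k]) for k in range(4)]
    )
    covs = covs @ covs.transpose(0, 2, 1)
    return means, covs


def _k4p2_residuals(x: np.ndarray, target: float) -> np.ndarray:
    means, covs = _k4p2_unpack(x)
    res = []
    for i, j in itertools.combinations(range(4), 2):
        res.append(
            symmetrized_kl(means[i], covs[i], means[j], covs[j]) - target
        )
    return np.array(res)


def solve_k4p2_design(
    target_kl: float,
    rng: np.random.Generator | None = None,
    kl_tolerance: float = 1e-4,
    n_restarts: int = 20,
) -> MixtureDesign:
    """Construct the K=4, p=2 design by numeric optimisation.

    Four components cannot be placed at pairwise-equal Euclidean distances in
    the plane, so the means sit on a square (side length optimised jointly)
    and each component gets its own covariance, parameterised through its
    Cholesky factor, chosen by least squares so that all six pairwise
    symmetrised KL divergences equal ``target_kl``.  The solved configuration
    is then randomly rotated about its centroid (covariances conjugated
    accordingly, which leaves every divergence unchanged) and translated to
    the standard centroid.
    """
    if target_kl <= 0:
        raise DesignError("target_kl must be positive")
    rng = np.random.default_rng() if rng is None else rng

    log_s0 = 0.5 * math.log(2.0 * DEFAULT_VARIANCE * target_kl)
    log_l0 = 0.5 * math.log(DEFAULT_VARIANCE)
    best = None
    for attempt in range(n_restarts):
        x0 = np.empty(13)
        x0[0] = log_s0
        for k in range(4):
            x0[1 + 3 * k] = log_l0
            x0[2 + 3 * k] = log_l0
            x0[3 + 3 * k] = 0.0
        if attempt > 0:
            x0 += rng.normal(scale=0.2, size=13)
        sol = optimize.least_squares(
            _k4p2_residuals, x0, args=(target_kl,), xtol=1e-14, ftol=1e-14,
            gtol=1e-14,
        )
        resid = np.max(np.abs(sol.fun))
        if best is None or resid < best[0]:
            best = (resid, sol.x)
        if resid < kl_tolerance:
            break
    resid, x = best
    if resid >= kl_tolerance:
        raise DesignError(
            f"K=4/p=2 optimisation did not reach tolerance {kl_tolerance:g}; "
            f"achieved residual {resid:.3g}"
        )

    means, covs = _k4p2_unpack(x)
    rot = random_rotation(2, rng)
    means = means @ rot.T + _CENTROID_COORD
    covs = rot @ covs @ rot.T
    comps = tuple(
        GaussianComponent(means[k], covs[k], 0.25) for k in range(4)
    )
    return MixtureDesign(
        K=4, p=2, components=comps, target_kl=target_kl,
        kl_tolerance=kl_tolerance,
    )


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def build_design(
    condition: Condition, rng: np.random.Generator
) -> MixtureDesign:
    """Construct the data-generating mixture for one grid cell.

    A fresh, randomly rotated mean configuration is produced on every call,
    so repeated calls with independent ``rng`` states yield independently
    randomised designs for each Monte-Carlo repetition.
    """
    K, p, target = condition.K, condition.p, float(condition.target_kl)
    if K == 4 and p == 2:
        return solve_k4p2_design(target, rng)
    means = place_equidistant_means(K, p, target, DEFAULT_VARIANCE, rng)
    cov = DEFAULT_VARIANCE * np.eye(p)
    comps = tuple(
        GaussianComponent(means[k], cov, 1.0 / K) for k in range(K)
    )
    return MixtureDesign(
        K=K, p=p, components=comps, target_kl=target, kl_tolerance=1e-8
    )
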