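"""Recovery scoring: was K selected correctly, and how close are the
parameters once components are matched?

Mixture components are only identified up to a permutation of their labels
(label switching), so before computing parameter errors the estimated
components are matched to the data-generating ones by exhaustive search over
all K! assignments, minimising the mean absolute difference between matched
mean vectors.  Errors are only defined — and only reported — for
repetitions in which the selected K equals the true K.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import MixtureDesign
from .estimate import FittedMixture

__all__ = [
    "RecoveryMetrics",
    "CellSummary",
    "match_components",
    "parameter_errors",
    "summarize_cell",
]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Outcome of a single simulation repetition."""

    K_true: int
    K_hat: int
    correct: bool
    matched_permutation: tuple | None = None
    mae_means: float | None = None
    mae_variances: float | None = None
    mae_covariances: float | None = None
    mae_weights: float | None = None

    def __post_init__(self) -> None:
        if self.correct != (self.K_true == self.K_hat):
            raise ValueError("correct flag inconsistent with K_true/K_hat")
        if not self.correct and self.mae_means is not None:
            raise ValueError("error fields require a correct selection")


@dataclass(frozen=True)
class CellSummary:
    """Aggregate over the repetitions of one grid cell."""

    condition: object
    n_reps: int
    accuracy: float
    K_hat_counts: dict
    mae_means: float | None
    mae_variances: float | None
    mae_covariances: float | None
    n_correct: int


def match_components(truth: MixtureDesign, fit: FittedMixture) -> tuple:
    """Best assignment of estimated components to true components.

    Enumerates all K! permutations (K <= 7, so exhaustive search is exact)
    and returns the tuple ``perm`` minimising the mean absolute difference
    between ``fit.means[i]`` and ``truth.means[perm[i]]``; ties break to the
    lexicographically smallest permutation.
    """
    if fit.failed or fit.means is None:
        raise ValueError("cannot match a failed fit")
    if fit.K != truth.K:
        raise ValueError(f"component counts differ: fit {fit.K}, truth {truth.K}")
    K = truth.K
    true_means = truth.means
    est_means = fit.means
    # K x K matrix of mean absolute differences between mean vectors
    cost = np.mean(
        np.abs(est_means[:, None, :] - true_means[None, :, :]), axis=2
    )
    # exact ties are possible with absolute-value costs (e.g. when all mean
    # differences share signs), so collect costs first and break ties toward
    # the lexicographically smallest permutation within a relative epsilon
    perms = list(itertools.permutations(range(K)))
    costs = np.array(
        [sum(cost[i, perm[i]] for i in range(K)) for perm in perms]
    )
    cmin = costs.min()
    tol = 1e-9 * (1.0 + cmin)
    for perm, c in zip(perms, costs):  # perms are in lexicographic order
        if c <= cmin + tol:
            return perm


def parameter_errors(truth: MixtureDesign, fit: FittedMixture,
                     permutation: tuple, metric: str = "mae") -> tuple:
    """(means, variances, covariances) error after matching.

    With ``metric="mae"`` (default) each entry is the mean absolute
    difference between matched true and estimated parameters: over the K*p
    mean entries, the K*p diagonal covariance entries, and the
    K*p*(p-1)/2 unique off-diagonal entries.  ``metric="mse"`` squares the
    differences instead.
    """
    if metric not in ("mae", "mse"):
        raise ValueError("metric must be 'mae' or 'mse'")
    perm = list(permutation)
    K, p = truth.K, truth.p
    d_means = fit.means - truth.means[perm]
    d_cov = fit.covariances - truth.covariances[perm]
    diag = np.array([np.diag(d_cov[k]) for k in range(K)])
    iu = np.triu_indices(p, k=1)
    off = np.array([d_cov[k][iu] for k in range(K)])

    def agg(x: np.ndarray) -> float:
        if x.size == 0:
            return 0.0
        x = np.abs(x)
        return float(np.mean(x * x) if metric == "mse" else np.mean(x))

    return agg(d_means), agg(diag), agg(off)


def score_repetition(truth: MixtureDesign, K_hat: int,
                     fit: FittedMixture | None,
                     metric: str = "mae") -> RecoveryMetrics:
    """RecoveryMetrics for one repetition given the selected fit."""
    correct = K_hat == truth.K
    if not correct:
        return RecoveryMetrics(K_true=truth.K, K_hat=K_hat, correct=False)
    perm = match_components(truth, fit)
    e_mu, e_var, e_cov = parameter_errors(truth, fit, perm, metric=metric)
    e_w = float(np.mean(np.abs(fit.weights - truth.weights[list(perm)])))
    return RecoveryMetrics(
        K_true=truth.K, K_hat=K_hat, correct=True,
        matched_permutation=perm, mae_means=e_mu, mae_variances=e_var,
        mae_covariances=e_cov, mae_weights=e_w,
    )


def summarize_cell(metrics: list, condition=None) -> CellSummary:
    """Aggregate repetition outcomes for one cell.

    Accuracy is the fraction of repetitions with the correct K; parameter
    errors are averaged over the correct repetitions only and are ``None``
    (a missing cell) when no repetition selected the correct K.
    """
    if not metrics:
        raise ValueError("need at least one repetition")
    n = len(metrics)
    correct = [m for m in metrics if m.correct]
    counts: dict = {}
    for m in metrics:
        counts[m.K_hat] = counts.get(m.K_hat, 0) + 1

    def avg(attr: str):
        if not correct:
            return None
        return float(np.mean([getattr(m, attr) for m in correct]))

    return CellSummary(
        condition=condition,
        n_reps=n,
        accuracy=len(correct) / n,
        K_hat_counts=counts,
        mae_means=avg("mae_means"),
        mae_variances=avg("mae_variances"),
        mae_covariances=avg("mae_covariances"),
        n_correct=len(correct),
    )
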