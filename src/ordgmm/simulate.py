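"""Synthetic-data generation: mixture sampling and ordinal thresholding.

Continuous samples are drawn from a :class:`~ordgmm.design.MixtureDesign`.
Each variable can then be mapped onto ``c`` ordinal categories: the cut
points are ``c + 1`` equally spaced thresholds between the empirical 0.50%
and 99.50% quantiles of that variable, the 1% of observations outside the
quantile range on either side are clamped into the nearest category, and
each category is labelled by the midpoint of its interval.  Midpoint labels
keep the ordinal data on the scale of the latent continuous variable, so
estimated component parameters remain directly comparable to the
data-generating ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import MixtureDesign

__all__ = [
    "ContinuousSample",
    "OrdinalSample",
    "ThresholdSet",
    "sample_mixture",
    "compute_thresholds",
    "discretize",
]

#: Quantile levels bounding the categorisation grid.
LOWER_QUANTILE = 0.005
UPPER_QUANTILE = 0.995


@dataclass(frozen=True)
class ContinuousSample:
    """N x p continuous draws with their true component labels (1..K)."""

    values: np.ndarray
    labels: np.ndarray
    design: MixtureDesign
    seed: int

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class VariableThresholds:
    """Cut points and midpoint labels for one variable."""

    lower: float
    upper: float
    cuts: np.ndarray      # c + 1 equally spaced values from lower to upper
    midpoints: np.ndarray  # c interval midpoints

    @property
    def n_categories(self) -> int:
        return self.midpoints.size


@dataclass(frozen=True)
class ThresholdSet:
    """Per-variable thresholds for a whole sample."""

    variables: tuple  # tuple of VariableThresholds, length p

    @property
    def n_categories(self) -> int:
        return self.variables[0].n_categories


@dataclass(frozen=True)
class OrdinalSample:
    """N x p ordinal data on the midpoint scale.

    Every entry of column j is one of the ``c`` midpoints of that column's
    threshold set; true labels are carried over from the continuous sample.
    """

    values: np.ndarray
    labels: np.ndarray
    n_categories: int
    thresholds: ThresholdSet
    seed: int


def sample_mixture(design: MixtureDesign, N: int, seed) -> ContinuousSample:
    """Draw N observations from the mixture.

    Component membership is multinomial with the design weights; given the
    component, the observation is multivariate Gaussian.  Fully deterministic
    for a fixed ``seed`` (an int or anything ``numpy.random.default_rng``
    accepts).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    K, p = design.K, design.p
    labels = rng.choice(K, size=N, p=design.weights)
    z = rng.standard_normal((N, p))
    chols = np.linalg.cholesky(design.covariances)  # K x p x p
    values = design.means[labels] + np.einsum("nij,nj->ni", chols[labels], z)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return ContinuousSample(values=values, labels=labels + 1,
                            design=design, seed=int(seed_int))


def compute_thresholds(column: np.ndarray, c: int) -> VariableThresholds:
    """Equal-width cut points between the 0.5% and 99.5% empirical quantiles.

    Quantiles use the linear-interpolation convention; differences between
    quantile estimators are O(1/N) and immaterial at the sample sizes used
    here.
    """
    column = np.asarray(column, dtype=float).ravel()
    if column.size < 2:
        raise ValueError("need at least two observations")
    if c < 2:
        raise ValueError("need at least two categories")
    lower, upper = np.quantile(column, [LOWER_QUANTILE, UPPER_QUANTILE])
    if upper <= lower:
        raise ValueError("degenerate column: 0.5% and 99.5% quantiles coincide")
    cuts = np.linspace(lower, upper, c + 1)
    midpoints = 0.5 * (cuts[:-1] + cuts[1:])
    return VariableThresholds(lower=float(lower), upper=float(upper),
                              cuts=cuts, midpoints=midpoints)


def _map_column(column: np.ndarray, thr: VariableThresholds) -> np.ndarray:
    # Half-open intervals [cut_i, cut_{i+1}), last interval closed; values
    # outside the quantile range are clamped into the nearest category.
    idx = np.searchsorted(thr.cuts, column, side="right") - 1
    idx = np.clip(idx, 0, thr.n_categories - 1)
    return thr.midpoints[idx]


def discretize(sample: ContinuousSample, c: int) -> OrdinalSample:
    """Map a continuous sample to ``c`` ordinal categories per variable.

    Thresholds are computed from each column's own values (empirically, per
    simulated dataset), and every observation is replaced by the midpoint
    label of the category it falls in.  The mapping is monotone
    non-decreasing within each column.
    """
    per_var = tuple(
        compute_thresholds(sample.values[:, j], c) for j in range(sample.p)
    )
    mapped = np.column_stack(
        [_map_column(sample.values[:, j], per_var[j]) for j in range(sample.p)]
    )
    return OrdinalSample(
        values=mapped,
        labels=sample.labels,
        n_categories=c,
        thresholds=ThresholdSet(variables=per_var),
        seed=sample.seed,
    )
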