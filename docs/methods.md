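# Methods

`ordgmm` studies a simple but practically ubiquitous misspecification of
Gaussian mixture modelling: the data-generating process is a mixture of
multivariate Gaussians on a latent continuous scale, but the analyst only
observes each variable thresholded into `c` ordered categories. The package
implements the whole simulation pipeline — mixture design construction,
sampling, ordinal thresholding, EM estimation with BIC selection of the
number of components, and recovery scoring — so that the degradation of
recovery can be mapped as a function of the number of categories `c`, the
number of variables `p`, the number of components `K`, their separation,
and the sample size `N`.

## Data-generating designs

A design is a `K`-component Gaussian mixture in `p` dimensions with equal
mixing weights `1/K`. Component separation is controlled through the
pairwise Kullback–Leibler divergence: all `K(K-1)/2` pairs of components
are required to have the same divergence `D_KL ∈ {2, 3.5, 5}` (nats),
ranging from heavily overlapping to clearly separated. For equal spherical
covariances `σ²I` the divergence reduces to `‖μ_i − μ_j‖² / (2σ²)`, so
equidistance in KL is equidistance in Euclidean distance: the means are
placed on a regular `(K−1)`-simplex with edge `√(2σ²·D_KL)`, with
`σ² = √0.25 ≈ 0.5` shared by all components. The simplex is given a fresh
uniformly random rotation (QR decomposition of a Gaussian matrix, sign-fixed
to determinant +1) for every repetition, and its centroid is translated to
`(0.5, …, 0.5)`, which puts individual coordinates roughly in `[−0.5, 1.5]`
for the separations studied. Randomising the configuration anew in each
repetition ensures results are not tied to one particular orientation
relative to the (axis-aligned) discretisation grid.

Four means cannot be pairwise equidistant in the plane, so the `K=4, p=2`
design instead fixes the means on a square (side length solved jointly) and
gives each component its own covariance, parameterised through its Cholesky
factor, chosen by least squares so that all six pairwise *symmetrised* KL
divergences `(KL(i‖j)+KL(j‖i))/2` hit the target within `1e−4`. The
symmetrised form is used because it coincides exactly with the plain
divergence whenever covariances are equal — i.e. in every other design.
Twenty random restarts are allowed; in practice the first converges. The
solved configuration is randomly rotated about its centroid with the
covariances conjugated, which leaves all divergences unchanged.

## Ordinal thresholding

For each variable separately, the 0.5% and 99.5% empirical quantiles
(linear-interpolation estimator) of the simulated column bound a grid of
`c+1` equally spaced cut points; the 1% of observations outside the bounds
are clamped into the nearest end category. Categories are labelled by their
interval midpoints, which keeps the ordinal data on the latent scale so
that estimated component parameters are directly comparable to the
generating ones. Intervals are half-open on the right with the last
interval closed; ties on a cut have probability zero under continuous
sampling. Thresholds are always computed from the dataset at hand, not from
the known mixture distribution.

Within a repetition the same continuous sample is reused across all
category counts (the per-repetition random stream is keyed on everything
*except* `c`), so varying `c` isolates the discretisation effect rather
than adding fresh sampling noise.

## Estimation

EM is implemented directly (E-step responsibilities via log-sum-exp;
M-step weighted means and family-specific covariance updates) for three
covariance regimes:

* **shared spherical** — one variance pooled over all components and
  variables (`Σ_k = σ²I`), parameter count `Kp + 1 + (K−1)`;
* **component spherical** — one spherical variance per component
  (`Σ_k = σ_k²I`), count `K(p+1) + (K−1)`; this is the classical latent
  profile structure and the constrained family used for the headline
  reproductions;
* **full unconstrained** — a full SPD covariance per component, count
  `Kp + Kp(p+1)/2 + (K−1)`.

K=1 is the closed-form MLE. For K≥2, each fit runs `n_init` k-means-style
initialisations (k-means++ seeding plus a few Lloyd iterations, via
`scipy.cluster.vq.kmeans2`); every restart runs a short EM stage
(`short_iters` iterations at tolerance `short_tol`) and only the
highest-likelihood survivor is refined to full convergence (relative
log-likelihood change `< tol`, default `1e−8`, or `max_iter = 500`
iterations). The two-stage schedule preserves the EM ascent property —
refinement continues from the short-stage parameters — and cuts runtime
several-fold; on the study grid it reproduces the same BIC selections as
single-stage runs.

Degeneracy is handled explicitly and without any variance prior or ridge:
a covariance update whose smallest eigenvalue falls below `1e−10`, an
empty component, or a diverging log-likelihood marks that restart as
degenerate; if every restart degenerates, the fit for that K is recorded
as *failed* rather than raising. This matters substantively: with very few
categories the data concentrate on a handful of grid atoms, component
variances can collapse to zero with unbounded likelihood, and model
selection must be able to observe and exclude those candidates. Selection
maximises `BIC = 2ℓ − m·ln N` over `K ∈ {1,…,7}` among non-failed fits,
with ties broken toward smaller K; K=1 never fails, so a selection always
exists.

Cross-checks: the full-covariance family matches scikit-learn's
`GaussianMixture` log-likelihood to `1e−3` per observation on small
two-cluster instances, and the shared-spherical family matches the
R package mclust's `EII` model on the same kind of fixture; both serve as
independent oracles in the test suite only.

## Recovery scoring

Component labels are only identified up to permutation, so estimated
components are matched to generating ones by exhaustive enumeration of all
`K!` assignments, minimising the mean absolute difference between matched
mean vectors (means are what the designs vary; matching on all parameters
is available via configuration). Exact cost ties are possible with
absolute-value costs and are broken toward the lexicographically smallest
permutation within a relative `1e−9` epsilon. Mean absolute errors are then
reported separately for means (`K·p` entries), variances (`K·p` diagonal
entries) and covariances (`K·p(p−1)/2` off-diagonal entries), with a mean
squared variant available. Errors are only defined in repetitions whose
selected K equals the true K; cells in which no repetition selected the
true K are reported as missing. Accuracy is the fraction of repetitions
with the correct K.

## Grid orchestration and seeding

Every repetition derives its random state from a `numpy.random.SeedSequence`
keyed on `(base_seed, K, p, round(1000·D_KL), N, rep)`; the EM stream
additionally keys on `c` and the family. This makes runs parallel-safe and
resume-safe: the long-format results table is appended incrementally and
rerunning a partially completed grid reproduces exactly the table an
uninterrupted run would have produced. The full study grid is
`3 K × 9 p × 3 D_KL × 3 N × 12 c`-levels (including continuous) = 2916
conditions; summaries aggregate accuracy and parameter errors over `K` and
`D_KL` into `p × c` tables per `N` (unweighted across cells, which
coincides with pooling at equal repetition counts), rounded to two
decimals, as CSV plus heat-map PNGs.

## Choice of the constrained family

The constrained ("isomorphic", latent-profile) estimation family is
implemented in two variants because the two readings differ observably.
With a *pooled* variance the likelihood of few-category data stays bounded
for small K, and BIC on binary `c=2` data from a well-separated two-
component bivariate mixture selects K̂=3 — exactly what mclust's `EII`
model selects on the same data. With *per-component* variances (`VII`),
higher-K fits collapse with singular covariances on the four observable
atoms, and underestimation becomes possible. The per-component variant is
used for the headline reproductions, since its parameter count
`K(p+1)+(K−1)` is the count entering the BIC-penalty analysis and its
failure mechanism is the one that drives the binary-data collapse. Note
that on such atomic data the selected K is initialisation-sensitive:
k-means-style restarts can land on a non-degenerate K=2 local maximum
(components on the two high-mass diagonal atoms with positive variances)
that wins the BIC comparison, whereas hierarchical-agglomeration
initialisations tend to collapse every K>1 fit, leaving K̂=1. Both
outcomes are faithful descriptions of the same unbounded-likelihood
landscape; the package reports what its estimator computes.

## Problem sizes in tests and reproduction runs

The full study (2916 conditions × 100 repetitions) is cluster-scale. The
shipped reproduction protocols (`ordgmm.protocols`) fix `N = 10,000` and
use about ten seeded repetitions per cell — the headline-accuracy
protocols run ten repetitions for each of the nine `K × D_KL` cells at the
stated `(p, c)`; the parameter-error protocol pools one repetition of each
of the nine `K × D_KL` conditions per `(p, c)` cell. Protocol runs use a
verified faster engine configuration (`n_init=2`, `short_iters=40`,
`tol=1e−6`, `max_iter=200`) that reproduces the same selections as the
library defaults on the study grid. Reduced repetitions widen the
Monte-Carlo error of reported proportions (≈ ±0.1 at ten repetitions)
without changing their expectation.

## What the generator does and does not emulate

The generator reproduces the latent-Gaussian-with-thresholds mechanism:
equal mixing weights, shared spherical generating covariances (except
`K=4, p=2`), equidistant separations, equal-width thresholds between fixed
quantiles. Real ordinal data typically violate several of these
assumptions — unequal class sizes, non-spherical within-class covariances,
unequally spaced thresholds, response styles, measurement non-invariance —
all of which are expected to make recovery harder. Passing tests therefore
demonstrate the mechanics and the best-case behaviour of the estimator
chain, not performance guarantees for real survey or symptom data.

## Known limitations

* The `K=4, p=2` design's mean layout and covariance parameterisation are
  one valid solution of an under-determined problem; other configurations
  with the same pairwise divergences exist, so numerical identity with any
  particular published configuration is not claimed.
* On heavily discretised data the mixture likelihood is unbounded for
  K above the number of occupied atoms; reported selections there are
  estimator-dependent (see above) and should be read as qualitative.
* Matched-mean errors in this pipeline are small (≈0.01–0.03 at `c ≥ 5`,
  `p ≥ 4`, `N = 10,000`) because midpoint coding is nearly unbiased for
  component means at moderate `c`; large mean biases appear only in
  low-`p`, low-`c` cells where correct selection is rare.
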