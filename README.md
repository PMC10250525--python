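# ordgmm — Gaussian mixture recovery from ordinal data

Gaussian mixture models (GMMs) fitted by EM with BIC selection of the
number of components are a standard tool for finding latent subgroups in
multivariate continuous data. In medical, social and behavioural research,
however, the observed variables are very often *ordinal* — symptom-severity
stages, Likert items, graded diagnoses — i.e. a latent continuous variable
seen only through a handful of ordered categories. `ordgmm` is a simulation
laboratory for quantifying what that discretisation does to GMM recovery:
it generates mixtures with controlled component separation, thresholds
them into `c ∈ {2,…,12}` categories, refits GMMs, and scores whether the
number of components `K` and the component parameters are recovered.

It is aimed at methodologists studying model-based clustering under
misspecification, and at applied researchers who want to know whether
fitting a GMM (or latent profile analysis) to their ordinal data is
defensible for their `p`, `c` and `N`.

## The model and the pipeline

Data are drawn from a K-component mixture

&nbsp;&nbsp;&nbsp;&nbsp;x ~ Σₖ πₖ N(μₖ, Σₖ), πₖ = 1/K,

whose components are pairwise equidistant in Kullback–Leibler divergence
D_KL ∈ {2, 3.5, 5}. With shared spherical covariance σ²I (σ² = √0.25) the
means form a regular (K−1)-simplex with edge √(2σ²·D_KL), freshly randomly
rotated per repetition; for K=4 in p=2 dimensions — where no equidistant
mean placement exists — the component covariances are optimised instead.
Each variable is then mapped to `c` categories by equal-width cuts between
its 0.5% and 99.5% quantiles, labelled by interval midpoints so the
ordinal data stay on the latent scale. Estimation runs EM under spherical
covariance constraints (pooled or per-component variance) or fully
unconstrained covariances, selects K ∈ {1,…,7} by BIC = 2ℓ − m·ln N with
degenerate (singular-covariance) fits excluded, and scores recovery:
accuracy of K̂, and mean absolute parameter errors after exhaustively
matching estimated to true components over all K! permutations.

See `docs/methods.md` for the complete account.

## Worked example

Build a well-separated two-component design in three dimensions, draw
10,000 observations thresholded to five categories, and fit:

```sh
$ ordgmm design --k 2 --p 3 --kl 5 --seed 1 --out design.json
$ ordgmm simulate --design design.json --n 10000 --categories 5 --seed 2 --out ordinal.csv
$ ordgmm fit --data ordinal.csv --family component_spherical --seed 3
K,loglik,n_params,bic,failed,selected
1,-41594.96084252137,4,-83226.76304653064,False,False
2,-38330.884662320415,9,-76744.66238798862,False,True
3,-38312.325760676205,14,-76753.59628656007,False,False
4,-38309.385678141625,19,-76793.7678233508,False,False
5,-38276.680020597196,24,-76774.40821012182,False,False
6,-38269.762561023774,29,-76806.62499283486,False,False
7,-38252.845765158345,34,-76818.84310296387,False,False
selected K = 2
```

The BIC table shows the signature of successful recovery: the jump of
~6,500 BIC points from K=1 to the true K=2 dwarfs the small likelihood
gains of K≥3, which the parameter penalty (5 extra parameters per
component) converts into worse BIC scores — so the true K wins. With only
`c = 2` categories the same pipeline behaves qualitatively differently:
higher-K fits collapse onto the few observable grid atoms with singular
covariances and are excluded as failed.

Grid studies are driven by a YAML config:

```sh
$ ordgmm run-grid --config grid.yaml --seed 7 --reps 10
$ ordgmm summarize --results results/results.csv --out summaries/
```

which writes a long-format repetition table and per-`N` accuracy and
parameter-error tables/heat-maps over `p × c`, averaged over K and D_KL.

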