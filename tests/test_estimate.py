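"""EM fitting, parameter counts, BIC, and model selection."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from ordgmm.design import Condition, build_design
from ordgmm.estimate import (
    EMConfig,
    ModelFamily,
    bic,
    fit_em,
    n_params,
    select_k,
)
from ordgmm.simulate import discretize, sample_mixture
from ordgmm.evaluate import match_components, parameter_errors

FAST = EMConfig(n_init=3, max_iter=300, tol=1e-6, short_iters=60,
                short_tol=1e-5)


@pytest.fixture(scope="module")
def separated_sample():
    cond = Condition(K=2, p=3, target_kl=5.0, N=2000)
    design = build_design(cond, np.random.default_rng(8))
    return design, sample_mixture(design, 2000, 9).values


class TestNParams:
    @pytest.mark.parametrize(
        "family,K,p,expected",
        [
            (ModelFamily.SHARED_SPHERICAL, 1, 2, 3),
            (ModelFamily.SHARED_SPHERICAL, 2, 4, 10),
            (ModelFamily.COMPONENT_SPHERICAL, 2, 4, 11),  # K(p+1) + (K-1)
            (ModelFamily.COMPONENT_SPHERICAL, 3, 10, 35),
            (ModelFamily.FULL_UNCONSTRAINED, 2, 2, 11),
        ],
    )
    def test_direct_counts(self, family, K, p, expected):
        assert n_params(K, p, family) == expected

    def test_per_component_penalty_switch(self):
        assert n_params(3, 5, ModelFamily.SHARED_SPHERICAL,
                        variance_count="per_component") == 3 * 6 + 2


class TestBic:
    def test_arithmetic(self):
        assert bic(-100.0, 3, 1000) == pytest.approx(
            -200.0 - 3 * math.log(1000)
        )
        assert bic(-5.0, 0, 50) == -10.0

    def test_monotone_in_params(self):
        vals = [bic(-100.0, m, 500) for m in range(5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestFitEm:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(400, 3)) * [1.0, 2.0, 0.5]
        f = fit_em(X, 1, ModelFamily.SHARED_SPHERICAL)
        assert f.means[0] == pytest.approx(X.mean(axis=0))
        expected_var = np.sum((X - X.mean(axis=0)) ** 2) / (400 * 3)
        assert f.covariances[0][0, 0] == pytest.approx(expected_var)
        assert f.converged and not f.failed

    @pytest.mark.parametrize("family", list(ModelFamily))
    def test_loglik_trace_nondecreasing(self, separated_sample, family):
        _, X = separated_sample
        f = fit_em(X, 3, family, EMConfig(n_init=2, seed=4))
        trace = np.array(f.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * (1 + np.abs(trace[:-1])))

    def test_recovers_separated_means(self):
        cond = Condition(K=2, p=3, target_kl=5.0, N=10_000)
        design = build_design(cond, np.random.default_rng(2))
        X = sample_mixture(design, 10_000, 3).values
        f = fit_em(X, 2, ModelFamily.SHARED_SPHERICAL, FAST)
        perm = match_components(design, f)
        err = np.abs(f.means - design.means[list(perm)])
        assert np.max(err) < 0.05

    def test_deterministic_given_seed(self, separated_sample):
        _, X = separated_sample
        a = fit_em(X, 2, ModelFamily.SHARED_SPHERICAL, EMConfig(seed=5))
        b = fit_em(X, 2, ModelFamily.SHARED_SPHERICAL, EMConfig(seed=5))
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.means, b.means)

    def test_nested_families_order_logliks(self, separated_sample):
        _, X = separated_sample
        lls = {
            fam: fit_em(X, 2, fam, EMConfig(n_init=4, seed=1)).loglik
            for fam in ModelFamily
        }
        # richer covariance structures can only raise the maximum likelihood
        assert lls[ModelFamily.SHARED_SPHERICAL] <= (
            lls[ModelFamily.COMPONENT_SPHERICAL] + 1e-6
        )
        assert lls[ModelFamily.COMPONENT_SPHERICAL] <= (
            lls[ModelFamily.FULL_UNCONSTRAINED] + 1e-6
        )

    def test_binary_data_degenerates_for_large_k(self, rng):
        cond = Condition(K=2, p=2, target_kl=5.0, N=5000, n_categories=2)
        design = build_design(cond, rng)
        data = discretize(sample_mixture(design, 5000, 1), 2).values
        f = fit_em(data, 5, ModelFamily.COMPONENT_SPHERICAL,
                   EMConfig(n_init=5, seed=0))
        # five components cannot all sit on four atoms with positive variance
        assert f.failed
        assert f.fail_reason  # singular/empty/diverged, depending on path

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_em(X, 10, ModelFamily.SHARED_SPHERICAL)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_em(X, 2, ModelFamily.SHARED_SPHERICAL)


class TestReferenceOracles:
    def test_sklearn_full_family_loglik(self, rng):
        """Best-of-restarts log-likelihood matches scikit-learn's full-
        covariance GMM to 1e-3 per observation on small instances."""
        from sklearn.mixture import GaussianMixture

        for trial in range(10):
            # keep the clusters clearly separated so best-of-restarts finds
            # the same (global) maximum in both implementations
            direction = rng.normal(size=2)
            direction *= 3.0 / np.linalg.norm(direction)
            center = rng.normal(scale=0.5, size=2)
            X = np.concatenate([
                rng.normal(loc=center - direction / 2, scale=0.6,
                           size=(250, 2)),
                rng.normal(loc=center + direction / 2, scale=0.6,
                           size=(250, 2)),
            ])
            ours = fit_em(X, 2, ModelFamily.FULL_UNCONSTRAINED,
                          EMConfig(n_init=10, seed=trial, tol=1e-8))
            ref = GaussianMixture(
                n_components=2, covariance_type="full", n_init=10,
                random_state=trial, tol=1e-8, max_iter=500, reg_covar=0.0,
            ).fit(X)
            assert ours.loglik / len(X) == pytest.approx(
                ref.score(X), abs=1e-3
            )

    def test_mclust_shared_spherical_loglik(self, tmp_path, rng):
        """Shared-spherical EM matches mclust's EII model on a small
        two-cluster dataset (independent R implementation)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; mclust oracle cannot run")
        X = np.concatenate([
            rng.normal(loc=[-2, 0], scale=0.7, size=(300, 2)),
            rng.normal(loc=[2, 1], scale=0.7, size=(300, 2)),
        ])
        csv = tmp_path / "x.csv"
        np.savetxt(csv, X, delimiter=",")
        script = (
            'suppressMessages(library(mclust));'
            f'X <- as.matrix(read.csv("{csv}", header=FALSE));'
            'f <- Mclust(X, G=2, modelNames="EII", verbose=FALSE);'
            'cat(f$loglik)'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref_ll = float(out.stdout.strip().split()[-1])
        ours = fit_em(X, 2, ModelFamily.SHARED_SPHERICAL,
                      EMConfig(n_init=5, seed=0, tol=1e-8))
        assert ours.loglik / len(X) == pytest.approx(ref_ll / len(X),
                                                     abs=1e-3)


class TestSelectK:
    def test_single_gaussian_selects_one(self):
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10_000, 3))
            sel = select_k(X, ModelFamily.SHARED_SPHERICAL, config=FAST)
            hits += sel.K_hat == 1
        assert hits >= 5

    def test_separated_two_component_continuous(self):
        hits = 0
        for seed in range(6):
            cond = Condition(K=2, p=3, target_kl=5.0, N=10_000)
            design = build_design(cond, np.random.default_rng(100 + seed))
            X = sample_mixture(design, 10_000, 200 + seed).values
            cfg = EMConfig(n_init=3, max_iter=300, tol=1e-6, short_iters=60,
                           short_tol=1e-5, seed=seed)
            sel = select_k(X, ModelFamily.SHARED_SPHERICAL, config=cfg)
            hits += sel.K_hat == 2
        assert hits >= 5

    def test_failed_fits_excluded(self, rng):
        cond = Condition(K=2, p=2, target_kl=5.0, N=5000, n_categories=2)
        design = build_design(cond, rng)
        data = discretize(sample_mixture(design, 5000, 1), 2).values
        sel = select_k(data, ModelFamily.COMPONENT_SPHERICAL,
                       config=EMConfig(n_init=5, seed=0))
        assert any(f.failed for f in sel.fits)
        assert not sel.selected.failed
        assert sel.fits[0].K == 1 and not sel.fits[0].failed

    def test_parameter_error_shrinks_with_n(self):
        errs = {}
        for N in (1000, 100_000):
            vals = []
            for seed in range(5):
                cond = Condition(K=2, p=2, target_kl=5.0, N=N)
                design = build_design(cond, np.random.default_rng(30 + seed))
                X = sample_mixture(design, N, 40 + seed).values
                f = fit_em(X, 2, ModelFamily.SHARED_SPHERICAL,
                           EMConfig(n_init=3, seed=seed, tol=1e-8))
                perm = match_components(design, f)
                vals.append(parameter_errors(design, f, perm)[0])
            errs[N] = np.median(vals)
        assert errs[100_000] < errs[1000]
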