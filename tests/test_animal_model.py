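import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from coturnix.animal_model import (
    ChainConfig,
    DesignMatrices,
    ModelSpec,
    build_design,
    gibbs_sample,
    retained_sample_count,
)
from coturnix.flock import FlockConfig, simulate_flock, simulate_pedigree
from coturnix.pedigree import a_inverse
from coturnix.posterior import heritability


@pytest.fixture(scope="module")
def small_flock():
    cfg = FlockConfig(n_sires=10, n_dams=30, n_offspring=200, seed=8)
    return simulate_flock(cfg)


@pytest.fixture(scope="module")
def small_run(small_flock):
    spec = ModelSpec(traits=("BW5", "BW6"))
    design = build_design(small_flock.phenotypes, small_flock.pedigree, spec)
    Ainv = a_inverse(small_flock.pedigree)
    chain = ChainConfig(n_iterations=3000, burn_in=500, thin=5, seed=1)
    return design, Ainv, spec, chain


class TestChainBookkeeping:
    def test_reference_configuration_retains_2000(self):
        cfg = ChainConfig(n_iterations=110_000, burn_in=10_000, thin=50)
        assert retained_sample_count(cfg) == 2000

    def test_trivial_configuration(self):
        assert retained_sample_count(ChainConfig(100, 0, 1)) == 100

    def test_floor_with_warning_when_not_exact(self):
        # exact division is silent
        assert retained_sample_count(ChainConfig(105, 5, 10)) == 10
        with pytest.warns(UserWarning, match="not divisible"):
            assert retained_sample_count(ChainConfig(103, 5, 10)) == 9

    def test_invalid_burn_in_raises(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iterations=100, burn_in=100, thin=1)


class TestBuildDesign:
    def test_default_flock_dimensions(self, small_flock):
        spec = ModelSpec(traits=("BW5", "BW6"))
        d = build_design(small_flock.phenotypes, small_flock.pedigree, spec)
        assert d.y.shape == (200, 2)
        assert d.X.shape == (200, 2)  # intercept + sex
        assert d.n_pedigree == 240
        assert d.animal_index.max() < 240

    def test_missing_records_dropped_listwise(self, small_flock):
        phen = small_flock.phenotypes.copy()
        phen.loc[phen.index[:10], "BW5"] = np.nan
        spec = ModelSpec(traits=("BW5", "BW6"))
        d = build_design(phen, small_flock.pedigree, spec)
        assert d.y.shape[0] == 190

    def test_single_animal_intercept_only(self, small_flock):
        phen = small_flock.phenotypes.iloc[:1]
        spec = ModelSpec(traits=("BW5",), fixed_effects=("intercept",))
        d = build_design(phen, small_flock.pedigree, spec)
        assert d.X.shape == (1, 1)
        assert np.all(d.X == 1.0)

    def test_single_sex_level_drops_factor_with_warning(self, small_flock):
        phen = small_flock.phenotypes[small_flock.phenotypes.sex == "F"]
        spec = ModelSpec(traits=("BW5",))
        with pytest.warns(UserWarning, match="single level"):
            d = build_design(phen, small_flock.pedigree, spec)
        assert d.fixed_names == ("intercept",)

    def test_unknown_animal_raises(self, small_flock):
        phen = small_flock.phenotypes.copy()
        phen.loc[phen.index[0], "id"] = 99_999
        with pytest.raises(ValueError, match="absent from pedigree"):
            build_design(phen, small_flock.pedigree, ModelSpec(traits=("BW5",)))

    def test_all_missing_trait_raises(self, small_flock):
        phen = small_flock.phenotypes.copy()
        phen["BW5"] = np.nan
        with pytest.raises(ValueError, match="all records missing"):
            build_design(phen, small_flock.pedigree, ModelSpec(traits=("BW5", "BW6")))


class TestGibbsSampler:
    def test_reproducible_given_seed(self, small_run):
        design, Ainv, spec, chain = small_run
        a = gibbs_sample(design, Ainv, spec, chain)
        b = gibbs_sample(design, Ainv, spec, chain)
        assert np.array_equal(a.g0, b.g0)
        assert np.array_equal(a.r0, b.r0)
        assert np.array_equal(a.beta, b.beta)

    def test_different_seeds_differ(self, small_run):
        design, Ainv, spec, chain = small_run
        a = gibbs_sample(design, Ainv, spec, chain)
        b = gibbs_sample(
            design, Ainv, spec,
            ChainConfig(chain.n_iterations, chain.burn_in, chain.thin, seed=2),
        )
        assert not np.allclose(a.g0, b.g0)

    def test_every_stored_matrix_positive_definite(self, small_run):
        design, Ainv, spec, chain = small_run
        post = gibbs_sample(design, Ainv, spec, chain)
        for M in (post.g0, post.r0):
            eig = np.linalg.eigvalsh(M)
            assert np.all(eig > 0)

    def test_permutation_invariance_of_posterior_means(self, small_flock):
        spec = ModelSpec(traits=("BW5", "BW6"))
        chain = ChainConfig(n_iterations=4000, burn_in=1000, thin=3, seed=5)
        Ainv = a_inverse(small_flock.pedigree)
        d1 = build_design(small_flock.phenotypes, small_flock.pedigree, spec)
        shuffled = small_flock.phenotypes.sample(frac=1.0, random_state=0)
        d2 = build_design(shuffled, small_flock.pedigree, spec)
        h1 = heritability(*_gr(gibbs_sample(d1, Ainv, spec, chain)), 0)
        h2 = heritability(*_gr(gibbs_sample(d2, Ainv, spec, chain)), 0)
        assert h1.mean() == pytest.approx(h2.mean(), abs=0.05)

    def test_prior_recovery_with_zero_records(self):
        """Stationary marginals of (G0, R0) with no data reproduce the
        inverse-Wishart priors (first-moment check)."""
        ped = simulate_pedigree(FlockConfig(n_sires=4, n_dams=8, n_offspring=20, seed=1))
        k, nu = 2, 7.0
        V = np.array([[2.0, 0.5], [0.5, 1.0]])
        spec = ModelSpec(
            traits=("a", "b"), fixed_effects=("intercept",),
            prior_g=(nu, V), prior_r=(nu, V),
        )
        design = DesignMatrices(
            y=np.empty((0, k)), X=np.empty((0, 1)),
            animal_index=np.empty(0, dtype=np.int64),
            trait_names=("a", "b"), fixed_names=("intercept",),
            n_pedigree=ped.n_animals,
        )
        post = gibbs_sample(design, a_inverse(ped), spec, ChainConfig(20000, 2000, 3, seed=4))
        expected = V / (nu - k - 1)
        assert np.allclose(post.g0.mean(axis=0), expected, rtol=0.1, atol=0.05)
        assert np.allclose(post.r0.mean(axis=0), expected, rtol=0.1, atol=0.05)

    def test_conjugate_reduction_matches_scaled_inv_chi2(self):
        """Without the genetic effect the model is Bayesian regression:
        sigma2_e | y is exactly scaled-inverse-chi-square and the sampled
        marginal must match it (KS distance < 0.05 at 2000 samples)."""
        rng = np.random.default_rng(11)
        n = 200
        y = 5.0 + 2.0 * rng.standard_normal(n)
        nu, V = 3.0, np.array([[4.0]])
        spec = ModelSpec(
            traits=("y",), fixed_effects=("intercept",),
            prior_g=(nu, V), prior_r=(nu, V),
        )
        design = DesignMatrices(
            y=y[:, None], X=np.ones((n, 1)),
            animal_index=np.zeros(n, dtype=np.int64),
            trait_names=("y",), fixed_names=("intercept",), n_pedigree=0,
        )
        post = gibbs_sample(design, None, spec, ChainConfig(11000, 1000, 5, seed=3))
        ssr = np.sum((y - y.mean()) ** 2)
        analytic = st.invgamma((nu + n - 1) / 2.0, scale=(V[0, 0] + ssr) / 2.0)
        ks = st.kstest(post.r0[:, 0, 0], analytic.cdf)
        assert ks.statistic < 0.05

    def test_matches_exact_grid_posterior_single_trait(self):
        """Independent oracle: for a small single-trait flock, integrate
        beta and u analytically and evaluate the exact joint posterior of
        (sigma2_a, sigma2_e) on a grid; the Gibbs posterior mean and SD
        of h2 must agree with the grid values."""
        from coturnix.pedigree import relationship_matrix

        cfg = FlockConfig(
            seed=2, n_sires=6, n_dams=18, n_offspring=80, trait_names=("BW6",)
        )
        data = simulate_flock(cfg)
        nu, V = 2.0, np.array([[200.0]])
        spec = ModelSpec(traits=("BW6",), prior_g=(nu, V), prior_r=(nu, V))
        design = build_design(data.phenotypes, data.pedigree, spec)
        post = gibbs_sample(
            design, a_inverse(data.pedigree), spec,
            ChainConfig(60000, 4000, 4, seed=1),
        )
        h2_gibbs = heritability(post.g0, post.r0, 0)

        A = relationship_matrix(data.pedigree)
        y = design.y[:, 0]
        X = design.X
        n = len(y)
        ZAZ = A[np.ix_(design.animal_index, design.animal_index)]

        def log_post(va, ve):
            Vm = va * ZAZ + ve * np.eye(n)
            Lc = np.linalg.cholesky(Vm)
            XtVi = np.linalg.solve(Vm, X)
            XtViX = X.T @ XtVi
            beta_hat = np.linalg.solve(XtViX, XtVi.T @ y)
            r = y - X @ beta_hat
            quad = r @ np.linalg.solve(Vm, r)
            ld = 2 * np.sum(np.log(np.diag(Lc)))
            _, ld2 = np.linalg.slogdet(XtViX)
            lp = (
                -(nu / 2 + 1) * np.log(va) - V[0, 0] / (2 * va)
                - (nu / 2 + 1) * np.log(ve) - V[0, 0] / (2 * ve)
            )
            return -0.5 * (ld + ld2 + quad) + lp

        vas = np.linspace(5, 1200, 70)
        ves = np.linspace(5, 800, 70)
        lg = np.array([[log_post(a, b) for b in ves] for a in vas])
        w = np.exp(lg - lg.max())
        w /= w.sum()
        VA, VE = np.meshgrid(vas, ves, indexing="ij")
        h2_grid = VA / (VA + VE)
        e_grid = (w * h2_grid).sum()
        sd_grid = np.sqrt((w * h2_grid**2).sum() - e_grid**2)
        assert h2_gibbs.mean() == pytest.approx(e_grid, abs=0.02)
        assert h2_gibbs.std() == pytest.approx(sd_grid, abs=0.02)

    def test_non_finite_y_raises(self, small_flock):
        spec = ModelSpec(traits=("BW5",))
        phen = small_flock.phenotypes.copy()
        phen.loc[phen.index[0], "BW5"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            build_design(phen, small_flock.pedigree, spec)
        d = build_design(small_flock.phenotypes, small_flock.pedigree, spec)
        d.y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            gibbs_sample(
                d, a_inverse(small_flock.pedigree), spec,
                ChainConfig(100, 10, 1, seed=0),
            )


def _gr(post):
    return post.g0, post.r0
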