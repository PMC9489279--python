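"""Design construction, sampler correctness, summaries, DIC, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from orsay_hostrange import trees
from orsay_hostrange.pmm import (
    ChainSettings,
    ModelSpec,
    PhylogeneticMixedModel,
    build_design,
    compute_dic,
    drop_unplaced_species,
    heidelberger_welch,
    pmcmc,
    sample_posterior,
    summarize_fit,
)
from orsay_hostrange.pmm.sampler import PosteriorSamples, gaussian_deviance
from orsay_hostrange.simulate import SimulationConfig, simulate_susceptibility, simulate_yule_tree


def gaussian_data(n=10, seed=0, beta=(1.5, 2.0), sigma=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = beta[0] + beta[1] * x + rng.normal(scale=sigma, size=n)
    return pd.DataFrame(
        {"species": ["s"] * n, "strain": [f"st{i}" for i in range(n)], "x": x, "score": y}
    )


class TestDesign:
    def test_intercept_only(self):
        data = gaussian_data(5)
        design = build_design(data, ModelSpec(response="gaussian"))
        np.testing.assert_array_equal(design.X, np.ones((5, 1)))
        assert design.fixed_names == ["intercept"]
        assert design.terms == []

    def test_phylo_incidence(self):
        tree = trees.parse_newick("((A:1,B:1):1,C:2);")
        rel = trees.relatedness_matrix(tree)
        data = pd.DataFrame(
            {
                "species": ["A", "A", "B", "B", "C", "C"],
                "strain": [f"st{i}" for i in range(6)],
                "n_infected": [1] * 6,
                "n_replicates": [3] * 6,
            }
        )
        design = build_design(
            data, ModelSpec(response="binomial", random=("phylo",)), rel
        )
        Z = design.terms[0].Z
        assert Z.shape == (6, 3)
        np.testing.assert_array_equal(Z.sum(axis=1), np.ones(6))
        np.testing.assert_array_equal(Z.sum(axis=0), [2, 2, 2])

    def test_linear_predictor_matches_generator_truth(self):
        tree = simulate_yule_tree(15, seed=4)
        cfg = SimulationConfig(seed=4, n_species=15, strains_per_species=1)
        obs, truth = simulate_susceptibility(tree, cfg)
        rel = trees.relatedness_matrix(tree)
        design = build_design(
            obs,
            ModelSpec(response="binomial", fixed=("focal_distance",), random=("phylo", "species")),
            rel,
        )
        beta = np.array([truth["beta0"], truth["beta1"]])
        u_phylo = np.array([truth["u_phylo"][sp] for sp in rel.taxon_order])
        u_species = np.array([truth["u_species"][sp] for sp in design.terms[1].levels])
        eta = design.linear_predictor(beta, {"phylo": u_phylo, "species": u_species})
        expected = np.array([truth["liability"][s] for s in obs["strain"]])
        resid = expected - eta  # the remaining strain-level residual draw
        assert np.var(resid) < 4 * cfg.sigma2_residual
        assert np.corrcoef(eta, expected)[0, 1] > 0.5

    def test_species_off_tree_rejected_and_droppable(self):
        tree = trees.parse_newick("(A:1,B:1);")
        rel = trees.relatedness_matrix(tree)
        data = pd.DataFrame(
            {
                "species": ["A", "X"],
                "strain": ["s1", "s2"],
                "n_infected": [1, 1],
                "n_replicates": [3, 3],
            }
        )
        with pytest.raises(ValueError, match="X"):
            build_design(data, ModelSpec(response="binomial", random=("phylo",)), rel)
        kept = drop_unplaced_species(data, rel)
        assert list(kept["species"]) == ["A"]


class TestGaussianSampler:
    def test_matches_conjugate_posterior(self):
        """Fixed effects only with known residual variance: the posterior of
        beta has a closed form that the chain must reproduce."""
        data = gaussian_data(n=10, seed=1)
        design = build_design(data, ModelSpec(response="gaussian", fixed=("x",)))
        sigma2 = 1.0
        samples = sample_posterior(
            design,
            chain=ChainSettings(22000, 2000, 2, seed=3),
            fix_residual_variance=sigma2,
        )
        X, y = design.X, design.y
        prior_prec = np.eye(2) / 1e8
        post_cov = np.linalg.inv(X.T @ X / sigma2 + prior_prec)
        post_mean = post_cov @ (X.T @ y / sigma2)
        S = samples.n_stored
        for j in range(2):
            mc_se = samples.fixed_effects[:, j].std() / np.sqrt(S / 20)  # conservative ESS
            assert abs(samples.fixed_effects[:, j].mean() - post_mean[j]) < 3 * mc_se
        emp_cov = np.cov(samples.fixed_effects.T)
        np.testing.assert_allclose(emp_cov, post_cov, rtol=0.2, atol=0.02)

    def test_variance_component_sum_identified_with_identity_A(self):
        """With A = I the phylo and species terms are exchangeable; their sum
        should match a single-term fit's variance within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        n_sp = 30
        species = [f"s{i}" for i in range(n_sp)]
        u = rng.normal(scale=np.sqrt(2.0), size=n_sp)
        data = pd.DataFrame(
            {
                "species": np.repeat(species, 2),
                "strain": [f"s{i}_r{j}" for i in range(n_sp) for j in range(2)],
                "score": np.repeat(u, 2) + rng.normal(scale=0.5, size=2 * n_sp),
            }
        )
        star = trees.parse_newick("(" + ",".join(f"{s}:1" for s in species) + ");")
        rel = trees.relatedness_matrix(star)  # A = I on a star tree
        np.testing.assert_allclose(rel.A, np.eye(n_sp))
        both = sample_posterior(
            build_design(data, ModelSpec(response="gaussian", random=("phylo", "species")), rel),
            chain=ChainSettings(12000, 2000, 10, seed=6),
        )
        single = sample_posterior(
            build_design(data, ModelSpec(response="gaussian", random=("species",))),
            chain=ChainSettings(12000, 2000, 10, seed=7),
        )
        total_both = (
            both.variance_components["phylo"] + both.variance_components["species"]
        ).mean()
        total_single = single.variance_components["species"].mean()
        assert total_both == pytest.approx(total_single, rel=0.5)


@pytest.fixture(scope="module")
def binomial_fit():
    tree = simulate_yule_tree(30, seed=21)
    cfg = SimulationConfig(seed=21, n_species=30, strains_per_species=2)
    obs, truth = simulate_susceptibility(tree, cfg)
    rel = trees.relatedness_matrix(tree)
    design = build_design(
        obs,
        ModelSpec(response="binomial", fixed=("focal_distance",), random=("phylo", "species")),
        rel,
    )
    samples = sample_posterior(
        design, chain=ChainSettings(8000, 2000, 6, seed=22), fix_residual_variance=1.0
    )
    return design, samples


class TestBinomialSampler:

    def test_mh_acceptance_in_band(self, binomial_fit):
        _, samples = binomial_fit
        assert 0.2 <= samples.meta["mh_acceptance_rate"] <= 0.7

    def test_variances_positive_and_finite(self, binomial_fit):
        _, samples = binomial_fit
        for draws in samples.variance_components.values():
            assert np.all(draws > 0)
            assert np.all(np.isfinite(draws))

    def test_tiny_alpha_v_kills_variance_component(self):
        """alpha_V -> 0 degenerates the parameter-expanded prior, forcing the
        phylogenetic variance to zero."""
        from orsay_hostrange.pmm import PriorSpec

        tree = simulate_yule_tree(15, seed=30)
        cfg = SimulationConfig(seed=30, n_species=15, strains_per_species=2)
        obs, _ = simulate_susceptibility(tree, cfg)
        rel = trees.relatedness_matrix(tree)
        design = build_design(
            obs, ModelSpec(response="binomial", random=("phylo",)), rel
        )
        wide = sample_posterior(
            design, chain=ChainSettings(4000, 1000, 3, seed=31), fix_residual_variance=1.0
        )
        narrow = sample_posterior(
            design,
            priors=PriorSpec(alpha_V=1e-10),
            chain=ChainSettings(4000, 1000, 3, seed=31),
            fix_residual_variance=1.0,
        )
        assert narrow.variance_components["phylo"].mean() < 1e-6
        assert narrow.variance_components["phylo"].mean() < wide.variance_components["phylo"].mean()

    def test_branch_length_doubling_halves_phylo_variance(self):
        """A scales linearly with branch lengths, so sigma2_p must compensate
        by half while fitted liabilities stay statistically unchanged."""
        tree = simulate_yule_tree(30, seed=33)
        cfg = SimulationConfig(seed=33, n_species=30, strains_per_species=2,
                               sigma2_phylo=2.0, sigma2_species=0.0)
        obs, _ = simulate_susceptibility(tree, cfg)
        rel1 = trees.relatedness_matrix(tree)
        doubled = trees.parse_newick(
            tree.newick()
        )
        # scale all branch lengths by 2 via a rescaled relatedness structure
        rel2 = trees.RelatednessStructure(
            taxon_order=rel1.taxon_order, A=2 * rel1.A, A_inv=rel1.A_inv / 2, height=2 * rel1.height
        )
        spec = ModelSpec(response="binomial", fixed=("focal_distance",), random=("phylo",))
        s1 = sample_posterior(
            build_design(obs, spec, rel1),
            chain=ChainSettings(8000, 2000, 6, seed=34),
            fix_residual_variance=1.0,
        )
        s2 = sample_posterior(
            build_design(obs, spec, rel2),
            chain=ChainSettings(8000, 2000, 6, seed=34),
            fix_residual_variance=1.0,
        )
        ratio = s2.variance_components["phylo"].mean() / s1.variance_components["phylo"].mean()
        assert 0.3 < ratio < 0.7
        from scipy.special import expit

        p1 = expit(s1.latent_liabilities).mean(axis=0)
        p2 = expit(s2.latent_liabilities).mean(axis=0)
        assert np.corrcoef(p1, p2)[0, 1] > 0.9


class TestSummary:
    def make_samples(self, draws):
        draws = np.asarray(draws, dtype=float)[:, None]
        S = draws.shape[0]
        return PosteriorSamples(
            fixed_names=["intercept"],
            fixed_effects=draws,
            variance_components={},
            residual_variance=np.ones(S),
            deviance=np.ones(S),
            latent_liabilities=None,
            mean_fitted=np.zeros(1),
        )

    def test_mean_and_too_few_draws(self):
        samples = self.make_samples(np.linspace(1, 3, 150))
        summary = summarize_fit(samples)
        assert summary.fixed.loc["intercept", "mean"] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            summarize_fit(self.make_samples([1.0, 2.0, 3.0]))

    def test_pmcmc_conventions(self):
        assert pmcmc(np.ones(1000)) == pytest.approx(0.002)
        rng = np.random.default_rng(0)
        sym = rng.standard_normal(2000)
        assert pmcmc(sym) > 0.9
        assert 0 < pmcmc(np.array([1.0] * 999 + [-1.0])) <= 1

    def test_hpd_bounds_ordered(self):
        rng = np.random.default_rng(1)
        samples = self.make_samples(rng.gamma(2.0, size=500))
        summary = summarize_fit(samples)
        assert summary.fixed.loc["intercept", "ci_low"] < summary.fixed.loc["intercept", "ci_high"]

    def test_summaries_deterministic(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(400)
        a = summarize_fit(self.make_samples(draws)).fixed
        b = summarize_fit(self.make_samples(draws)).fixed
        pd.testing.assert_frame_equal(a, b)


class TestDic:
    def test_identical_draws_give_zero_pd(self):
        n = 4
        y = np.array([0.0, 1.0, 2.0, 3.0])
        data = pd.DataFrame(
            {"species": ["s"] * n, "strain": list("abcd"), "score": y}
        )
        design = build_design(data, ModelSpec(response="gaussian"))
        mu = np.zeros(n)
        dev = gaussian_deviance(y, mu, 1.0)
        S = 10
        samples = PosteriorSamples(
            fixed_names=["intercept"],
            fixed_effects=np.zeros((S, 1)),
            variance_components={},
            residual_variance=np.ones(S),
            deviance=np.full(S, dev),
            latent_liabilities=None,
            mean_fitted=mu,
        )
        assert compute_dic(samples, design) == pytest.approx(dev)

    def test_closed_form_gaussian_deviance(self):
        # beta = 0, sigma2 = 1: D = sum(log(2 pi) + y^2)
        y = np.array([0.0, 1.0])
        assert gaussian_deviance(y, np.zeros(2), 1.0) == pytest.approx(
            float(np.sum(np.log(2 * np.pi) + y**2))
        )

    def test_dic_prefers_generating_covariate(self):
        """Adding the true covariate should lower DIC in nearly all replicates."""
        wins = 0
        R = 20
        for r in range(R):
            rng = np.random.default_rng(100 + r)
            n = 120
            x = rng.normal(size=n)
            y = 0.5 - 2.0 * x + rng.normal(size=n)
            data = pd.DataFrame(
                {"species": ["s"] * n, "strain": [f"t{i}" for i in range(n)], "x": x, "score": y}
            )
            with_x = sample_posterior(
                build_design(data, ModelSpec(response="gaussian", fixed=("x",))),
                chain=ChainSettings(3000, 500, 5, seed=200 + r),
            )
            without = sample_posterior(
                build_design(data, ModelSpec(response="gaussian")),
                chain=ChainSettings(3000, 500, 5, seed=300 + r),
            )
            d1 = compute_dic(with_x, build_design(data, ModelSpec(response="gaussian", fixed=("x",))))
            d0 = compute_dic(without, build_design(data, ModelSpec(response="gaussian")))
            wins += d1 < d0
        assert wins >= int(0.95 * R)

    def test_too_few_draws(self):
        data = gaussian_data(4)
        design = build_design(data, ModelSpec(response="gaussian"))
        samples = PosteriorSamples(
            fixed_names=["intercept"],
            fixed_effects=np.zeros((1, 1)),
            variance_components={},
            residual_variance=np.ones(1),
            deviance=np.ones(1),
            latent_liabilities=None,
            mean_fitted=np.zeros(4),
        )
        with pytest.raises(ValueError):
            compute_dic(samples, design)


class TestStationarity:
    def test_iid_passes(self):
        rng = np.random.default_rng(11)
        assert heidelberger_welch(rng.standard_normal(1000)).passed

    def test_monotone_trend_fails(self):
        assert not heidelberger_welch(np.arange(1, 1001, dtype=float)).passed

    def test_constant_chain_fails_with_message(self):
        result = heidelberger_welch(np.ones(200))
        assert not result.passed
        assert "degenerate" in result.message

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(600)
        a = heidelberger_welch(x)
        b = heidelberger_welch(-4.0 * x + 17.0)
        assert a.passed == b.passed
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-6)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            heidelberger_welch(np.arange(50.0))


class TestEstimator:
    def test_fit_attributes_and_determinism(self):
        tree = simulate_yule_tree(12, seed=50)
        cfg = SimulationConfig(seed=50, n_species=12, strains_per_species=2)
        obs, _ = simulate_susceptibility(tree, cfg)
        rel = trees.relatedness_matrix(tree)
        model = PhylogeneticMixedModel(
            response="binomial",
            fixed=("focal_distance",),
            random=("phylo", "species"),
            n_iterations=3000,
            burn_in=600,
            thin=4,
            seed=9,
            fix_residual_variance=1.0,
        )
        model.fit(obs, rel=rel)
        assert model.samples_.n_stored == 600
        assert np.isfinite(model.dic_)
        assert set(model.summary_.fixed.index) == {"intercept", "focal_distance"}
        probs = model.predict()
        assert probs.shape == (len(obs),)
        assert np.all((probs >= 0) & (probs <= 1))
        # bit-reproducible given the seed
        again = PhylogeneticMixedModel(**model.get_params()).fit(obs, rel=rel)
        np.testing.assert_array_equal(model.samples_.fixed_effects, again.samples_.fixed_effects)
        assert model.dic_ == again.dic_

    def test_get_set_params_roundtrip(self):
        model = PhylogeneticMixedModel(response="gaussian", seed=3)
        params = model.get_params()
        assert params["seed"] == 3
        model.set_params(seed=4)
        assert model.seed == 4
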