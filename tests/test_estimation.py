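"""Estimation machinery: PSRF, classifiers, marginal likelihood/BIC, small fits."""

import warnings

import numpy as np
import pytest

from ersmix import (
    ClassSpec,
    ItemParameters,
    McmcConfig,
    ModelSpec,
    PriorSpec,
    SimulationDesign,
    bic,
    classify,
    fit,
    marginal_loglik,
    naive_ers_classify,
    psrf,
    psrf_univariate,
    simulate_dataset,
)

from conftest import oracle_category_probs


class TestPsrf:
    def test_identical_chains_are_converged(self, rng):
        draws = rng.normal(size=(400, 3))
        val = psrf(np.stack([draws, draws]))
        assert 0.95 < val < 1.001

    def test_disjoint_chains_diverge(self, rng):
        a = rng.normal(size=(200, 2))
        b = rng.normal(size=(200, 2)) + 50.0
        assert psrf(np.stack([a, b])) > 10

    def test_matches_brute_force_between_within_computation(self, rng):
        chains = rng.normal(size=(2, 60, 3)) + rng.normal(size=(2, 1, 3))
        m, n, p = chains.shape
        means = chains.mean(axis=1)
        W = sum(np.cov(chains[j].T, ddof=1) for j in range(m)) / m
        Bn = np.cov(means.T, ddof=1)
        lam = np.linalg.eigvals(np.linalg.solve(W, Bn)).real.max()
        expected = (n - 1) / n + (m + 1) / m * lam
        assert np.isclose(psrf(chains), expected, atol=1e-6)

    def test_univariate_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.normal(size=(3, 500, 2))
        mine = psrf_univariate(chains)
        ref = az.rhat(az.convert_to_dataset(chains)).x.values
        assert np.allclose(mine, ref, atol=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((1, 10, 2)))


class TestClassifiers:
    def test_modal_membership(self):
        probs = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1]])
        assert classify(probs).tolist() == [0, 1]

    def test_ties_go_to_normal(self):
        probs = np.array([[0.5, 0.5, 0.0]])
        assert classify(probs).tolist() == [0]

    def test_naive_wald_rule(self):
        assert naive_ers_classify(1.0, 0.1) == 0
        assert naive_ers_classify(0.7, 0.1) == 1  # statistic -3.0 -> ERS
        assert naive_ers_classify(1.3, 0.2) == 0  # statistic 1.5 inside +-1.96
        assert naive_ers_classify(1.5, 0.2) == 2  # statistic 2.5 -> MRS

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            naive_ers_classify(1.0, 0.0)


def brute_force_marginal_loglik(y, items, classes, n_quad=15):
    """Plain-loop quadrature oracle for the observed-data log-likelihood."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    N, I = y.shape
    total = 0.0
    for n in range(N):
        like = 0.0
        for g in range(classes.n_classes):
            if g == 0 and classes.n_classes > 1:
                om_pairs = [(1.0, 1.0)]
            else:
                om_pairs = [
                    (np.exp(classes.omega_logmean[g] + np.sqrt(2 * classes.omega_logvar[g]) * t),
                     w / np.sqrt(np.pi))
                    for t, w in zip(nodes, weights)
                ]
            gsum = 0.0
            for om, ow in om_pairs:
                for t, w in zip(nodes, weights):
                    th = classes.theta_mean[g] + np.sqrt(2 * classes.theta_var[g]) * t
                    prob = 1.0
                    for i in range(I):
                        p = oracle_category_probs(
                            th, items.alpha1[i], items.beta[g, i], items.tau[i], weight=om
                        )
                        prob *= p[y[n, i]]
                    gsum += ow * (w / np.sqrt(np.pi)) * prob
            like += classes.mixing[g] * gsum
        total += np.log(like)
    return total


@pytest.fixture(scope="module")
def toy():
    items = ItemParameters(
        alpha1=[1.1, 0.8],
        beta=[[0.3, -0.3], [0.8, -0.8]],
        tau=[[-0.5, 0.0, 0.5], [-0.4, 0.1, 0.3]],
    )
    classes = ClassSpec(
        mixing=[0.6, 0.4],
        theta_mean=[0.0, 0.2],
        theta_var=[1.0, 0.8],
        omega_logmean=[0.0, -0.9],
        omega_logvar=[0.0, 0.2],
    )
    y = np.array([[0, 3], [2, 1], [3, 3]])
    return y, items, classes


class TestMarginalLikelihoodAndBic:
    def test_matches_brute_force_quadrature(self, toy):
        y, items, classes = toy
        mine = marginal_loglik(y, items, classes, n_quad=15)
        ref = brute_force_marginal_loglik(y, items, classes, n_quad=15)
        assert np.isclose(mine, ref, atol=1e-6)

    def test_free_parameter_counts(self):
        I, J = 20, 4
        gpcm = ModelSpec(family="gpcm", n_categories=J)
        assert gpcm.n_free_parameters(I) == 20 + 19 + 40
        ers = ModelSpec(family="ers-gpcm", n_categories=J)
        assert ers.n_free_parameters(I) == gpcm.n_free_parameters(I) + 1
        mix = ModelSpec(family="mix-ers-gpcm", n_classes=3, n_categories=J)
        assert mix.n_free_parameters(I) == 20 + 3 * 19 + 40 + 2 * 4 + 2
        cd = ModelSpec(family="mix-ers-gpcm-cd", n_classes=3, n_categories=J)
        assert cd.n_free_parameters(I) == mix.n_free_parameters(I) + 1
        pcm = ModelSpec(family="gpcm", n_categories=J, restriction="RSM")
        assert pcm.n_free_parameters(I) == 19 + (J - 2)

    def test_penalty_is_monotone_in_k_at_equal_likelihood(self, toy):
        y, items, classes = toy
        ll = marginal_loglik(y, items, classes)
        k_small = ModelSpec(family="mix-ers-gpcm", n_classes=2, n_categories=4).n_free_parameters(2)
        k_big = ModelSpec(family="mix-ers-gpcm-cd", n_classes=2, n_categories=4).n_free_parameters(2)
        n = y.shape[0]
        assert k_big > k_small
        assert -2 * ll + k_big * np.log(n) > -2 * ll + k_small * np.log(n)


SMOKE = dict(n_iterations=700, n_burnin=300, n_chains=1, seed=4)


@pytest.fixture(scope="module")
def gpcm_data():
    design = SimulationDesign(
        n_respondents=350, n_items=10, n_categories=4,
        class_proportions=(1.0,), omega_dists=(), seed=17,
    )
    return simulate_dataset(design, model="mix-ers-gpcm")


@pytest.fixture(scope="module")
def gpcm_fit(gpcm_data):
    spec = ModelSpec(family="gpcm", n_categories=4)
    return fit(gpcm_data, spec, mcmc=McmcConfig(**SMOKE))


class TestFit:
    def test_single_class_recovery(self, gpcm_data, gpcm_fit):
        items = gpcm_data.items
        post = gpcm_fit
        assert np.corrcoef(post.eap["alpha1"], items.alpha1)[0, 1] > 0.8
        assert np.corrcoef(post.eap["beta"][0], items.beta[0])[0, 1] > 0.95
        assert np.corrcoef(post.theta_eap, gpcm_data.true_theta())[0, 1] > 0.85

    def test_identification_constraints_in_point_estimates(self, gpcm_fit):
        assert abs(gpcm_fit.eap["beta"].mean()) < 1e-10
        assert np.abs(gpcm_fit.eap["tau"].sum(axis=1)).max() < 1e-10

    def test_gpcm_beats_mixture_bic_on_single_class_data(self, gpcm_data, gpcm_fit):
        mix_spec = ModelSpec(family="mix-ers-gpcm", n_classes=3, n_categories=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mix_post = fit(gpcm_data, mix_spec, mcmc=McmcConfig(**SMOKE))
        assert bic(gpcm_fit, gpcm_data) < bic(mix_post, gpcm_data)

    @pytest.mark.parametrize("restriction", ["GRSM", "PCM", "RSM"])
    def test_restricted_fits_respect_their_constraints(self, gpcm_data, restriction):
        spec = ModelSpec(family="gpcm", n_categories=4, restriction=restriction)
        post = fit(gpcm_data, spec,
                   mcmc=McmcConfig(n_iterations=150, n_burnin=50, n_chains=1, seed=3))
        if restriction in ("GRSM", "RSM"):
            assert post.eap["tau"].shape[0] == 1  # one shared threshold vector
        if restriction in ("PCM", "RSM"):
            assert np.all(post.eap["alpha1"] == 1.0)
        assert np.isfinite(bic(post, gpcm_data))

    def test_class_specific_discrimination_option(self):
        design = SimulationDesign(n_respondents=300, n_items=8, seed=4)
        data = simulate_dataset(design)
        spec = ModelSpec(family="mix-ers-gpcm", n_classes=3, n_categories=4,
                         class_specific_alpha=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit(data, spec,
                       mcmc=McmcConfig(n_iterations=150, n_burnin=50, n_chains=1, seed=3))
        assert post.eap["alpha1"].shape == (3, 8)

    def test_small_sample_mixture_warning(self):
        design = SimulationDesign(n_respondents=120, n_items=8, seed=23)
        data = simulate_dataset(design)
        spec = ModelSpec(family="mix-ers-gpcm", n_classes=3, n_categories=4)
        with pytest.warns(UserWarning, match="unreliable"):
            fit(data, spec, mcmc=McmcConfig(n_iterations=60, n_burnin=20, n_chains=1, seed=1))

    def test_invalid_responses_rejected(self):
        spec = ModelSpec(family="gpcm", n_categories=4)
        with pytest.raises(ValueError):
            fit(np.array([[0, 5], [1, 1]]), spec)

    def test_burnin_must_be_shorter_than_chain(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iterations=100, n_burnin=100)
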