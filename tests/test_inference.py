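"""Null fits and variational optimisation of the evidence lower bound."""

import numpy as np
import pytest
from scipy.optimize import minimize

from bayesrvat.inference import (
    DegeneratePhenotypeError,
    VariationalPosterior,
    _ElboProblem,
    draw_base_samples,
    elbo,
    fit_alternative,
    fit_null,
    partition_carriers,
)
from bayesrvat.model import ModelParams, burden_score, log_likelihood
from bayesrvat.simulation import SimScenario, simulate_dataset
from tests.conftest import gh_log_marginal, make_toy_dataset


class TestFitNull:
    def test_gaussian_closed_form(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        F = np.ones((4, 1))
        fit = fit_null(y, F, "continuous")
        assert fit.params.alpha[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.params.sigma2 == pytest.approx(1.0, abs=1e-12)
        assert fit.loglik == pytest.approx(-2 * np.log(2 * np.pi) - 2, abs=1e-10)

    def test_balanced_logistic(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_null(y, np.ones((4, 1)), "binary")
        assert fit.params.alpha[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.loglik == pytest.approx(4 * np.log(0.5), abs=1e-8)

    def test_matches_numeric_ml_oracle(self):
        rng = np.random.default_rng(4)
        n, k = 50, 3
        F = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
        y = F @ rng.standard_normal(k) + rng.standard_normal(n)
        fit = fit_null(y, F, "continuous")

        def neg_ll(w):
            alpha, log_s2 = w[:k], w[k]
            r = y - F @ alpha
            return 0.5 * n * (np.log(2 * np.pi) + log_s2) + 0.5 * r @ r / np.exp(log_s2)

        res = minimize(neg_ll, np.zeros(k + 1), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_binary_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        F = np.column_stack([np.ones(80), rng.standard_normal(80)])
        y = rng.binomial(1, 0.4, 80).astype(float)
        fit = fit_null(y, F, "binary")
        ref = sm.Logit(y, F).fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert fit.params.alpha == pytest.approx(ref.params, abs=1e-4)

    def test_degenerate_phenotype(self):
        y = np.arange(4.0)
        F = np.column_stack([np.ones(4), y])
        with pytest.raises(DegeneratePhenotypeError):
            fit_null(y, F, "continuous")


class TestPartitionCarriers:
    def test_definition(self):
        X = np.array([[0, 0], [1, 0], [0, 0], [0, 2], [0, 0]], float)
        carriers, noncarriers = partition_carriers(X)
        assert carriers.tolist() == [1, 3]
        assert noncarriers.tolist() == [0, 2, 4]

    def test_all_carriers_degenerate_partition(self):
        X = np.ones((4, 2))
        carriers, noncarriers = partition_carriers(X)
        assert len(carriers) == 4 and len(noncarriers) == 0

    @pytest.mark.parametrize("trait_type", ["continuous", "binary"])
    def test_sparse_equals_dense_elbo(self, trait_type):
        data, priors = make_toy_dataset(n=200, s=4, L=2, seed=7, trait_type=trait_type)
        eps = draw_base_samples(0, data.gene_id, 16, 2)
        params = ModelParams(
            alpha=np.array([0.1, -0.3]),
            beta=0.8,
            sigma2=1.2 if trait_type == "continuous" else None,
        )
        post = VariationalPosterior(mu=np.array([0.7, 1.4]), log_sd=np.array([-0.5, 0.1]))
        sparse = elbo(params, post, data, priors, eps)
        # dense oracle: full-likelihood recomputation per Monte Carlo sample
        phi = post.mu + post.sd * eps
        lls = [
            log_likelihood(
                data.y, data.F, burden_score(data.X, data.A, p, priors.b0), params, trait_type
            )
            for p in phi
        ]
        kl = _ElboProblem(data, priors, eps).kl(post)
        assert sparse == pytest.approx(np.mean(lls) - kl, abs=1e-10)


class TestElbo:
    def test_identity_at_null(self):
        data, priors = make_toy_dataset(n=150, s=3, L=1, seed=2)
        null = fit_null(data.y, data.F, "continuous")
        post = VariationalPosterior(mu=priors.phi_mean, log_sd=np.log(priors.phi_sd))
        eps = draw_base_samples(1, data.gene_id, 16, 1)
        assert elbo(null.params, post, data, priors, eps) == pytest.approx(
            null.loglik, abs=1e-10
        )

    def test_kl_vanishes_when_posterior_equals_prior(self):
        data, priors = make_toy_dataset(n=60, s=3, L=2, seed=3)
        eps = draw_base_samples(2, data.gene_id, 8, 2)
        post = VariationalPosterior(mu=priors.phi_mean, log_sd=np.log(priors.phi_sd))
        assert _ElboProblem(data, priors, eps).kl(post) == pytest.approx(0.0, abs=1e-14)

    def test_never_exceeds_quadrature_marginal(self):
        # randomized (params, posterior) settings on an L=1 toy
        data, priors = make_toy_dataset(n=100, s=3, L=1, seed=5)
        rng = np.random.default_rng(11)
        eps = draw_base_samples(3, data.gene_id, 64, 1)
        for _ in range(20):
            params = ModelParams(
                alpha=rng.standard_normal(2) * 0.3,
                beta=rng.uniform(-1.5, 1.5),
                sigma2=float(rng.uniform(0.6, 2.0)),
            )
            post = VariationalPosterior(
                mu=priors.phi_mean + rng.uniform(-1, 1, 1),
                log_sd=np.log(priors.phi_sd) + rng.uniform(-1, 0.5, 1),
            )
            bound = elbo(params, post, data, priors, eps)
            exact = gh_log_marginal(data, params, priors)
            assert bound <= exact + 1e-8


class TestFitAlternative:
    def test_seed_determinism_bit_identical(self):
        data, priors = make_toy_dataset(n=120, s=4, L=2, seed=9)
        f1 = fit_alternative(data, priors, seed=3)
        f2 = fit_alternative(data, priors, seed=3)
        assert np.array_equal(f1.posterior.mu, f2.posterior.mu)
        assert np.array_equal(f1.posterior.log_sd, f2.posterior.log_sd)
        assert f1.elbo_value == f2.elbo_value
        assert np.array_equal(f1.params.alpha, f2.params.alpha)

    def test_different_seed_changes_base_samples(self):
        assert not np.array_equal(
            draw_base_samples(0, "g", 4, 2), draw_base_samples(1, "g", 4, 2)
        )
        assert not np.array_equal(
            draw_base_samples(0, "g1", 4, 2), draw_base_samples(0, "g2", 4, 2)
        )

    def test_optimised_elbo_not_below_initialisation(self):
        data, priors = make_toy_dataset(n=150, s=4, L=2, seed=13, beta_true=2.0)
        fit = fit_alternative(data, priors, seed=0)
        null = fit_null(data.y, data.F, "continuous")
        init_post = VariationalPosterior(mu=priors.phi_mean, log_sd=np.log(priors.phi_sd))
        init = elbo(null.params, init_post, data, priors, fit.base_samples)
        assert fit.elbo_value >= init - 1e-9
        assert fit.converged

    def test_signal_raises_bound_above_null(self):
        scenario = SimScenario(
            n_individuals=3000, n_variants=50, variance_explained=0.02,
            n_contributing_continuous=2, seed=21,
        )
        data, _ = simulate_dataset(scenario)
        from bayesrvat.model import default_priors

        priors = default_priors(data.A)
        fit = fit_alternative(data, priors, seed=0)
        null = fit_null(data.y, data.F, "continuous")
        assert fit.elbo_value > null.loglik
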