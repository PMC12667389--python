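"""Shared fixtures and independent oracles for the test suite.

The quadrature helpers compute the exact log marginal likelihood and exact
posterior moments of the burden model by Gauss-Hermite integration over
the aggregation weights — feasible only for one or two annotation columns,
which is exactly what the bound/fidelity checks need. They deliberately
share no code with the variational implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from bayesrvat.annotations import AnnotationMatrix, GeneDataset
from bayesrvat.model import ModelParams, PriorSpec, burden_score, log_likelihood


def make_toy_dataset(
    n: int = 100,
    s: int = 3,
    L: int = 1,
    seed: int = 0,
    trait_type: str = "continuous",
    beta_true: float = 1.0,
    maf: float = 0.05,
    b0: float = 2.0,
) -> tuple[GeneDataset, PriorSpec]:
    """Small dense gene dataset with L continuous annotation columns.

    MAFs are deliberately common so that tiny cohorts contain carriers.
    """
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, maf, size=(n, s)).astype(float)
    A = AnnotationMatrix(
        values=rng.uniform(0.2, 1.0, size=(s, L)),
        column_names=[f"score_{j}" for j in range(L)],
        column_groups={"functional": list(range(L))},
        processed=True,
    )
    priors = PriorSpec(phi_mean=np.full(L, 1.0), phi_sd=np.full(L, 1.0), b0=b0)
    F = np.column_stack([np.ones(n), rng.standard_normal(n)])
    phi_true = rng.uniform(0.5, 2.0, size=L)
    g = burden_score(X, A, phi_true, b0)
    if trait_type == "continuous":
        y = F @ np.array([0.0, 0.2]) + beta_true * g + rng.standard_normal(n)
    else:
        from scipy.special import expit

        y = rng.binomial(1, expit(F @ np.array([-1.0, 0.2]) + beta_true * g)).astype(float)
    data = GeneDataset(
        gene_id=f"toy{seed}", X=X, A=A, y=y, trait_type=trait_type, F=F
    )
    return data, priors


def _gh_grid(priors: PriorSpec, n_nodes: int = 61):
    """Tensor Gauss-Hermite grid under the Gaussian prior.

    Returns (phi_grid, log_weights) with weights normalised to sum to 1,
    so sum_i w_i f(phi_i) approximates E_prior[f(phi)].
    """
    nodes, weights = hermegauss(n_nodes)  # E[f(Z)] for Z ~ N(0,1), weight e^{-x^2/2}
    log_w1 = np.log(weights) - 0.5 * np.log(2 * np.pi)
    L = priors.n_annotations
    grids, logws = [], []
    for combo in itertools.product(range(n_nodes), repeat=L):
        grids.append([priors.phi_mean[l] + priors.phi_sd[l] * nodes[c] for l, c in enumerate(combo)])
        logws.append(sum(log_w1[c] for c in combo))
    return np.array(grids), np.array(logws)


def gh_log_marginal(
    data: GeneDataset, params: ModelParams, priors: PriorSpec, n_nodes: int = 61
) -> float:
    """Exact log p(y | theta) = log E_prior[p(y | theta, phi)] by quadrature."""
    phi_grid, log_w = _gh_grid(priors, n_nodes)
    lls = np.array(
        [
            log_likelihood(
                data.y, data.F, burden_score(data.X, data.A, phi, priors.b0), params, data.trait_type
            )
            for phi in phi_grid
        ]
    )
    return float(logsumexp(lls + log_w))


def gh_posterior_mean(
    data: GeneDataset, params: ModelParams, priors: PriorSpec, n_nodes: int = 41
) -> np.ndarray:
    """Exact posterior mean E[phi | y, theta] by quadrature."""
    phi_grid, log_w = _gh_grid(priors, n_nodes)
    lls = np.array(
        [
            log_likelihood(
                data.y, data.F, burden_score(data.X, data.A, phi, priors.b0), params, data.trait_type
            )
            for phi in phi_grid
        ]
    )
    log_post = lls + log_w
    log_post -= logsumexp(log_post)
    return np.exp(log_post) @ phi_grid


def gh_burden_shift_expectation(
    data: GeneDataset,
    mu: np.ndarray,
    sd: np.ndarray,
    b0: float,
    A0: np.ndarray,
    n_nodes: int = 41,
) -> np.ndarray:
    """E_{phi ~ N(mu, diag(sd^2))}[g(X, A) - g(X, A0)] per individual.

    Quadrature under the given Gaussian — the exact value of the Monte
    Carlo expectation the annotation-importance scores estimate.
    """
    gauss = PriorSpec(phi_mean=np.asarray(mu), phi_sd=np.asarray(sd), b0=b0)
    phi_grid, log_w = _gh_grid(gauss, n_nodes)
    w = np.exp(log_w - logsumexp(log_w))
    diff = np.array(
        [
            burden_score(data.X, data.A, phi, b0) - burden_score(data.X, A0, phi, b0)
            for phi in phi_grid
        ]
    )
    return w @ diff


@pytest.fixture(scope="session")
def toy_factory():
    return make_toy_dataset


@pytest.fixture(scope="session")
def quad_log_marginal():
    return gh_log_marginal


@pytest.fixture(scope="session")
def quad_posterior_mean():
    return gh_posterior_mean
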