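"""Burden model core: saturated aggregation, likelihoods, allelic-series priors.

The model for a continuous trait is

    y = F alpha + g_phi(X, A) beta + eps,    eps ~ N(0, sigma2 I)

with the per-individual burden score

    g_phi(X, A) = sigmoid(X A phi - b0),

where ``X`` (N x S) holds minor-allele dosages, ``A`` (S x L) processed
variant annotations (higher = more deleterious), ``phi`` (L,) the
annotation aggregation weights, and ``b0 > 0`` an offset placing
non-carriers at a burden near zero. The sigmoid encodes saturation: once a
gene is disrupted, further variants add little. For binary traits the
Gaussian likelihood is replaced by a Bernoulli likelihood with a sigmoid
link on ``F alpha + g beta``.

Aggregation weights carry independent Gaussian priors expressing an
allelic series: putative loss-of-function (pLoF) variants get a strong
positive prior (a single carrier's burden is near one), other consequence
classes weaker and more uncertain priors, and continuous annotation
columns small positive adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .annotations import AnnotationMatrix, CONSEQUENCE_CLASSES

__all__ = [
    "PriorSpec",
    "ModelParams",
    "burden_score",
    "log_likelihood",
    "default_priors",
    "DEFAULT_PRIOR_CONFIG",
]

#: Default prior hyperparameters (mean, sd) per annotation group, and the
#: saturation offset b0. Consequence one-hots are prioritised by class;
#: every continuous column shares the "continuous" entry. Overridable via
#: :func:`default_priors` arguments or the run config.
DEFAULT_PRIOR_CONFIG: dict = {
    "b0": 5.0,
    "pLoF": (10.0, 1.0),
    "missense": (2.0, 2.0),
    "other_nonsynonymous": (1.0, 2.0),
    "continuous": (0.25, 0.5),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors over aggregation weights phi.

    Attributes
    ----------
    phi_mean, phi_sd : (L,) arrays; ``phi_sd`` strictly positive.
    b0 : positive saturation offset (fixed, not estimated).
    """

    phi_mean: np.ndarray
    phi_sd: np.ndarray
    b0: float

    def __post_init__(self):
        object.__setattr__(self, "phi_mean", np.asarray(self.phi_mean, float))
        object.__setattr__(self, "phi_sd", np.asarray(self.phi_sd, float))
        if self.phi_mean.shape != self.phi_sd.shape or self.phi_mean.ndim != 1:
            raise ValueError("phi_mean and phi_sd must be 1-D arrays of equal length")
        if not np.all(self.phi_sd > 0):
            raise ValueError("phi_sd must be strictly positive")
        if not self.b0 > 0:
            raise ValueError("b0 must be positive")

    @property
    def n_annotations(self) -> int:
        return self.phi_mean.shape[0]


@dataclass
class ModelParams:
    """Trait-model parameters theta = {alpha, beta, sigma2}.

    ``sigma2`` is the residual variance for continuous traits and must be
    ``None`` for binary traits.
    """

    alpha: np.ndarray
    beta: float
    sigma2: float | None = None

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float))
        if self.sigma2 is not None and not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


def burden_score(
    X: np.ndarray, A: np.ndarray | AnnotationMatrix, phi: np.ndarray, b0: float
) -> np.ndarray:
    """Per-individual burden g = sigmoid(X A phi - b0), strictly in (0, 1).

    ``X`` is N x S dosages, ``A`` the processed S x L annotation matrix
    (or an :class:`AnnotationMatrix`), ``phi`` the L aggregation weights.
    """
    A_values = A.values if isinstance(A, AnnotationMatrix) else np.asarray(A, float)
    phi = np.asarray(phi, float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi contains non-finite entries")
    return expit(np.asarray(X, float) @ (A_values @ phi) - b0)


def log_likelihood(
    y: np.ndarray,
    F: np.ndarray,
    g: np.ndarray,
    params: ModelParams,
    trait_type: str,
) -> float:
    """Log-likelihood of the trait given burden scores.

    Continuous: sum of N(y_i | (F alpha)_i + g_i beta, sigma2) log-densities.
    Binary: sum of Bernoulli log-masses with p_i = sigmoid((F alpha)_i + g_i beta).
    """
    y = np.asarray(y, float)
    eta = F @ params.alpha + g * params.beta
    if trait_type == "continuous":
        if params.sigma2 is None:
            raise ValueError("sigma2 required for continuous traits")
        r = y - eta
        n = y.shape[0]
        return float(-0.5 * n * np.log(2 * np.pi * params.sigma2) - 0.5 * r @ r / params.sigma2)
    elif trait_type == "binary":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binary phenotype must be coded 0/1")
        return float(np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta)))
    raise ValueError(f"unknown trait_type {trait_type!r}")


def default_priors(
    A: AnnotationMatrix,
    flat_consequence: bool = False,
    config: dict | None = None,
) -> PriorSpec:
    """Allelic-series prior for an annotation matrix.

    Consequence one-hot columns receive class-specific priors (strong for
    pLoF, weaker and wider for missense / other nonsynonymous); every
    continuous column receives a small positive-mean prior allowing
    moderate adjustments. With ``flat_consequence=True`` all consequence
    columns share the missense prior — the flat-prior ablation that drops
    the pLoF-dominant assumption.
    """
    if not A.processed:
        raise ValueError("annotation matrix must be processed")
    cfg = dict(DEFAULT_PRIOR_CONFIG)
    if config:
        cfg.update(config)
    L = A.values.shape[1]
    mean = np.empty(L)
    sd = np.empty(L)
    conseq_cols = set(A.column_groups.get("consequence", ()))
    for j, name in enumerate(A.column_names):
        if j in conseq_cols:
            if name not in CONSEQUENCE_CLASSES:
                raise ValueError(f"unknown consequence column {name!r}")
            key = "missense" if flat_consequence else name
            mean[j], sd[j] = cfg[key]
        else:
            mean[j], sd[j] = cfg["continuous"]
    spec = PriorSpec(phi_mean=mean, phi_sd=sd, b0=float(cfg["b0"]))
    if not flat_consequence and "pLoF" in A.column_names:
        j = A.column_names.index("pLoF")
        if expit(spec.phi_mean[j] - spec.b0) < 0.99:
            raise ValueError("pLoF prior must place single carriers near burden one")
    return spec
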