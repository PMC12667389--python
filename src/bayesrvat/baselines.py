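"""Classical burden-test baselines: pLoF burden, ACAT-Conseq, ACAT-MultiAnnot.

All baselines are likelihood-ratio tests of a single burden covariate in a
linear (continuous trait) or logistic (binary trait) model adjusting for
the same covariates F. For continuous traits the statistic has the closed
form N log(RSS_null / RSS_alt); for binary traits null and alternative
logistic models are fitted by quasi-Newton optimisation. Multiple
per-mask or per-annotation p-values are combined with the aggregated
Cauchy association test (ACAT), which is well calibrated under dependence.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2

from .annotations import CONSEQUENCE_CLASSES, GeneDataset
from .inference import _logistic_ml

__all__ = [
    "burden_lrt",
    "acat_combine",
    "acat_conseq",
    "acat_multiannot",
    "plof_burden",
]


def burden_lrt(
    y: np.ndarray, F: np.ndarray, burden: np.ndarray, trait_type: str
) -> float:
    """LRT p-value for adding one burden covariate to the covariate model.

    Returns NaN for a degenerate (constant) burden, the classical signal
    that the gene has no testable carriers.
    """
    y = np.asarray(y, float)
    F = np.asarray(F, float)
    burden = np.asarray(burden, float)
    if not np.all(np.isfinite(burden)):
        raise ValueError("burden contains non-finite values")
    if np.ptp(burden) == 0:
        return float("nan")  # degenerate burden
    design = np.column_stack([F, burden])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return float("nan")  # burden collinear with covariates
    n = y.shape[0]
    if trait_type == "continuous":
        rss0 = _rss(y, F)
        rss1 = _rss(y, design)
        if rss1 <= 0:
            return 0.0  # perfect fit; p at the numeric floor
        stat = n * np.log(rss0 / rss1)
    elif trait_type == "binary":
        _, ll0, _ = _logistic_ml(y, F)
        _, ll1, _ = _logistic_ml(y, design)
        stat = 2.0 * (ll1 - ll0)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    return float(chi2.sf(max(stat, 0.0), df=1))


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ coef
    return float(r @ r)


def acat_combine(p_values, weights=None) -> float:
    """Aggregated Cauchy combination of (possibly dependent) p-values.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i; combined
    p = 0.5 - arctan(T)/pi. P-values are clipped to [1e-300, 1 - 1e-16];
    below 1e-15 the tangent term is replaced by its asymptote 1/(p pi),
    and a very large T short-circuits to p = 1/(T pi) — both standard
    numerical safeguards for extreme tails.
    """
    p = np.asarray(p_values, float)
    p = p[~np.isnan(p)] if np.isnan(p).any() else p
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if weights is None:
        w = np.ones(p.size)
    else:
        w = np.asarray(weights, float)
        if w.shape != p.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, matching, not all zero")
    p = np.clip(p, 1e-300, 1 - 1e-16)
    small = p < 1e-15
    t = np.empty_like(p)
    t[~small] = np.tan((0.5 - p[~small]) * np.pi)
    t[small] = 1.0 / (p[small] * np.pi)
    T = float(np.sum(w * t) / np.sum(w))
    if T > 1e15:
        return 1.0 / (T * np.pi)
    return float(0.5 - np.arctan(T) / np.pi)


def _mask_burden(data: GeneDataset, variant_mask: np.ndarray) -> np.ndarray:
    """Unweighted dosage sum over a variant subset (classical mask burden)."""
    return data.X[:, variant_mask].sum(axis=1)


def plof_burden(data: GeneDataset) -> float:
    """Classical pLoF burden test: dosage sum over pLoF variants."""
    j = data.A.column_names.index("pLoF")
    mask = data.A.values[:, j] > 0
    if not mask.any():
        return float("nan")
    return burden_lrt(data.y, data.F, _mask_burden(data, mask), data.trait_type)


def acat_conseq(data: GeneDataset) -> float:
    """ACAT over per-consequence-class mask burdens (pLoF/missense/other)."""
    ps = []
    for cls in CONSEQUENCE_CLASSES:
        j = data.A.column_names.index(cls)
        mask = data.A.values[:, j] > 0
        if not mask.any():
            continue  # mask with no qualifying variants is skipped
        p = burden_lrt(data.y, data.F, _mask_burden(data, mask), data.trait_type)
        if not np.isnan(p):
            ps.append(p)
    if not ps:
        return float("nan")
    return acat_combine(ps)


def acat_multiannot(data: GeneDataset) -> float:
    """ACAT over annotation-weighted burden tests, one per column of A.

    Each burden is X A[:, l] (weighted dosage sum). Degenerate burdens are
    skipped; duplicated columns contribute duplicated p-values by design.
    """
    ps = []
    for l in range(data.A.n_annotations):
        p = burden_lrt(data.y, data.F, data.X @ data.A.values[:, l], data.trait_type)
        if not np.isnan(p):
            ps.append(p)
    if not ps:
        return float("nan")
    return acat_combine(ps)
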