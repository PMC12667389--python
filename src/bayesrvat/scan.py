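"""Multi-gene scan orchestration: two-stage prefiltering, Bonferroni reporting.

The Bayesian burden test is an order of magnitude costlier than classical
burden tests, so a scan can optionally run a cheap stage-1 test (default
ACAT-Conseq) on every gene and promote only genes with stage-1 p below a
threshold (default 1e-2) to the Bayesian stage-2 test. Prefiltering is a
compute-saving device, not a p-value combination rule: genes stopped at
stage 1 keep their stage-1 p-value (method flagged ``stage1_only``), and
the Bonferroni denominator is always the total number of gene-trait tests
attempted, never the filtered count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import EmptyGeneError, GeneDataset
from .association import TestConfig, test_gene
from .baselines import acat_conseq, acat_multiannot, plof_burden
from .inference import fit_null

__all__ = [
    "ScanConfig",
    "n_total_tests",
    "bonferroni_threshold",
    "run_scan",
    "run_baseline_scan",
    "write_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "gene",
    "trait",
    "method",
    "stage1_p",
    "p",
    "lrt_stat",
    "n_variants",
    "n_carriers",
    "bonferroni_significant",
    "converged",
]

_STAGE1_METHODS = {
    "ACAT-Conseq": acat_conseq,
    "ACAT-MultiAnnot": acat_multiannot,
    "pLoF": plof_burden,
}


@dataclass
class ScanConfig:
    """Configuration of a multi-gene, multi-trait scan."""

    traits: list[str] = field(default_factory=lambda: ["trait"])
    genes: list[str] = field(default_factory=list)
    prefilter_enabled: bool = True
    stage1_method: str = "ACAT-Conseq"
    prefilter_threshold: float = 1e-2
    alpha: float = 0.05
    seed: int = 0
    test: TestConfig = field(default_factory=TestConfig)

    def __post_init__(self):
        if not 0 < self.prefilter_threshold < 1:
            raise ValueError("prefilter threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.stage1_method not in _STAGE1_METHODS:
            raise ValueError(f"unknown stage-1 method {self.stage1_method!r}")


def n_total_tests(n_genes: int, n_traits: int) -> int:
    """Family size of a scan: every gene-trait pair attempted."""
    return int(n_genes) * int(n_traits)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Raw p-value threshold controlling FWER at ``alpha`` over ``n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    return float(alpha) / float(n_tests)


def run_scan(config: ScanConfig, dataset_provider) -> tuple[pd.DataFrame, dict]:
    """Run the (optionally two-stage) Bayesian burden scan.

    ``dataset_provider(gene_id, trait)`` returns a :class:`GeneDataset`
    (phenotype attached) or raises :class:`EmptyGeneError`. Results are
    deterministic given the config seed and independent of gene processing
    order (each gene's randomness is keyed by its id).
    """
    if not config.genes:
        raise ValueError("empty gene list")
    total = n_total_tests(len(config.genes), len(config.traits))
    threshold = bonferroni_threshold(config.alpha, total)
    stage1_fn = _STAGE1_METHODS[config.stage1_method]
    rows = []
    for trait in config.traits:
        null_cache: dict[tuple, object] = {}
        for gene in sorted(config.genes):
            try:
                data = dataset_provider(gene, trait)
            except EmptyGeneError:
                rows.append(
                    dict(
                        gene=gene, trait=trait, method="NA", stage1_p=np.nan, p=np.nan,
                        lrt_stat=np.nan, n_variants=0, n_carriers=0,
                        bonferroni_significant=False, converged=False,
                    )
                )
                continue
            stage1_p = np.nan
            if config.prefilter_enabled:
                stage1_p = stage1_fn(data)
                promote = np.isfinite(stage1_p) and stage1_p < config.prefilter_threshold
            else:
                promote = True
            if promote:
                # the covariates-only null is shared across genes of a trait;
                # key on the actual (y, F) content so reuse is always valid
                key = (
                    trait,
                    hashlib.sha1(data.y.tobytes() + data.F.tobytes()).hexdigest(),
                )
                null = null_cache.get(key)
                if null is None:
                    null = fit_null(data.y, data.F, data.trait_type)
                    null_cache[key] = null
                cfg = TestConfig(**{**asdict(config.test), "seed": config.seed})
                res = test_gene(data, config=cfg, trait_id=trait, null=null)
                rows.append(
                    dict(
                        gene=gene, trait=trait, method="BayesRVAT",
                        stage1_p=stage1_p, p=res.p_value, lrt_stat=res.lrt_stat,
                        n_variants=res.n_variants, n_carriers=res.n_carriers,
                        bonferroni_significant=bool(res.p_value < threshold),
                        converged=res.converged,
                    )
                )
            else:
                rows.append(
                    dict(
                        gene=gene, trait=trait, method="stage1_only",
                        stage1_p=stage1_p, p=stage1_p, lrt_stat=np.nan,
                        n_variants=data.n_variants, n_carriers=data.n_carriers,
                        bonferroni_significant=bool(stage1_p < threshold),
                        converged=True,
                    )
                )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    summary = {
        "n_genes": len(config.genes),
        "n_traits": len(config.traits),
        "n_tests": total,
        "bonferroni_threshold": threshold,
        "n_significant": int(results["bonferroni_significant"].sum()),
        "n_stage2": int((results["method"] == "BayesRVAT").sum()),
    }
    return results, summary


def run_baseline_scan(
    config: ScanConfig, dataset_provider, methods: tuple[str, ...] = ("pLoF", "ACAT-Conseq", "ACAT-MultiAnnot")
) -> pd.DataFrame:
    """Run classical burden baselines over the same gene-trait grid."""
    total = n_total_tests(len(config.genes), len(config.traits))
    threshold = bonferroni_threshold(config.alpha, total)
    rows = []
    for trait in config.traits:
        for gene in sorted(config.genes):
            try:
                data = dataset_provider(gene, trait)
            except EmptyGeneError:
                data = None
            for m in methods:
                p = _STAGE1_METHODS[m](data) if data is not None else np.nan
                rows.append(
                    dict(
                        gene=gene, trait=trait, method=m, stage1_p=np.nan, p=p,
                        lrt_stat=np.nan,
                        n_variants=data.n_variants if data is not None else 0,
                        n_carriers=data.n_carriers if data is not None else 0,
                        bonferroni_significant=bool(np.isfinite(p) and p < threshold),
                        converged=data is not None,
                    )
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _config_hash(config: ScanConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_results(results: pd.DataFrame, out_dir, config: ScanConfig | None = None) -> dict:
    """Write the results TSV and a run manifest; returns written paths.

    The manifest records the config hash, seed and package version so a
    rerun can be verified bit-identical. Refuses empty results and schema
    violations before writing anything.
    """
    if results is None or results.empty:
        raise ValueError("refusing to write empty results")
    if list(results.columns) != RESULT_COLUMNS:
        raise ValueError(f"results schema must be {RESULT_COLUMNS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "results.tsv"
    results.to_csv(results_path, sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed if config else None,
        "config_sha256": _config_hash(config) if config else None,
        "n_rows": int(len(results)),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"results": results_path, "manifest": manifest_path}
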