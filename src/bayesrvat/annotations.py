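"""Variant annotation processing and per-gene data loading.

Raw inputs are a genotype source (VCF or a sample x variant dosage table),
a variant annotation table (consequence term plus named continuous scores),
and phenotype/covariate tables. This module turns them into the processed
per-gene bundle the burden model consumes: dosage matrix ``X`` (N x S),
annotation matrix ``A`` (S x L, non-negative, higher = more deleterious),
phenotype ``y`` and covariates ``F``.

Continuous scores are oriented (reversing columns where lower raw values
mean more deleterious, e.g. SIFT or allele frequency), rank-transformed to
the Phred scale ``-10 log10(rank / M)`` across the full ranking population
of M variants, and range-normalised to [0, 1]. Consequence classes become
binary one-hot columns and are not Phred-scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PLOF",
    "MISSENSE",
    "OTHER_NONSYNONYMOUS",
    "EXCLUDED",
    "CONSEQUENCE_CLASSES",
    "VariantRecord",
    "AnnotationMatrix",
    "GeneDataset",
    "ScoreColumn",
    "EmptyGeneError",
    "classify_consequence",
    "phred_scale",
    "build_annotation_matrix",
    "load_gene_data",
    "load_annotation_table",
    "read_score_config",
]

PLOF = "pLoF"
MISSENSE = "missense"
OTHER_NONSYNONYMOUS = "other_nonsynonymous"
EXCLUDED = "excluded"
CONSEQUENCE_CLASSES = (PLOF, MISSENSE, OTHER_NONSYNONYMOUS)

# Sequence-Ontology-style consequence terms. pLoF = protein-truncating /
# loss-of-function classes; other protein-altering terms fall in the
# "other nonsynonymous" bucket; non-coding or synonymous terms are excluded.
_PLOF_TERMS = {
    "splice_donor_variant",
    "splice_acceptor_variant",
    "frameshift_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
}
_MISSENSE_TERMS = {"missense_variant"}
_OTHER_TERMS = {
    "inframe_insertion",
    "inframe_deletion",
    "protein_altering_variant",
    "coding_sequence_variant",
}
_EXCLUDED_TERMS = {
    "synonymous_variant",
    "stop_retained_variant",
    "start_retained_variant",
    "splice_region_variant",
    "intron_variant",
    "intergenic_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "non_coding_transcript_variant",
    "non_coding_transcript_exon_variant",
}


def classify_consequence(consequence_term: str) -> str:
    """Map a Sequence-Ontology consequence term to a consequence class.

    Splice donor/acceptor, frameshift, stop-gained/lost and start-lost
    terms are pLoF; missense terms are missense; other protein-altering
    terms are other_nonsynonymous; synonymous/non-coding terms (and, with
    a warning, unknown terms) are excluded.
    """
    term = consequence_term.strip().lower().replace(" ", "_").replace("-", "_")
    if term in _PLOF_TERMS:
        return PLOF
    if term in _MISSENSE_TERMS:
        return MISSENSE
    if term in _OTHER_TERMS:
        return OTHER_NONSYNONYMOUS
    if term not in _EXCLUDED_TERMS:
        logger.warning("unknown consequence term %r treated as excluded", consequence_term)
    return EXCLUDED


def phred_scale(raw_scores: np.ndarray) -> np.ndarray:
    """Rank-based Phred transform, higher input = more deleterious.

    Returns ``-10 log10(rank_i / M)`` where ``rank_i`` is the descending
    rank (average rank on ties) of score i among the M scores. The most
    deleterious score maps to the largest value; the least deleterious to
    exactly 0. Invariant under strictly monotone transforms of the input.
    """
    raw_scores = np.asarray(raw_scores, float)
    if raw_scores.ndim != 1 or raw_scores.size == 0:
        raise ValueError("raw_scores must be a non-empty 1-D vector")
    if np.isnan(raw_scores).any():
        raise ValueError("raw_scores contains missing values; impute before ranking")
    m = raw_scores.size
    ranks = rankdata(-raw_scores, method="average")
    return -10.0 * np.log10(ranks / m)


@dataclass(frozen=True)
class ScoreColumn:
    """Declared continuous score column: group membership and orientation."""

    name: str
    group: str
    higher_is_deleterious: bool = True


@dataclass(frozen=True)
class VariantRecord:
    """One rare variant: identity, consequence class, raw scores, frequency."""

    variant_id: str
    gene_id: str
    consequence_class: str
    raw_scores: np.ndarray  # (L_cont,), NaN = missing
    maf: float

    def __post_init__(self):
        object.__setattr__(self, "raw_scores", np.asarray(self.raw_scores, float))
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf {self.maf} outside [0, 0.5]")
        if self.consequence_class not in CONSEQUENCE_CLASSES + (EXCLUDED,):
            raise ValueError(f"unknown consequence class {self.consequence_class!r}")


@dataclass
class AnnotationMatrix:
    """Processed S x L annotation matrix with named, grouped columns."""

    values: np.ndarray
    column_names: list[str]
    column_groups: dict[str, list[int]]
    processed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values shape inconsistent with column_names")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("duplicated column names")
        seen: set[int] = set()
        for group, idx in self.column_groups.items():
            if seen.intersection(idx):
                raise ValueError(f"column assigned to more than one group (group {group!r})")
            seen.update(idx)
        if self.processed and np.any(self.values < 0):
            raise ValueError("processed annotation matrix must be non-negative")

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_annotations(self) -> int:
        return self.values.shape[1]

    def columns_in_group(self, group: str) -> list[int]:
        return list(self.column_groups.get(group, []))

    def subset_variants(self, rows: np.ndarray) -> "AnnotationMatrix":
        return AnnotationMatrix(
            values=self.values[rows],
            column_names=list(self.column_names),
            column_groups={g: list(ix) for g, ix in self.column_groups.items()},
            processed=self.processed,
        )


class EmptyGeneError(Exception):
    """No qualifying variants for a gene (caller records NA, not a crash)."""


@dataclass
class GeneDataset:
    """One gene's test unit: X (N x S), processed A (S x L), y, F."""

    gene_id: str
    X: np.ndarray
    A: AnnotationMatrix
    y: np.ndarray | None
    trait_type: str
    F: np.ndarray
    sample_ids: list[str] | None = None
    variant_ids: list[str] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.F = np.asarray(self.F, float)
        n = self.X.shape[0]
        if self.A.n_variants != self.X.shape[1]:
            raise ValueError("X columns and A rows disagree")
        if self.F.shape[0] != n:
            raise ValueError("F rows and X rows disagree")
        if self.y is not None:
            self.y = np.asarray(self.y, float)
            if self.y.shape[0] != n:
                raise ValueError("y length and X rows disagree")
            if self.trait_type == "binary" and not np.isin(self.y, (0.0, 1.0)).all():
                raise ValueError("binary phenotype must be coded 0/1")
        if self.F.size and np.linalg.matrix_rank(self.F) < self.F.shape[1]:
            raise ValueError("covariate matrix F is rank deficient")

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_variants(self) -> int:
        return self.X.shape[1]

    @property
    def n_carriers(self) -> int:
        return int(np.count_nonzero(self.X.sum(axis=1) > 0))


def build_annotation_matrix(
    records: list[VariantRecord],
    score_columns: list[ScoreColumn],
) -> AnnotationMatrix:
    """Assemble the processed annotation matrix for a set of variants.

    Layout: three consequence one-hot columns (pLoF, missense,
    other_nonsynonymous) followed by the declared continuous columns. Each
    continuous column is oriented so higher = more deleterious, has missing
    values imputed to the column median, is Phred-scaled by descending rank
    across *all* supplied records (the ranking population), and is divided
    by its maximum so entries lie in [0, 1].

    Records classified ``excluded`` must be filtered out beforehand.
    """
    if not records:
        raise ValueError("no variant records supplied")
    genes = {r.gene_id for r in records}
    if any(r.consequence_class == EXCLUDED for r in records):
        raise ValueError("excluded-class records must be dropped before building A")
    names = [n.name for n in score_columns]
    if len(set(names)) != len(names):
        raise ValueError("duplicated score column names")
    s = len(records)
    n_cont = len(score_columns)
    values = np.zeros((s, 3 + n_cont))
    for i, rec in enumerate(records):
        values[i, CONSEQUENCE_CLASSES.index(rec.consequence_class)] = 1.0
        if rec.raw_scores.shape != (n_cont,):
            raise ValueError(
                f"record {rec.variant_id}: expected {n_cont} raw scores, got {rec.raw_scores.shape}"
            )
        values[i, 3:] = rec.raw_scores
    # orient, impute, Phred-scale, range-normalise each continuous column
    for j, col in enumerate(score_columns):
        raw = values[:, 3 + j]
        if not col.higher_is_deleterious:
            raw = -raw
        if np.isnan(raw).all():
            raise ValueError(f"annotation column {col.name!r} is entirely missing")
        median = np.nanmedian(raw)
        raw = np.where(np.isnan(raw), median, raw)
        phred = phred_scale(raw)
        top = phred.max()
        values[:, 3 + j] = phred / top if top > 0 else phred
    column_names = list(CONSEQUENCE_CLASSES) + names
    column_groups: dict[str, list[int]] = {"consequence": [0, 1, 2]}
    for j, col in enumerate(score_columns):
        column_groups.setdefault(col.group, []).append(3 + j)
    if len(genes) > 1:
        logger.info("annotation matrix built from %d genes (shared ranking population)", len(genes))
    return AnnotationMatrix(
        values=values,
        column_names=column_names,
        column_groups=column_groups,
        processed=True,
    )


def read_score_config(path) -> list[ScoreColumn]:
    """Read the sidecar YAML declaring each score column's group/orientation.

    Expected form::

        columns:
          CADD: {group: functional, higher_is_deleterious: true}
          SIFT: {group: functional, higher_is_deleterious: false}
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cols = []
    for name, spec in cfg["columns"].items():
        cols.append(
            ScoreColumn(
                name=str(name),
                group=str(spec["group"]),
                higher_is_deleterious=bool(spec.get("higher_is_deleterious", True)),
            )
        )
    return cols


def load_annotation_table(
    path, score_columns: list[ScoreColumn]
) -> pd.DataFrame:
    """Read the variant annotation TSV (variant_id, gene_id, consequence, scores)."""
    tab = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene_id": str})
    required = {"variant_id", "gene_id", "consequence"}
    if not required.issubset(tab.columns):
        raise ValueError(f"annotation table missing columns {sorted(required - set(tab.columns))}")
    missing = [c.name for c in score_columns if c.name not in tab.columns]
    if missing:
        raise ValueError(f"annotation table missing declared score columns {missing}")
    tab["consequence_class"] = tab["consequence"].map(classify_consequence)
    return tab


def _read_vcf_dosages(path) -> tuple[pd.DataFrame, list[str]]:
    """Read GT dosages from a VCF; multi-allelic records are split per ALT.

    Missing genotypes count as dosage 0. Returns (sample x variant dosage
    frame, sample ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        gts = np.array([g[:2] for g in rec.genotypes], dtype=int)  # allele idx, -1 = missing
        for k, alt in enumerate(rec.ALT):
            vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            cols[vid] = (gts == k + 1).sum(axis=1).astype(float)
    return pd.DataFrame(cols, index=samples), samples


def _read_dosage_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    tab.index = tab.index.astype(str)
    return tab.astype(float)


def load_gene_data(
    genotype_source,
    annotation_table,
    phenotype_table,
    covariate_table,
    gene_id: str,
    maf_threshold: float = 1e-3,
    trait: str | None = None,
    trait_type: str = "continuous",
    score_columns: list[ScoreColumn] | None = None,
) -> GeneDataset:
    """Assemble a :class:`GeneDataset` for one gene from file inputs.

    ``genotype_source`` is a VCF path (``.vcf``) or a dosage TSV (rows =
    samples, columns = variant ids). ``annotation_table`` may be a path or
    a pre-loaded frame from :func:`load_annotation_table`. Variants are
    restricted to the gene, to non-excluded consequence classes, and to
    sample MAF in (0, ``maf_threshold``); missing genotypes are imputed to
    dosage 0. Raises :class:`EmptyGeneError` when no variant qualifies.
    """
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must lie in (0, 0.5]")
    score_columns = score_columns or []
    if not isinstance(annotation_table, pd.DataFrame):
        annotation_table = load_annotation_table(annotation_table, score_columns)

    if str(genotype_source).endswith((".vcf", ".vcf.gz")):
        dosages, _ = _read_vcf_dosages(genotype_source)
    else:
        dosages = _read_dosage_table(genotype_source)
    dosages = dosages.fillna(0.0)

    pheno = pd.read_csv(phenotype_table, sep="\t", dtype={"sample_id": str})
    covar = pd.read_csv(covariate_table, sep="\t", dtype={"sample_id": str})
    pheno = pheno.set_index("sample_id")
    covar = covar.set_index("sample_id")
    trait = trait or pheno.columns[0]

    missing = [s for s in pheno.index if s not in dosages.index or s not in covar.index]
    if missing:
        raise ValueError(f"samples missing from genotype or covariate source: {missing}")
    samples = list(pheno.index)
    dosages = dosages.loc[samples]
    covar = covar.loc[samples]

    # Ranking population = every qualifying variant in the loaded dataset
    # (all genes), so Phred scales are comparable across genes.
    usable = annotation_table[annotation_table["consequence_class"] != EXCLUDED]
    all_ids, records = [], []
    n = len(samples)
    for _, row in usable.iterrows():
        vid = row["variant_id"]
        if vid not in dosages.columns:
            continue
        dos = dosages[vid].to_numpy()
        af = dos.sum() / (2 * n)
        maf = min(af, 1 - af)
        if not 0 < maf < maf_threshold:
            continue
        all_ids.append(vid)
        records.append(
            VariantRecord(
                variant_id=vid,
                gene_id=row["gene_id"],
                consequence_class=row["consequence_class"],
                raw_scores=np.array([row[c.name] for c in score_columns], float),
                maf=maf,
            )
        )
    gene_rows = np.array(
        [i for i, r in enumerate(records) if r.gene_id == gene_id], dtype=int
    )
    if gene_rows.size == 0:
        raise EmptyGeneError(f"no qualifying variants for gene {gene_id!r}")

    A = build_annotation_matrix(records, score_columns).subset_variants(gene_rows)
    keep_ids = [all_ids[i] for i in gene_rows]
    X = dosages[keep_ids].to_numpy()

    Fcols = covar.to_numpy(float)
    has_intercept = Fcols.size and np.any(np.all(Fcols == 1.0, axis=0))
    F = Fcols if has_intercept else np.column_stack([np.ones(n), Fcols])

    y = pheno[trait].to_numpy(float)
    return GeneDataset(
        gene_id=gene_id,
        X=X,
        A=A,
        y=y,
        trait_type=trait_type,
        F=F,
        sample_ids=samples,
        variant_ids=keep_ids,
    )
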