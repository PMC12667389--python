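"""Annotation processing and gene-data loading."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesrvat.annotations import (
    EXCLUDED,
    MISSENSE,
    OTHER_NONSYNONYMOUS,
    PLOF,
    EmptyGeneError,
    ScoreColumn,
    VariantRecord,
    build_annotation_matrix,
    classify_consequence,
    load_gene_data,
    phred_scale,
)


@pytest.mark.parametrize(
    "term,expected",
    [
        ("stop_gained", PLOF),
        ("stop_lost", PLOF),
        ("start_lost", PLOF),
        ("frameshift_variant", PLOF),
        ("splice_donor_variant", PLOF),
        ("splice_acceptor_variant", PLOF),
        ("missense_variant", MISSENSE),
        ("inframe_deletion", OTHER_NONSYNONYMOUS),
        ("protein_altering_variant", OTHER_NONSYNONYMOUS),
        ("synonymous_variant", EXCLUDED),
        ("intron_variant", EXCLUDED),
        ("Stop-Gained", PLOF),  # case/separator robustness
    ],
)
def test_classify_consequence(term, expected):
    assert classify_consequence(term) == expected


def test_unknown_term_excluded_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assert classify_consequence("mystery_term") == EXCLUDED
    assert "mystery_term" in caplog.text


class TestPhredScale:
    def test_top_and_bottom_ranks(self):
        top = phred_scale(np.arange(100.0))[-1]
        assert top == pytest.approx(-10 * np.log10(1 / 100), abs=1e-12)
        assert top == pytest.approx(20.0)
        assert phred_scale(np.arange(10.0))[0] == 0.0

    def test_worked_example_matches_brute_force(self):
        scores = np.array([3.0, 1.0, 2.0, 0.5])
        out = phred_scale(scores)
        assert out == pytest.approx([6.0206, 1.2494, 3.0103, 0.0], abs=1e-4)
        # brute-force oracle: sort descending, positional ranks, direct log
        order = np.argsort(-scores)
        expected = np.empty(4)
        for rank, idx in enumerate(order, start=1):
            expected[idx] = -10 * np.log10(rank / 4)
        assert out == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(25)
        assert phred_scale(x) == pytest.approx(phred_scale(np.exp(2 * x) + 7), abs=1e-10)

    def test_ties_share_average_rank(self):
        out = phred_scale(np.array([1.0, 1.0, 0.0]))
        assert out[0] == out[1]
        assert out[0] == pytest.approx(-10 * np.log10(1.5 / 3))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            phred_scale(np.array([np.nan, np.nan]))


def _rec(vid, cls, scores, maf=1e-4, gene="G1"):
    return VariantRecord(
        variant_id=vid, gene_id=gene, consequence_class=cls, raw_scores=np.asarray(scores, float), maf=maf
    )


class TestBuildAnnotationMatrix:
    def test_one_hot_consequence_block(self):
        A = build_annotation_matrix([_rec("v1", PLOF, []), _rec("v2", MISSENSE, [])], [])
        assert A.values[:, :3].tolist() == [[1, 0, 0], [0, 1, 0]]
        assert A.processed

    def test_one_hots_sum_to_one_and_nonnegative(self):
        recs = [
            _rec("v1", PLOF, [0.3, 5.0]),
            _rec("v2", MISSENSE, [0.9, 1.0]),
            _rec("v3", OTHER_NONSYNONYMOUS, [np.nan, 3.0]),
        ]
        cols = [ScoreColumn("a", "functional"), ScoreColumn("b", "splicing")]
        A = build_annotation_matrix(recs, cols)
        assert np.all(A.values >= 0)
        assert A.values[:, :3].sum(axis=1) == pytest.approx(np.ones(3))
        assert A.values[:, 3:].max() <= 1.0

    def test_reversed_orientation_column(self):
        # SIFT-like: lower raw value = more deleterious
        recs = [_rec("v1", PLOF, [0.01]), _rec("v2", MISSENSE, [0.9])]
        A = build_annotation_matrix(recs, [ScoreColumn("sift", "functional", False)])
        j = A.column_names.index("sift")
        assert A.values[0, j] > A.values[1, j]
        assert A.values[0, j] == 1.0  # most deleterious after range normalisation

    def test_constant_column_ties(self):
        recs = [_rec("v1", PLOF, [2.0]), _rec("v2", MISSENSE, [2.0])]
        A = build_annotation_matrix(recs, [ScoreColumn("c", "functional")])
        j = A.column_names.index("c")
        assert A.values[0, j] == A.values[1, j]

    def test_median_imputation_before_ranking(self):
        recs = [_rec("v1", PLOF, [1.0]), _rec("v2", MISSENSE, [np.nan]), _rec("v3", MISSENSE, [3.0])]
        A = build_annotation_matrix(recs, [ScoreColumn("c", "functional")])
        j = A.column_names.index("c")
        # imputed value 2.0 ranks in the middle
        assert A.values[2, j] > A.values[1, j] > A.values[0, j]

    def test_excluded_records_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            build_annotation_matrix([_rec("v1", EXCLUDED, [])], [])

    def test_column_in_single_group(self):
        recs = [_rec("v1", PLOF, [1.0, 2.0])]
        A = build_annotation_matrix(
            recs, [ScoreColumn("a", "functional"), ScoreColumn("b", "rbp")]
        )
        seen = sorted(i for idx in A.column_groups.values() for i in idx)
        assert seen == list(range(A.n_annotations))


SCORES_YAML = """\
columns:
  CADD: {group: functional, higher_is_deleterious: true}
  SIFT: {group: functional, higher_is_deleterious: false}
"""


def _write_file_fixture(tmp_path, n=30, missing_genotype=False):
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(n)]
    # variants: 2 qualifying for G1, one too common, one for G2
    dosage = pd.DataFrame(
        {
            "1:100:A:T": rng.binomial(1, 0.02, n).astype(float),
            "1:200:C:G": rng.binomial(1, 0.02, n).astype(float),
            "1:300:G:A": np.ones(n),  # MAF too high
            "2:400:T:C": rng.binomial(1, 0.02, n).astype(float),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    dosage.iloc[0, 0] = 1.0  # ensure polymorphic
    dosage.iloc[1, 1] = 1.0
    dosage.iloc[2, 3] = 1.0
    if missing_genotype:
        dosage.iloc[3, 0] = np.nan
    dosage.to_csv(tmp_path / "dosages.tsv", sep="\t")
    ann = pd.DataFrame(
        {
            "variant_id": ["1:100:A:T", "1:200:C:G", "1:300:G:A", "2:400:T:C"],
            "gene_id": ["G1", "G1", "G1", "G2"],
            "consequence": ["stop_gained", "missense_variant", "missense_variant", "stop_gained"],
            "CADD": [25.0, 10.0, 5.0, 30.0],
            "SIFT": [0.0, 0.4, 0.9, 0.01],
        }
    )
    ann.to_csv(tmp_path / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame({"sample_id": samples, "trait": rng.standard_normal(n)}).to_csv(
        tmp_path / "phenotype.tsv", sep="\t", index=False
    )
    pd.DataFrame({"sample_id": samples, "age": rng.normal(50, 5, n)}).to_csv(
        tmp_path / "covariates.tsv", sep="\t", index=False
    )
    (tmp_path / "scores.yaml").write_text(SCORES_YAML)
    return tmp_path


class TestLoadGeneData:
    def _load(self, tmp_path, gene="G1", maf_threshold=0.3, **kw):
        from bayesrvat.annotations import read_score_config

        cols = read_score_config(tmp_path / "scores.yaml")
        return load_gene_data(
            tmp_path / "dosages.tsv",
            tmp_path / "annotations.tsv",
            tmp_path / "phenotype.tsv",
            tmp_path / "covariates.tsv",
            gene,
            maf_threshold=maf_threshold,
            score_columns=cols,
            **kw,
        )

    def test_dimensions_and_filtering(self, tmp_path):
        data = self._load(_write_file_fixture(tmp_path))
        assert data.X.shape == (30, 2)  # the MAF>=threshold variant is dropped
        assert data.A.n_variants == 2
        assert data.variant_ids == ["1:100:A:T", "1:200:C:G"]
        assert data.F.shape[1] == 2 and np.all(data.F[:, 0] == 1.0)  # intercept added

    def test_empty_gene_signal(self, tmp_path):
        fixture = _write_file_fixture(tmp_path)
        with pytest.raises(EmptyGeneError):
            self._load(fixture, gene="G1", maf_threshold=1e-4)

    def test_missing_genotype_imputed_to_zero(self, tmp_path):
        data = self._load(_write_file_fixture(tmp_path, missing_genotype=True))
        assert data.X[3, 0] == 0.0

    def test_sample_mismatch_lists_ids(self, tmp_path):
        fixture = _write_file_fixture(tmp_path)
        pheno = pd.read_csv(fixture / "phenotype.tsv", sep="\t")
        pheno.loc[0, "sample_id"] = "ghost"
        pheno.to_csv(fixture / "phenotype.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="ghost"):
            self._load(fixture)

    def test_reload_round_trip_bit_identical(self, tmp_path):
        fixture = _write_file_fixture(tmp_path)
        d1 = self._load(fixture)
        # re-serialise the loaded matrices and reload through pandas
        out = tmp_path / "roundtrip"
        out.mkdir()
        pd.DataFrame(d1.X, index=d1.sample_ids, columns=d1.variant_ids).to_csv(
            out / "X.tsv", sep="\t"
        )
        X2 = pd.read_csv(out / "X.tsv", sep="\t", index_col=0).to_numpy()
        d2 = self._load(fixture)
        assert np.array_equal(d1.X, X2)
        assert np.array_equal(d1.A.values, d2.A.values)
        assert np.array_equal(d1.y, d2.y)
        assert np.array_equal(d1.F, d2.F)


VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\ts3
"""


def test_vcf_dosages_missing_and_multiallelic(tmp_path):
    vcf = tmp_path / "g.vcf"
    vcf.write_text(
        VCF_HEADER
        + "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\t0/0\n"
        + "1\t200\t.\tC\tG,CA\t.\tPASS\t.\tGT\t0/2\t0/1\t0/0\t1/2\n"
    )
    from bayesrvat.annotations import _read_vcf_dosages

    dos, samples = _read_vcf_dosages(vcf)
    assert samples == ["s0", "s1", "s2", "s3"]
    assert dos["1:100:A:T"].tolist() == [1, 0, 0, 0]  # ./. counted as 0
    assert dos["1:200:C:G"].tolist() == [0, 1, 0, 1]
    assert dos["1:200:C:CA"].tolist() == [1, 0, 0, 1]
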