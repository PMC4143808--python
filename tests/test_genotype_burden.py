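"""Genotype IO, MAF computation, and transcript burden scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longfam.genotype_burden import (
    GenotypeMatrix,
    TranscriptAnnotation,
    build_burden_sets,
    compute_maf,
    read_genotypes,
    select_burden_variants,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def write_vcf(tmp_path, body, header=VCF_HEADER):
    path = tmp_path / "test.vcf"
    path.write_text(header + body)
    return path


def make_gm(dosage, variant_ids=None, subject_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variant_ids = variant_ids or [f"v{j}" for j in range(m)]
    subject_ids = subject_ids or [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        dict(chrom="3", pos=np.arange(1, m + 1), ref="A", alt="G", flipped=False),
        index=variant_ids,
    )
    return GenotypeMatrix(
        subject_ids=subject_ids, variant_ids=variant_ids, dosage=dosage,
        variants=variants,
    )


class TestReadGenotypes:
    def test_gt_calls_become_dosages(self, tmp_path):
        path = write_vcf(tmp_path, "3\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        gm = read_genotypes(path, fmt="vcf")
        assert gm.subject_ids == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(gm.dosage[:, 0], [0, 1, 2])
        assert not gm.variants["flipped"].iloc[0]

    def test_major_alt_allele_is_flipped(self, tmp_path):
        path = write_vcf(tmp_path, "3\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\n")
        gm = read_genotypes(path, fmt="vcf")
        np.testing.assert_array_equal(gm.dosage[:, 0], [0, 0, 1])
        assert gm.variants["flipped"].iloc[0]

    def test_fractional_dosage_field_passthrough(self, tmp_path):
        header = VCF_HEADER.replace(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n',
        )
        path = write_vcf(
            tmp_path, "3\t100\tsnp1\tA\tG\t.\tPASS\t.\tDS\t0.3\t1.7\t0.1\n", header
        )
        gm = read_genotypes(path, fmt="vcf")
        np.testing.assert_allclose(gm.dosage[:, 0], [0.3, 1.7, 0.1], atol=1e-6)

    def test_missing_genotype_is_nan(self, tmp_path):
        path = write_vcf(tmp_path, "3\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\n")
        gm = read_genotypes(path, fmt="vcf")
        assert np.isnan(gm.dosage[0, 0])

    def test_dosage_tsv_round_trip(self, tmp_path):
        from longfam.simdata import write_dosage_tsv

        gm = make_gm([[0, 1], [2, 0], [1, 1]], variant_ids=["3_100", "3_200"])
        path = tmp_path / "dose.tsv"
        write_dosage_tsv(gm, path)
        back = read_genotypes(path, fmt="dosage-tsv")
        np.testing.assert_array_equal(back.dosage, gm.dosage)
        assert back.variants["pos"].tolist() == [100, 200]

    def test_malformed_dosage_tsv_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("subject_id\tv1\ns1\tnot_a_number\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_genotypes(path, fmt="dosage-tsv")


class TestComputeMaf:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 0, 1, 1], 0.25),
            ([0, 0, 0, 0], 0.0),
            ([2, 2, 2, 1], 0.125),  # folded from 7/8
        ],
    )
    def test_known_frequencies(self, dosages, expected):
        gm = make_gm(np.asarray(dosages)[:, None])
        assert compute_maf(gm).iloc[0] == pytest.approx(expected)

    def test_all_missing_variant_flagged_nan(self):
        gm = make_gm(np.full((3, 1), np.nan))
        assert np.isnan(compute_maf(gm).iloc[0])

    def test_recovers_truth_within_binomial_error(self):
        rng = np.random.default_rng(5)
        p_true = 0.12
        n = 4000
        gm = make_gm(rng.binomial(2, p_true, size=(n, 1)).astype(float))
        se = np.sqrt(p_true * (1 - p_true) / (2 * n))
        assert abs(compute_maf(gm).iloc[0] - p_true) < 4 * se


def annotation(rows):
    return TranscriptAnnotation(
        records=pd.DataFrame(rows, columns=["variant_id", "transcript", "category"])
    )


class TestSelectBurdenVariants:
    def test_maf_exactly_five_percent_excluded(self):
        # folded MAF exactly 0.05 (alt count 2 of 40 alleles)
        dosage = np.zeros((20, 1))
        dosage[0, 0] = 2
        gm = make_gm(dosage)
        ann = annotation([("v0", "T1", "missense")])
        assert compute_maf(gm).iloc[0] == pytest.approx(0.05)
        assert select_burden_variants(gm, ann) == {}

    def test_category_other_excluded_regardless_of_maf(self):
        dosage = np.zeros((20, 1))
        dosage[0, 0] = 1
        gm = make_gm(dosage)
        assert select_burden_variants(gm, annotation([("v0", "T1", "other")])) == {}

    def test_annotation_is_transcript_specific(self):
        dosage = np.zeros((20, 1))
        dosage[0, 0] = 1
        gm = make_gm(dosage)
        ann = annotation([("v0", "TA", "missense"), ("v0", "TB", "other")])
        assert select_burden_variants(gm, ann) == {"TA": ["v0"]}

    def test_unknown_variant_skipped_with_warning(self, caplog):
        dosage = np.zeros((20, 1))
        dosage[0, 0] = 1
        gm = make_gm(dosage)
        ann = annotation([("v0", "T1", "missense"), ("ghost", "T1", "stop-gained")])
        with caplog.at_level("WARNING"):
            out = select_burden_variants(gm, ann)
        assert out == {"T1": ["v0"]}
        assert "unknown variants" in caplog.text


class TestBuildBurdenSets:
    def test_low_total_frequency_transcript_dropped(self):
        # two variants with MAF 0.004 and 0.005: total 0.009 < 0.01
        n = 1000
        dosage = np.zeros((n, 2))
        dosage[:8, 0] = 1  # maf 0.004
        dosage[:10, 1] = 1  # maf 0.005
        gm = make_gm(dosage)
        assert build_burden_sets(gm, {"T1": ["v0", "v1"]}) == []

    def test_scores_are_dosage_sums(self):
        dosage = np.array([[0, 1, 0], [2, 0, 1], [0, 0, 0], [1, 1, 1]], dtype=float)
        gm = make_gm(dosage)
        sets = build_burden_sets(gm, {"T1": ["v0", "v1", "v2"]}, min_total_freq=0.0)
        scores = sets[0].scores
        assert scores.tolist() == [1.0, 3.0, 0.0, 3.0]

    def test_missing_dosage_mean_imputed(self):
        dosage = np.array([[1.0], [np.nan], [0.0], [1.0]])
        gm = make_gm(dosage)
        sets = build_burden_sets(gm, {"T1": ["v0"]}, min_total_freq=0.0)
        assert sets[0].scores.iloc[1] == pytest.approx(2.0 / 3.0)

    def test_lower_floor_never_drops_more_transcripts(self, small_sim):
        from longfam.genotype_burden import select_burden_variants

        gm = small_sim.gm
        sel = select_burden_variants(gm, small_sim.annotation)
        n_loose = len(build_burden_sets(gm, sel, min_total_freq=0.001))
        n_tight = len(build_burden_sets(gm, sel, min_total_freq=0.02))
        assert n_loose >= n_tight

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        data=st.lists(
            st.lists(st.integers(min_value=0, max_value=2), min_size=3, max_size=3),
            min_size=2,
            max_size=8,
        ),
        perm=st.permutations([0, 1, 2]),
    )
    def test_scores_invariant_to_member_order_and_bounded(self, data, perm):
        dosage = np.asarray(data, dtype=float)
        gm = make_gm(dosage)
        members = ["v0", "v1", "v2"]
        a = build_burden_sets(gm, {"T": members}, min_total_freq=0.0)
        b = build_burden_sets(
            gm, {"T": [members[j] for j in perm]}, min_total_freq=0.0
        )
        assert np.allclose(a[0].scores, b[0].scores)
        assert (a[0].scores >= 0).all() and (a[0].scores <= 2 * 3).all()
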