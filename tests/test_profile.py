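"""Variant ingestion, retention filtering and VAF-matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonaltide.profile import (
    ConflictError,
    FilterThresholds,
    InsufficientDataError,
    MutationRecord,
    ParseError,
    RegionCall,
    VafMatrix,
    build_vaf_matrix,
    cn_profile_correlation,
    filter_variant,
    mutation_burden,
    read_region_calls,
)
from clonaltide.simulate import SimConfig, simulate_tumour, write_region_counts, write_region_vcf

from conftest import calls_from_truth, matrix_from_truth


def make_call(depth, alt, n_depth=0, n_alt=0, pos=100):
    return RegionCall(
        mutation=MutationRecord(chrom="chr1", pos=pos, ref="A", alt="T", gene="G1"),
        region="R1",
        depth=depth,
        alt_reads=alt,
        normal_depth=n_depth,
        normal_alt=n_alt,
    )


def fisher_greater_oracle(alt_t, depth_t, alt_n, depth_n):
    """One-sided hypergeometric tail by direct enumeration."""
    total_alt = alt_t + alt_n
    total = depth_t + depth_n

    def pmf(k):
        return (
            math.comb(depth_t, k)
            * math.comb(depth_n, total_alt - k)
            / math.comb(total, total_alt)
        )

    k_max = min(depth_t, total_alt)
    return sum(pmf(k) for k in range(alt_t, k_max + 1) if total_alt - k <= depth_n)


class TestMutationRecord:
    def test_kind_inference(self):
        assert MutationRecord("chr1", 5, "A", "T").kind == "SNV"
        assert MutationRecord("chr1", 5, "AT", "A").kind == "INDEL"
        assert MutationRecord("chr1", 5, "A", "ATT").kind == "INDEL"

    def test_invalid_records(self):
        with pytest.raises(ValueError):
            MutationRecord("chr1", 0, "A", "T")
        with pytest.raises(ValueError):
            MutationRecord("chr1", 5, "A", "A")


class TestFilter:
    @pytest.mark.parametrize(
        "depth,alt,reason",
        [
            (19, 10, "depth"),          # below minimum read depth of 20
            (100, 3, "supporting_reads"),  # below four supporting reads
            (200, 9, "vaf"),            # 4.5% < 5% minimum VAF
        ],
    )
    def test_failure_reasons(self, depth, alt, reason):
        res = filter_variant(make_call(depth, alt))
        assert not res.passed and res.reason == reason

    def test_fisher_pass_matches_hypergeometric_enumeration(self):
        call = make_call(100, 30, n_depth=100, n_alt=0)
        res = filter_variant(call)
        p_oracle = fisher_greater_oracle(30, 100, 0, 100)
        assert p_oracle < 0.05
        assert res.passed

    def test_fisher_blocks_germline_like_signal(self):
        # same alt fraction in tumour and normal: no somatic enrichment
        res = filter_variant(make_call(100, 30, n_depth=100, n_alt=30))
        assert not res.passed and res.reason == "fisher_p"

    def test_fisher_skipped_without_normal(self):
        assert filter_variant(make_call(100, 30)).passed

    @given(
        depth=st.integers(20, 500),
        alt=st.integers(0, 500),
        bump=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_alt_reads(self, depth, alt, bump):
        alt = min(alt, depth)
        alt2 = min(alt + bump, depth)
        before = filter_variant(make_call(depth, alt, n_depth=100, n_alt=0))
        after = filter_variant(make_call(depth, alt2, n_depth=100, n_alt=0))
        if before.passed:
            assert after.passed


class TestReaders:
    def test_tsv_row(self, tmp_path):
        path = tmp_path / "r1.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\tdepth\talt_reads\n"
            "chr2\t500\tG\tC\tKRAS\t100\t30\n"
        )
        calls = read_region_calls(path, "R1")
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.30)
        assert calls[0].mutation.gene == "KRAS"

    def test_vcf_and_tsv_dialects_agree(self, tmp_path):
        vcf = tmp_path / "r1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            "##contig=<ID=chr2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            "chr2\t500\t.\tG\tC\t.\t.\tGENE=KRAS\tDP:AD\t100:70,30\n"
        )
        tsv = tmp_path / "r1.tsv"
        tsv.write_text(
            "chrom\tpos\tref\talt\tgene\tdepth\talt_reads\nchr2\t500\tG\tC\tKRAS\t100\t30\n"
        )
        a = read_region_calls(vcf, "R1")[0]
        b = read_region_calls(tsv, "R1")[0]
        assert a.mutation == b.mutation
        assert (a.depth, a.alt_reads) == (b.depth, b.alt_reads)

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\n1\t2\n")
        with pytest.raises(ParseError, match="missing required columns"):
            read_region_calls(path, "R1")

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tdepth\talt_reads\nchr1\t100\tA\tT\t10\t30\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_region_calls(path, "R1")

    def test_simulator_roundtrip_tsv_and_vcf(self, tmp_path, small_truth):
        write_region_counts(small_truth, tmp_path)
        vcf_path = write_region_vcf(small_truth, "R1", tmp_path / "t_R1.vcf")
        tsv_calls = read_region_calls(tmp_path / f"{small_truth.tumour_id}_R1.tsv", "R1")
        vcf_calls = read_region_calls(vcf_path, "R1")
        by_key = {c.mutation.key: c for c in tsv_calls}
        assert len(tsv_calls) == len(vcf_calls) == len(small_truth.true_vaf)
        for c in vcf_calls:
            t = by_key[c.mutation.key]
            assert (c.depth, c.alt_reads) == (t.depth, t.alt_reads)
            assert c.normal_depth == t.normal_depth
        for c in tsv_calls:
            m = next(k for k, r in small_truth.records.items() if r.key == c.mutation.key)
            assert c.depth == int(small_truth.depth.loc[m, "R1"])
            assert c.alt_reads == int(small_truth.alt.loc[m, "R1"])


class TestVafMatrix:
    def test_present_everywhere(self):
        calls = {
            r: [make_call(100, 30, n_depth=100)] for r in ("R1", "R2", "R3")
        }
        m = build_vaf_matrix(calls, "T1")
        assert m.present.to_numpy().all()
        assert m.vaf.iloc[0, 0] == pytest.approx(0.3)

    def test_private_mutation_row(self):
        passing = make_call(100, 30, n_depth=100)
        failing = make_call(100, 1, n_depth=100)
        m = build_vaf_matrix({"R1": [passing], "R2": [failing], "R3": [failing]}, "T1")
        assert m.present.loc[passing.mutation.key].tolist() == [True, False, False]
        # raw counts kept for the absent cells
        assert m.depth.loc[passing.mutation.key, "R2"] == 100

    def test_region_order_permutation_invariance(self, small_truth):
        calls = calls_from_truth(small_truth)
        m1 = build_vaf_matrix(calls, "T1")
        m2 = build_vaf_matrix(dict(reversed(list(calls.items()))), "T1")
        assert set(m1.vaf.index) == set(m2.vaf.index)
        pd.testing.assert_frame_equal(m1.vaf, m2.vaf[m1.vaf.columns])

    def test_conflicting_duplicates_raise(self):
        a, b = make_call(100, 30), make_call(100, 31)
        with pytest.raises(ConflictError):
            build_vaf_matrix({"R1": [a, b]}, "T1")

    def test_matches_truth_oracle(self, small_truth):
        m = matrix_from_truth(small_truth)
        expected = set()
        for mut in small_truth.true_vaf.index:
            for r in small_truth.true_vaf.columns:
                call = RegionCall(
                    mutation=small_truth.records[mut],
                    region=r,
                    depth=int(small_truth.depth.loc[mut, r]),
                    alt_reads=int(small_truth.alt.loc[mut, r]),
                    normal_depth=500,
                    normal_alt=0,
                )
                if filter_variant(call).passed:
                    expected.add(small_truth.records[mut].key)
                    break
        assert set(m.vaf.index) == expected

    def test_deep_noise_free_filter_matches_analytic_truth(self):
        # at depth 10,000 the filter decision equals the analytic VAF rule
        thresholds = FilterThresholds()
        for vaf in (0.0, 0.25, 0.5):
            alt = int(round(10_000 * vaf))
            res = filter_variant(make_call(10_000, alt, n_depth=10_000, n_alt=0))
            assert res.passed == (vaf >= thresholds.min_vaf)


class TestBurdenAndCn:
    def test_burden_arithmetic(self, small_truth):
        m = matrix_from_truth(small_truth)
        n = len(m.mutation_ids)
        assert mutation_burden(m, 1.0) == pytest.approx(n)
        assert mutation_burden(m, 2.0) == pytest.approx(n / 2)
        with pytest.raises(ValueError):
            mutation_burden(m, 0.0)

    def test_empty_matrix_zero_burden(self):
        empty = VafMatrix(
            tumour_id="T0",
            mutations=[],
            regions=["R1"],
            depth=pd.DataFrame(columns=["R1"]),
            alt=pd.DataFrame(columns=["R1"]),
            vaf=pd.DataFrame(columns=["R1"]),
            present=pd.DataFrame(columns=["R1"]),
        )
        assert mutation_burden(empty, 1.0) == 0.0

    def test_cn_identical_and_negated(self):
        genes = [f"G{i}" for i in range(10)]
        base = pd.Series(np.linspace(1, 4, 10), index=genes)
        r, med = cn_profile_correlation({"R1": base, "R2": base.copy()})
        assert r.loc["R1", "R2"] == pytest.approx(1.0)
        assert med == pytest.approx(1.0)
        r, med = cn_profile_correlation({"R1": base, "R2": -base})
        assert r.loc["R1", "R2"] == pytest.approx(-1.0)

    def test_cn_matches_covariance_formula(self, rng):
        genes = [f"G{i}" for i in range(30)]
        tables = {
            f"R{k}": pd.Series(rng.normal(2, 0.5, 30), index=genes) for k in range(3)
        }
        r_mat, med = cn_profile_correlation(tables)
        x, y = tables["R0"].to_numpy(), tables["R1"].to_numpy()
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r_mat.loc["R0", "R1"] == pytest.approx(manual, abs=1e-12)
        assert med == pytest.approx(
            np.median([r_mat.loc["R0", "R1"], r_mat.loc["R0", "R2"], r_mat.loc["R1", "R2"]])
        )

    def test_cn_too_few_shared_genes(self):
        a = pd.Series([1.0, 2.0], index=["G1", "G2"])
        with pytest.raises(InsufficientDataError):
            cn_profile_correlation({"R1": a, "R2": a})
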