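"""Germline genotyping, variant counting, filters, and the statistical core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr, ndtri
from scipy.stats import betabinom as sp_betabinom
from scipy.stats import chi2_contingency

from duomut.calling import (
    NA,
    GermlineGenotype,
    NullParams,
    SiteCounts,
    augment_alleles,
    betabinom_tail_pvalue,
    call_site,
    combine_counts,
    estimate_null_params,
    fit_betabinom,
    identify_germline_alleles,
    is_na,
    left_align_indel,
    merge_cross_modality_indels,
    realign_indel_counts,
    stouffer_meta,
    strand_bias_pvalue,
    tumor_variant_counts,
    variant_filter,
)

from conftest import make_column

NULLS = {
    "DNA": NullParams(alpha=1.0, beta=999.0, modality="DNA"),
    "RNA": NullParams(alpha=1.0, beta=999.0, modality="RNA"),
}


class TestGermlineGenotype:
    @pytest.mark.parametrize(
        "tallies, expected",
        [
            ({"A": (50, 47), "C": (2, 1)}, {"A", "C"}),  # 3% passes the 2% bar
            ({"A": (50, 49), "C": (1, 0)}, {"A"}),  # 1% excluded
            ({"A": (25, 25), "G": (25, 25)}, {"A", "G"}),
        ],
    )
    def test_prevalence_threshold(self, tallies, expected):
        assert identify_germline_alleles(make_column(tallies)).alleles == expected

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            identify_germline_alleles(make_column({}))

    def test_augmentation_only_adds(self):
        g = GermlineGenotype({"A"})
        site = ("sim1", 1000)
        assert augment_alleles(g, {site: {"C"}}, None, site).alleles == {"A", "C"}
        assert augment_alleles(g, None, {site: {"+G"}}, site).alleles == {"A", "+G"}
        assert augment_alleles(g, {}, {}, site).alleles == {"A"}
        assert augment_alleles(g, {("sim1", 99): {"T"}}, None, site).alleles == {"A"}


class TestTumorVariantCounts:
    def test_counting_with_excluded_minor_variant(self):
        col = make_column({"A": (45, 45), "C": (5, 3), "G": (1, 1)})
        counts = tumor_variant_counts(col, GermlineGenotype({"A"}))
        assert counts.major_variant == "C"
        assert (counts.k, counts.g, counts.n) == (8, 90, 98)  # G excluded from n
        assert counts.total_variant == 10

    def test_no_variant_allele(self):
        counts = tumor_variant_counts(make_column({"A": (50, 50)}), GermlineGenotype({"A"}))
        assert counts.major_variant is None and counts.k == 0 and counts.n == 100

    def test_tie_break_matches_ranking_oracle(self):
        # equal counts: higher summed base quality wins; then lexicographic
        col = make_column({"A": (5, 5), "C": (3, 2, 150, []), "G": (3, 2, 180, [])})
        got = tumor_variant_counts(col, GermlineGenotype({"A"}))
        ranking = sorted(
            [(a, t.count, t.qual_sum) for a, t in col.tallies.items() if a != "A"],
            key=lambda x: (-x[1], -x[2], x[0]),
        )
        assert got.major_variant == ranking[0][0] == "G"
        col2 = make_column({"A": (5, 5), "C": (3, 2, 175, []), "G": (3, 2, 175, [])})
        assert tumor_variant_counts(col2, GermlineGenotype({"A"})).major_variant == "C"


class TestIndelRealign:
    def _site(self, pos, major, k, g):
        return SiteCounts(
            "sim1", pos, major_variant=major if k else None, k=k, g=g,
            k_fwd=k // 2, k_rev=k - k // 2, g_fwd=g // 2, g_rev=g - g // 2,
            total_variant=k,
        )

    def test_moves_to_strongest_neighbor(self):
        window = [self._site(100, "+A", 2, 50), self._site(103, "+A", 5, 20)]
        out = {s.position: s for s in realign_indel_counts(window)}
        assert (out[103].k, out[103].g) == (7, 18)
        assert out[103].n == 25  # n preserved at destination
        assert out[100].k == 0 and out[100].major_variant is None

    def test_different_alleles_do_not_move(self):
        window = [self._site(100, "+A", 2, 50), self._site(103, "+T", 5, 20)]
        out = {s.position: s for s in realign_indel_counts(window)}
        assert out[100].k == 2 and out[103].k == 5

    def test_beyond_window_does_not_move(self):
        window = [self._site(100, "+A", 2, 50), self._site(125, "+A", 5, 20)]
        out = {s.position: s for s in realign_indel_counts(window)}
        assert out[100].k == 2 and out[125].k == 5

    @settings(deadline=None, max_examples=50)
    @given(st.lists(
        st.tuples(st.integers(0, 60), st.sampled_from(["+A", "-1"]),
                  st.integers(0, 8), st.integers(10, 40)),
        min_size=2, max_size=8, unique_by=lambda t: t[0],
    ))
    def test_total_variant_reads_conserved(self, spec):
        window = [self._site(pos, major, k, g) for pos, major, k, g in spec]
        before = sum(s.k for s in window)
        out = realign_indel_counts(window)
        assert sum(s.k for s in out) == before

    def test_cross_modality_merge(self):
        d = [self._site(100, "+A", 4, 30)]
        r = [self._site(105, "+A", 6, 20)]
        pairs = merge_cross_modality_indels(d, r)
        assert len(pairs) == 1 and r[0].position == 100
        r2 = [self._site(125, "+A", 6, 20)]
        assert merge_cross_modality_indels(d, r2) == []
        r3 = [self._site(105, "+AT", 6, 20)]
        assert merge_cross_modality_indels(d, r3) == []

    def test_merge_prefers_nearest(self):
        d = [self._site(100, "-2", 4, 30)]
        r = [self._site(118, "-2", 2, 20), self._site(103, "-2", 2, 20)]
        pairs = merge_cross_modality_indels(d, r)
        assert len(pairs) == 1 and pairs[0][1].position == 100
        assert {s.position for s in r} == {100, 118}


class TestVariantFilter:
    def _counts(self, major="C", k_fwd=5, k_rev=5, g_fwd=40, g_rev=40,
                total=None, dists=(5, 12, 20, 33, 41)):
        k = k_fwd + k_rev
        return SiteCounts(
            "sim1", 500, major_variant=major, k=k, g=g_fwd + g_rev,
            k_fwd=k_fwd, k_rev=k_rev, g_fwd=g_fwd, g_rev=g_rev,
            total_variant=total if total is not None else k,
            end_distances=list(dists)[:k] or [5, 12, 20][: max(k, 1)],
        )

    def test_strand_bias_matches_chi_square_oracle(self):
        counts = self._counts(k_fwd=20, k_rev=0, g_fwd=50, g_rev=50,
                              dists=range(20))
        oracle = chi2_contingency([[20, 0], [50, 50]], correction=False)[1]
        assert strand_bias_pvalue(20, 0, 50, 50) == pytest.approx(oracle)
        assert oracle < 0.01
        ok, reasons = variant_filter(counts)
        assert not ok and "strand_bias" in reasons

    def test_zero_margin_tables_pass(self):
        assert strand_bias_pvalue(3, 2, 0, 0) == 1.0

    def test_indel_requires_both_strands(self):
        counts = self._counts(major="+G", k_fwd=6, k_rev=0, g_fwd=30, g_rev=30,
                              dists=(4, 9, 15, 22, 28, 35))
        ok, reasons = variant_filter(counts)
        assert not ok and "indel_strand" in reasons

    def test_prevalence_three_quarters(self):
        counts = self._counts(k_fwd=4, k_rev=4, total=12, dists=(4, 9, 15, 22, 28, 35, 40, 11))
        ok, reasons = variant_filter(counts)
        assert not ok and "prevalence" in reasons  # 8/12 < 0.75

    def test_end_distance_mad(self):
        counts = self._counts(k_fwd=2, k_rev=1, dists=(3, 3, 3))
        ok, reasons = variant_filter(counts)
        assert not ok and "end_distance_mad" in reasons

    def test_clean_variant_passes(self):
        ok, reasons = variant_filter(self._counts())
        assert ok and reasons == []

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            variant_filter(SiteCounts("sim1", 1, g=10))


class TestBetaBinomialTail:
    def test_uniform_closed_form(self):
        for n in (1, 5, 10, 33):
            for k in range(n + 1):
                expected = 1.0 - k / (n + 1)
                assert betabinom_tail_pvalue(k, n, 1, 1) == pytest.approx(expected, rel=1e-12)

    def test_k_zero_is_exactly_one(self):
        assert betabinom_tail_pvalue(0, 500, 0.3, 77) == 1.0

    def test_matches_pmf_summation_oracle(self):
        # brute-force upper-tail sum via scipy's beta-binomial pmf
        for (k, n, a, b) in [(5, 50, 2, 98), (3, 20, 0.5, 0.5), (12, 30, 10, 100)]:
            oracle = float(sp_betabinom.pmf(np.arange(k, n + 1), n, a, b).sum())
            assert betabinom_tail_pvalue(k, n, a, b) == pytest.approx(oracle, rel=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(1, 40), st.floats(0.2, 50), st.floats(0.2, 50))
    def test_nonincreasing_in_k(self, n, a, b):
        p = [betabinom_tail_pvalue(k, n, a, b) for k in range(n + 1)]
        # non-increasing up to float roundoff in near-1 tails
        assert all(x >= y - 1e-12 for x, y in zip(p, p[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            betabinom_tail_pvalue(3, 2, 1, 1)
        with pytest.raises(ValueError):
            betabinom_tail_pvalue(1, 2, 0, 1)


class TestNullFit:
    def test_parameter_recovery(self, rng):
        n = rng.poisson(80, 20000).clip(10)
        k = sp_betabinom.rvs(n, 2.0, 500.0, random_state=rng)
        fit = fit_betabinom(k, n)
        assert fit.alpha == pytest.approx(2.0, rel=0.2)
        assert fit.beta == pytest.approx(500.0, rel=0.2)

    def test_degenerate_all_zero_falls_back(self, caplog):
        with caplog.at_level("WARNING"):
            fit = fit_betabinom(np.zeros(100, int), np.full(100, 50))
        assert fit.alpha > 0 and fit.beta > 0
        assert fit.mean < 0.01

    def test_estimate_requires_positive_target(self):
        with pytest.raises(ValueError):
            estimate_null_params(iter([]), target_sites=0)

    def test_sampler_shortfall_named(self):
        sampler = iter([(0, 50, 0, 40)] * 10)
        with pytest.raises(ValueError, match="10 of 50"):
            estimate_null_params(sampler, target_sites=50)


class TestStoufferMeta:
    def test_zero_rna_weight_is_exact_identity(self):
        for p in (0.5, 1e-12, 0.999):
            assert stouffer_meta(p, 100, NA, 0) == p
            assert stouffer_meta(p, 100, 0.4, 0) == p

    def test_equal_halves_stay_half(self):
        assert stouffer_meta(0.5, 100, 0.5, 100) == pytest.approx(0.5, abs=1e-12)

    def test_matches_normal_quantile_oracle(self):
        z = ndtri(1 - 0.05)
        expected = 1 - ndtr(z * math.sqrt(2))  # equal weights, equal p
        got = stouffer_meta(0.05, 100, 0.05, 100)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.01001, abs=5e-5)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(1e-10, 0.499), st.integers(1, 500))
    def test_agreeing_evidence_strengthens(self, p, n):
        assert stouffer_meta(p, n, p, n) <= p

    def test_both_missing_is_na(self):
        assert is_na(stouffer_meta(NA, 0, NA, 0))


class TestCallSite:
    def _germ(self):
        return make_column({"A": (20, 20)}, ref_base="A")

    def test_agreement_combines_both_modalities(self):
        dna = make_column({"A": (45, 45), "C": (5, 5, 350, [5, 12, 20, 30, 8, 16, 25, 33, 40, 11])})
        rna = make_column({"A": (30, 30), "C": (4, 4, 280, [6, 13, 21, 31, 9, 17, 26, 34])})
        call = call_site(self._germ(), dna, rna, null_params=NULLS)
        expected = stouffer_meta(call.p_dna, call.n_dna, call.p_rna, call.n_rna)
        assert call.p_meta == pytest.approx(expected)
        assert call.p_meta < call.p_dna

    def test_rna_only_evidence_excluded(self):
        dna = make_column({"A": (50, 50)})
        rna = make_column({"A": (20, 20), "T": (10, 10, 700, [5, 12, 20, 30, 8, 16, 25, 33, 40, 11,
                                                              6, 13, 21, 31, 9, 17, 26, 34, 41, 12])})
        call = call_site(self._germ(), dna, rna, null_params=NULLS)
        assert call.p_dna == 1.0
        assert call.p_meta == 1.0  # RNA-editing-like signal never carries meta
        assert call.p_rna < 1e-6

    def test_dna_filter_failure_falls_back_to_rna(self):
        # DNA variant on one strand only with biased table -> NA
        dna = make_column({"A": (60, 0), "C": (8, 0, 280, [3, 3, 3, 3, 3, 3, 3, 3])})
        rna = make_column({"A": (30, 30), "C": (5, 5, 350, [5, 12, 20, 30, 8, 16, 25, 33, 40, 11])})
        call = call_site(self._germ(), dna, rna, null_params=NULLS)
        assert is_na(call.p_dna) and call.filter_flags
        assert call.p_meta == call.p_rna

    def test_combine_counts_na_vs_na(self):
        d = SiteCounts("sim1", 9, major_variant="C", k=3, g=0, k_fwd=3,
                       total_variant=3, end_distances=[3, 3, 3])
        r = SiteCounts("sim1", 9, major_variant="C", k=3, g=0, k_fwd=3,
                       total_variant=3, end_distances=[4, 4, 4])
        call = combine_counts(d, r, NULLS, "sim1", 9)
        assert is_na(call.p_dna) and is_na(call.p_rna) and is_na(call.p_meta)


class TestLeftAlign:
    def test_deletion_shifts_through_repeat(self):
        #      0123456789
        ref = "GGTATATACC"
        # within the alternating TATATA repeat, deleting two bases at offset
        # 5 is equivalent to deleting at 2 (leftmost placement)
        off, allele = left_align_indel(ref, 5, "-2")
        assert (off, allele) == (2, "-2")
        assert ref[:5] + ref[7:] == ref[:2] + ref[4:]  # same edited sequence

    def test_insertion_of_spike_base_cannot_shift(self):
        assert left_align_indel("AAAAA", 3, "+V") == (3, "+V")

    def test_insertion_shifts_through_run(self):
        off, allele = left_align_indel("GGAAAC", 4, "+A")
        assert off == 1 and allele == "+A"
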