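"""Read-, base- and site-level quality filtering."""

import numpy as np
import pysam
import pytest

from duomut.pileup import (
    AlleleObservation,
    ReadPolicy,
    base_passes_filters,
    homopolymer_flank_ok,
    homopolymer_ok_array,
    mismatch_indel_sum,
    pileup_region,
    pileup_site,
    read_passes_filters,
    site_quality_gate,
)

from conftest import make_column, make_read, write_bam


class TestReadFilter:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(mapq=19), False),  # mapping quality below 20
            (dict(mapq=20), True),  # boundary passes
            (dict(mapq=30, nm=3), False),  # mismatch+indel sum 3 > 2
            (dict(mapq=30, nm=2), True),
            (dict(mapq=30, nm=1), True),
            (dict(proper_pair=False), False),
            (dict(duplicate=True), False),
            (dict(qcfail=True), False),
            (dict(secondary=True), False),
            (dict(x0=2), False),  # multiple equal-best placements
            (dict(x0=1), True),
        ],
    )
    def test_clauses(self, kwargs, expected):
        assert read_passes_filters(make_read(**kwargs)) is expected

    def test_indel_events_counted_once(self):
        # 3-base insertion: NM counts 3 inserted bases, but the filter sum
        # counts one insertion event
        read = make_read(seq="A" * 53, cigar=[(0, 25), (1, 3), (0, 25)], nm=3)
        assert mismatch_indel_sum(read) == 1
        assert read_passes_filters(read)

    def test_missing_nm_without_reference_is_explicit(self):
        read = make_read(name="lost", with_nm=False)
        with pytest.raises(ValueError, match="lost"):
            read_passes_filters(read)

    def test_missing_nm_recomputed_from_reference(self, small_fixture):
        ref = pysam.FastaFile(small_fixture["reference"])
        seq = ref.fetch("sim1", 100, 150)
        read = make_read(seq=seq, with_nm=False)
        read.reference_start = 100
        assert mismatch_indel_sum(read, ref) == 0
        mutated = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
        read2 = make_read(seq=mutated, with_nm=False)
        read2.reference_start = 100
        assert mismatch_indel_sum(read2, ref) == 1


class TestBaseFilter:
    @pytest.mark.parametrize(
        "quality, end_distance, expected",
        [
            (19, 25, False),  # base quality below 20
            (20, 25, True),
            (35, 1, False),  # within terminal two bases
            (35, 2, True),  # first allowed interior position
            (35, 0, False),
        ],
    )
    def test_clauses(self, quality, end_distance, expected):
        obs = AlleleObservation("C", "+", quality, end_distance)
        assert base_passes_filters(obs, read_length=50) is expected


class TestPileup:
    def _clean_reads(self, ref, start=1000, n=10, **kw):
        seq = ref.fetch("sim1", start, start + 50)
        return [make_read(name=f"c{i}", start=start, seq=seq, **kw) for i in range(n)]

    def test_counts_and_duplicate_exclusion(self, small_fixture, tmp_path):
        ref = pysam.FastaFile(small_fixture["reference"])
        reads = self._clean_reads(ref)
        dup_seq = "C" * 50
        reads.append(make_read(name="dup", start=1000, seq=dup_seq, duplicate=True, nm=50))
        bam_path = write_bam(reads, tmp_path / "t.bam", contig_len=20000)
        with pysam.AlignmentFile(bam_path) as bam:
            col = pileup_site(bam, "sim1", 1020, reference=ref)
        assert col.hq_depth == 10
        assert col.count(ref.fetch("sim1", 1020, 1021)) == 10
        assert col.count("C") == 0
        assert col.raw_depth == 11  # duplicate still counted pre-filter

    def test_germline_accepts_everything(self, small_fixture, tmp_path):
        ref = pysam.FastaFile(small_fixture["reference"])
        reads = self._clean_reads(ref, n=3)
        low = make_read(name="low", start=1000, seq=ref.fetch("sim1", 1000, 1050),
                        quals=[5] * 50, mapq=3, duplicate=True)
        reads.append(low)
        bam_path = write_bam(reads, tmp_path / "g.bam", contig_len=20000)
        with pysam.AlignmentFile(bam_path) as bam:
            col = pileup_site(bam, "sim1", 1020, reference=ref, germline=True)
            tumor = pileup_site(bam, "sim1", 1020, reference=ref, germline=False)
        assert col.hq_depth == 4  # low-quality duplicate still tallied
        assert tumor.hq_depth == 3

    def test_insertion_and_deletion_anchoring(self, small_fixture, tmp_path):
        ref = pysam.FastaFile(small_fixture["reference"])
        base = ref.fetch("sim1", 1000, 1050)
        ins = make_read(name="ins", start=1000, seq=base[:25] + "VV" + base[25:],
                        cigar=[(0, 25), (1, 2), (0, 25)], nm=2)
        dele = make_read(name="del", start=1000, seq=base[:25] + base[27:],
                         cigar=[(0, 25), (2, 2), (0, 23)], nm=2)
        bam_path = write_bam([ins, dele], tmp_path / "i.bam", contig_len=20000)
        with pysam.AlignmentFile(bam_path) as bam:
            pile = pileup_region(bam, "sim1", 1000, 1060, reference=ref)
        # insertion anchored at preceding aligned base (position 1024);
        # deletion at its first deleted base (1025); both may left-shift by
        # normalisation, so scan for them
        found = {a for pos in pile.indels for a in pile.indels[pos]}
        assert "+VV" in found
        assert "-2" in found

    def test_strand_and_allele_sums_consistent(self, spiked):
        ref = pysam.FastaFile(spiked["reference"])
        with pysam.AlignmentFile(spiked["dna"]) as bam:
            pile = pileup_region(bam, "sim1", 4000, 5000, reference=ref)
        for pos in range(4000, 5000, 37):
            col = pile.column(pos)
            total = sum(t.fwd + t.rev for t in col.tallies.values())
            assert total == col.hq_depth
            assert col.hq_depth <= col.raw_depth

    def test_removing_reads_never_increases_depth(self, spiked, tmp_path):
        ref = pysam.FastaFile(spiked["reference"])
        with pysam.AlignmentFile(spiked["dna"]) as bam:
            reads = list(bam.fetch("sim1", 3000, 3400))
        full = write_bam([r for r in reads], tmp_path / "full.bam", contig_len=20000)
        sub = write_bam(reads[::2], tmp_path / "sub.bam", contig_len=20000)
        with pysam.AlignmentFile(full) as fb, pysam.AlignmentFile(sub) as sb:
            pf = pileup_region(fb, "sim1", 3100, 3300, reference=ref)
            ps = pileup_region(sb, "sim1", 3100, 3300, reference=ref)
        assert np.all(ps.hq_depth <= pf.hq_depth)

    def test_refiltering_filtered_reads_is_noop(self, spiked, tmp_path):
        """Keeping only reads that pass the read filter and re-piling gives
        identical high-quality tallies (filter idempotence)."""
        ref = pysam.FastaFile(spiked["reference"])
        with pysam.AlignmentFile(spiked["dna"]) as bam:
            reads = list(bam.fetch("sim1", 6000, 6500))
        passing = [r for r in reads if read_passes_filters(r, ReadPolicy(), ref)]
        filtered = write_bam(passing, tmp_path / "filt.bam", contig_len=20000)
        with pysam.AlignmentFile(spiked["dna"]) as fb, pysam.AlignmentFile(filtered) as sb:
            pf = pileup_region(fb, "sim1", 6100, 6400, reference=ref)
            ps = pileup_region(sb, "sim1", 6100, 6400, reference=ref)
        assert np.array_equal(pf.sub_counts, ps.sub_counts)

    def test_germline_hq_equals_raw_on_covered_sites(self, small_fixture):
        ref = pysam.FastaFile(small_fixture["reference"])
        with pysam.AlignmentFile(small_fixture["alignments"]) as bam:
            pile = pileup_region(bam, "sim1", 2000, 2500, reference=ref, germline=True)
        # no indels in the generator: every covered base is tallied
        assert np.array_equal(pile.hq_depth, pile.raw)

    def test_position_outside_contig_errors(self, small_fixture):
        ref = pysam.FastaFile(small_fixture["reference"])
        with pysam.AlignmentFile(small_fixture["alignments"]) as bam:
            with pytest.raises(ValueError):
                pileup_site(bam, "sim1", 10**7, reference=ref)


class TestHomopolymer:
    def test_flank_run_boundaries(self):
        #                     0123456789
        seq = np.frombuffer(b"GTAAAAACGT", dtype=np.uint8)
        ok = homopolymer_ok_array(seq)
        assert not ok[7]  # C has AAAAA (run of 5) on its left
        assert not ok[1]  # T has the same run of 5 on its right
        assert ok[8]  # G: left C run 1, right T run 1
        seq4 = np.frombuffer(b"GTAAAACGTC", dtype=np.uint8)
        ok4 = homopolymer_ok_array(seq4)
        assert ok4[6]  # C with AAAA (run of 4) left: boundary allowed
        assert ok4[1]  # T with run of 4 right: boundary allowed

    def test_within_run_positions(self):
        # interior of a run of 10: every position has a flanking run > 4 on
        # at least one side (its own run, truncated at the site)
        seq = np.frombuffer(b"AAAAAAAAAA", dtype=np.uint8)
        assert not homopolymer_ok_array(seq).any()

    def test_scalar_matches_vector(self, small_fixture):
        ref = pysam.FastaFile(small_fixture["reference"])
        seq = ref.fetch("sim1")
        arr = homopolymer_ok_array(np.frombuffer(seq.encode(), np.uint8))
        for pos in range(0, len(seq), 97):
            assert homopolymer_flank_ok(ref, "sim1", pos) == arr[pos]

    def test_contig_edges_never_error(self, small_fixture):
        ref = pysam.FastaFile(small_fixture["reference"])
        for pos in (0, 1, len(ref.fetch("sim1")) - 1):
            assert homopolymer_flank_ok(ref, "sim1", pos) in (True, False)


class _FlatRef:
    """Minimal reference accessor over a fixed sequence (no homopolymers)."""

    def __init__(self, seq="ACGT" * 300):
        self.seq = seq

    def fetch(self, contig, start, end):
        return self.seq[start:end]

    def get_reference_length(self, contig):
        return len(self.seq)


class TestSiteGate:
    REF = _FlatRef()

    def _col(self, depth, raw=None):
        return make_column({"A": (depth // 2, depth - depth // 2)}, raw_depth=raw)

    def test_germline_depth_below_ten_fails(self):
        assert not site_quality_gate(self._col(9), self._col(50), self._col(50), self.REF)
        assert site_quality_gate(self._col(10), self._col(50), self._col(50), self.REF)

    def test_tumor_depth_or_over_modalities(self):
        assert site_quality_gate(self._col(30), self._col(4), self._col(12), self.REF)
        assert not site_quality_gate(self._col(30), self._col(4), self._col(4), self.REF)

    def test_missing_modality_counts_as_zero(self):
        assert site_quality_gate(self._col(30), self._col(8), None, self.REF)
        assert not site_quality_gate(self._col(30), self._col(4), None, self.REF)

    def test_hq_proportion_quarter(self):
        bad = self._col(20, raw=100)  # 20% high-quality
        ok = self._col(20, raw=60)
        assert not site_quality_gate(self._col(30), bad, bad, self.REF)
        assert site_quality_gate(self._col(30), bad, ok, self.REF)

    def test_nearby_germline_indel_blocks(self):
        assert not site_quality_gate(
            self._col(30), self._col(50), self._col(50), self.REF,
            germline_indel_nearby=True,
        )
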