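"""Pileup construction with high-quality read, base, and site filters.

Turns coordinate-sorted, indexed alignments into per-site, per-allele,
per-strand tallies.  Three filter layers are applied before any variant
logic runs:

* **read level** — mapping quality, mismatch+indel budget, proper pairing,
  duplicate/qc-fail flags, singular-best-alignment status;
* **base level** — base quality and exclusion of the terminal bases of the
  aligned read sequence;
* **site level** — germline depth, tumor high-quality depth, flanking
  homopolymers, high-quality-base proportion, and nearby germline indels.

Germline alignments are exempt from the read- and base-level filters: every
aligned base from a primary germline alignment is tallied, so the germline
genotype reflects all observed alleles.

Alleles are represented as strings: ``"A"``/``"C"``/… for (mis)matching
bases, ``"+SEQ"`` for an insertion of SEQ anchored at the preceding aligned
position, and ``"-L"`` for a deletion of L bases anchored at the first
deleted position.  Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ReadPolicy",
    "AlleleObservation",
    "AlleleTally",
    "PileupColumn",
    "RegionPileup",
    "read_passes_filters",
    "base_passes_filters",
    "mismatch_indel_sum",
    "pileup_region",
    "pileup_site",
    "homopolymer_flank_ok",
    "homopolymer_ok_array",
    "site_quality_gate",
]

# base identity -> tally slot; V is the simulator's spike allele, slot 5
# collects N and any other IUPAC code.
ALLELE_BASES = "ACGTVN"
_BASE_INDEX = np.full(256, 5, dtype=np.int8)
for _i, _b in enumerate(ALLELE_BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i
N_BASE_SLOTS = len(ALLELE_BASES)

_CIGAR_ALIGNED = (0, 7, 8)  # M, =, X


@dataclass(frozen=True)
class ReadPolicy:
    """Thresholds of the high-quality data filter.

    Defaults are the caller's standard operating point: base quality >= 20,
    mapping quality >= 20, at most 2 reference mismatches+insertions+
    deletions per read, proper pairs only, no duplicates or qc-failures,
    the terminal 2 bases of the aligned sequence excluded, and all germline
    bases accepted.
    """

    min_base_quality: int = 20
    min_mapping_quality: int = 20
    max_mismatch_indel_sum: int = 2
    require_proper_pair: bool = True
    exclude_duplicates_qcfail: bool = True
    terminal_exclusion: int = 2
    germline_accept_all: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_base_quality",
            "min_mapping_quality",
            "max_mismatch_indel_sum",
            "terminal_exclusion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"ReadPolicy.{name} must be non-negative")


@dataclass(frozen=True)
class AlleleObservation:
    """One quality-annotated allele observation from a single read.

    ``end_distance`` is the distance from the observation to the nearer end
    of the *aligned* read sequence (soft-clipped bases excluded), in query
    coordinates.
    """

    allele: str
    strand: str  # "+" or "-"
    base_quality: int
    end_distance: int

    def __post_init__(self) -> None:
        if self.end_distance < 0:
            raise ValueError("end_distance must be >= 0")
        if self.allele.startswith("+") and len(self.allele) < 2:
            raise ValueError("insertion allele needs a sequence")
        if self.allele.startswith("-") and int(self.allele[1:]) < 1:
            raise ValueError("deletion length must be >= 1")


@dataclass
class AlleleTally:
    """Per-allele aggregate at one site: strand counts, quality mass,
    and the end distances of the supporting reads (kept only for
    non-reference alleles; the reference allele's list may be empty)."""

    fwd: int = 0
    rev: int = 0
    qual_sum: int = 0
    end_distances: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return self.fwd + self.rev


@dataclass
class PileupColumn:
    """All quality-passing allele observations at one genomic site."""

    contig: str
    position: int  # 0-based
    tallies: dict  # allele string -> AlleleTally
    raw_depth: int
    hq_depth: int
    ref_base: str

    def count(self, allele: str) -> int:
        t = self.tallies.get(allele)
        return t.count if t is not None else 0

    def alleles(self):
        return [a for a, t in self.tallies.items() if t.count > 0]


def mismatch_indel_sum(read, reference=None) -> int:
    """Reference mismatches + insertion events + deletion events for a read.

    Mismatch count comes from the NM tag (which counts mismatched, inserted
    and deleted bases) minus the inserted/deleted base totals; indel events
    are then added back, so a 3-base insertion costs 1, not 3.  When NM is
    absent the mismatches are recomputed against ``reference`` (a
    pysam.FastaFile-like accessor); without either, an error names the read.
    """
    n_ins = n_del = ins_bases = del_bases = 0
    for op, length in read.cigartuples or ():
        if op == 1:
            n_ins += 1
            ins_bases += length
        elif op == 2:
            n_del += 1
            del_bases += length
    if read.has_tag("NM"):
        mismatches = int(read.get_tag("NM")) - ins_bases - del_bases
    elif reference is not None:
        mismatches = 0
        refseq = reference.fetch(
            read.reference_name, read.reference_start, read.reference_end
        ).upper()
        qseq = read.query_sequence
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if qseq[qpos].upper() != refseq[rpos - read.reference_start]:
                mismatches += 1
    else:
        raise ValueError(
            f"read {read.query_name!r} has no NM tag and no reference was "
            "supplied to recompute mismatches"
        )
    return mismatches + n_ins + n_del


def read_passes_filters(read, policy: ReadPolicy = ReadPolicy(), reference=None) -> bool:
    """Read-level clause of the high-quality data filter.

    A read passes iff it is the singular best alignment (primary,
    non-supplementary, and — when the aligner reports a best-hit count —
    that count is 1), properly paired, not a duplicate or qc-failure, has
    mapping quality >= threshold, and carries at most
    ``max_mismatch_indel_sum`` mismatches+indel events.  With
    ``germline_accept_all`` callers should bypass this for germline sources
    (see :func:`pileup_region`).
    """
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.has_tag("X0") and int(read.get_tag("X0")) > 1:
        return False
    if policy.exclude_duplicates_qcfail and (read.is_duplicate or read.is_qcfail):
        return False
    if policy.require_proper_pair and not read.is_proper_pair:
        return False
    if read.mapping_quality < policy.min_mapping_quality:
        return False
    return mismatch_indel_sum(read, reference) <= policy.max_mismatch_indel_sum


def base_passes_filters(
    obs: AlleleObservation, read_length: int, policy: ReadPolicy = ReadPolicy()
) -> bool:
    """Base-level clause: quality >= threshold and not within the terminal
    bases of the aligned read sequence (``read_length`` is the aligned
    length; an observation with end_distance < terminal_exclusion fails)."""
    del read_length  # end_distance already encodes both ends
    if obs.base_quality < policy.min_base_quality:
        return False
    return obs.end_distance >= policy.terminal_exclusion


class RegionPileup:
    """Vectorised pileup over one contiguous region.

    Substitution/reference-base observations live in dense arrays indexed by
    ``(offset, base-slot, strand)``; indel observations, which are sparse,
    live in a dict keyed by anchor position.  ``column(pos)`` materialises a
    :class:`PileupColumn` for any position in the region.
    """

    def __init__(self, contig: str, start: int, end: int, ref_seq: str):
        L = end - start
        self.contig = contig
        self.start = start
        self.end = end
        self.ref_str = ref_seq.upper()
        self.ref_bytes = np.frombuffer(self.ref_str.encode(), dtype=np.uint8)
        if len(self.ref_bytes) != L:
            raise ValueError("reference slice length does not match region")
        self.ref_index = _BASE_INDEX[self.ref_bytes]
        self.sub_counts = np.zeros((L, N_BASE_SLOTS, 2), dtype=np.int32)
        self.qual_sums = np.zeros((L, N_BASE_SLOTS), dtype=np.int64)
        self.raw = np.zeros(L, dtype=np.int32)
        self.indels: dict[int, dict[str, AlleleTally]] = {}
        # end distances of non-reference base observations, for the MAD filter
        self._var_pos = []
        self._var_base = []
        self._var_dist = []
        self._finalized = False

    # -- accumulation -----------------------------------------------------

    def add_raw_span(self, ref_start: int, ref_end: int) -> None:
        lo = max(ref_start, self.start) - self.start
        hi = min(ref_end, self.end) - self.start
        if hi > lo:
            self.raw[lo:hi] += 1

    def add_read_observations(self, read, policy: ReadPolicy, filter_bases: bool) -> None:
        """Walk a read's CIGAR and tally its in-region observations."""
        quals = read.query_qualities
        seq = read.query_sequence
        if seq is None:
            return
        qbytes = np.frombuffer(seq.encode(), dtype=np.uint8)
        qarr = np.asarray(quals, dtype=np.int32) if quals is not None else np.full(len(seq), 30, np.int32)
        qstart = read.query_alignment_start
        qend = read.query_alignment_end
        strand = 1 if read.is_reverse else 0
        rpos = read.reference_start
        qpos = 0
        for op, length in read.cigartuples:
            if op in _CIGAR_ALIGNED:
                lo = max(rpos, self.start)
                hi = min(rpos + length, self.end)
                if hi > lo:
                    roff = np.arange(lo - self.start, hi - self.start)
                    qoff = np.arange(qpos + (lo - rpos), qpos + (hi - rpos))
                    dist = np.minimum(qoff - qstart, (qend - 1) - qoff)
                    bq = qarr[qoff]
                    if filter_bases:
                        keep = (bq >= policy.min_base_quality) & (
                            dist >= policy.terminal_exclusion
                        )
                        roff, qoff, dist, bq = roff[keep], qoff[keep], dist[keep], bq[keep]
                    bidx = _BASE_INDEX[qbytes[qoff]]
                    np.add.at(self.sub_counts, (roff, bidx, strand), 1)
                    np.add.at(self.qual_sums, (roff, bidx), bq)
                    nonref = bidx != self.ref_index[roff]
                    if nonref.any():
                        self._var_pos.append(roff[nonref] + self.start)
                        self._var_base.append(bidx[nonref])
                        self._var_dist.append(dist[nonref])
                rpos += length
                qpos += length
            elif op == 1:  # insertion, anchored at preceding aligned position
                anchor = rpos - 1
                if self.start <= anchor < self.end:
                    ins_seq = seq[qpos : qpos + length].upper()
                    bq = int(qarr[qpos : qpos + length].min())
                    dist = int(
                        min(qpos - qstart, (qend - 1) - (qpos + length - 1))
                    )
                    if (not filter_bases) or (
                        bq >= policy.min_base_quality
                        and dist >= policy.terminal_exclusion
                    ):
                        self._add_indel("+" + ins_seq, anchor, strand, bq, dist)
                qpos += length
            elif op == 2:  # deletion, anchored at first deleted position
                if self.start <= rpos < self.end:
                    # no bases of its own: inherit min flanking base quality
                    left = int(qarr[qpos - 1]) if qpos > 0 else 255
                    right = int(qarr[qpos]) if qpos < len(qarr) else 255
                    bq = min(left, right)
                    dist = int(min(qpos - 1 - qstart, (qend - 1) - qpos))
                    dist = max(dist, 0)
                    if (not filter_bases) or (
                        bq >= policy.min_base_quality
                        and dist >= policy.terminal_exclusion
                    ):
                        self._add_indel(f"-{length}", rpos, strand, bq, dist)
                rpos += length
            elif op == 3:  # N: reference skip (spliced RNA)
                rpos += length
            elif op == 4:  # soft clip
                qpos += length
            # H/P consume nothing we track

    def _add_indel(self, allele: str, pos: int, strand: int, qual: int, dist: int) -> None:
        # left-normalise so equivalent indel representations share a position
        from .calling import left_align_indel

        off, allele = left_align_indel(self.ref_str, pos - self.start, allele)
        pos = self.start + off
        tally = self.indels.setdefault(pos, {}).setdefault(allele, AlleleTally())
        if strand:
            tally.rev += 1
        else:
            tally.fwd += 1
        tally.qual_sum += qual
        tally.end_distances.append(dist)

    def finalize(self) -> None:
        if self._var_pos:
            self.var_pos = np.concatenate(self._var_pos)
            self.var_base = np.concatenate(self._var_base)
            self.var_dist = np.concatenate(self._var_dist)
        else:
            self.var_pos = np.empty(0, dtype=np.int64)
            self.var_base = np.empty(0, dtype=np.int8)
            self.var_dist = np.empty(0, dtype=np.int64)
        order = np.argsort(self.var_pos, kind="stable")
        self.var_pos = self.var_pos[order]
        self.var_base = self.var_base[order]
        self.var_dist = self.var_dist[order]
        indel_depth = np.zeros(self.end - self.start, dtype=np.int32)
        for pos, alleles in self.indels.items():
            indel_depth[pos - self.start] += sum(t.count for t in alleles.values())
        self.hq_depth = self.sub_counts.sum(axis=(1, 2)) + indel_depth
        self._finalized = True

    # -- access -----------------------------------------------------------

    def hq_depth_at(self, pos: int) -> int:
        return int(self.hq_depth[pos - self.start])

    def raw_depth_at(self, pos: int) -> int:
        return int(self.raw[pos - self.start])

    def _end_distances(self, pos: int, base_slot: int) -> list:
        lo = np.searchsorted(self.var_pos, pos, side="left")
        hi = np.searchsorted(self.var_pos, pos, side="right")
        sel = self.var_base[lo:hi] == base_slot
        return self.var_dist[lo:hi][sel].tolist()

    def column(self, pos: int) -> PileupColumn:
        if not self._finalized:
            raise RuntimeError("RegionPileup not finalized")
        off = pos - self.start
        if not 0 <= off < self.end - self.start:
            raise IndexError(f"position {pos} outside region")
        tallies: dict[str, AlleleTally] = {}
        ref_slot = int(self.ref_index[off])
        for b in range(N_BASE_SLOTS):
            fwd = int(self.sub_counts[off, b, 0])
            rev = int(self.sub_counts[off, b, 1])
            if fwd + rev == 0:
                continue
            dists = self._end_distances(pos, b) if b != ref_slot else []
            tallies[ALLELE_BASES[b]] = AlleleTally(
                fwd=fwd, rev=rev, qual_sum=int(self.qual_sums[off, b]), end_distances=dists
            )
        for allele, t in self.indels.get(pos, {}).items():
            tallies[allele] = replace(t, end_distances=list(t.end_distances))
        return PileupColumn(
            contig=self.contig,
            position=pos,
            tallies=tallies,
            raw_depth=int(self.raw[off]),
            hq_depth=int(self.hq_depth[off]),
            ref_base=chr(self.ref_bytes[off]),
        )


def pileup_region(
    alignments,
    contig: str,
    start: int,
    end: int,
    policy: ReadPolicy = ReadPolicy(),
    reference=None,
    germline: bool = False,
) -> RegionPileup:
    """Build a :class:`RegionPileup` for ``[start, end)``.

    ``alignments`` is an open ``pysam.AlignmentFile`` with an index;
    ``reference`` an open ``pysam.FastaFile``.  With ``germline=True`` and
    ``policy.germline_accept_all`` the read and base filters are bypassed
    (primary, mapped alignments only) so that every observed germline allele
    is tallied.
    """
    if reference is None:
        raise ValueError("a reference accessor is required")
    if contig not in reference.references:
        raise ValueError(f"contig {contig!r} not in reference")
    clen = reference.get_reference_length(contig)
    if not 0 <= start < end <= clen:
        raise ValueError(f"region {contig}:{start}-{end} outside contig of length {clen}")
    accept_all = germline and policy.germline_accept_all
    pile = RegionPileup(contig, start, end, reference.fetch(contig, start, end))
    for read in alignments.fetch(contig, start, end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        pile.add_raw_span(read.reference_start, read.reference_end)
        if not accept_all and not read_passes_filters(read, policy, reference):
            continue
        pile.add_read_observations(read, policy, filter_bases=not accept_all)
    pile.finalize()
    return pile


def pileup_site(
    alignments,
    contig: str,
    position: int,
    policy: ReadPolicy = ReadPolicy(),
    reference=None,
    germline: bool = False,
) -> PileupColumn:
    """Single-site convenience wrapper around :func:`pileup_region`."""
    return pileup_region(
        alignments, contig, position, position + 1, policy, reference, germline
    ).column(position)


def homopolymer_flank_ok(reference, contig: str, position: int, max_run: int = 4) -> bool:
    """True unless a single-nucleotide run longer than ``max_run`` abuts the
    site on either flank.  Flanks truncated at contig ends are evaluated as
    seen (never an error)."""
    clen = reference.get_reference_length(contig)
    left = reference.fetch(contig, max(0, position - max_run - 1), position).upper()
    right = reference.fetch(contig, position + 1, min(clen, position + max_run + 2)).upper()
    run = 0
    for ch in reversed(left):
        if ch == left[-1]:
            run += 1
        else:
            break
    if left and run > max_run:
        return False
    run = 0
    for ch in right:
        if ch == right[0]:
            run += 1
        else:
            break
    return not (right and run > max_run)


def homopolymer_ok_array(ref_bytes: np.ndarray, max_run: int = 4) -> np.ndarray:
    """Vectorised :func:`homopolymer_flank_ok` over a contiguous reference
    slice; element i answers for position i of the slice (flanks truncated at
    the slice edges)."""
    L = len(ref_bytes)
    if L == 0:
        return np.zeros(0, dtype=bool)
    # run id per position, then run lengths
    change = np.empty(L, dtype=bool)
    change[0] = True
    change[1:] = ref_bytes[1:] != ref_bytes[:-1]
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    # run ending immediately left of i is the run of i-1 (unless same run as i,
    # in which case the adjacent left run is i's own run truncated at i-1:
    # positions i-1, i-2, ... share ref_bytes[i-1] == ref_bytes[i]? No: if
    # i-1 is in the same run as i, the maximal run adjacent on the left is
    # that run minus position i onward — its length up to i-1.
    starts = np.zeros(len(run_len), dtype=np.int64)
    np.cumsum(run_len[:-1], out=starts[1:])
    left_bad = np.zeros(L, dtype=bool)
    right_bad = np.zeros(L, dtype=bool)
    idx = np.arange(L)
    # left flank: run of identical bases ending at i-1
    prev_same = np.zeros(L, dtype=np.int64)
    prev_same[1:] = np.where(
        ref_bytes[1:] == ref_bytes[:-1],
        idx[1:] - starts[run_id[1:]],  # same run: length from run start to i-1
        run_len[run_id[:-1]],  # different: full previous run
    )
    left_bad = prev_same > max_run
    next_same = np.zeros(L, dtype=np.int64)
    ends = starts + run_len  # one past run end
    next_same[:-1] = np.where(
        ref_bytes[:-1] == ref_bytes[1:],
        ends[run_id[:-1]] - (idx[:-1] + 1),
        run_len[run_id[1:]],
    )
    right_bad = next_same > max_run
    return ~(left_bad | right_bad)


def site_quality_gate(
    germline_col: PileupColumn | None,
    dna_col: PileupColumn | None,
    rna_col: PileupColumn | None,
    reference,
    germline_indel_nearby: bool = False,
    min_germline_depth: int = 10,
    min_tumor_hq_depth: int = 5,
    min_hq_proportion: float = 0.25,
) -> bool:
    """Site-level clause of the high-quality data filter.

    Requires germline depth >= 10, tumor high-quality depth >= 5 in DNA *or*
    RNA, no homopolymer run > 4 on either flank, a high-quality-base
    proportion >= 0.25 in DNA or RNA, and no germline indel at >= 10% allele
    fraction within +/-50 positions (``germline_indel_nearby`` summarises
    that scan).  Missing modalities count as depth 0.
    """
    ref_col = germline_col or dna_col or rna_col
    if ref_col is None:
        return False
    g_depth = germline_col.hq_depth if germline_col is not None else 0
    if g_depth < min_germline_depth:
        return False
    hq = [c.hq_depth if c is not None else 0 for c in (dna_col, rna_col)]
    if max(hq) < min_tumor_hq_depth:
        return False
    prop_ok = False
    for c in (dna_col, rna_col):
        if c is not None and c.raw_depth > 0 and c.hq_depth / c.raw_depth >= min_hq_proportion:
            prop_ok = True
    if not prop_ok:
        return False
    if not homopolymer_flank_ok(reference, ref_col.contig, ref_col.position):
        return False
    return not germline_indel_nearby
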