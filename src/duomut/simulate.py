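"""Spike-in tumor simulation and synthetic alignment fixtures.

Two layers:

* a **from-scratch fixture generator** that writes a synthetic reference and
  internally consistent paired-end alignments (flags, qualities, NM tags,
  duplicates, heterozygous germline SNPs, uniform sequencing error), so the
  whole pipeline can be exercised without external data;
* the **spike-in editor**, which samples ground-truth mutation sites from
  exons (substitutions : insertions : deletions at 90 : 5 : 5, indel lengths
  1-6 at 60 : 20 : 9 : 5 : 5 : 1 percent) and edits a fixed fraction of the
  reads overlapping each site to carry the mutant allele.  Substituted and
  inserted bases use the non-nucleotide character ``V`` so spiked alleles can
  never collide with the germline genotype.  The original, unedited
  alignments then serve as the simulated germline — any real somatic
  variants present simply join the germline genotype and are not truth
  positives.

Sites that end up with zero eligible reads stay in the truth table flagged
uncovered, mirroring the reality that no technology covers every site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .calling import left_align_indel

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "FixtureConfig",
    "SyntheticGenome",
    "make_genome",
    "write_reference",
    "simulate_reads",
    "generate_fixture_alignments",
    "expression_profile",
    "sample_truth",
    "spike_alignments",
    "truth_to_tsv",
    "truth_from_tsv",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Truth-set sampling parameters.

    Defaults are the standard simulation design: 500 sites per genome,
    mutant classes substitution/insertion/deletion at rates 0.90/0.05/0.05,
    indel lengths 1..6 at rates 0.60/0.20/0.09/0.05/0.05/0.01.
    """

    n_sites: int = 500
    class_rates: tuple = (0.90, 0.05, 0.05)
    indel_length_rates: tuple = (0.60, 0.20, 0.09, 0.05, 0.05, 0.01)
    maf: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.class_rates, self.indel_length_rates):
            if abs(sum(rates) - 1.0) > 1e-9:
                raise ValueError("rates must sum to 1")
        if not 0 < self.maf <= 1:
            raise ValueError("maf must be in (0, 1]")


@dataclass
class TruthRecord:
    """One ground-truth mutation: position (0-based), allele in the caller's
    string notation (substitution base, ``+SEQ`` insertion, ``-L`` deletion),
    the targeted mutant allele fraction, and per-modality coverage flags set
    during spiking."""

    contig: str
    position: int
    allele_class: str  # substitution / insertion / deletion
    allele: str
    target_maf: float
    covered_dna: bool = False
    covered_rna: bool = False


# ---------------------------------------------------------------------------
# synthetic genome + reads


@dataclass(frozen=True)
class FixtureConfig:
    contig: str = "sim1"
    length: int = 20000
    depth: float = 50.0
    read_length: int = 100
    fragment_mean: int = 260
    fragment_sd: float = 30.0
    error_rate: float = 0.003
    low_qual_rate: float = 0.02
    base_quality: int = 35
    low_base_quality: int = 11
    duplicate_rate: float = 0.02
    qcfail_rate: float = 0.005
    het_snp_rate: float = 1.0 / 1500.0
    mapping_quality: int = 60
    paired: bool = True
    seed: int = 0


@dataclass
class SyntheticGenome:
    contig: str
    sequence: str
    het_sites: dict = field(default_factory=dict)  # 0-based pos -> alt base


def make_genome(length: int, contig: str = "sim1", het_snp_rate: float = 1 / 1500, seed: int = 0) -> SyntheticGenome:
    """Random reference plus a diploid individual's heterozygous SNPs
    (placed at roughly one per 1.5 kb, the human-like rate)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_BASES), size=length))
    n_het = rng.binomial(length, het_snp_rate)
    het = {}
    for pos in sorted(rng.choice(length, size=n_het, replace=False).tolist()):
        ref = seq[pos]
        het[pos] = rng.choice([b for b in _BASES if b != ref])
    return SyntheticGenome(contig=contig, sequence=seq, het_sites=het)


def write_reference(genome: SyntheticGenome, path) -> str:
    path = str(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.contig}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    pysam.faidx(path)
    return path


def expression_profile(n_exons: int, dropout: float = 0.2, sigma: float = 0.8, seed: int = 0) -> np.ndarray:
    """Per-exon depth multipliers emulating expression-dependent RNA
    coverage: a lognormal spread with a fraction of unexpressed exons."""
    rng = np.random.default_rng(seed)
    scale = rng.lognormal(mean=-(sigma ** 2) / 2, sigma=sigma, size=n_exons)
    scale[rng.random(n_exons) < dropout] = 0.0
    return scale


def simulate_reads(
    genome: SyntheticGenome,
    out_bam,
    config: FixtureConfig,
    regions: list | None = None,
    seed: int | None = None,
) -> str:
    """Write sorted, indexed paired-end alignments drawn from ``genome``.

    ``regions`` is an optional list of ``(start, end, depth_scale)`` tuples
    restricting fragments to sub-intervals (exons) with per-interval depth
    multipliers — the RNA-like mode.  Without it, fragments cover the whole
    contig at ``config.depth``.  Reads carry valid flags, per-base
    qualities, MAPQ, and an NM tag consistent with their sequence; output is
    deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = len(genome.sequence)
    rl = config.read_length
    if regions is None:
        regions = [(0, L, 1.0)]
    seq_arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    records = []  # (sort_pos, serial, read-tuple)
    serial = 0
    for start, end, scale in regions:
        span = end - start
        if span < rl or scale <= 0:
            continue
        target_depth = config.depth * scale
        n_frag = int(round(target_depth * span / (2 * rl if config.paired else rl)))
        if n_frag == 0:
            continue
        flens = np.clip(
            rng.normal(config.fragment_mean, config.fragment_sd, n_frag).round().astype(int),
            rl,
            L,
        )
        # fragments may begin upstream of the interval (transcripts are not
        # clipped at exon edges), keeping mate/strand coverage balanced at
        # every interior position
        lo = np.maximum(0, start - (flens - rl))
        hi = np.maximum(lo, np.minimum(end - rl, L - flens))
        starts = lo + (rng.random(n_frag) * (hi - lo + 1)).astype(int)
        haps = rng.random(n_frag) < 0.5
        for fstart, flen, hap in zip(starts, flens, haps):
            fend = int(fstart + flen)
            name = f"frag{serial}"
            mates = [(int(fstart), False)]  # (read start, reverse?)
            if config.paired:
                mates.append((fend - rl, True))
            built = []
            for rstart, is_rev in mates:
                arr = seq_arr[rstart : rstart + rl].copy()
                if hap:
                    for pos, alt in genome.het_sites.items():
                        if rstart <= pos < rstart + rl:
                            arr[pos - rstart] = ord(alt)
                nerr = rng.binomial(rl, config.error_rate)
                if nerr:
                    for qpos in rng.choice(rl, size=nerr, replace=False):
                        cur = chr(arr[qpos])
                        arr[qpos] = ord(rng.choice([b for b in _BASES if b != cur]))
                quals = np.full(rl, config.base_quality, dtype=np.uint8)
                nlow = rng.binomial(rl, config.low_qual_rate)
                if nlow:
                    quals[rng.choice(rl, size=nlow, replace=False)] = config.low_base_quality
                nm = int((arr != seq_arr[rstart : rstart + rl]).sum())
                built.append((rstart, is_rev, arr.tobytes().decode(), quals.tolist(), nm))
            is_dup = bool(rng.random() < config.duplicate_rate)
            is_qcfail = bool(rng.random() < config.qcfail_rate)
            for i, (rstart, is_rev, seq, quals, nm) in enumerate(built):
                flag = 0
                if config.paired:
                    flag |= 0x1 | 0x2  # paired, proper pair
                    flag |= 0x40 if i == 0 else 0x80
                    if is_rev:
                        flag |= 0x10
                    else:
                        flag |= 0x20  # mate reverse
                if is_dup:
                    flag |= 0x400
                if is_qcfail:
                    flag |= 0x200
                mate_start = built[1 - i][0] if config.paired else rstart
                tlen = 0
                if config.paired:
                    tlen = flen if i == 0 else -flen
                records.append(
                    (rstart, serial, (name, flag, rstart, seq, quals, nm, mate_start, int(tlen)))
                )
            serial += 1
    records.sort(key=lambda r: (r[0], r[1]))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.contig, "LN": L}],
    }
    out_bam = str(out_bam)
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for _, _, (name, flag, rstart, seq, quals, nm, mate_start, tlen) in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = rstart
            a.mapping_quality = config.mapping_quality
            a.cigartuples = [(0, rl)]
            a.query_sequence = seq
            a.query_qualities = quals
            if config.paired:
                a.next_reference_id = 0
                a.next_reference_start = mate_start
                a.template_length = tlen
            a.set_tag("NM", nm)
            bam.write(a)
    pysam.index(out_bam)
    return out_bam


def generate_fixture_alignments(out_dir, config: FixtureConfig = FixtureConfig()) -> dict:
    """One-call fixture: synthetic reference + sorted, indexed alignments.

    Returns ``{"reference": fasta_path, "alignments": bam_path,
    "genome": SyntheticGenome}``; byte-identical for identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(
        config.length, config.contig, config.het_snp_rate, seed=config.seed
    )
    ref = write_reference(genome, out_dir / "reference.fa")
    bam = simulate_reads(genome, out_dir / "alignments.bam", config, seed=config.seed + 1)
    return {"reference": ref, "alignments": bam, "genome": genome}


# ---------------------------------------------------------------------------
# truth sampling


def sample_truth(
    exons: list,
    config: SimulationConfig,
    contig: str = "sim1",
    reference: str | None = None,
) -> list:
    """Sample ``config.n_sites`` distinct ground-truth mutation sites from
    exon space.

    ``exons`` is a list of 0-based half-open ``(start, end)`` intervals;
    ``reference`` (the contig sequence, optional) left-normalises deletion
    positions so the spiked representation matches the caller's left-aligned
    alleles.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    offsets = []
    for start, end in exons:
        if end > start:
            offsets.append((start, end))
    space = sum(e - s for s, e in offsets)
    if space < config.n_sites:
        raise ValueError(f"exon space ({space}) smaller than n_sites ({config.n_sites})")
    if config.n_sites == 0:
        return []
    flat = rng.choice(space, size=config.n_sites, replace=False)
    flat.sort()
    positions = []
    bounds = np.cumsum([e - s for s, e in offsets])
    for off in flat:
        i = int(np.searchsorted(bounds, off, side="right"))
        base = bounds[i - 1] if i else 0
        positions.append(offsets[i][0] + int(off - base))
    classes = rng.choice(
        ["substitution", "insertion", "deletion"], size=config.n_sites, p=config.class_rates
    )
    records = []
    taken = set()
    for pos, cls in zip(positions, classes):
        if cls == "substitution":
            allele = "V"
        else:
            length = int(rng.choice(np.arange(1, 7), p=config.indel_length_rates))
            if cls == "insertion":
                allele = "+" + "V" * length
            else:
                allele = f"-{length}"
                if reference is not None:
                    pos, allele = left_align_indel(reference, pos, allele)
        if pos in taken:
            continue  # rare collision after left-normalisation
        taken.add(pos)
        records.append(
            TruthRecord(
                contig=contig,
                position=int(pos),
                allele_class=str(cls),
                allele=allele,
                target_maf=config.maf,
            )
        )
    records.sort(key=lambda r: r.position)
    return records


def truth_to_tsv(truth: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tclass\tallele\ttarget_maf\tcovered_dna\tcovered_rna\n")
        for r in truth:
            fh.write(
                f"{r.contig}\t{r.position + 1}\t{r.allele_class}\t{r.allele}"
                f"\t{r.target_maf:g}\t{int(r.covered_dna)}\t{int(r.covered_rna)}\n"
            )


def truth_from_tsv(path) -> list:
    records = []
    with open(path) as fh:
        header = fh.readline()
        del header
        for line in fh:
            c, p, cls, allele, maf, cd, cr = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    contig=c,
                    position=int(p) - 1,
                    allele_class=cls,
                    allele=allele,
                    target_maf=float(maf),
                    covered_dna=bool(int(cd)),
                    covered_rna=bool(int(cr)),
                )
            )
    return records


# ---------------------------------------------------------------------------
# read editing


def _expand_cigar(read) -> list:
    """Per-base expansion of the CIGAR as (op, query_index, ref_index)
    triples (None where the op does not consume that coordinate)."""
    out = []
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):
            for _ in range(length):
                out.append((0, qpos, rpos))
                qpos += 1
                rpos += 1
        elif op in (1, 4):  # insertion / soft clip consume query
            for _ in range(length):
                out.append((op, qpos, None))
                qpos += 1
        elif op in (2, 3):  # deletion / ref skip
            for _ in range(length):
                out.append((op, None, rpos))
                rpos += 1
        elif op == 5:  # hard clip: no coordinates
            out.append((5, None, length))
    return out


def _compress(elements, seq_chars, quals):
    cigar = []
    for op, _q, _r in elements:
        if op == 5:
            cigar.append((5, _r))
            continue
        if cigar and cigar[-1][0] == op and op != 5:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar, "".join(seq_chars), quals


def _apply_edits(read, edits) -> None:
    """Rewrite one read in place to carry the given spiked alleles.

    ``edits``: list of (class, ref position, payload) with payload the
    insertion length or deletion length (substitutions need none).  Base
    qualities at edited positions are preserved; inserted bases copy the
    anchor base's quality.  The NM tag is left untouched so the spiked
    allele does not count against the read-level mismatch budget.
    """
    elements = _expand_cigar(read)
    seq = list(read.query_sequence)
    quals = list(read.query_qualities)
    # apply right-to-left so earlier query indices stay valid
    for cls, rpos, payload in sorted(edits, key=lambda e: -e[1]):
        if cls == "substitution":
            for op, q, r in elements:
                if op == 0 and r == rpos:
                    seq[q] = "V"
                    break
        elif cls == "insertion":
            idx = next(
                i for i, (op, q, r) in enumerate(elements) if op == 0 and r == rpos
            )
            q_anchor = elements[idx][1]
            ins = [(1, None, None)] * payload
            elements[idx + 1 : idx + 1] = ins
            seq[q_anchor + 1 : q_anchor + 1] = ["V"] * payload
            quals[q_anchor + 1 : q_anchor + 1] = [quals[q_anchor]] * payload
            # re-number query indices
            elements = _renumber(elements)
        else:  # deletion of [rpos, rpos+payload)
            new_elements = []
            drop_q = set()
            for op, q, r in elements:
                if op == 0 and r is not None and rpos <= r < rpos + payload:
                    new_elements.append((2, None, r))
                    drop_q.add(q)
                else:
                    new_elements.append((op, q, r))
            seq = [ch for i, ch in enumerate(seq) if i not in drop_q]
            quals = [qv for i, qv in enumerate(quals) if i not in drop_q]
            elements = _renumber(new_elements)
    cigar, new_seq, new_quals = _compress(elements, seq, quals)
    read.query_sequence = new_seq
    read.query_qualities = new_quals
    read.cigartuples = cigar


def _renumber(elements):
    out = []
    q = 0
    for op, old_q, r in elements:
        if op in (0, 1, 4):
            out.append((op, q, r))
            q += 1
        else:
            out.append((op, old_q, r))
    return out


def _eligible(read, rec: TruthRecord) -> bool:
    """Can this read carry the spiked allele with a well-formed alignment?"""
    pairs = {r: q for op, q, r in _expand_cigar(read) if op == 0}
    pos = rec.position
    if rec.allele_class == "substitution":
        return pos in pairs
    if rec.allele_class == "insertion":
        return pos in pairs and pos + 1 in pairs
    length = int(rec.allele[1:])
    return pos - 1 in pairs and all(pos + i in pairs for i in range(length)) and pos + length in pairs


def spike_alignments(
    alignments_path,
    truth: list,
    out_path,
    seed: int = 0,
    maf: float | None = None,
    modality: str = "dna",
) -> list:
    """Edit reads so each covered truth site carries its mutant allele at
    exactly ``round(maf * eligible_read_count)`` reads.

    Reads are chosen uniformly at random (seeded); reads not overlapping a
    truth site are copied through byte-for-byte.  Returns the truth list
    with the modality's covered flags updated (``covered_*`` is False at
    sites where no read could carry the allele).  Output is coordinate
    sorted and indexed.
    """
    rng = np.random.default_rng(seed)
    alignments_path = str(alignments_path)
    out_path = str(out_path)
    edits_by_read: dict = {}
    updated = []
    with pysam.AlignmentFile(alignments_path, "rb") as bam:
        for rec in truth:
            target = rec.target_maf if maf is None else maf
            eligible = []
            for read in bam.fetch(rec.contig, max(0, rec.position - 1), rec.position + 1):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if _eligible(read, rec):
                    eligible.append(read)
            n_edit = int(round(target * len(eligible)))
            covered = n_edit > 0
            if covered:
                chosen = rng.choice(len(eligible), size=n_edit, replace=False)
                for i in chosen:
                    read = eligible[int(i)]
                    key = (read.query_name, read.is_read1, read.reference_start)
                    payload = None
                    if rec.allele_class != "substitution":
                        payload = (
                            len(rec.allele) - 1
                            if rec.allele_class == "insertion"
                            else int(rec.allele[1:])
                        )
                    edits_by_read.setdefault(key, []).append(
                        (rec.allele_class, rec.position, payload)
                    )
            updated.append(
                replace(
                    rec,
                    covered_dna=covered if modality == "dna" else rec.covered_dna,
                    covered_rna=covered if modality == "rna" else rec.covered_rna,
                )
            )
    with pysam.AlignmentFile(alignments_path, "rb") as src, pysam.AlignmentFile(
        out_path, "wb", template=src
    ) as dst:
        for read in src.fetch(until_eof=True):
            key = (read.query_name, read.is_read1, read.reference_start)
            edits = edits_by_read.get(key)
            if edits:
                _apply_edits(read, edits)
            dst.write(read)
    pysam.index(out_path)
    return updated
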