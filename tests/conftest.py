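"""Shared fixtures: in-memory reads, synthetic genomes, and a spiked
two-modality alignment set that several test modules re-use."""

from __future__ import annotations

import hypothesis
import numpy as np
import pysam
import pytest

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None
)
hypothesis.settings.load_profile("deterministic")

from duomut.pileup import AlleleTally, PileupColumn
from duomut.pipeline import CallerConfig, call_regions
from duomut.simulate import (
    FixtureConfig,
    SimulationConfig,
    expression_profile,
    generate_fixture_alignments,
    sample_truth,
    simulate_reads,
    spike_alignments,
)

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "sim1", "LN": 1_000_000}]}
)


def make_read(
    name: str = "r1",
    start: int = 100,
    seq: str = "A" * 50,
    quals=None,
    mapq: int = 60,
    cigar=None,
    nm: int = 0,
    proper_pair: bool = True,
    duplicate: bool = False,
    qcfail: bool = False,
    secondary: bool = False,
    reverse: bool = False,
    x0: int | None = None,
    with_nm: bool = True,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = cigar or [(0, len(seq))]
    a.query_sequence = seq
    a.query_qualities = quals if quals is not None else [35] * len(seq)
    flag = 0x1 | 0x40
    if proper_pair:
        flag |= 0x2
    if duplicate:
        flag |= 0x400
    if qcfail:
        flag |= 0x200
    if secondary:
        flag |= 0x100
    if reverse:
        flag |= 0x10
    a.flag = flag
    if with_nm:
        a.set_tag("NM", nm)
    if x0 is not None:
        a.set_tag("X0", x0)
    return a


def make_column(
    tallies: dict,
    position: int = 1000,
    contig: str = "sim1",
    ref_base: str = "A",
    raw_depth: int | None = None,
) -> PileupColumn:
    """Build a pileup column from {allele: (fwd, rev)} or
    {allele: (fwd, rev, qual_sum, distances)} shorthand."""
    built = {}
    for allele, spec in tallies.items():
        fwd, rev = spec[0], spec[1]
        qual = spec[2] if len(spec) > 2 else 35 * (fwd + rev)
        dists = list(spec[3]) if len(spec) > 3 else []
        built[allele] = AlleleTally(fwd=fwd, rev=rev, qual_sum=qual, end_distances=dists)
    hq = sum(t.count for t in built.values())
    return PileupColumn(
        contig=contig,
        position=position,
        tallies=built,
        raw_depth=raw_depth if raw_depth is not None else hq,
        hq_depth=hq,
        ref_base=ref_base,
    )


def write_bam(reads, path, contig_len: int = 1_000_000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "sim1", "LN": contig_len}]}
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for read in sorted(reads, key=lambda r: r.reference_start):
            bam.write(read)
    pysam.index(path)
    return path


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """20 kb genome, depth 50: reference + DNA-like alignments."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture_alignments(out, FixtureConfig(length=20000, depth=50, seed=7))


@pytest.fixture(scope="session")
def spiked(small_fixture, tmp_path_factory):
    """Two-modality spike-in at 30% MAF over exon intervals; the unedited
    alignments act as the simulated germline."""
    out = tmp_path_factory.mktemp("spiked")
    genome = small_fixture["genome"]
    exons = [(s, s + 300) for s in range(100, 19500, 500)]
    cfg = SimulationConfig(n_sites=12, maf=0.3, seed=3)
    truth = sample_truth(exons, cfg, contig=genome.contig, reference=genome.sequence)
    dna_spiked = out / "dna_spiked.bam"
    truth = spike_alignments(small_fixture["alignments"], truth, dna_spiked, seed=11, modality="dna")
    scales = expression_profile(len(exons), seed=5)
    rna_bam = simulate_reads(
        genome,
        out / "rna.bam",
        FixtureConfig(length=20000, depth=50, seed=7),
        regions=[(s, e, sc) for (s, e), sc in zip(exons, scales)],
        seed=99,
    )
    rna_spiked = out / "rna_spiked.bam"
    truth = spike_alignments(rna_bam, truth, rna_spiked, seed=12, modality="rna")
    return {
        "genome": genome,
        "reference": small_fixture["reference"],
        "germline": small_fixture["alignments"],
        "rna_germline": str(rna_bam),
        "dna": str(dna_spiked),
        "rna": str(rna_spiked),
        "exons": exons,
        "regions": [(genome.contig, s, e) for s, e in exons],
        "truth": truth,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def called(spiked):
    """Full caller run over the spiked fixture."""
    config = CallerConfig(null_target_sites=3000, seed=1)
    result = call_regions(
        spiked["dna"],
        spiked["rna"],
        spiked["germline"],
        spiked["reference"],
        spiked["regions"],
        config=config,
    )
    return {"result": result, **spiked}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
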