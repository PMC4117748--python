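"""Whole-region orchestration of the mutation caller.

``call_regions`` runs the complete per-site algorithm across a region set:
pileup + high-quality data filter, germline genotyping with polymorphism /
artifact augmentation, per-modality variant counting, within-modality indel
re-alignment and cross-modality indel merging, the high-quality variant
filter, beta-binomial testing, and the Stouffer meta combination.  It also
fits the beta-binomial null parameters from randomly sampled high-quality
sites when they are not supplied.

Sites where neither modality shows a single non-germline read are emitted
through a vectorised fast path (k = 0, P = 1); only sites carrying variant
evidence take the full per-site object path.  Both paths share the same
filter arithmetic, and the dual-route agreement is exercised in the tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from . import calling
from .calling import (
    GermlineGenotype,
    NullParams,
    SiteCounts,
    augment_alleles,
    combine_counts,
    estimate_null_params,
    identify_germline_alleles,
    is_na,
    merge_cross_modality_indels,
    realign_indel_counts,
    tumor_variant_counts,
)
from .pileup import (
    N_BASE_SLOTS,
    ReadPolicy,
    RegionPileup,
    homopolymer_ok_array,
    pileup_region,
)

logger = logging.getLogger(__name__)

__all__ = ["CallerConfig", "CallResult", "call_regions"]

#: padding added around each region while building pileups so that indel
#: re-alignment, homopolymer flanks and the germline indel scan see context
#: beyond the region edge; calls are only emitted inside the region proper.
_CONTEXT_PAD = 50


@dataclass
class CallerConfig:
    """Operating parameters; defaults are the caller's standard values."""

    policy: ReadPolicy = field(default_factory=ReadPolicy)
    min_germline_depth: int = 10
    min_tumor_hq_depth: int = 5
    min_hq_proportion: float = 0.25
    germline_prevalence: float = 0.02
    indel_realign_span: int = 20
    indel_merge_window: int = 20
    germline_indel_af: float = 0.10
    germline_indel_range: int = 50
    meta_threshold: float = 1.1e-9
    dna_threshold: float = 9.3e-9
    null_target_sites: int = 50000
    seed: int = 0
    germline_mode: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["policy"] = dataclasses.asdict(self.policy)
        return d


@dataclass
class CallResult:
    """Call table plus run metadata (test counts, null parameters, seed)."""

    table: pd.DataFrame
    n_tests: dict
    null_params: dict
    n_sites_gated: int
    config: CallerConfig
    seed: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["sig_meta"]]


def _open_alignment(source):
    if source is None:
        return None, False
    if isinstance(source, pysam.AlignmentFile):
        return source, False
    return pysam.AlignmentFile(str(source)), True


def _open_reference(source):
    if isinstance(source, pysam.FastaFile):
        return source, False
    return pysam.FastaFile(str(source)), True


class _RegionData:
    """Per-region pileups plus the vectorised gate/candidate masks."""

    def __init__(self, contig, start, end, gp, dp, rp, config, ref_slice):
        self.contig = contig
        self.start = start  # region proper (unpadded)
        self.end = end
        self.gp = gp
        self.dp = dp
        self.rp = rp
        pstart = gp.start if gp is not None else (dp or rp).start
        self.pstart = pstart
        lo = start - pstart
        hi = end - pstart
        self.sl = slice(lo, hi)
        L = end - start

        def _hq(p):
            return p.hq_depth[self.sl] if p is not None else np.zeros(L, np.int32)

        def _raw(p):
            return p.raw[self.sl] if p is not None else np.zeros(L, np.int32)

        d_hq, r_hq = _hq(dp), _hq(rp)
        d_raw, r_raw = _raw(dp), _raw(rp)
        gate = np.ones(L, dtype=bool)
        if not config.germline_mode:
            gate &= _hq(gp) >= config.min_germline_depth
        gate &= np.maximum(d_hq, r_hq) >= config.min_tumor_hq_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_ok = np.zeros(L, dtype=bool)
            for hq, raw in ((d_hq, d_raw), (r_hq, r_raw)):
                with_raw = raw > 0
                frac = np.zeros(L)
                frac[with_raw] = hq[with_raw] / raw[with_raw]
                prop_ok |= with_raw & (frac >= config.min_hq_proportion)
        gate &= prop_ok
        # homopolymer flanks, evaluated on the padded reference slice
        homo = homopolymer_ok_array(
            np.frombuffer(ref_slice.upper().encode(), np.uint8)
        )
        gate &= homo[lo:hi]
        # germline indel exclusion zone
        if gp is not None:
            bad = np.zeros(L, dtype=bool)
            for pos, alleles in gp.indels.items():
                depth = gp.hq_depth_at(pos)
                if depth <= 0:
                    continue
                if max(t.count for t in alleles.values()) / depth >= config.germline_indel_af:
                    zlo = max(start, pos - config.germline_indel_range) - start
                    zhi = min(end, pos + config.germline_indel_range + 1) - start
                    if zhi > zlo:
                        bad[zlo:zhi] = True
            gate &= ~bad
        self.gate = gate
        self.d_hq, self.r_hq = d_hq, r_hq

        # germline-allele mask per base slot (prevalence >= 2%); fast path only
        if config.germline_mode:
            ref_idx = (gp or dp or rp).ref_index[self.sl]
            gmask = np.zeros((L, N_BASE_SLOTS), dtype=bool)
            gmask[np.arange(L), ref_idx] = True
        else:
            g_counts = gp.sub_counts[self.sl].sum(axis=2)
            g_depth = np.maximum(gp.hq_depth[self.sl], 1)
            gmask = g_counts / g_depth[:, None] >= config.germline_prevalence
        self.gmask = gmask

        def _tumor_arrays(p):
            if p is None:
                return np.zeros((L, N_BASE_SLOTS), np.int64), np.zeros(L, np.int64)
            counts = p.sub_counts[self.sl].sum(axis=2)
            return counts, counts.sum(axis=1)

        self.d_counts, _ = _tumor_arrays(dp)
        self.r_counts, _ = _tumor_arrays(rp)
        d_var = ((self.d_counts > 0) & ~gmask).any(axis=1)
        r_var = ((self.r_counts > 0) & ~gmask).any(axis=1)
        indel_pos = np.zeros(L, dtype=bool)
        for p in (dp, rp):
            if p is None:
                continue
            for pos in p.indels:
                if start <= pos < end:
                    indel_pos[pos - start] = True
        self.candidates = gate & (d_var | r_var | indel_pos)
        # fast-path germline-matching read counts per modality
        self.d_g = (self.d_counts * gmask).sum(axis=1)
        self.r_g = (self.r_counts * gmask).sum(axis=1)


def _genotype_at(rd: _RegionData, pos: int, config, polymorphisms, artifacts) -> GermlineGenotype:
    if config.germline_mode:
        ref_base = chr((rd.gp or rd.dp or rd.rp).ref_bytes[pos - rd.pstart])
        genotype = GermlineGenotype({ref_base}, source_depth=0)
    else:
        genotype = identify_germline_alleles(
            rd.gp.column(pos), config.germline_prevalence
        )
    if config.germline_mode:
        return genotype  # reference-as-germline mode runs without augmentation
    return augment_alleles(genotype, polymorphisms, artifacts, (rd.contig, pos))


def _null_sampler_factory(region_data, config, polymorphisms, artifacts, rna_present):
    """Random high-quality sites as (k_dna, n_dna, k_rna, n_rna) tuples.

    Eligible sites passed the site gate *and* have high-quality tumor depth
    in both modalities (both-modality requirement dropped when no RNA input
    exists).  Sampling order is a seeded permutation of eligible sites.
    """
    eligible = []
    for ri, rd in enumerate(region_data):
        ok = rd.gate & (rd.d_hq >= config.min_tumor_hq_depth)
        if rna_present:
            ok = ok & (rd.r_hq >= config.min_tumor_hq_depth)
        for off in np.flatnonzero(ok):
            eligible.append((ri, int(off)))

    def sampler(seed):
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(eligible))
        for idx in order:
            ri, off = eligible[idx]
            rd = region_data[ri]
            pos = rd.start + off
            if rd.candidates[off]:
                genotype = _genotype_at(rd, pos, config, polymorphisms, artifacts)
                d = (
                    tumor_variant_counts(rd.dp.column(pos), genotype)
                    if rd.dp is not None
                    else SiteCounts(rd.contig, pos)
                )
                r = (
                    tumor_variant_counts(rd.rp.column(pos), genotype)
                    if rd.rp is not None
                    else SiteCounts(rd.contig, pos)
                )
                yield (d.k, d.n, r.k, r.n)
            else:
                yield (0, int(rd.d_g[off]), 0, int(rd.r_g[off]))

    return sampler


def call_regions(
    tumor_dna,
    tumor_rna,
    germline,
    reference,
    regions,
    polymorphisms: dict | None = None,
    artifacts: dict | None = None,
    config: CallerConfig | None = None,
    null_params: dict | None = None,
) -> CallResult:
    """Run the full caller over ``regions`` (0-based half-open intervals).

    ``tumor_dna`` / ``tumor_rna`` / ``germline`` are paths or open
    ``pysam.AlignmentFile`` handles (``tumor_rna`` optional; ``germline``
    may be None only in ``config.germline_mode``, where the reference genome
    itself serves as the germline and no allele augmentation is applied).
    Returns every gated site with counts, MAFs, P-values and filter flags,
    plus the number of statistical tests applied per model.
    """
    config = config or CallerConfig()
    if config.germline_mode:
        polymorphisms = artifacts = None
    dna, close_d = _open_alignment(tumor_dna)
    rna, close_r = _open_alignment(tumor_rna)
    germ, close_g = _open_alignment(germline)
    ref, close_ref = _open_reference(reference)
    if germ is None and not config.germline_mode:
        raise ValueError("germline alignments required outside germline mode")
    if dna is None:
        raise ValueError("tumor DNA alignments are required")
    try:
        region_data = []
        for contig, start, end in regions:
            if contig not in ref.references:
                raise ValueError(f"region contig {contig!r} not in reference")
            clen = ref.get_reference_length(contig)
            if not 0 <= start < end <= clen:
                raise ValueError(f"region {contig}:{start}-{end} outside reference")
            pstart = max(0, start - _CONTEXT_PAD)
            pend = min(clen, end + _CONTEXT_PAD)
            gp = (
                pileup_region(germ, contig, pstart, pend, config.policy, ref, germline=True)
                if germ is not None
                else None
            )
            dp = pileup_region(dna, contig, pstart, pend, config.policy, ref)
            rp = (
                pileup_region(rna, contig, pstart, pend, config.policy, ref)
                if rna is not None
                else None
            )
            ref_slice = ref.fetch(contig, pstart, pend)
            region_data.append(
                _RegionData(contig, start, end, gp, dp, rp, config, ref_slice)
            )

        if null_params is None:
            sampler = _null_sampler_factory(
                region_data, config, polymorphisms, artifacts, rna_present=rna is not None
            )
            if rna is not None:
                null_params = estimate_null_params(
                    sampler, config.null_target_sites, config.seed
                )
            else:
                rows = []
                it = sampler(config.seed)
                for rec in it:
                    rows.append(rec)
                    if len(rows) >= config.null_target_sites:
                        break
                if len(rows) < config.null_target_sites:
                    raise ValueError(
                        f"site sampler exhausted after {len(rows)} of "
                        f"{config.null_target_sites} requested sites"
                    )
                arr = np.asarray(rows, dtype=np.int64)
                null_params = {"DNA": calling.fit_betabinom(arr[:, 0], arr[:, 1], "DNA")}

        rows = []
        tests = {"DNA": 0, "RNA": 0, "META": 0}
        n_gated = 0
        for rd in region_data:
            n_gated += int(rd.gate.sum())
            cand_offsets = np.flatnonzero(rd.candidates)
            # full path: build counts, re-align indels, merge, test
            dna_counts, rna_counts, genotypes = {}, {}, {}
            for off in cand_offsets:
                pos = rd.start + int(off)
                genotype = _genotype_at(rd, pos, config, polymorphisms, artifacts)
                genotypes[pos] = genotype
                dna_counts[pos] = (
                    tumor_variant_counts(rd.dp.column(pos), genotype)
                    if rd.dp is not None
                    else SiteCounts(rd.contig, pos)
                )
                rna_counts[pos] = (
                    tumor_variant_counts(rd.rp.column(pos), genotype)
                    if rd.rp is not None
                    else SiteCounts(rd.contig, pos)
                )
            d_list = realign_indel_counts(
                list(dna_counts.values()), config.indel_realign_span
            )
            r_list = realign_indel_counts(
                list(rna_counts.values()), config.indel_realign_span
            )
            if rd.rp is not None:
                merge_cross_modality_indels(d_list, r_list, config.indel_merge_window)
            d_map = _index_counts(d_list)
            r_map = _index_counts(r_list)
            positions = sorted(set(d_map) | set(r_map))
            ref_bytes = (rd.gp or rd.dp or rd.rp).ref_bytes
            for pos in positions:
                if not (rd.start <= pos < rd.end) or not rd.gate[pos - rd.start]:
                    continue
                d = d_map.get(pos) or SiteCounts(rd.contig, pos)
                r = r_map.get(pos) or SiteCounts(rd.contig, pos)
                call = combine_counts(
                    d, r, null_params, rd.contig, pos, chr(ref_bytes[pos - rd.pstart])
                )
                d_applied = d.k >= 1 and not is_na(call.p_dna)
                r_applied = r.k >= 1 and not is_na(call.p_rna)
                tests["DNA"] += d_applied
                tests["RNA"] += r_applied
                agree = d.major_variant is not None and d.major_variant == r.major_variant
                tests["META"] += (d_applied or (agree and r_applied))
                rows.append(_row_from_call(call, config))
            # fast path: gated sites with no variant evidence anywhere
            plain = rd.gate & ~rd.candidates
            covered_positions = set(positions)
            for off in np.flatnonzero(plain):
                pos = rd.start + int(off)
                if pos in covered_positions:
                    continue
                n_d = int(rd.d_g[off])
                n_r = int(rd.r_g[off])
                p_dna = 1.0 if n_d > 0 else np.nan
                p_rna = 1.0 if n_r > 0 else np.nan
                rows.append(
                    (
                        rd.contig,
                        pos,
                        chr(ref_bytes[pos - rd.pstart]),
                        None, 0, n_d, n_d, np.nan, p_dna,
                        None, 0, n_r, n_r, np.nan, p_rna,
                        p_dna, "", False, False,
                    )
                )
        table = pd.DataFrame(
            rows,
            columns=[
                "contig", "pos", "ref",
                "major_dna", "k_dna", "g_dna", "n_dna", "maf_dna", "p_dna",
                "major_rna", "k_rna", "g_rna", "n_rna", "maf_rna", "p_rna",
                "p_meta", "filters", "sig_dna", "sig_meta",
            ],
        )
        if len(table):
            table = table.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
        logger.info(
            "gated %d sites; applied tests DNA=%d RNA=%d META=%d",
            n_gated, tests["DNA"], tests["RNA"], tests["META"],
        )
        return CallResult(
            table=table,
            n_tests=tests,
            null_params=null_params,
            n_sites_gated=n_gated,
            config=config,
            seed=config.seed,
        )
    finally:
        for handle, close in (
            (dna, close_d), (rna, close_r), (germ, close_g), (ref, close_ref),
        ):
            if close and handle is not None:
                handle.close()


def _index_counts(counts_list):
    out = {}
    for c in counts_list:
        prev = out.get(c.position)
        if prev is None or (c.k, c.n) > (prev.k, prev.n):
            out[c.position] = c
    return out


def _row_from_call(call, config: CallerConfig):
    maf_d = call.maf_dna
    maf_r = call.maf_rna
    sig_d = (not is_na(call.p_dna)) and call.p_dna <= config.dna_threshold
    sig_m = (not is_na(call.p_meta)) and call.p_meta <= config.meta_threshold
    return (
        call.contig,
        call.position,
        call.ref_base,
        call.major_dna, call.k_dna, call.g_dna, call.n_dna,
        maf_d if not is_na(maf_d) else np.nan,
        call.p_dna if not is_na(call.p_dna) else np.nan,
        call.major_rna, call.k_rna, call.g_rna, call.n_rna,
        maf_r if not is_na(maf_r) else np.nan,
        call.p_rna if not is_na(call.p_rna) else np.nan,
        call.p_meta if not is_na(call.p_meta) else np.nan,
        ",".join(sorted(call.filter_flags)),
        sig_d,
        sig_m,
    )
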