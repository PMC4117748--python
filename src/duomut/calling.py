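"""Per-site somatic mutation statistics.

The detection algorithm, per exonic site:

1. filter for high-quality data (see :mod:`duomut.pileup`);
2. identify germline alleles — any allele at >= 2% prevalence in germline
   reads;
3. augment the germline genotype with known population polymorphisms and
   mapping-artifact alleles (these block calls even when unobserved in the
   germline sample);
4. from tumor reads let ``g`` = reads matching germline alleles, the
   *major variant* = the most frequent non-germline allele, ``k`` = its
   read count, ``n = k + g``;
5. for indel major variants, re-align counts onto the strongest nearby site
   carrying the same allele (within 20 positions), and merge matching
   DNA/RNA indels onto a shared position before testing.

If the high-quality *variant* filter passes, the evidence ``k`` of ``n`` is
tested against a beta-binomial null (parameters fit per modality from
50 000 randomly sampled high-quality sites); otherwise P = 1 when k = 0 and
P = NA when the filter rejected real variant reads.  DNA and RNA P-values
are combined by Stouffer's method weighted by the square root of each
modality's read depth — but only when the two modalities nominate the same
major variant allele, which excludes RNA-only signals such as RNA editing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp, ndtr, ndtri
from scipy.stats import chi2

logger = logging.getLogger(__name__)

NA = float("nan")

__all__ = [
    "GermlineGenotype",
    "SiteCounts",
    "NullParams",
    "MutationCall",
    "identify_germline_alleles",
    "augment_alleles",
    "left_align_indel",
    "tumor_variant_counts",
    "realign_indel_counts",
    "merge_cross_modality_indels",
    "variant_filter",
    "strand_bias_pvalue",
    "fit_betabinom",
    "estimate_null_params",
    "betabinom_tail_pvalue",
    "stouffer_meta",
    "call_site",
    "is_na",
]


def is_na(p) -> bool:
    return p is None or (isinstance(p, float) and math.isnan(p))


@dataclass
class GermlineGenotype:
    """Alleles treated as germline at a site: everything observed at >= 2%
    prevalence in germline reads plus any augmented polymorphism/artifact
    alleles."""

    alleles: set
    source_depth: int = 0

    def __contains__(self, allele: str) -> bool:
        return allele in self.alleles


@dataclass
class SiteCounts:
    """Step-4 tallies for one modality at one site.

    ``k``: reads carrying the major variant allele; ``g``: reads matching
    any germline allele; ``n = k + g`` (reads carrying *other* non-germline
    alleles are excluded from n); ``total_variant``: all non-germline reads,
    the denominator of the major-variant prevalence filter.
    """

    contig: str
    position: int
    major_variant: str | None = None
    k: int = 0
    g: int = 0
    k_fwd: int = 0
    k_rev: int = 0
    g_fwd: int = 0
    g_rev: int = 0
    total_variant: int = 0
    end_distances: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.k + self.g

    def __post_init__(self) -> None:
        if self.k < 0 or self.g < 0:
            raise ValueError("counts must be non-negative")
        if (self.major_variant is None) != (self.k == 0):
            raise ValueError("major_variant must be None iff k == 0")


@dataclass(frozen=True)
class NullParams:
    """Beta-binomial null parameters for one modality."""

    alpha: float
    beta: float
    modality: str = "DNA"
    sites_used: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class MutationCall:
    """One tested site: per-modality evidence, P-values and filter flags."""

    contig: str
    position: int
    ref_base: str = "N"
    major_dna: str | None = None
    k_dna: int = 0
    g_dna: int = 0
    major_rna: str | None = None
    k_rna: int = 0
    g_rna: int = 0
    p_dna: float = NA
    p_rna: float = NA
    p_meta: float = NA
    filter_flags: set = field(default_factory=set)

    @property
    def n_dna(self) -> int:
        return self.k_dna + self.g_dna

    @property
    def n_rna(self) -> int:
        return self.k_rna + self.g_rna

    @property
    def maf_dna(self) -> float:
        return self.k_dna / self.n_dna if self.n_dna else NA

    @property
    def maf_rna(self) -> float:
        return self.k_rna / self.n_rna if self.n_rna else NA


# ---------------------------------------------------------------------------
# germline genotype


def identify_germline_alleles(germline_col, min_prevalence: float = 0.02) -> GermlineGenotype:
    """Alleles at >= ``min_prevalence`` fraction of germline high-quality
    depth.  The caller must have gated on germline depth first; zero depth
    is an error here."""
    depth = germline_col.hq_depth
    if depth <= 0:
        raise ValueError(
            f"zero germline depth at {germline_col.contig}:{germline_col.position}"
        )
    alleles = {
        a for a, t in germline_col.tallies.items() if t.count / depth >= min_prevalence
    }
    return GermlineGenotype(alleles=alleles, source_depth=depth)


def augment_alleles(
    genotype: GermlineGenotype,
    polymorphisms: dict | None,
    artifacts: dict | None,
    site: tuple,
) -> GermlineGenotype:
    """Union the genotype with any known polymorphism / mapping-artifact
    alleles mapped at ``site`` (a ``(contig, 0-based position)`` key).
    Augmentation only ever adds alleles — blocking calls on these alleles
    even when they were unobserved in this germline sample."""
    extra = set()
    for mapping in (polymorphisms, artifacts):
        if mapping:
            extra |= set(mapping.get(site, ()))
    if not extra:
        return genotype
    return GermlineGenotype(genotype.alleles | extra, genotype.source_depth)


def left_align_indel(ref_seq: str, offset: int, allele: str) -> tuple[int, str]:
    """Left-normalise an indel allele against ``ref_seq`` (a reference slice;
    ``offset`` indexes into it).

    Insertions are anchored at the preceding aligned position, deletions at
    their first deleted position.  Returns the normalised (offset, allele).
    Insertion sequences containing the non-reference spike character are
    unshiftable and returned as-is.
    """
    if allele.startswith("+"):
        seq = allele[1:]
        while offset > 0 and seq and ref_seq[offset] == seq[-1]:
            seq = ref_seq[offset] + seq[:-1]
            offset -= 1
        return offset, "+" + seq
    if allele.startswith("-"):
        length = int(allele[1:])
        while offset > 0 and offset + length <= len(ref_seq) and ref_seq[offset - 1] == ref_seq[offset + length - 1]:
            offset -= 1
        return offset, allele
    return offset, allele


# ---------------------------------------------------------------------------
# tumor variant counting


def tumor_variant_counts(tumor_col, genotype: GermlineGenotype) -> SiteCounts:
    """Step-4 counts for one tumor modality.

    Ties for the major variant break on higher summed base quality, then
    lexicographically smallest allele, so the result is deterministic.
    """
    g_fwd = g_rev = 0
    candidates = []
    total_variant = 0
    for allele, t in tumor_col.tallies.items():
        if t.count == 0:
            continue
        if allele in genotype:
            g_fwd += t.fwd
            g_rev += t.rev
        else:
            total_variant += t.count
            candidates.append((allele, t))
    if candidates:
        candidates.sort(key=lambda at: (-at[1].count, -at[1].qual_sum, at[0]))
        major, tally = candidates[0]
        return SiteCounts(
            contig=tumor_col.contig,
            position=tumor_col.position,
            major_variant=major,
            k=tally.count,
            g=g_fwd + g_rev,
            k_fwd=tally.fwd,
            k_rev=tally.rev,
            g_fwd=g_fwd,
            g_rev=g_rev,
            total_variant=total_variant,
            end_distances=list(tally.end_distances),
        )
    return SiteCounts(
        contig=tumor_col.contig,
        position=tumor_col.position,
        g=g_fwd + g_rev,
        g_fwd=g_fwd,
        g_rev=g_rev,
    )


def _is_indel(allele: str | None) -> bool:
    return allele is not None and allele[0] in "+-"


def realign_indel_counts(window: list[SiteCounts], span: int = 20) -> list[SiteCounts]:
    """Re-align nearby indel evidence within one modality.

    For each site whose major variant is an indel, scan the ``span``
    neighboring positions for the site ``s`` with maximal ``k`` and the same
    major variant allele; if ``s`` differs, move this site's variant reads
    there (incrementing k at s, decrementing g at s, so n at s is unchanged)
    and zero the donor.  Sites must be position-sorted and single-modality.
    Processing is in position order against current state; ``g`` at the
    destination never drops below zero.
    """
    sites = sorted(window, key=lambda s: s.position)
    for i, site in enumerate(sites):
        if not _is_indel(site.major_variant) or site.k == 0:
            continue
        candidates = [
            other
            for other in sites
            if other.major_variant == site.major_variant
            and abs(other.position - site.position) <= span
        ]
        # maximal k; ties -> nearest, then lowest position (deterministic)
        best = max(
            candidates,
            key=lambda o: (o.k, -abs(o.position - site.position), -o.position),
        )
        if best is site:
            continue
        moved = site.k
        best.k += moved
        best.k_fwd += site.k_fwd
        best.k_rev += site.k_rev
        best.end_distances.extend(site.end_distances)
        dec = min(best.g, moved)
        best.g -= dec
        dec_f = min(best.g_fwd, dec)
        best.g_fwd -= dec_f
        best.g_rev -= min(best.g_rev, dec - dec_f)
        site.k = site.k_fwd = site.k_rev = 0
        site.major_variant = None
        site.end_distances = []
    return sites


def merge_cross_modality_indels(
    dna_sites: list[SiteCounts], rna_sites: list[SiteCounts], window: int = 20
) -> list[tuple[SiteCounts, SiteCounts]]:
    """Merge matching DNA/RNA indel major variants onto a shared position.

    An indel major variant in one modality matching an indel major variant
    of the *same allele* within ``window`` positions in the other modality
    is recorded at the DNA site's position prior to statistical testing
    (multi-way ambiguity resolves to the nearest position, then the lowest).
    Returns the merged (dna, rna) pairs; the RNA sites are repositioned in
    place.
    """
    pairs = []
    used = set()
    for d in dna_sites:
        if not _is_indel(d.major_variant):
            continue
        best = None
        for r in rna_sites:
            if id(r) in used or r.major_variant != d.major_variant:
                continue
            dist = abs(r.position - d.position)
            if dist > window:
                continue
            key = (dist, r.position)
            if best is None or key < best[0]:
                best = (key, r)
        if best is not None:
            r = best[1]
            used.add(id(r))
            r.position = d.position
            pairs.append((d, r))
    return pairs


# ---------------------------------------------------------------------------
# high-quality variant filter


def strand_bias_pvalue(k_fwd: int, k_rev: int, g_fwd: int, g_rev: int) -> float:
    """Pearson chi-square (no continuity correction) P-value of the 2x2
    strand table {variant, germline} x {forward, reverse}.  Tables with a
    zero margin are uninformative and return 1."""
    a, b, c, d = k_fwd, k_rev, g_fwd, g_rev
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2.sf(stat, 1))


def variant_filter(
    counts: SiteCounts, tumor_col=None, germline_col=None, strand_bias_alpha: float = 0.01
) -> tuple[bool, list[str]]:
    """High-quality variant filter; returns (passed, failed-clause labels).

    Clauses: no significant strand bias of variant vs germline-allele reads
    (chi-square P >= 0.01); indel variants supported on both strands; major
    variant prevalence (k over all variant reads) >= 0.75; MAD of variant
    reads' distances to their aligned read ends >= 1.  ``tumor_col`` /
    ``germline_col`` are accepted for interface symmetry; every quantity
    needed is carried on ``counts``.
    """
    del tumor_col, germline_col
    if counts.k < 1:
        raise ValueError("variant filter requires k >= 1")
    reasons = []
    if strand_bias_pvalue(counts.k_fwd, counts.k_rev, counts.g_fwd, counts.g_rev) < strand_bias_alpha:
        reasons.append("strand_bias")
    if _is_indel(counts.major_variant) and (counts.k_fwd < 1 or counts.k_rev < 1):
        reasons.append("indel_strand")
    if counts.total_variant > 0 and counts.k / counts.total_variant < 0.75:
        reasons.append("prevalence")
    if counts.end_distances:
        d = np.asarray(counts.end_distances, dtype=float)
        mad = float(np.median(np.abs(d - np.median(d))))
        if mad < 1:
            reasons.append("end_distance_mad")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# beta-binomial null


def betabinom_tail_pvalue(k: int, n: int, alpha: float, beta: float) -> float:
    """Upper-tail beta-binomial probability P(X >= k | n, alpha, beta).

    Equals ``1 - sum_{i<k} C(n,i) B(i+alpha, n-i+beta) / B(alpha, beta)``;
    evaluated as a direct log-space sum over i = k..n so that very small
    tails keep full relative precision.  ``k = 0`` returns exactly 1.
    """
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + betaln(i + alpha, n - i + beta)
        - betaln(alpha, beta)
    )
    return float(min(1.0, math.exp(logsumexp(logpmf))))


def _betabinom_nll(log_ab: np.ndarray, k: np.ndarray, n: np.ndarray, w: np.ndarray) -> float:
    a, b = np.exp(log_ab)
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return np.inf
    ll = w * (betaln(k + a, n - k + b) - betaln(a, b))
    return -float(ll.sum())


def fit_betabinom(k, n, modality: str = "DNA") -> NullParams:
    """Maximum-likelihood beta-binomial fit to per-site counts k of n.

    Optimises (log alpha, log beta) by Nelder-Mead from a moment-style
    start; observations are aggregated by unique (k, n) so the likelihood is
    cheap even for 50 000 sites.  If no variant read is observed anywhere,
    falls back to method-of-moments on pseudocount-augmented data with a
    logged warning.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if k.size == 0:
        raise ValueError("no sites to fit")
    if np.any((k < 0) | (n <= 0) | (k > n)):
        raise ValueError("require 0 <= k <= n with n > 0")
    degenerate = not np.any(k > 0)
    if degenerate:
        logger.warning(
            "all %d sites have k = 0; fitting on pseudocount-augmented data", k.size
        )
        k = np.append(k, 1)
        n = np.append(n, int(np.median(n)))
    pairs, w = np.unique(np.stack([k, n], axis=1), axis=0, return_counts=True)
    ku, nu = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
    p_hat = max(float(k.sum()) / float(n.sum()), 1.0 / (float(n.sum()) + 1.0))
    # moment-style start: estimate the intra-class correlation from the
    # variance of per-site fractions, clamped to a sane range
    z = k / n
    inv_n = float(np.mean(1.0 / n))
    var = float(np.var(z))
    base = p_hat * (1 - p_hat)
    rho = 0.01
    if base > 0 and inv_n < 1:
        rho = (var - base * inv_n) / (base * (1 - inv_n))
    rho = float(np.clip(rho, 1e-6, 0.99))
    m0 = (1 - rho) / rho
    x0 = np.log([max(p_hat * m0, 1e-8), max((1 - p_hat) * m0, 1e-8)])
    if degenerate:
        return NullParams(
            alpha=float(np.exp(x0[0])), beta=float(np.exp(x0[1])),
            modality=modality, sites_used=int(k.size) - 1,
        )
    res = minimize(
        _betabinom_nll, x0, args=(ku, nu, w.astype(float)),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    a, b = np.exp(res.x)
    return NullParams(alpha=float(a), beta=float(b), modality=modality, sites_used=int(k.size))


def estimate_null_params(site_sampler, target_sites: int = 50000, seed: int | None = None) -> dict:
    """Fit per-modality null parameters from randomly sampled sites.

    ``site_sampler`` yields ``(k_dna, n_dna, k_rna, n_rna)`` tuples for
    sites that passed the high-quality data filter in both tumor modalities
    (call it with ``seed`` if it is a callable).  Sampling stops once
    ``target_sites`` sites are collected; exhausting the sampler earlier is
    an error naming the shortfall.
    """
    if target_sites <= 0:
        raise ValueError("target_sites must be positive")
    it = site_sampler(seed) if callable(site_sampler) else iter(site_sampler)
    rows = []
    for rec in it:
        rows.append(rec)
        if len(rows) >= target_sites:
            break
    if len(rows) < target_sites:
        raise ValueError(
            f"site sampler exhausted after {len(rows)} of {target_sites} requested sites"
        )
    arr = np.asarray(rows, dtype=np.int64)
    return {
        "DNA": fit_betabinom(arr[:, 0], arr[:, 1], "DNA"),
        "RNA": fit_betabinom(arr[:, 2], arr[:, 3], "RNA"),
    }


# ---------------------------------------------------------------------------
# meta combination

_P_LO = 1e-300
_P_HI = 1.0 - 1e-16


def stouffer_meta(p_dna: float, n_dna: int, p_rna: float, n_rna: int) -> float:
    """Stouffer combination of the two modality P-values with weights
    sqrt(n) per modality:

        1 - Phi( (Phi^-1(1-p_D) sqrt(n_D) + Phi^-1(1-p_R) sqrt(n_R))
                 / sqrt(n_D + n_R) )

    A missing P-value or a zero weight leaves the other P-value unchanged
    (exactly); both missing yields NA.  P-values are clamped to
    [1e-300, 1-1e-16] before the quantile transform.
    """
    dna_ok = not is_na(p_dna) and n_dna > 0
    rna_ok = not is_na(p_rna) and n_rna > 0
    if not dna_ok and not rna_ok:
        return NA
    if not rna_ok:
        return float(p_dna)
    if not dna_ok:
        return float(p_rna)
    zd = ndtri(1.0 - min(max(p_dna, _P_LO), _P_HI))
    zr = ndtri(1.0 - min(max(p_rna, _P_LO), _P_HI))
    z = (zd * math.sqrt(n_dna) + zr * math.sqrt(n_rna)) / math.sqrt(n_dna + n_rna)
    return float(1.0 - ndtr(z))


# ---------------------------------------------------------------------------
# single-site call


def _modality_pvalue(counts: SiteCounts, params: NullParams) -> tuple[float, list[str]]:
    if counts.n == 0:
        return NA, []  # modality absent at this site
    if counts.k == 0:
        return 1.0, []
    passed, reasons = variant_filter(counts)
    if not passed:
        return NA, reasons
    if params is None:
        raise ValueError(f"no null parameters for a {counts.k}-read variant site")
    return betabinom_tail_pvalue(counts.k, counts.n, params.alpha, params.beta), []


def combine_counts(dna: SiteCounts, rna: SiteCounts, null_params: dict, contig: str, position: int, ref_base: str = "N") -> MutationCall:
    """Apply per-modality tests and the meta rule to precomputed counts."""
    p_dna, fl_d = _modality_pvalue(dna, null_params.get("DNA"))
    p_rna, fl_r = _modality_pvalue(rna, null_params.get("RNA"))
    flags = {f"DNA:{r}" for r in fl_d} | {f"RNA:{r}" for r in fl_r}
    agree = (
        dna.major_variant is not None and rna.major_variant == dna.major_variant
    )
    if agree:
        p_meta = stouffer_meta(p_dna, dna.n, p_rna, rna.n)
    else:
        p_meta = p_dna
    return MutationCall(
        contig=contig,
        position=position,
        ref_base=ref_base,
        major_dna=dna.major_variant,
        k_dna=dna.k,
        g_dna=dna.g,
        major_rna=rna.major_variant,
        k_rna=rna.k,
        g_rna=rna.g,
        p_dna=p_dna,
        p_rna=p_rna,
        p_meta=p_meta,
        filter_flags=flags,
    )


def call_site(
    germline_col,
    dna_col,
    rna_col,
    genotype: GermlineGenotype | None = None,
    null_params: dict | None = None,
    min_prevalence: float = 0.02,
    polymorphisms: dict | None = None,
    artifacts: dict | None = None,
) -> MutationCall:
    """Full per-site call from pileup columns (the site is assumed to have
    passed the site quality gate).

    The meta P-value combines modalities only when their major variant
    alleles agree — irrespective of filtering — otherwise it equals the DNA
    P-value; with agreement and a failed (NA) DNA filter it falls back to
    the RNA P-value.  Sites with only RNA variant evidence therefore never
    gain meta support (the guard against RNA editing).
    """
    if null_params is None:
        raise ValueError("null_params required")
    ref_col = dna_col or rna_col or germline_col
    contig, position = ref_col.contig, ref_col.position
    if genotype is None:
        genotype = identify_germline_alleles(germline_col, min_prevalence)
        genotype = augment_alleles(genotype, polymorphisms, artifacts, (contig, position))
    empty = SiteCounts(contig=contig, position=position)
    dna = tumor_variant_counts(dna_col, genotype) if dna_col is not None else empty
    rna = tumor_variant_counts(rna_col, genotype) if rna_col is not None else empty
    return combine_counts(dna, rna, null_params, contig, position, ref_col.ref_base)
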