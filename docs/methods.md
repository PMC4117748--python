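# Methods

## Detection model

`duomut` treats each exonic genomic site independently. The per-site
procedure:

1. **High-quality data filter.** Tumor observations must come from reads
   with mapping quality ≥ 20, at most 2 reference mismatches + insertion
   events + deletion events, a proper pair orientation, no duplicate or
   qc-fail flag, and singular-best-alignment status (primary,
   non-supplementary, and a best-hit count of 1 when the aligner reports
   one); the base itself must have quality ≥ 20 and sit outside the
   terminal two bases of the aligned read sequence. *All* bases from
   germline alignments are accepted, so the germline genotype reflects
   everything the germline sample shows. A site is analysed only if
   germline depth ≥ 10, tumor high-quality depth ≥ 5 in DNA *or* RNA, no
   homopolymer run > 4 abuts the site on either flank, the high-quality
   proportion of tumor bases is ≥ 0.25 in at least one modality, and no
   germline indel allele reaches 10% allele fraction within ±50 positions.
2. **Germline genotype.** Alleles at ≥ 2% prevalence among germline reads,
   plus any configured population-polymorphism or mapping-artifact alleles
   at the site. Augmented alleles block somatic calls even when unobserved
   in this particular germline sample.
3. **Variant counting.** g = tumor reads matching germline alleles; the
   major variant is the most frequent non-germline allele (ties resolved by
   higher summed base quality, then lexicographically smallest allele);
   k = its count; n = k + g. Reads carrying *other* non-germline alleles
   count toward the major-variant prevalence denominator but not toward n.
4. **Indel handling.** Indel alleles are left-normalised against the
   reference on tally. Within a modality, an indel major variant donates
   its reads to the site within 20 positions holding the maximal k of the
   same allele (k incremented, g decremented at the recipient, so n there
   is unchanged). Across modalities, matching indel major variants within
   20 positions are merged to the DNA site's position before testing, so
   the meta model can combine evidence despite representation differences
   between DNA and RNA alignments.
5. **High-quality variant filter.** A variant is testable when the 2×2
   strand table of variant vs germline-allele reads shows no significant
   bias (Pearson chi-square without continuity correction, P ≥ 0.01;
   zero-margin tables pass), indel variants have ≥ 1 read on each strand,
   the major variant holds ≥ 75% of all variant reads, and the median
   absolute deviation of the variant reads' distances to their aligned
   read ends is ≥ 1 (a single supporting read therefore never tests). If
   the filter fails with k ≥ 1, P = NA (the site is not callable); with
   k = 0, P = 1.
6. **Statistics.** Per modality, P = P(X ≥ k) for X beta-binomial(n, α, β),
   evaluated as a log-space sum of the pmf over i = k..n — algebraically
   identical to one minus the lower sum but accurate for very small tails.
   The null parameters (α, β) are fitted per modality by maximum likelihood
   (Nelder–Mead on (log α, log β), observations aggregated by unique
   (k, n)) to sites sampled at random until 50 000 have passed the data
   filter in both tumor modalities. Sampled sites may include true somatic
   mutations; at realistic mutation rates the contamination is negligible
   and in the worst case biases P-values conservatively.
7. **Meta combination.** When DNA and RNA nominate the same major variant
   allele — irrespective of filter outcomes — P_META combines the two by
   Stouffer's method with weights √n per modality (n being the filtered
   k + g, matching the test's own sample size); if P_DNA is NA the meta
   value falls back to P_RNA, and a zero-depth modality leaves the other
   P-value exactly unchanged. When the alleles differ (including an absent
   RNA variant), P_META = P_DNA, which structurally excludes RNA-only
   signals such as RNA editing. P-values are clamped to
   [1e-300, 1 − 1e-16] before the normal-quantile transform.

Default significance thresholds are P_META ≤ 1.1×10⁻⁹ and
P_DNA ≤ 9.3×10⁻⁹. No multiple-testing adjustment is applied; the total
number of applied tests is reported in the run metadata so users can
adjust if desired.

**Germline-variant mode** runs the same engine with the reference genome
standing in for the germline sample (genotype = reference base, no
augmentation, no germline-depth gate). The artifact-list builder applies
this mode to normal-tissue RNA alignments and exports every significant
non-reference allele as a site/allele list for augmentation.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| min base / mapping quality | 20 / 20 | phred floors for tumor observations |
| mismatch+indel budget | 2 | per-read sum of mismatches and indel events |
| terminal exclusion | 2 | bases trimmed from each aligned read end |
| germline prevalence | 0.02 | allele fraction defining the germline genotype |
| germline depth / tumor HQ depth | 10 / 5 | site gate |
| homopolymer limit | 4 | maximal flanking single-base run |
| germline indel exclusion | 10% within ±50 bp | site gate |
| strand-bias alpha | 0.01 | variant filter chi-square level |
| major-variant prevalence | 0.75 | variant filter |
| end-distance MAD | ≥ 1 | variant filter |
| null sample | 50 000 sites | beta-binomial fit per modality |
| indel realign / merge window | 20 | positions |
| P_META / P_DNA thresholds | 1.1e-9 / 9.3e-9 | call significance |

## Synthetic data

The fixture generator emits a random reference, a diploid individual's
heterozygous SNPs (~1 per 1.5 kb), and coordinate-sorted indexed paired-end
alignments with proper flags, per-base qualities, MAPQ, NM tags consistent
with each read's sequence, a uniform substitution error rate (0.3% default),
sporadic low-quality bases, duplicate and qc-fail flagged reads.
Fragments may begin upstream of a target interval so that interior
positions receive balanced mate/strand coverage, as they do in real
libraries. RNA-like coverage uses per-exon lognormal depth multipliers
with a 20% unexpressed fraction; the benchmark's DNA coverage uses a
milder lognormal profile without dropout, emulating exome
capture-efficiency variation.

The spike-in simulator samples truth sites from exons (substitution :
insertion : deletion at 90 : 5 : 5%; indel lengths 1–6 at
60 : 20 : 9 : 5 : 5 : 1%), then edits exactly `round(MAF × eligible reads)`
randomly chosen reads per site. Substituted and inserted bases use the
non-nucleotide IUPAC character `V`, which cannot collide with any germline
allele; deletion truth positions are left-normalised at sampling time so
the spiked representation matches the caller's normalised alleles. Edited
reads keep their original base qualities, and their NM tag is left
untouched so the spiked allele does not count against the read-level
mismatch budget — the spike probes detection, not the mismatch filter.
The unedited alignments serve as the simulated germline, exactly mirroring
how a spike-in benchmark preserves real depth patterns, errors and germline
variants.

What the generator does **not** emulate: alignment ambiguity and mapping
artifacts, indel sequencing errors, quality-score miscalibration, splice
junctions in RNA reads (RNA fixtures are contiguous within exons), GC and
strand biases, and real germline structure beyond independent het SNPs.
Green tests on these fixtures therefore demonstrate the algorithm's
arithmetic and its behaviour under controlled coverage/error conditions,
not robustness to every artifact of real libraries — the artifact-allele
augmentation path exists precisely because real data contain failure modes
the simulator does not generate.

## Benchmark design and problem sizes

The standard benchmark genome is 200 kb with 400 exons of 300 bp (~120 kb
of exon space), mean depth 60 in both modalities, 500 truth sites spiked at
10% MAF, and null fitting at 20 000 sampled sites (the package default of
50 000 is more than this genome offers; the estimate is already stable at
a few thousand). At this scale the run finishes in well under a minute.
Scoring uses partial AUC over the false positive rate range [0, 10⁻⁵] on
the step ROC, and a permutation test (100 permutations) in which the two
models' site-wise ranks are swapped by fair coins. The companion
sensitivity run spikes 60 sites at 30% MAF: the lower spike density keeps
the sampled null representative of non-mutant sites, as it is genome-wide
at realistic mutation rates (~10⁻⁵).

## Numerical choices

- Beta-binomial tails: log-space `logsumexp` over the upper sum; k = 0
  returns exactly 1; tails are monotone in k up to ~10⁻¹⁶ roundoff near 1.
- Null fit initialisation: moment-style estimate of the intra-class
  correlation from per-site fractions, clamped to [10⁻⁶, 0.99]; if no
  variant read exists anywhere, a pseudocount-augmented moment estimate is
  returned with a logged warning.
- Major-variant ties: summed base quality, then lexicographic order —
  deterministic by construction.
- Indel realignment ties: maximal k, then nearest position, then lowest
  position. Cross-modality merges record at the DNA position, nearest
  first.
- Strand-bias tables with a zero margin pass (no information either way).
- ROC: NA P-values rank last (never called); partial AUC integrates the
  right-continuous step function.
- Permutation P-values use the +1 correction: p ∈ [1/(n_perm+1), 1].
- Deep-sequencing validation: the germline 2% condition uses a one-sided
  exact binomial test; the tumor-vs-germline condition uses the pooled
  score (z) test; false-positive classification requires ≥ 80% binomial
  power (null 3×10⁻³, alpha 0.05) at the observed tumor depth. The exact
  "proportions test" variants are open choices; both are config-switchable
  at the function interface.
- Coordinates are 0-based half-open internally and 1-based in every
  emitted TSV/VCF.

## Known limitations

- Mate pairs overlapping the same site are counted twice (no mate
  de-duplication); this slightly overstates n at short-fragment sites.
- The germline-accept-all rule means germline sequencing errors can enter
  the genotype at low depth (a 2%-prevalence allele at depth 50 is one
  read); the germline-depth gate bounds but does not remove this effect.
- Reference-allele-as-variant sites (possible when the germline is
  homozygous non-reference) skip the end-distance MAD clause because end
  distances are tracked for non-reference observations only.
- Beta-binomial fitting assumes a single error regime per modality;
  context-specific error rates (e.g. 8-oxoG artifacts) are not modelled
  and should be handled through the artifact allele list.
- The CLI processes one contig's regions per invocation efficiently but
  holds per-region pileup arrays in memory; extremely long single regions
  (tens of Mb) should be split.
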