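"""Scoring callers against ground truth and orthogonal deep sequencing.

Covers: ROC curves with partial AUC over a very low false-positive-rate
range (0 to 1e-5) against simulator truth; permutation tests on AUC
differences (per-site random swapping of two models' discrimination ranks);
classification of predictions as true/false positives against deep
whole-genome sequencing; absolute-count performance curves with AUC to a
fixed false-positive total; and the one-sided Fisher comparison of RNA vs
DNA mutant allele fractions with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, binomtest, fisher_exact
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "PerformanceCurve",
    "ValidationVerdict",
    "roc_curve_from_pvalues",
    "roc_and_partial_auc",
    "partial_auc",
    "permutation_auc_test",
    "binomial_power",
    "wgs_classify",
    "validation_curve",
    "validation_curve_compare",
    "fisher_maf_compare",
    "bh_fdr",
]


@dataclass
class PerformanceCurve:
    """Monotone step curve of detection performance.

    ``x``/``y`` are false/true positives — as rates for ROC curves, as
    absolute counts for deep-sequencing validation curves where the total
    positives and negatives are unknown.
    """

    x: np.ndarray
    y: np.ndarray
    label: str = ""
    kind: str = "rate"  # "rate" (ROC) or "count"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.x) < 0) or np.any(np.diff(self.y) < 0):
            raise ValueError("curve coordinates must be non-decreasing")


@dataclass
class ValidationVerdict:
    """Deep-sequencing classification of one predicted mutation."""

    verdict: str  # true_positive / false_positive / uninformative
    reason: str
    germline_depth: int = 0
    tumor_mutant: int = 0
    germline_mutant: int = 0
    power: float = float("nan")


def _prepare_scores(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float).copy()
    p[np.isnan(p)] = 1.0  # filter-failed sites are never callable
    return p


def roc_curve_from_pvalues(pvalues, labels, label: str = "") -> PerformanceCurve:
    """ROC step curve from per-site P-values (smaller = called earlier).

    Ties advance TP and FP jointly.  NA P-values rank last (never called).
    """
    p = _prepare_scores(pvalues)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative site")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    # collapse ties: keep the last point of each distinct threshold
    last = np.flatnonzero(np.diff(p_sorted, append=np.inf) != 0)
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    return PerformanceCurve(fpr, tpr, label=label, kind="rate")


def partial_auc(curve: PerformanceCurve, x_max: float) -> float:
    """Area under the right-continuous step curve over x in [0, x_max]."""
    x, y = curve.x, curve.y
    area = 0.0
    for i in range(len(x) - 1):
        lo = x[i]
        hi = min(x[i + 1], x_max)
        if hi > lo:
            area += (hi - lo) * y[i]
        if x[i + 1] >= x_max:
            return area
    if x_max > x[-1]:
        area += (x_max - x[-1]) * y[-1]
    return area


def roc_and_partial_auc(
    pvalues, labels, fpr_max: float = 1e-5, label: str = ""
) -> tuple[PerformanceCurve, float]:
    """ROC plus partial AUC over the false positive rate range [0, fpr_max].

    Callers should already have restricted sites to germline depth >= 10
    (the call table only contains gated sites).
    """
    curve = roc_curve_from_pvalues(pvalues, labels, label=label)
    return curve, partial_auc(curve, fpr_max)


def permutation_auc_test(
    model_a_scores,
    model_b_scores,
    labels,
    n_perm: int = 100,
    seed: int | None = None,
    fpr_max: float = 1e-5,
) -> tuple[float, float]:
    """Permutation P-value for the partial-AUC advantage of model A over B.

    The null randomly swaps the two models' discrimination ranks at each
    site (a fair coin per site); p is the fraction of permuted AUC
    differences at least as large as observed, with the +1 correction, so p
    is always within [1/(n_perm+1), 1].  Returns (observed difference, p).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    a = _prepare_scores(model_a_scores)
    b = _prepare_scores(model_b_scores)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("model scores must be aligned site-wise")
    _, auc_a = roc_and_partial_auc(a, y, fpr_max)
    _, auc_b = roc_and_partial_auc(b, y, fpr_max)
    observed = auc_a - auc_b
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(a.size) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        _, qa = roc_and_partial_auc(pa, y, fpr_max)
        _, qb = roc_and_partial_auc(pb, y, fpr_max)
        if qa - qb >= observed:
            hits += 1
    return observed, (hits + 1) / (n_perm + 1)


def binomial_power(
    depth: int, alt_fraction: float, null_p: float = 3e-3, alpha: float = 0.05
) -> float:
    """Power to detect an allele at ``alt_fraction`` given ``depth`` reads.

    The critical count c is the smallest count whose upper binomial tail
    under the null probability is <= alpha; power is the upper tail at c
    under the alternative.  Zero depth (or no attainable critical count)
    gives zero power.
    """
    if depth <= 0 or not (0 <= alt_fraction <= 1) or math.isnan(alt_fraction):
        return 0.0
    c = None
    for cand in range(1, depth + 1):
        if binom.sf(cand - 1, depth, null_p) <= alpha:
            c = cand
            break
    if c is None:
        return 0.0
    return float(binom.sf(c - 1, depth, alt_fraction))


def wgs_classify(
    predicted,
    tumor_deep_counts: tuple,
    germline_deep_counts: tuple,
    germline_max_fraction: float = 0.02,
    one_sample_p: float = 0.25,
    two_sample_alpha: float = 0.05,
    power_null: float = 3e-3,
    power_alpha: float = 0.05,
    min_power: float = 0.8,
) -> ValidationVerdict:
    """Classify one predicted mutation against deep sequencing.

    ``tumor_deep_counts`` / ``germline_deep_counts`` are (depth, mutant
    reads) at the predicted site, unfiltered.  True positive if germline
    depth >= 10 and either (1) >= 1 tumor mutant read with zero germline
    mutant reads, or (2) the germline mutant proportion is not significantly
    above 2% (exact binomial, P > 0.25) while the tumor proportion is
    significantly above the germline's (proportions z-test, P < 0.05).
    Otherwise false positive if the tumor depth affords >= 80% power to see
    the predicted MAF (binomial, null 3e-3, alpha 0.05); else uninformative.
    TP and FP are mutually exclusive by construction.
    """
    t_depth, t_mut = tumor_deep_counts
    g_depth, g_mut = germline_deep_counts
    maf = getattr(predicted, "maf_dna", predicted)
    base = dict(
        germline_depth=g_depth, tumor_mutant=t_mut, germline_mutant=g_mut
    )
    if g_depth < 10:
        return ValidationVerdict("uninformative", "germline_depth", **base)
    if t_mut >= 1 and g_mut == 0:
        return ValidationVerdict("true_positive", "tumor_only_evidence", **base)
    if t_depth > 0:
        p_germ = binomtest(
            g_mut, g_depth, germline_max_fraction, alternative="greater"
        ).pvalue
        if p_germ > one_sample_p and (t_mut > 0 or g_mut > 0):
            stat, p_two = proportions_ztest(
                [t_mut, g_mut], [t_depth, g_depth], alternative="larger"
            )
            del stat
            if not math.isnan(p_two) and p_two < two_sample_alpha:
                return ValidationVerdict(
                    "true_positive", "proportions_test", **base
                )
    power = binomial_power(t_depth, float(maf), power_null, power_alpha)
    if power >= min_power:
        return ValidationVerdict("false_positive", "powered_absence", power=power, **base)
    return ValidationVerdict("uninformative", "underpowered", power=power, **base)


def validation_curve(pvalues, verdicts, label: str = "") -> PerformanceCurve:
    """Absolute-count performance curve: cumulative (FP, TP) as the P-value
    threshold loosens; uninformative predictions are ignored."""
    p = _prepare_scores(pvalues)
    v = np.asarray([getattr(x, "verdict", x) for x in verdicts])
    keep = v != "uninformative"
    p, v = p[keep], v[keep]
    order = np.argsort(p, kind="stable")
    is_tp = (v[order] == "true_positive").astype(int)
    tp = np.cumsum(is_tp)
    fp = np.cumsum(1 - is_tp)
    p_sorted = p[order]
    last = np.flatnonzero(np.diff(p_sorted, append=np.inf) != 0)
    return PerformanceCurve(
        np.concatenate([[0], fp[last]]),
        np.concatenate([[0], tp[last]]),
        label=label,
        kind="count",
    )


def _tp_at_fp(curve: PerformanceCurve, fp_point: float) -> float:
    idx = np.searchsorted(curve.x, fp_point, side="right") - 1
    return float(curve.y[max(idx, 0)])


def validation_curve_compare(
    models: dict,
    auc_fp_max: float = 3000,
    fp_points: tuple = (250, 500, 1000),
    n_perm: int = 100,
    seed: int | None = None,
) -> dict:
    """Compare models against deep-sequencing verdicts.

    ``models`` maps label -> (pvalues, verdicts), aligned site-wise across
    models.  Reports each model's curve, AUC from 0 to ``auc_fp_max`` false
    positives, TP counts at the fixed FP points, and pairwise permutation
    P-values for the AUC difference (per-site swaps of the models'
    (P-value, verdict) pairs).
    """
    out = {"models": {}, "pairwise": {}}
    for label, (p, v) in models.items():
        curve = validation_curve(p, v, label)
        out["models"][label] = {
            "curve": curve,
            "auc": partial_auc(curve, auc_fp_max),
            "tp_at_fp": {pt: _tp_at_fp(curve, pt) for pt in fp_points},
        }
    labels = list(models)
    rng = np.random.default_rng(seed)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            pa, va = models[la]
            pb, vb = models[lb]
            pa = _prepare_scores(pa)
            pb = _prepare_scores(pb)
            va = np.asarray([getattr(x, "verdict", x) for x in va])
            vb = np.asarray([getattr(x, "verdict", x) for x in vb])
            if pa.shape != pb.shape:
                raise ValueError("models must be aligned site-wise")
            observed = partial_auc(validation_curve(pa, va), auc_fp_max) - partial_auc(
                validation_curve(pb, vb), auc_fp_max
            )
            hits = 0
            for _ in range(n_perm):
                swap = rng.random(pa.size) < 0.5
                qa = np.where(swap, pb, pa)
                qb = np.where(swap, pa, pb)
                wa = np.where(swap, vb, va)
                wb = np.where(swap, va, vb)
                d = partial_auc(validation_curve(qa, wa), auc_fp_max) - partial_auc(
                    validation_curve(qb, wb), auc_fp_max
                )
                if d >= observed:
                    hits += 1
            out["pairwise"][(la, lb)] = {
                "auc_difference": observed,
                "p_value": (hits + 1) / (n_perm + 1),
            }
    return out


def fisher_maf_compare(
    dna_counts: tuple, rna_counts: tuple, direction: str = "rna_greater"
) -> float:
    """One-sided Fisher exact test comparing mutant allele fractions between
    modalities.  ``dna_counts``/``rna_counts`` are (mutant, germline) read
    counts; ``direction`` picks which modality is tested for the larger
    fraction.  An all-zero table returns 1."""
    d_mut, d_germ = dna_counts
    r_mut, r_germ = rna_counts
    if min(d_mut, d_germ, r_mut, r_germ) < 0:
        raise ValueError("counts must be non-negative")
    if d_mut + d_germ + r_mut + r_germ == 0:
        return 1.0
    table = [[r_mut, r_germ], [d_mut, d_germ]]
    alternative = {"rna_greater": "greater", "dna_greater": "less"}[direction]
    return float(fisher_exact(table, alternative=alternative)[1])


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg significance flags at FDR ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]
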