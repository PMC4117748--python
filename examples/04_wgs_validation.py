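"""Classifying predictions against orthogonal deep sequencing.

Given unfiltered allele counts from whole-genome sequencing at a predicted
site, a prediction is a true positive when the tumor carries the mutant
allele and the germline does not (or carries it at no more than background
levels), and a false positive only when the deep data had the statistical
power to see the predicted MAF and saw nothing.
"""

from duomut.evaluate import validation_curve_compare, wgs_classify

cases = [
    ("clean tumor evidence", 0.30, (40, 6), (25, 0)),
    ("germline carries allele", 0.30, (40, 6), (25, 5)),
    ("shallow germline", 0.30, (40, 6), (8, 0)),
    ("powered absence", 0.25, (30, 0), (20, 0)),
    ("underpowered absence", 0.05, (12, 0), (20, 0)),
]
print(f"{'case':<26} {'verdict':<16} reason")
verdicts = []
for name, maf, tumor, germ in cases:
    v = wgs_classify(maf, tumor, germ)
    verdicts.append(v)
    print(f"{name:<26} {v.verdict:<16} {v.reason}")

# performance curves in absolute counts (total positives unknown in real
# validation data): cumulative TP vs FP as the P-value threshold loosens
pvals = [1e-12, 1e-10, 1e-8, 1e-6, 1e-4]
report = validation_curve_compare({"model": (pvals, verdicts)}, auc_fp_max=3,
                                  fp_points=(1, 2), n_perm=1)
m = report["models"]["model"]
print("\ncurve (FP, TP):", list(zip(m["curve"].x.astype(int), m["curve"].y.astype(int))))
print("TP at 1 FP:", m["tp_at_fp"][1], "| AUC to 3 FP:", m["auc"])
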