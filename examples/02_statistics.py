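"""The two statistics at the caller's core, in isolation.

The beta-binomial upper tail asks: how surprising are k variant reads of n,
given the overdispersed background error distribution (alpha, beta)?  The
Stouffer combination merges the DNA and RNA answers with weights
proportional to the square root of each modality's depth.
"""

from duomut.calling import betabinom_tail_pvalue, stouffer_meta

alpha, beta = 1.0, 999.0  # background: ~0.1% error rate, modest dispersion

print("k of 60 reads -> P(X >= k) under the null:")
for k in (0, 1, 2, 4, 6, 10):
    p = betabinom_tail_pvalue(k, 60, alpha, beta)
    print(f"  k={k:>2}: {p:.3e}")

print("\nCombining two modest signals (p=1e-5 each) at equal depth 60:")
p_meta = stouffer_meta(1e-5, 60, 1e-5, 60)
print(f"  meta P = {p_meta:.3e}  (agreeing evidence compounds)")

print("\nUneven depth: strong RNA (p=1e-8, depth 200) + weak DNA (p=0.2, depth 15):")
print(f"  meta P = {stouffer_meta(0.2, 15, 1e-8, 200):.3e}")

print("\nNo RNA coverage (depth 0): meta equals the DNA P-value exactly:")
print(f"  meta P = {stouffer_meta(3e-4, 60, float('nan'), 0):.3e}")
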