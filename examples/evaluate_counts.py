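"""The evaluation arithmetic on published benchmark counts.

Given raw TP/FP/FN counts, the evaluator derives precision, recall and
F_beta for any beta: beta = 1 balances the two, beta = 2 favors recall
(a false positive can be filtered by hand later; a false negative is
lost), beta = 0 collapses to precision.
"""

from residuefinder import EvalResult, f_beta

# mutation extraction on 20 full-text articles: high precision, low
# recall, because full text uses many formats abstracts do not
result = EvalResult(tp=66, fp=3, fn=102, betas=(0.0, 1.0, 2.0))
print("TP=66 FP=3 FN=102 ->", result.rounded())

# the broadest residue library on the same articles: recall 0.944 at the
# cost of precision
result = EvalResult(tp=385, fp=602, fn=23, betas=(1.0, 2.0))
print("TP=385 FP=602 FN=23 ->", result.rounded())

# F_beta sweeps from precision to recall as beta grows
p, r = 0.390, 0.944
for beta in (0, 0.5, 1, 2, 5):
    print(f"beta={beta:<3} F={f_beta(p, r, beta):.3f}")
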