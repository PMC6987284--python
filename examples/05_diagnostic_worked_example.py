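"""Diagnostic-accuracy arithmetic on a published-style confusion table.

A crossed evaluation of 68 cases produced arm matrices (TP 11, TN 18,
FP 2, FN 0) and (TP 16, TN 19, FP 2, FN 0).  This script pools them and
prints every point estimate with its exact (Clopper-Pearson) 95% CI.
"""

from focusradiomics.diagnostics import (ConfusionMatrix, clopper_pearson,
                                        display_metrics, metrics,
                                        round_half_up)

pooled = ConfusionMatrix(11, 18, 2, 0) + ConfusionMatrix(16, 19, 2, 0)
print(f"pooled: TP={pooled.TP} TN={pooled.TN} FP={pooled.FP} FN={pooled.FN} "
      f"(n={pooled.total})")

m = metrics(pooled)
disp = display_metrics(m)
ci_of = {
    "sensitivity": (pooled.TP, pooled.TP + pooled.FN),
    "specificity": (pooled.TN, pooled.TN + pooled.FP),
    "accuracy": (pooled.TP + pooled.TN, pooled.total),
    "ppv": (pooled.TP, pooled.TP + pooled.FP),
    "npv": (pooled.TN, pooled.TN + pooled.FN),
}
for name, (x, n) in ci_of.items():
    lo, hi = clopper_pearson(x, n)
    print(f"{name:12s} {x}/{n} = {disp[name]:>5s}  "
          f"95% CI {round_half_up(lo)}-{round_half_up(hi)}%")
print(f"{'LR+':12s} {disp['lr_positive']:>13s}")
print(f"{'LR-':12s} {disp['lr_negative']:>13s}")

print("\nWith zero false negatives the sensitivity CI is the degenerate "
      "x = n case, whose exact\nlower bound is 100*(0.025)^(1/27) ~ 87% — "
      "an interval a normal approximation cannot produce.")
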