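"""Stenosis classification rules and the evaluation metrics.

Shows the two published threshold rules on representative DSA values,
the narrowest-slice rule for a disc level, and the agreement metrics
(Dice, ICC(2,1), exact binomial CIs) on small worked examples.
"""

import numpy as np

from canalseg import (
    ConfusionCounts,
    DSAMeasurement,
    classify_dichotomous,
    classify_severe,
    confusion_metrics,
    dice,
    icc,
    level_summary,
)

print("threshold rules (stenosis < 100 mm^2, severe < 75 mm^2):")
for dsa in (127.6, 100.0, 90.0, 75.0, 50.6):
    print(f"  DSA {dsa:6.1f} -> {classify_dichotomous(dsa):8}  / severe rule: {classify_severe(dsa)}")

values = [112, 108, 104, 101, 98, 94, 97, 102, 107, 111, 115]
meas = [DSAMeasurement("p01", "lumbar", "L4-L5", off, float(v))
        for off, v in zip(range(-5, 6), values)]
min_dsa, call = level_summary(meas)
print(f"\nnarrowest-slice rule: level minimum {min_dsa:.0f} mm^2 -> {call.dichotomous} "
      f"(the level is judged by its narrowest of 11 slices)")

a = np.zeros((20, 20), bool)
b = np.zeros((20, 20), bool)
a.ravel()[:100] = True
b.ravel()[50:150] = True
print(f"\nDice of two 100-pixel masks overlapping in 50: {dice(a, b):.2f}")

pairs = np.array([[118, 122], [96, 91], [73, 78], [140, 133], [105, 110], [62, 60.0]])
est, (lo, hi) = icc(pairs)
print(f"ICC(2,1) of a 6-subject, 2-rater DSA table: {est:.3f} (95% CI {lo:.2f}-{hi:.2f})")

m = confusion_metrics(ConfusionCounts(tp=281, fp=49, tn=550, fn=110))
print("\nclassification metrics for a 990-slice confusion table "
      "(281/391 stenotic detected, 550/599 normal correct):")
for name in ("accuracy", "sensitivity", "specificity"):
    d = m[name]
    print(f"  {name:12} {d['percent']:5.1f}% [{d['k']}/{d['n']}] "
          f"(95% CI {d['ci'][0]:.1f}-{d['ci'][1]:.1f})")
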