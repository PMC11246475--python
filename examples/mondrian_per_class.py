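"""Marginal vs class-conditional (Mondrian) coverage on imbalanced data.

Marginal calibration guarantees coverage on average over all instances;
rare classes can fall short.  Mondrian calibration computes one threshold
per class from that class's own calibration scores, pulling every class
toward the nominal level — at the price of wider sets.
"""

import numpy as np

import conformap as cm

alpha = 0.10
priors = (0.45, 0.25, 0.15, 0.10, 0.05)  # class 4 is rare
spec = cm.ClassificationGeneratorSpec(
    n=12_000, n_classes=5, priors=priors, difficulty=12.0, seed=11
)
probs, labels = cm.gen_classification_table(spec)
cal, test = slice(0, 4000), slice(4000, None)

lac = cm.calibrate_lac(probs[cal], labels[cal], alpha)
mon = cm.calibrate_mondrian(probs[cal], labels[cal], alpha)

rep_lac = cm.classification_report(cm.predict_set(probs[test], lac, alpha), labels[test])
rep_mon = cm.classification_report(cm.predict_set_mondrian(probs[test], mon), labels[test])

print(f"marginal LAC:  coverage = {rep_lac.empirical_marginal_coverage:.3f}, "
      f"mean set size = {rep_lac.average_set_size:.2f}")
print(f"Mondrian:      coverage = {rep_mon.empirical_marginal_coverage:.3f}, "
      f"mean set size = {rep_mon.average_set_size:.2f}")
print("\nper-class coverage (prior, LAC, Mondrian, Mondrian threshold):")
for c in range(5):
    print(f"  class {c}: prior {priors[c]:.2f}  "
          f"LAC {rep_lac.per_class_coverage[c]:.3f}  "
          f"Mondrian {rep_mon.per_class_coverage[c]:.3f}  "
          f"t_{c} = {mon.thresholds[c]:.3f}")

# Under marginal calibration some classes sit below 0.90 while others sit
# above; Mondrian thresholds differ per class and hold each class near the
# nominal level, which matters when errors on a rare class are costly.
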