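"""Confidence-based review: accuracy-vs-budget curves and review efficiency.

Ten equal-length clips with known accuracies are "reviewed" (accuracy set
to 1) in different orders.  Reviewing worst-first (ascending accuracy) is
optimal; sorting by a well-calibrated confidence score should approach it,
and a random order defines the zero point of the efficiency scale.
"""

import numpy as np

from deepaction import review_summary

rng = np.random.default_rng(3)
accs = rng.permutation(np.linspace(0.3, 0.95, 10))
sizes = np.full(10, 120)

# a slightly noisy confidence score that tracks true accuracy
conf = np.clip(accs + rng.normal(0.0, 0.04, 10), 0.0, 1.0)

summary = review_summary(accs, sizes, confidences=conf,
                         n_permutations=500, seed=0)
print("accuracy after reviewing k clips (confidence order):")
for k in (0, 3, 6, 10):
    print(f"  k={k:>2}: conf {summary.curve_candidate.acc_k[k]:.3f}  "
          f"optimal {summary.curve_optimal.acc_k[k]:.3f}  "
          f"random {summary.curve_random.acc_k[k]:.3f}")
print(f"mean improvement over random: conf {summary.mean_ior_candidate:.4f}, "
      f"optimal {summary.mean_ior_optimal:.4f}")
print(f"review efficiency = {summary.efficiency:.3f}")
# Efficiency 1 would mean the confidence ordering matches the optimal
# (ascending true accuracy) one; 0 means it is no better than random.
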