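"""Classification metric suite with Wilson-score confidence intervals.

The suite reports accuracy, AUC, sensitivity, specificity, F measure and
MCC.  The AUC interval is a Wilson score interval at per-interval coverage
sqrt(0.95), the convention for two simultaneous two-sided intervals with
joint 95% coverage.
"""

import numpy as np

from crmloc import SIMULTANEOUS_COVERAGE, confusion, metric_suite, wilson_interval

rng = np.random.default_rng(1)
y = rng.integers(0, 2, 300)
scores = np.clip(0.6 * y + 0.2 + rng.normal(0, 0.18, 300), 0, 1)

record = metric_suite(confusion(y, scores), y, scores)
for key, value in record.to_dict().items():
    print(f"{key:12s} {value}")

lo, hi = wilson_interval(0.9, n=100, coverage=SIMULTANEOUS_COVERAGE)
print(f"\nWilson interval for 90/100 at coverage sqrt(0.95): "
      f"({lo:.4f}, {hi:.4f})")
# The interval is asymmetric around 0.9 and shrinks as n grows.
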