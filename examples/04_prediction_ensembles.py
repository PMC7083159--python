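"""Combine seven classifiers' class probabilities four ways.

Majority voting, simple averaging, weighted averaging (higher weight to
the two most accurate models), and stacking with a neural meta-learner
that reads the concatenated 14-element probability vector.
"""

import numpy as np

from crmloc import (
    ProbabilityMatrix,
    WeightVector,
    fit_stacking,
    majority_vote,
    predict_stacking,
    simple_average,
    weighted_average,
)

rng = np.random.default_rng(0)
y = rng.integers(0, 2, 200)  # 1 = abnormal

models = []
for j in range(7):
    noise = rng.normal(0, 0.28 + 0.06 * j, 200)  # later models are noisier
    p_abn = np.clip(0.7 * y + 0.15 + noise, 0, 1)
    models.append(ProbabilityMatrix(np.column_stack([p_abn, 1 - p_abn]),
                                    model_id=f"model{j+1}"))

for m in models:
    print(f"{m.model_id} accuracy: {(m.labels() == y).mean():.3f}")

vote = majority_vote(models)
avg = simple_average(models)
weighted = weighted_average(
    models, WeightVector([0.25, 0.25, 0.1, 0.1, 0.1, 0.1, 0.1])
)
meta = fit_stacking(models[:], y, seed=0)
stacked = predict_stacking(meta, models)

for name, labels in [
    ("vote", vote),
    ("average", avg.labels()),
    ("weighted", weighted.labels()),
    ("stacking", stacked.labels()),
]:
    print(f"{name:9s} accuracy: {(labels == y).mean():.3f}")

# Accuracy is against the simulated truth; weighting the two cleanest
# models highest typically edges out the uniform average, matching the
# intuition that better base learners deserve more say.
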