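"""Simulate a labelled deployment and classify it with KNN.

Generates a two-occasion recording (training + testing) of five behaviours,
10 s each at 20 Hz, classifies every raw test sample by majority vote of its
3 nearest training samples, and applies a 0.7 minimum-majority threshold.
"""

from accelknn import (
    accuracy,
    confusion_counts,
    classify_dataset,
    default_ethogram,
    precision,
    recall,
    simulate_dataset,
)

spec = default_ethogram(seed=1)
train, test = simulate_dataset(spec)
print(f"training: {len(train)} samples, testing: {len(test)} samples "
      f"({len(spec.templates)} behaviours x {spec.seconds_per_behavior:.0f} s "
      f"at {spec.sample_rate:.0f} Hz)")

votes = classify_dataset(test, train, k=3, rng_seed=1)
counts = confusion_counts(votes, list(test.labels()), threshold=0.7)
print(f"confusion quadruple at threshold 0.7: TP={counts.tp} FP={counts.fp} "
      f"TN={counts.tn} FN={counts.fn}")
print(f"accuracy  = {accuracy(counts):.3f}   "
      "(kept-and-correct plus discarded-and-incorrect, over all samples)")
print(f"precision = {precision(counts):.3f}   (correct share of kept classifications)")
print(f"recall    = {recall(counts):.3f}   (kept share of correct classifications)")
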