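"""Sweep the minimum-majority threshold and rank-correlate each metric.

Raising the threshold discards more low-confidence classifications: the
proportion of data classified (and recall) can only fall, while precision
typically rises.  Spearman's r against the threshold grid quantifies each
trend; with five thresholds the p-value is an exact permutation p.
"""

from accelknn import classify_dataset, default_ethogram, simulate_dataset, sweep

spec = default_ethogram(seed=1)
train, test = simulate_dataset(spec)
votes = classify_dataset(test, train, k=3, rng_seed=1)
result = sweep(votes, list(test.labels()))  # thresholds 0.5 ... 0.9

print("thr   prop_classed  accuracy  precision  recall")
for rep in result.reports:
    fmt = lambda v: "  NA " if v is None else f"{v:.3f}"
    print(f"{rep.threshold:.1f}      {rep.proportion_classified:.3f}     "
          f"{fmt(rep.accuracy)}     {fmt(rep.precision)}    {fmt(rep.recall)}")

print("\nSpearman rank correlation of each metric against the threshold:")
for name, sr in result.correlations.items():
    if sr.r is None:
        print(f"  {name:<22} r = NA (constant over the grid)")
    else:
        print(f"  {name:<22} r = {sr.r:+.3f}  p = {sr.p:.3f}")
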