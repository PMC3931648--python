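# Methods

## Classification model

Each raw accelerometer sample is a point in the three-dimensional feature
space of (x, y, z) acceleration in g.  A query is labelled by majority vote
of its k nearest training samples under Euclidean distance, with confidence
`prob = n_wc / k` (the winning class's share of the k votes).  No feature
scaling is applied: the three axes already share units, and scaling would
change the geometry the method relies on.  No summary statistics or
windowing are computed — classification is per raw sample.

The model's assumptions are therefore: (i) behaviours occupy distinct,
sufficiently populated regions of the raw feature space in the training
data; (ii) device orientation relative to the body is stable between the
training and testing occasions (the static component is informative only if
it is); (iii) the sampling rate is at least twice the fastest body movement
of interest, so the dynamic component is represented rather than aliased.

### Tie rules

Two kinds of tie arise and both are resolved deterministically given the
seed:

* **Distance ties at the k-th rank** — the lexicographically-first training
  indices among the tied candidates are taken (a stable argsort), keeping
  the neighbourhood size exactly k so the `prob` denominator is well
  defined.  With continuous inputs such ties have probability zero; the rule
  matters only for constructed data.
* **Vote ties** — when two or more labels share the maximal count, one is
  drawn uniformly at random among them, driven by the run seed and the
  query's index.  Seeding per (run, query) makes batch classification and
  single-point classification agree exactly, and makes results independent
  of training-row order.

`k` defaults to 3 and is exposed as a parameter; small odd values avoid
vote ties when few classes are in contention.

## Threshold filter and discard-aware evaluation

A minimum-majority threshold discards classifications with `prob` below the
cut-off.  "Meets the threshold" is `prob >= threshold`: with k = 3 and a 0.9
cut-off, a strict `>` would also discard unanimous `prob = 1` votes, which
is never the intent.  Discarded samples are flagged, never dropped, so the
four outcomes partition the test set:

|              | kept | discarded |
|--------------|------|-----------|
| correct      | TP   | FN        |
| incorrect    | FP   | TN        |

Note that TP + FN (the classifier's correct calls) and FP + TN are invariant
in the threshold; only the filter moves mass between the columns.  It
follows that the proportion classified, (TP+FP)/n, and recall are
non-increasing in the threshold, and that at threshold 0 accuracy equals
precision and recall is exactly 1 whenever TP > 0.  These forced identities
are used as self-checks in the test suite.

Metrics are dataset-level (multiclass collapsed to correct/incorrect), which
is what the single-quadruple definitions above compute; a one-vs-rest
per-behaviour quadruple is available as a diagnostic
(`evaluate.per_behavior_counts`) but is not the headline computation.
Zero-denominator metrics (e.g. precision when everything was discarded) are
reported as an explicit `None`/`NA`, never silently 0 or 1, since high
thresholds can legitimately discard everything.

## Threshold sweep and rank correlation

The sweep evaluates thresholds {0.5, 0.6, 0.7, 0.8, 0.9} (configurable) on
identical votes and rank-correlates each metric against the threshold with
Spearman's r (average ranks for ties).  The p-value is an exact permutation
p — the share of all n! orderings with |r| at least the observed — whenever
n ≤ 9, because the usual t-approximation is poor at the sweep's n = 5;
larger n uses the t-approximation with n − 2 degrees of freedom.  Undefined
metrics are dropped pairwise; fewer than three defined pairs, or zero rank
variance (a constant metric), yields an undefined correlation rather than a
number.

Note that with k = 3 the confidence can only take values {1/3, 2/3, 1}, so
several thresholds in the 0.5–0.9 grid are equivalent cuts; tied metric
values then cap |r| below 1 (e.g. r = ±0.866 when the grid splits into two
tied groups).  This is a property of the grid and the vote granularity, not
a numerical artefact.

## Synthetic signal generator

A behaviour template is a posture (pitch, then roll, in degrees, applied to
the upright-device gravity vector (0, 0, −1) g), a set of sinusoidal
dynamic components (axis, frequency, amplitude, phase), and an i.i.d.
Gaussian per-axis noise level.  A segment of duration T at rate f has
round(T·f) samples; a deployment concatenates one segment per behaviour,
and the two-occasion design generates training and testing recordings from
independent seeds (seed and seed+1) over the identical schedule.  Component
frequencies must stay below the Nyquist limit f/2, enforced at generation
time.

What it emulates: the static/dynamic decomposition that makes behaviours
separable, sensor jitter, phase-incoherent gaits between occasions (the
`phase_jitter` flag randomizes component phases per segment), and — via a
posture offset applied to test templates only — a device that shifted
position between occasions.  What it does **not** emulate: biomechanically
realistic gait waveforms, behaviour-transition dynamics, soft-tissue
artefacts, or auxiliary channels (e.g. pressure).  Passing tests on this
generator show the classifier and metrics behave correctly on signals with
the assumed structure; they do not certify accuracy levels on any real
species.

### Default ethogram

The packaged fixture is a five-behaviour human-like ethogram — Stand,
Lying, Walk, Run, Crawl — at 20 Hz, 10 s per behaviour (1000 samples per
recording; 2000 at 40 Hz).  Postures separate the stationary behaviours
(Stand 0°, Crawl 60°, Lying 90° pitch); the gaits lean forward (Walk 10°,
Run 25°) and oscillate on the x axis at walking/running stride rates
(2 Hz × 0.30 g and 3.5 Hz × 0.80 g).  Noise is 0.05 g per axis —
the scale of sensor-and-attachment jitter on a well-fitted device.  Dynamic
components sit on the x axis while pitch separates classes in the (y, z)
plane, so every sample of a gait cycle stays closer to its own class than
to its neighbours' — "well separated by construction".  All template
numbers are fixture choices on human-plausible scales, not measurements.

## Numerical and interface choices

* CSV interchange: comma-separated, one header row, `time,x,y,z[,label]`,
  UTF-8, `.` decimal mark.  Coordinates are parsed with Python's exact
  `float` conversion and written at repr precision, so write-then-read is
  bit-faithful; the `time` column may be omitted and is then reconstructed
  from the sample rate.
* The distance computation is exhaustive and vectorised (a full test×train
  distance matrix); at the design scale (1000–2000 samples per recording)
  this is well under a second, so no spatial index is used.
* Simulator specs load from a small JSON schema (see
  `accelknn.simulate.read_sim_spec`); the packaged ethogram needs no file.
* Degenerate inputs fail loudly: empty datasets, k larger than the training
  set, unlabelled training samples, non-finite coordinates, Nyquist
  violations and duplicate behaviour names all raise before any computation.

## Problem sizes used in tests and the acceptance script

Replicated runs use the design scale itself (1000-sample recordings, ten
seeded replicates), which completes in seconds; the noise-ladder degradation
check shortens segments to 2 s per behaviour across four widely spaced noise
levels, enough to order the means unambiguously.  The exhaustive-oracle
suite uses training sets up to 200 points and k ∈ {1, 3, 5, 7}.

## Known limitations

* Per-sample classification ignores temporal structure entirely; a
  behaviour's samples are i.i.d. draws as far as the classifier is
  concerned, and no smoothing of the label sequence is attempted.
* The classifier cannot flag novel behaviours — a sample from an unseen
  class is always assigned one of the training labels (possibly with high
  confidence).
* Threshold selection is left to the user (per-deployment trial and error
  on held-out labelled data); no automatic selection is provided.
* The exact-permutation Spearman p is exact *conditional on the observed
  ranks*; with heavily tied metrics it remains valid but coarse.
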