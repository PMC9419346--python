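# Methods

## Problem and pipeline

Hip-worn accelerometers are the standard device in child physical-activity
surveillance, but their legacy counts cut-point (a minute is sedentary when
the vertical axis registers under 100 counts) measures *stillness*, not
*sitting*. Thigh-worn inclinometers (activPAL) measure posture directly but
are rarely deployed at scale. This package implements a posture classifier
for hip accelerometry in children — a convolutional feature extractor over
10-s windows of 10 Hz triaxial acceleration, a bidirectional LSTM over
sequences of window features, and a softmax sitting probability per epoch —
together with the downstream machinery needed to use and evaluate it:
epoch preprocessing, Choi non-wear detection, sedentary bout pattern
variables, and method-agreement statistics against inclinometer ground
truth.

Stages, in pipeline order:

1. **Preprocessing** (`preprocess`). 30 Hz raw acceleration is reduced to
   10 Hz by block means over 3 consecutive samples. Block means rather than
   naive decimation: the device literature states only that 10 Hz values
   are used, and means are phase-robust with mild anti-aliasing.
   Inclinometer events are expanded to per-second labels (a second belongs
   to the event covering its start instant; a boundary exactly on a second
   hands the second to the new event) and aggregated to 10-s epochs:
   sitting iff ≥ 6 of 10 seconds are sitting. Trailing partial epochs and
   windows are dropped, never padded — padding would fabricate signal.
2. **Non-wear** (`nonwear_choi`). Choi algorithm on 60-s vertical-axis
   counts with a 90-min window, 2-min spike tolerance and 30-min zero-count
   flanks on each side of an absorbed spike. Absorbed spike minutes count
   toward the 90-min run length (the standard construction). Verified
   against an independent per-minute interval-enumeration oracle.
3. **Classification** (`posture_model`). CNN → BiLSTM → softmax. Label rule
   is strict: sitting iff probability > 0.5, so a probability of exactly
   0.5 is non-sitting.
4. **Variable derivation** (`bout_metrics`). Bouts are maximal runs of
   sitting epochs (minimum one epoch, no interruption tolerance; an unworn
   epoch terminates a bout without creating a break). Six participant-season
   variables: total sedentary min/day, breaks/day, min/day in bouts ≥ 30 min,
   mean bout duration, usual bout duration, and alpha.
5. **Evaluation** (`evaluation`). Per-participant-season confusion metrics,
   transition pairing with a lag tolerance, and agreement statistics
   (bias, MAE, MAPE, Spearman, Lin's CCC). Metrics are computed per
   participant-season and then averaged — never pooled micro-averages.
   Zero-denominator metrics propagate as missing (NaN) and are excluded
   from across-season means.

## Model

Each 10-s epoch is a 100 × 3 window (10 s at 10 Hz). Defaults: two valid
(no-padding) conv layers of 32 and 64 filters, kernel 5 samples, ReLU,
max-pool 2, then global average pooling → a 64-dim feature per epoch;
a BiLSTM with 64 hidden units per direction over sequences of 9 epochs;
a dense softmax head. Dropout 0.2 on the features during training. About
63k parameters. The published method does not state its final
hyperparameters, so these are the package's own choices, sized to train in
minutes on one CPU while preserving the topology; all are config-exposed
and a small grid-selection utility (`grid_select`, argmax of the selection
metric with ties broken toward fewer parameters) stands in for a full
search.

Choices that matter:

* **Normalization.** Per-axis global standardization using training-set
  mean/SD, stored in the model bundle. Per-window normalization would
  remove the gravity offset that encodes posture.
* **Sequence context at prediction.** Every epoch is predicted exactly
  once, from the stride-1 sequence in which it occupies the centre
  position; edge sequences replicate the first/last window and padded
  outputs are discarded. This avoids any output-averaging ambiguity.
* **Selection metric.** Mean of (A) epoch balanced accuracy and (B)
  balanced accuracy for sit-to-stand transitions between adjacent epochs,
  on held-out participants, with equal weights. Early stopping keeps the
  best checkpoint (default patience 5, max 30 passes, Adam, lr 1e-3,
  batch 16 sequences).
* **Implementation.** The network is written directly in numpy (im2col
  convolution, BPTT through the BiLSTM, Adam) with analytic gradients
  verified against finite differences in the test suite. Training is
  single-threaded deterministic given the seed, which the tests rely on.

## Transition pairing

Predicted and true sit-to-stand times are matched one-to-one within a
tolerance (default 60 s; sensitivity = matched/true, PPV = matched/pred).
True transitions are processed chronologically and each takes the
*earliest* still-unmatched prediction within ±tolerance. Because each true
time is compatible with a contiguous interval of predictions, this
earliest-feasible rule provably attains the maximum possible number of
matches (verified against an exhaustive bipartite oracle on all small grid
instances); a nearest-first rule does not, stranding later true times whose
only candidates were consumed.

## The 100 cpm comparator

A minute is classified sedentary iff vertical counts < 100, strict at the
boundary (100 → non-sedentary). The comparator's bout grid is 60 s, so its
minimum bout is 1 min and its alpha uses xmin = 1 min, versus 10 s
(= 1/6 min) for the classifier and the inclinometer.

## Sedentary pattern variables

* **Usual bout duration** is the duration-weighted median (lower
  convention): the smallest bout duration x such that bouts ≤ x accumulate
  ≥ 50 % of sitting time. The nonlinear x^n/(x^n + W50^n) fit used in some
  older work is deliberately not the default; the weighted median is the
  definition stated with the variable.
* **Alpha** is the continuous maximum-likelihood power-law exponent
  α = 1 + n (Σ ln(xᵢ/xmin))⁻¹. It errors when all bouts equal xmin
  (undefined) and the participant-season is then excluded.
* Mean/usual bout duration and alpha are computed on the bout list pooled
  across a participant-season's valid days; per-day fits are unstable below
  ~50 bouts. Per-day variables (totals, breaks, time in ≥30-min bouts) are
  averaged over valid days. A valid day requires ≥ 480 min of simultaneous
  two-monitor wear; a participant-season requires ≥ 3 valid days.
* Bouts truncated by non-wear contribute their observed duration; nothing
  is imputed.

## Synthetic study generator

No deposited raw data exist for this design, so the `synthetic` module
generates the three device streams for simulated children, with exact
ground truth:

* **Posture process.** Alternating sit/upright renewal. Sitting bout
  durations are continuous power-law draws (α = 1.40, xmin = 10 s — the
  scale reported for children's inclinometer data). Because α < 2 the
  distribution has infinite mean, a day cannot be filled by unconstrained
  alternation without the realized sitting fraction drifting toward 0.5;
  instead each day fills a sitting-time *budget* pᵢ·T (T = nominal wear,
  default 12 h; pᵢ the child's sitting fraction ~ Normal(0.62, 0.06)),
  with only the final draw per day censored at the budget. Each sitting
  bout brings an upright partner uᵢ = sᵢ·(1 − pᵢ)/pᵢ·LogNormal with a
  mean-one noise factor (σ = 0.5), which pins the realized sitting fraction
  at pᵢ and makes realized day length vary around T (12.2 ± 1.9 h at the
  12-h default) the way real wear time does. The starting posture
  alternates from a random per-day choice so day-end censoring removes
  sitting and upright mass evenly. With these conditions the pooled exact
  sitting bouts recover α̂ ≈ 1.43 by pure MLE (censoring of ~1 bout in ~25
  accounts for the ~0.03 upward shift), and the bundle sitting fraction
  stays within 3 points of the target.
* **Inclinometer registration.** A new posture lasting under 10 s fails to
  register and its time is credited to the preceding registered posture
  (merging, not deletion — matching how an evidence-accumulating
  inclinometer behaves). Idempotent; the first event may be short.
* **Hip signal.** Gravity vector tilted by a posture-dependent angle
  (easy: 45° sitting vs 5° upright; hard: 20° vs 10° plus ±6° per-event
  jitter), Gaussian sensor noise (σ = 0.01/0.02 g), continuous 1.6–2.4 Hz
  walking oscillation of 0.2–0.5 g during upright bouts (hard: gated into
  bursts), and sparse 0.4-s fidget bumps ≤ 0.12 g during sitting. On easy
  difficulty every pure sitting window has lower dynamic variance than
  every pure upright window, so a variance threshold alone reaches ≥ 0.99
  balanced accuracy on aggregated labels — the floor that justifies
  requiring ≥ 0.95 from the trained network.
* **Counts.** Per second the vertical axis is mean-centred; absolute
  deviations above a 0.05 g dead band integrate into the minute's counts
  (scale 30). Still minutes give exactly zero counts (so Choi is
  exercisable), fidgety sitting minutes give small nonzero counts
  (≪ 100 cpm), walking minutes exceed the cut-point by an order of
  magnitude.

What the generator does *not* emulate: biomechanical gait, postural
transitions with intermediate angles, monitor clock drift (a fixed-offset
shift can be applied in preprocessing for sensitivity analyses),
inclinometer misclassification, or spontaneous non-wear. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
architecture can learn posture from tilt-plus-dynamics signal — not that
this implementation reaches any particular accuracy on real children, which
would require the original (non-public) training data and weights.

## Problem sizes

The default test/acceptance experiment trains on 6 children and selects on
2 (one 2-h day each, 720 epochs per child), tests on 2, seed 7 — chosen as
a CPU-scale analogue of the real design (156/38/84 children with ~17k
epochs per participant-season). Participant-season variables are evaluated
on 8 children × 4 days at 10-h nominal wear with an oracle classifier
(pipeline identity), the trained classifier, and the 100 cpm comparator.

## Numerical conventions

* Timestamps are timezone-naive local time; DST is out of scope.
* Event files are written at 0.1-s resolution with integer decisecond
  arithmetic; readers enforce contiguity to 0.05 s and reject, never
  repair, gaps and overlaps.
* Raw CSV samples are written at %.8e so float32 values round-trip exactly;
  epoch-prediction probabilities use repr() round-tripping.
* All randomness flows from explicit `numpy.random.Generator` seed
  sequences; reruns are byte-identical.
* The duration-weighted median uses a 1e-12 slack when comparing cumulative
  sums to the half-total to absorb float accumulation.
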