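# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Data model

A *frame* is one time-aligned reading of all 20 channels in the fixed order
P⁰…P¹⁵, T⁰, A⁰…A² (device units throughout; no physical calibration is
attempted, since the hardware emits raw PCB-coded values). The pressure
stream defines the clock: the temperature/acceleration stream arrives with
an unspecified delay, so each pressure timestamp is paired with the most
recent auxiliary reading at or before it (last observation carried forward).
Interpolation was considered and rejected: the delay magnitude is unknown,
and LOCF is the only rule that never fabricates values. Pressure messages
that precede the first auxiliary reading cannot be completed and are dropped
with a logged count — a bounded head loss of the same kind as the warm-up
frames discarded at the start of every recording.

Timestamps are accepted in two dialects — `HH:MM:SS:ffff` (the device's
colon-before-fraction printing) and standard `HH:MM:SS.ffff` — and always
emitted as ISO-8601 with a dot.

A *recording* is a time-ordered run of frames carrying a single event label
(the collection protocol tags whole bouts, not frames). Classifier inputs
are windows of the `w` frames before the prediction instant, `w` ∈ [4, 32];
the first `w` frames of a recording yield no window, and windows never cross
recording boundaries. The window stride is configurable (default 1 for
maximal data; the bundled pipeline uses 2 to halve volume).

## Splits

Samples are partitioned 60/20/20 into train/validation/test per class:
validation and test each receive the nearest integer to their share and
train takes the rest, which keeps every partition within one sample of its
exact per-class share. The split is deterministic under its seed. The
default unit is the window (adjacent overlapping windows may land in
different partitions, so test scores are optimistic about temporal
generalisation); a stricter recording-level unit is available and
recommended whenever enough recordings per class exist.

## Networks and training

The classifiers are built from dense layers (time-distributed when the
input still has a time axis), 1-D convolutions over time, max pooling (size
2), a single LSTM returning its final hidden state, and dropout. Layer
order is fixed: optional conv (+ optional pooling) → optional LSTM → dense
stack → 1-unit sigmoid head; with no LSTM the dense stack acts per time
step and is flattened before the head. The engine is written in numpy
(float64, CPU); gradients are exact back-propagation, verified against
finite differences in the test suite.

Numerical choices:

* cross-entropy uses the natural log with probabilities clipped to
  [10⁻⁷, 1−10⁻⁷]; the sigmoid is fused into the loss gradient
  ((p − y)/batch) for stability;
* weights are Glorot-uniform initialised from the model seed; the LSTM
  forget-gate bias starts at 1;
* dropout rate defaults to 0.2 after each hidden dense layer (0 disables);
* optimizers: plain SGD, Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), RMSProp
  (ρ = 0.9, ε = 10⁻⁸), at learning rates {0.1, 0.01, 0.001};
* early stopping monitors validation loss with patience 10 by default and
  restores the best epoch's weights; validation AUC is recorded once, after
  restoration;
* per-channel standardisation (mean/sd fitted on the training windows) is
  part of the trained model and is applied to all later inputs;
* class imbalance is not reweighted by default.

Training is bitwise reproducible given (seed, config, data) on a fixed
numpy build.

## Hyperparameter search

The space: dense depth 1–11, units 1–64 and activation tanh/selu per layer,
conv on/off with 1–50 filters, window 2–32 and selu/sigmoid activation,
pooling on/off, LSTM on/off with 1–50 units, optimizer and learning rate as
above, batch size 1–50, history length 4–32, and an arbitrary non-empty
subset of the 20 channels (each toggled independently at probability ½ when
sampling randomly). The TPE sampler is univariate: after 10 random start-up
trials it splits completed trials at the top 25% by validation AUC, models
each scalar parameter with a Parzen (Gaussian-kernel) density over the good
trials, and picks the candidate maximising the good/bad density ratio;
categorical parameters and the per-channel toggles use smoothed category
frequencies. The trial budget defaults to 50 (desk-scale runs use far
fewer). Ties in validation AUC keep trial order (stable sort).

The search operates on one master split built at the maximal window (32
frames, all 20 channels); each trial slices its own window suffix and
channel columns, so train/validation/test membership is identical across
trials and across nodes.

## The cascade

Five binary nodes form the fixed tree shown in the README; its leaves are
exactly the six events, verified by exhaustive enumeration of all decision
assignments. Each node decides class 1 when its model's probability is at
least the threshold (default 0.5 — the natural cut-off for a sigmoid head;
the threshold is per-tree configurable). The reported path probability is
the product of taken-branch probabilities (1−p on 0-branches) — a
confidence surrogate, not a calibrated posterior. For evaluation, all five
nodes are scored per window and each leaf receives the product of branch
probabilities along its path; these leaf scores sum to 1 and back the
one-vs-rest AUCs.

Every node lookup goes through the ranked registry filtered by the failed
channel set, so a single sensor failure silently re-routes each node to its
best surviving model; when no model for a *visited* node survives, the
prediction raises an explicit node-unavailable condition (off-path dead
nodes are merely recorded and leaf scores are withheld). Streaming
inference keeps a rolling buffer of 32 frames (the maximal window; each
node slices its suffix), emits one result per stride, and forwards each
risk-flagged result (imbalance or stumbling) to the alert sink exactly
once. The alert sink is an abstract interface with console, file and
in-memory implementations; messaging transports are out of scope.

## Aggregate evaluation

Binary nodes report the confusion-count metrics (accuracy, precision,
recall, specificity, NPV, F1) plus rank-based AUC; zero-denominator metrics
are reported as undefined, never as 0. Cascade performance is reported two
ways, clearly labelled, because they answer different questions: six-class
accuracy with per-event one-vs-rest AUC macro-averaged over events present
in the truth, and the plain mean of each metric over the five binary
models. The package emits both and does not privilege either.

## The synthetic generator

The generator emulates the study conditions — ~4 Hz, 20 channels, six
events, whole recordings per event — with deliberately simple signal
families, since no signal model of the original hardware is available:

* static events are Gaussian noise around per-band baselines (heel 220,
  midfoot 90, toe 160 device units standing; 30 sitting), with occasional
  foot shifts (sitting) or toe taps (standing);
* imbalance adds a 0.4 Hz sway of amplitude 90 that alternates load between
  the medial (odd-indexed) and lateral (even-indexed) sensor bands, with a
  matched 40-unit acceleration oscillation;
* gaits are rectified-sinusoid pressure bumps sweeping heel to toe with
  per-sensor phase offsets spanning 40% of the cycle: walking at 1 Hz and
  amplitude 320, running at 2.5 Hz and amplitude 560 with a 65% contact
  duty cycle (flight frames collapse to the 10-unit residual);
* stumbling is the walking signal with Poisson bursts (rate 0.15 starts per
  frame, 3 frames long) of ±420-unit acceleration spikes and irregular
  pressure. The rate reflects a collection bout that deliberately performs
  repeated stumbles; windows of 16 frames then almost always contain a
  burst, keeping the learning problem well-posed;
* temperature is a random walk (sd 0.05/frame), giving the slow drift real
  thermistors show.

Every recording draws from its own seed stream derived from (master seed,
event code, CRC-32 of the recording id), so datasets are bitwise
reproducible and recordings mutually independent. A note on sampling: the
default 4 Hz rate puts the 2.5 Hz running cadence above the 2 Hz Nyquist
limit, where it aliases to 1.5 Hz — exactly the regime a real 4 Hz insole
would face, and the classifiers never rely on recovering the true cadence.
The spectral fidelity of the signal model itself (dominant frequency of
summed pressure within 20% of the configured cadence) is therefore checked
at a 16 Hz simulation rate.

What passing tests show — and what they do not: the synthetic events are
separable by construction (a total-pressure threshold alone tells sitting
from running), so high AUCs here demonstrate that the pipeline, the cascade
topology and the training loop work end to end, not that the architecture
would reach the same numbers on real gait data. Real recordings add
subject-to-subject variability, sensor drift and nonstationarity, fuzzy
event boundaries and hardware dropouts that the generator deliberately
omits; its parameters are exposed precisely so separability can be degraded
for stress testing.

## Bundled configurations

The five published best-model configurations ship as YAML fixtures. Two are
internally inconsistent as printed and are flagged by the loader rather
than silently repaired: the unbalanced model lists 9 per-layer unit counts
for 11 layers, two of them (5034, 624) outside the 1–64 search bound — the
fixture preserves the printed list and builds with the documented
comma-split reading [32, 4, 38, 50, 34, 38, 22, 6, 24, 58, 58], which
restores both the layer count and the bound; and the stumbling model's conv
window (10) exceeds its 4-frame history, so it is clamped to the window
length at build time. Both flags stay attached to the loaded configuration.

## Problem sizes

The bundled baseline pipeline simulates 35 recordings of 60 s (5–8 per
event), windows them at stride 2 into ≈3 700 samples, and trains one small
fixed model per node (two time-distributed dense layers of 24 and 12 tanh
units over all 20 channels, window 16 — 32 for running-vs-walking — Adam at
10⁻³, batch 32, ≤30 epochs with patience 6). These sizes give each node
hundreds of minority-class windows, a held-out test set above 700 windows,
and a complete run in tens of seconds on one CPU core.

## Known limitations

* The numpy engine trains small networks comfortably but has no GPU path
  and no convolution-over-channels variants; the architecture space is
  exactly the search space above.
* The TPE sampler is univariate (no interaction modelling) and does not
  prune trials.
* Window-level splitting leaks temporally adjacent windows across
  partitions; use the recording-level unit for honest generalisation
  estimates when data allow.
* The path-probability confidence is uncalibrated, and leaf scores assume
  the five node models are probabilistically consistent, which training
  does not enforce.
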