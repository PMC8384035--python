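# Methods

This note documents the models implemented in `myogait`, their assumptions,
the synthetic data generator that exercises them, and the numerical choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signals and their clocks

A trial carries three streams on independent clocks: multi-channel raw sEMG
(default 1111.11 Hz), two foot-switch (FSR) pressure channels (500 Hz) used
for ground-truth phase labelling, and one joint-angle trace in degrees
(100 Hz). Stream lengths follow the floor convention
`n = floor(duration × rate)`, matching the truncation semantics of
acquisition hardware. Alignment places everything on the sEMG clock: phase
labels transfer by nearest neighbour (phase is categorical — interpolating
codes would be meaningless), and the angle is linearly interpolated with
clamping at the trace ends. Time origin is stream-relative zero; hardware
trigger offsets are assumed already applied.

## Gait phases and FSR labelling

Four phases partition the cycle: IC (heel contact only), FF (heel and
forefoot loaded), HO (forefoot only), TO (swing, no contact). A channel is
"on" above a threshold fraction (default 0.5) of its own maximum. Runs
shorter than 20 ms are merged into the preceding run — shorter events are
sensor chatter, not gait. Cycle boundaries are TO→IC transitions; per-phase
areas are measured only over *complete* cycles (between successive
transitions), so k detected transitions yield k−1 cycles and partial
head/tail cycles never bias the effect matrix.

## Activation dynamics

The envelope chain is: 4th-order Butterworth band-pass 20–450 Hz, 50 Hz mains
notch (Q = 30), full-wave rectification, division by the peak rectified
value, 4th-order 4 Hz low-pass, all zero-phase. The corner frequencies are
conventional for surface EMG; the 4 Hz envelope cutoff reflects that muscle
activation evolves far more slowly than the interference pattern. Negative
filter undershoot is clipped at zero; slight overshoot above 1 is retained.

Neural activation applies the standard second-order recursive filter with a
pure electromechanical delay d:

    u(i) = α·e(i − d) − β₁·u(i−1) − β₂·u(i−2)

parameterised by its poles: β₁ = γ₁+γ₂, β₂ = γ₁·γ₂ with |γⱼ| < 1 for
stability, and α = 1 + β₁ + β₂ so the DC gain is exactly one (a sustained
envelope maps to the same sustained activation). Defaults γ₁ = γ₂ = −0.5 and
d = 40 ms sit comfortably inside the stability region; when a reference
activation trace is available, `fit_activation_params` recovers (γ₁, γ₂, d)
by a coarse grid over the stability region and delay candidates followed by
Nelder–Mead refinement, and is guaranteed never to return parameters worse
(in MSE) than the defaults. The reference signal is an explicit argument —
nothing in the model dictates what it should be (force, angle, a calibrated
activation), so the choice belongs to the caller. The delay is rounded to
whole envelope samples.

The neural-to-muscle map a = (e^{A·u} − 1)/(e^{A} − 1) uses shape factor
A = −2 by default (A = −3 strongly exponential, A → 0 linear). A = 0 is
handled by its analytic limit a = u. The map is strictly increasing with
a(0) = 0, a(1) = 1, so activations inherit the envelope's [0, 1] scale.

## Muscle selection

Per-phase areas Aᵢ (trapezoidal integral of a(t) over each phase segment,
averaged over all complete cycles — the cycle count is recorded) normalise
per muscle to effects Eᵢ = Aᵢ/max(A), making every row's maximum exactly 1.

The discard rule formalises "similar activation across most of the cycle":
muscle m is discarded when at least three of its phase-effects have a
within-δ partner in the same row, i.e. |E[m,p] − E[m,q]| ≤ δ for some q ≠ p.
Counting *partnered phases* (rather than similar pairs, or inter-muscle
similarity) is the reading that behaves correctly on the bundled reference
table: it discards the flat profiles (VM, VL, BF, and SL whose IC≈TO and
FF≈HO pairs partner all four phases) while keeping TA and ST, whose rows are
mutually similar but individually sharply phase-selective — inter-muscle
redundancy would wrongly drop one of them. δ = 0.15 sits mid-way in the
interval (≈0.06–0.19) over which the retained subset on the reference table
is unchanged. After discarding, any phase whose best retained effect falls
below 0.6 gets back the strongest discarded muscle for that phase (input
order breaks ties), so at least the four per-phase dominant muscles always
survive.

## Windowing and features

180 ms windows with 40 ms increment (200 and 44 samples at 1111.11 Hz —
millisecond specs are rounded to samples). Features are computed on
band-passed *raw* sEMG, not the activation envelope, per standard myoelectric
practice: MAV and WL carry amplitude, ZC and SSC carry spectral shape; the
ZC/SSC noise thresholds default to 0 and are exposed because hardware noise
floors differ. Window phase is the majority label; windows straddling a
transition keep the majority (transition windows are the dominant error
source and no relabelling is attempted). Each window carries the angle at
its end time and at end + horizon (default 40 ms = one increment, so a
prediction lines up with the next incoming window); windows whose future
query time exceeds the recorded trace are dropped.

## Networks

No deep-learning framework is used: the networks are small enough
(20–60 units) that exact numpy backpropagation through time trains them in
seconds on one CPU, and the implementation is fully deterministic given a
seed. LSTM cells use the standard gate formulation with forget-bias 1 and
Glorot initialisation; optimisation is Adam with global gradient-norm
clipping at 5.

* **Phase classifier**: LSTM(40) → LSTM(40) → Dense(20, ReLU) →
  Dropout(0.5) → softmax(4). Dropout follows the fully connected layer only.
* **Angle predictor**: LSTM(30)×3 → Dense(5, ReLU) as feature extractor,
  then LSTM(30)×2 → Dense(60, ReLU) → Dense(1), trained end-to-end (the
  joint objective shapes the extractor for prediction). The "30-30-30-5" /
  "30-30-60-1" stacks are read as recurrent layers with a dense projection
  at each block's end; layer kinds are configurable through the size tuples.
* Phase input to the predictor is one-hot by default (better gradient
  conditioning); a single ordinal channel is available via
  `phase_encoding="ordinal"`.

Training slices the window stream into sequences of 10 windows (400 ms of
context — long enough to span a phase, short enough that BPTT stays cheap),
stride 1, and never lets a sequence cross a trial boundary. Defaults:
Adam lr 1e-3, batch 64, a 10% validation split with early stopping, epochs
12–15 for the experiment drivers (loss curves are flat well before that on
the synthetic task). Inference runs the whole window stream as one sequence,
one output per window, so streams shorter than the training sequence length
are handled naturally. Inputs (and regression targets) are standardised with
statistics frozen at fit time.

Fine-tuning continues training of *all* weights at lr 1e-4 (nothing in the
task suggests freezing; the shift touches amplitudes and timing, which every
layer sees). Budgets are expressed in minutes of windows (1 min = 1500
windows at the 40 ms increment); each budget restarts from the base model
and trains on the first m minutes of shifted-condition data; data beyond the
largest budget is the fixed held-out test set so all budgets are compared on
identical data.

## Metrics and protocols

Pearson R uses the population (1/n) convention consistently — the choice
cancels between numerator and denominator. NRMSE divides by the *predicted*
trace's range (deliberate, if unusual; a reference-range variant sits behind
`use_reference_range=True`). The one-way ANOVA is computed from closed-form
between/within sums of squares with scipy supplying only the F tail
probability; identical groups give F = 0, p = 1. The modified leave-one-out
CV tests each trial of each subject once, training on that subject's
remaining trials plus all other subjects' trials.

## The synthetic generator

The generator emulates exactly the structure the decoder exploits, and no
more. A cycle schedule is drawn with mean 1.1 s and 5% duration jitter;
phase fractions default to IC 0.10, FF 0.35, HO 0.30, TO 0.25 —
conventional gait-analysis values. Per-muscle envelopes are sums of
raised-cosine bursts (compact support; a burst of gain g and width w has
area exactly g·w/2, making per-phase areas analytically checkable) placed at
phase midpoints with per-muscle, per-phase gains whose default pattern gives
every phase a dominant muscle. Raw sEMG is the envelope times band-limited
(20–450 Hz) unit-variance Gaussian noise. FSR channels are 0/1 plateaus from
the schedule plus 5% Gaussian noise — enough that thresholding is
non-trivial but reliable.

The angle trace is an affine readout of the weighted burst-kernel mixture
*delayed* by the EMD (default 40 ms), mapped into a plausible ankle range
(−20° to 15°) plus 0.3° sensor noise. Generating the angle from the same
kernels (rather than an independent keyframe spline) makes the
electromechanical lead exact by construction: the cross-correlation between
the weighted envelope mixture and the angle peaks at the configured delay to
within one sEMG sample, which the test suite verifies.

The "exoskeleton" condition applies +30% gain to the plantarflexors
(SL, GM, GL — the muscles the assistance offloads), a 20% shorter IC phase
(renormalising the other phases so cycle length is preserved and the factor
is exact), and a 15 ms burst delay. These magnitudes produce a clearly
measurable cross-condition accuracy drop (≈10 points on the default
experiment) without making the shifted task unlearnable.

What the generator does **not** model: motor-unit physiology, sEMG
non-stationarity and fatigue, electrode lift-off and motion artifact,
cross-talk between channels, ground-reaction forces, multi-joint coupling,
and inter-subject variability beyond what different seeds provide. Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes when that structure is present — they do not certify performance on
human recordings.

## Experiment sizes

The experiment drivers and the acceptance script use desk-scale problem
sizes chosen to keep the full suite fast while leaving the effects far from
the noise floor: ~2 min trials for single-condition training (≈3000
windows), 5.5 min condition pairs for the shift experiments (4-minute
maximum adaptation budget plus a ≈1.5 min held-out tail), 80/20
chronological train/test splits, and medians over 5 seeds where a criterion
concerns an ordering rather than a single run.

## Known limitations

* The selection rule's δ is a reconstruction with a verified validity
  interval on the reference table, not a universally calibrated constant.
* The NRMSE convention (predicted range) makes the metric sensitive to
  prediction amplitude errors in both numerator and denominator.
* `fit_activation_params` assumes the reference is an activation-scale
  trace; fitting against raw force or angle requires the caller to normalise
  first.
* Fine-tuning budgets count windows, not wall-clock recording time of the
  original multi-rate streams (identical at the default 40 ms increment).
* The numpy networks are CPU-only and single-threaded by design; they are
  not intended for embedded real-time deployment.
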