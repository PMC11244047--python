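# Methods

This note documents the models, numerical choices and limitations behind
the package. Module surfaces are described in the README; here the focus is
on *why* the defaults are what they are and what a green test does and does
not establish.

## Synthetic IMU signal model

No raw six-axis recordings of the Bafa Wubu routine are publicly available,
so every recognition experiment in this package runs on synthetic streams.
The generator deliberately uses the simplest signal model that makes the
whole processing chain consequential:

    channel(t) = gravity static component (accelerometer only)
               + A · sin(2π f t + φ)                (fundamental)
               + A/2 · sin(4π f t + 2φ + 0.7)       (one harmonic)
               + interference (> 5 Hz)  + white noise,

clipped to ±16 g / ±2000 °/s *after* noise addition, mimicking sensor
saturation. Each of the seven motion sets has a fixed deterministic
signature: a gravity orientation (arm posture), a fundamental tempo in the
tai chi band 0.2–2 Hz, and per-axis accelerometer/gyroscope amplitudes. The
static knee raise (SKR) has a strictly smaller gyroscope amplitude than
every locomotive set, encoding that it is a held stance. Because all
movement content sits below 2.4 Hz (fundamental ≤ 0.8 Hz default plus one
harmonic), the 5 Hz low-pass removes exactly the injected contamination and
nothing else.

Scripted sessions render events on a continuous global time base and join
consecutive events with linear cross-fades labelled `"transition"`, so the
window-labelling rules for mixed windows are exercised. Per-class labelled
sample counts equal the scripted durations exactly.

Parameters a user may care about:

* **raw rate** — 200 Hz default. The wearable's native rate is not
  documented anywhere authoritative; 200 Hz was chosen once so that both
  the 5 Hz filter and the 4:1 decimation to 50 Hz do real work. It is
  configurable (≥ 100 Hz).
* **moderate noise** (`moderate_noise()`) — white SD 0.1 g / 20 °/s plus a
  25 Hz interferer at 0.3 g / 50 °/s. Sized so that the filter removes most
  but not all contamination after decimation: the residual in-band noise
  makes the noisy end-to-end benchmark non-trivial without burying the
  signal.

What the generator does **not** emulate: biomechanically realistic limb
kinematics, inter-subject style variation beyond the noise seed,
orientation drift, sensor bias, or packet loss. A model that is perfect on
this synthetic world has been shown to learn well-separated oscillatory
signatures through the real preprocessing chain — nothing more. Published
accuracies on real practitioners are therefore *not* reproduced here, by
design; the end-to-end criteria are property-based (high accuracy on
noiseless separable data, large margin over the majority baseline under
moderate noise).

## Preprocessing

* **Filter** — the cutoff (5 Hz) is given by the deployment context; the
  family and order are not. A 4th-order Butterworth applied
  forward-backward (`sosfiltfilt`, zero phase) is the standard choice for
  human-movement signals: maximally flat passband, exact DC gain 1, and no
  group delay, which matters because windows are cut on the filtered
  signal. The zero-phase property is tested as commutation with time
  reversal away from the edge-padding transients (finite-signal padding
  breaks exact commutation at the edges).
* **Downsampling** — plain decimation when the source rate is an integer
  multiple of 50 Hz (safe: content is already below 5 Hz ≪ 25 Hz Nyquist),
  polyphase rational resampling otherwise. Labels follow by nearest-sample
  index mapping.
* **Segmentation** — uniform sliding windows, m = ⌊(n − L)/H⌋ + 1 with
  L = 100 and H = 50 at the defaults. Movement-boundary-aligned
  segmentation was considered and rejected: the stated 50 % overlap only
  makes sense for uniform sliding.
* **Window labelling** — majority vote over per-sample labels;
  `"transition"` samples do not vote; 50/50 ties go to the centre sample
  (falling back to the first tied class in canonical order); windows with
  no class samples at all are dropped.
* **Standardization** — per-channel z-scoring with training-set statistics
  stored in the model bundle. Accelerometer (g) and gyroscope (°/s)
  channels differ by two orders of magnitude; without this the optimizer
  effectively ignores the accelerometer. Zero-variance channels get an sd
  floor of 1e-8 and a warning.

## The TCN

Stack of `n_blocks` homogeneous blocks — dilated causal 1D convolution →
batch normalization → ReLU → dropout — with no residual connections,
followed by global average pooling over time, one hidden fully connected
layer (`dense_units`, ReLU — its width is a tuned hyperparameter) and a
softmax output over the 7 classes. Defaults: 20 blocks, dropout 0.44,
1000 epochs, 7 output classes.

Choices the deployment context leaves open, fixed here once:

* **kernel 3, 32 filters, dilations cycling (1, 2, 4, 8, 16, 32)** —
  uncapped doubling over 20 blocks would give an astronomically dilated
  stack; cycling keeps the receptive field bounded while covering the
  window: RF = 1 + Σ(k−1)·d = 385 ≥ 100 at the defaults. Building a model
  whose receptive field does not cover the window is a configuration error.
* **cross-entropy + Adam (lr 1e-3), batch 64** — standard for softmax
  classification.
* **block ordering** conv → batch-norm → ReLU → dropout.
* **split unit** — default *subject-wise* 2/3–1/3 to prevent identity
  leakage; window-wise is available (`SplitSpec(unit="window")`).

Everything (forward, backward, Adam) is NumPy, so given a seed, training is
bit-deterministic — there is no separate "deterministic mode". The tuner is
a seeded random search over a {field: candidates-or-range} space maximizing
validation accuracy; ranges spanning ≥ 2 decades sample log-uniformly.
Divergent trials (non-finite loss) stop early and score whatever accuracy
the wreckage achieves, which is how absurd learning rates lose the search.

Scaled test configuration: 4 blocks, 16 filters, dilations (4, 8, 16, 32)
(RF 121), 60–100 epochs. This trains in tens of seconds on one CPU and
reaches 100 % validation accuracy on noiseless synthetic sessions.

## Evaluation

Per-class accuracy is the recall reading of a true/false-count table:
`100 · true / (true + false)` where `true` is the diagonal entry and
`false` the rest of the true-class row. Percentages are **rounded half-up**
to one decimal (`decimal.ROUND_HALF_UP`), the printed precision of reports
in this area; a class with no true instances reports *undefined* (`None`),
not 0. Overall accuracy is `100 · trace / total`.

## Repetition counting

The deployed system pushed one window prediction per second (2 s windows,
50 % overlap) and incremented a counter per detected movement. The event
rule is the package's own, since only the counting is documented:

* **smoothing** — recursive sliding mode of width k = 3: the window at
  position i mixes the previous smoothed label with the raw present and
  next label. Feeding the smoothed past back in collapses alternating
  flicker (W,P,W,P,… → all W) while genuine boundaries switch without
  delay; ties keep the previous smoothed label.
* **events** — maximal runs of ≥ `min_run` = 2 identical labels. A single
  2 s window is unreliable under 50 % overlap (each second of signal is
  double-covered), hence the 2-window minimum. `"transition"` labels break
  runs but never form events. Each window is credited one hop of time, so
  events are non-overlapping.
* **discrepancies** — a class is flagged when |count − expected| >
  tolerance; the designed full set expects 7 per class. Attribution of a
  discrepancy to poor technique versus poor compliance is a coaching
  judgement, not a computable rule, and is out of scope.

On a noiseless scripted full session labelled by the ground-truth oracle,
this chain recovers the designed 7-per-class distribution exactly; that is
the calibration the counting parameters must (and do) pass.

## Intervention statistics

`synth_cohort` draws (pre, post) pairs from a bivariate normal with the
published per-(arm, outcome) means/SDs, arm sizes 21/29, and correlation
ρ = 0.7 — a typical test–retest correlation for these measures; the true
value was never reported, so it is a parameter, and no p value of the
original cohort is treated as reproducible. The marginals are exact:
balance/grip values are *not* truncated at zero (≈ 2 % of balance draws go
negative at the published means/SDs), because the calibration tests
(type-I error, power) rely on exact normality. Cohorts used to study
truncation-sensitive questions should post-process accordingly.

The 2 × 2 mixed ANOVA uses the exact two-stratum decomposition:

* between-subjects (group): one-way comparison of subject means
  (pre + post)/2, error = subjects within groups, df (1, N − 2);
* within-subjects (time, group × time): effect-coded contrasts on
  difference scores d = post − pre, error = time × subjects within groups,
  df (1, N − 2). The time contrast is the *unweighted* mean of the group
  mean changes (Type III), matching SPSS conventions for unbalanced arms.

Partial eta squared is SS_effect / (SS_effect + SS_error of that effect's
stratum), with sums of squares reported on the original observation metric
(exposed on the result for the decomposition invariant). Degenerate inputs:
a zero effect sum of squares reports F = 0 (not 0/0); an all-zero
difference vector in the paired t reports t = 0, p = 1 by convention.
Normality results never gate the ANOVA — both are reported, no branching.

Follow-up contrasts: paired t per arm, Welch t between arms on post scores,
and Welch t on change scores. Both between-arm readings are reported
because a "significantly different after the intervention" claim is
ambiguous between them.

Calibration properties verified by the test suite: the interaction test's
type-I error under an equal-arms null lies in [0.03, 0.07] over 2000
replicates, and a +1 post-SD shift of the precision arm's post mean at
n = 21/29 is detected with ≥ 80 % power — consistent with the study
design's stated 80 % post-hoc power.

## Known limitations

* The TCN is CPU-NumPy: fine at desk scale (thousands of windows, small
  stacks), not for the full 20-block / 1000-epoch configuration on large
  corpora.
* Synthetic separability is by construction; no claim transfers to real
  practitioner recordings.
* The counting event rule is one reasonable formalization; consecutive
  identical movements merged by the smoother would be counted once, which
  is why the designed session interleaves classes.
* Streaming is replayed offline; no latency or transport behaviour is
  modelled.
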