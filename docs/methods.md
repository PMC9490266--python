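# Methods

This note documents the models and procedures implemented in `spikealpha`,
the defaults they use, and the design decisions taken where the underlying
approach left choices open.

## Problem setting

The package targets EEG studies of trait openness during reasoning tasks:
participants with known questionnaire scores solve symbolic (matrix) and
deductive (verbal) items while 14-channel scalp EEG is recorded at 128 Hz
(AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4). Two analyses
are supported: (1) quantifying the task-related change of upper-alpha
(10–12 Hz) band power between a pre-trial reference interval and a
pre-response activation interval, and (2) classifying a participant's
ternary openness level directly from single activation epochs with a hybrid
spiking/analog convolutional network.

## Openness labeling

Questionnaire scores (1–6 Likert means) are ternarized at the cohort mean
± SD: `low` below μ−σ, `high` above μ+σ, `medium` on the closed interval
between them. Boundary scores are labeled medium; the closed-interval
convention was chosen because the verbal rule ("between μ−σ and μ+σ")
does not specify strictness, and assigning boundaries to the central class
is the conservative reading. With the published cohort statistics
(μ = 3.75, σ = 0.71) the cutoffs are 3.04 and 4.46.

## Clock alignment and epoch extraction

EEG and behavioral software run on separate hosts; a constant session
offset Δt = t₂ − t₁ (behavioral minus EEG timestamp of a shared event)
maps behavioral stamps onto the EEG clock as T + Δt. No drift model is
applied — sessions are under an hour and the hosts are NTP-disciplined in
the assumed acquisition setup.

Each trial yields two epochs: the **reference** epoch is the 5 s of the
inter-trial fixation cross (ending at fixation offset), and the
**activation** epoch is the 1 s immediately preceding the response. Trials
whose mapped intervals fall outside the recording are skipped with a
logged warning rather than aborting the run; the extraction report lists
the skipped trial ids and reasons. Whether an activation window may
overlap stimulus onset for very fast responses is not constrained — with
unlimited response time such trials are rare, and the amplitude screen
removes pathological epochs.

## Preprocessing filter

Recordings are bandpass filtered 0.1–50 Hz with a zero-phase linear-phase
FIR (`filtfilt`). The tap count follows the Hamming-window design rule
N = ⌈3.3·fs/Δf⌉ with transition bandwidth Δf = 0.35 Hz (1207 taps at
128 Hz), forced odd for a type-I filter; a literal tap-count override is
available in `FilterSpec.numtaps`. After design, the tap mean is
subtracted so the response at 0 Hz is exactly zero: a plain windowed
bandpass with a 0.1 Hz low edge leaves a few percent DC leakage, whereas
the mean-subtraction nulls DC while perturbing all other frequencies by
less than 2×10⁻⁴. Edge transients extend about 3·N samples from each end
of a filtered recording; epochs are cut from continuous recordings well
inside these margins in normal use.

## Upper-alpha band power and TRP

Band power is estimated per epoch and channel with an FFT filter on
Hanning windows of 1000 ms with 900 ms overlap:

1. Window k starts at sample round(k · 0.1 · fs). At 128 Hz the nominal
   100-ms hop is 12.8 samples; rounding each start (rather than fixing an
   integer hop) keeps the window count at ⌊(N_ms − 1000)/100⌋ + 1 for any
   epoch length — 41 windows for the 5-s reference, 1 for the 1-s
   activation — and the last window ends exactly at the epoch boundary.
2. Each windowed segment is multiplied by the Hanning taper, FFT'd, all
   bins outside the closed band [10, 12] Hz are zeroed (symmetrically over
   negative frequencies), and the inverse transform is squared sample-wise
   and averaged. The closed-interval bin selection keeps both edge bins;
   at a 1-Hz bin spacing this retains the full Hann-spread energy of
   mid-band components (a half-open selection would clip ~17% of an 11-Hz
   tone's windowed energy).
3. Per-window powers (μV²) are averaged into the trial mean.

The task-related power change per channel i is

    TRP(i) = ln Pow_act(i) − ln Pow_ref(i),

natural log by default (the base is configurable; conclusions are
base-invariant up to scale). Positive TRP is alpha synchronization.
Single-trial TRPs are averaged per participant and channel, and bilateral
pairs are averaged into seven scalp areas (anterior-frontal AF3/4,
frontal-lateral F7/8, frontal-medial F3/4, fronto-central FC5/6, temporal
T7/8, parietal P7/8, occipital O1/2).

Artifact screening is automated: an epoch is kept iff its maximum absolute
amplitude is ≤ 100 μV (configurable; the boundary keeps the epoch). This
replaces visual inspection; it catches blinks and gross movement but not
low-amplitude EMG.

## Poisson encoding and the IF convolution block

For classification, each activation epoch is scaled into [−1, 1] by one
global maximum-absolute value (per-epoch, shared across channels so that
between-channel amplitude ratios — the informative signal — survive;
per-channel scaling is available as an option). The scaled epoch is
unrolled over T = 16 timesteps: at each step every entry x fires a spike
of polarity sign(x) with probability |x| (independent uniform draws). The
comparison on |x| with the sign attached preserves negative-going signal;
a literal unsigned comparison (negative entries never fire) is retained
behind a flag for comparison.

The spike frames drive a temporal convolution (8 kernels of length 64,
'same' padding) with integrate-and-fire neurons: V[t] = V[t−1] + w∗o[t];
wherever V strictly exceeds V_th = 2 the unit emits a spike and hard-resets
to zero. The membrane potential after the last timestep, V[T], feeds the
downstream analog blocks. BatchNorm is applied once to V[T] (not inside
each timestep): V[T] is the only tensor consumed downstream, so
normalizing per timestep would add cost without affecting what deeper
blocks see.

**Backward pass.** The spike nonlinearity is non-differentiable; its
derivative is approximated by the constant surrogate 1/V_th at the
terminal timestep, and ∂V[T]/∂w by the correlation of the input spikes
accumulated over all T steps with the output gradient — resets are ignored
in the gradient. This terminal-step scheme (rather than full
backpropagation through time) is the training rule implemented and tested;
with resets disabled and no threshold crossings it is exact up to the
1/V_th factor, and exactly the true gradient when V_th = 1 (verified by
finite differences).

Convolutions and their gradients are evaluated by FFT along the time axis;
this is exact to rounding and several-fold faster than an im2col matmul at
these sizes on one CPU.

## Architecture

Input (14, 128) → Poisson encoder → IF temporal conv, 8 × (1, 64), same
padding, BatchNorm → depthwise spatial conv 16 × (14, 1), valid, ELU,
average pool (1, 4), dropout 0.5 → separable temporal conv 16 × (1, 16),
same (standard separable: per-map depthwise followed by pointwise 1×1),
BatchNorm, ELU, average pool (1, 8), dropout 0.5 → flatten (64) →
dense (3) → softmax. The shape trace
(8,14,128) → (16,1,128) → (16,1,32) → (16,1,32) → (16,1,4) → 64 → 3 is
asserted at construction. The analog comparison variant replaces the
encoder + IF block with an ordinary convolution and is built from the same
configuration, consuming identical datasets.

Conv blocks carry no bias (BatchNorm follows them); the dense layer has a
bias. Weights are Glorot-uniform initialized from a seeded generator.
Dropout is active only during training. The public API always returns
softmax probabilities; the loss consumes logits internally.

## Training and evaluation

Loss is categorical cross-entropy, optimized with Adam. Defaults:
learning rate 1e-2, 30 epochs, batch size 32 — the package's
convergence/runtime compromise for ~500-sample datasets on a single CPU
core, chosen by profiling the synthetic task (1e-3 underfits this data
badly within any reasonable epoch budget). All stochastic elements
(initialization, shuffling, dropout, the encoder) draw from seeded
generators, so a fixed seed reproduces loss histories bit-for-bit.

Because the Poisson encoder is stochastic, single-draw inference is
needlessly noisy; at evaluation the spiking variant averages softmax
outputs over `eval_passes = 8` independent seeded encoder draws
(rate-coded inference averaging). The analog variant is deterministic and
uses one pass.

Evaluation reports accuracy and macro-averaged precision, recall and F1
over the three classes, plus the 3×3 confusion matrix; classes never
predicted contribute 0 to the macro averages with a warning. The protocol
is stratified 5-fold cross-validation — each fold is an 80/20 split,
reconciling the two ways the split is usually stated — with per-fold
metrics and fold means reported; a single stratified 80/20 holdout mode is
also provided. Samples are pooled across participants by default, which
leaks subject identity between train and test; the generated datasets
carry participant indices so subject-wise splitting can be performed, and
the pooling choice is deliberate to match the protocol being modeled.

## Synthetic data generator

The generator exists so every stage is testable without access to human
recordings. Its defaults encode the assumed study design: 3 openness
levels × 7 participants × 24 trials (4 blocks of 6), 128 Hz, questionnaire
scores Normal(3.75, 0.71) clipped to [1, 6].

Each trial's signal is 1/f background noise (spectral shaping of white
noise, exponent 1, 8 μV RMS) + an upper-alpha sinusoid (11 Hz, random
phase per segment, 10 μV reference amplitude) + white sensor noise
(2 μV). The activation interval's alpha amplitude on a channel is the
reference amplitude × exp(Δ/2), where Δ is the programmed log-power change
for the channel's area — so the programmed TRP equals Δ exactly, since
power scales with amplitude squared. A per-trial lognormal gain (σ = 0.1)
applied to both intervals models slow alpha-amplitude drift and cancels in
the log-power change. Amplitudes are plausible scalp-EEG magnitudes;
they were fixed once and are configurable.

Two effect templates ship:

- the **qualitative template** (default): symbolic task — frontal areas
  +0.6 for high openness, +0.1 otherwise; deductive task — anterior
  frontal/frontal-lateral +0.6 for low openness, +0.1 otherwise; all other
  areas 0. This mirrors the direction-reversal pattern the analysis
  targets. Note it leaves low and medium statistically identical within
  the symbolic task, so three-class accuracy on it is ceilinged at 2/3.
- the **separable template** (`separable_effect_template(delta)`): low
  −Δ, medium 0, high +Δ on the frontal areas in both tasks — three
  mutually distinct classes for classifier learning checks.

Effect magnitudes are free parameters throughout; no attempt is made to
match any published effect size.

What the generator does *not* emulate: real artifacts (blinks, EMG) beyond
optional amplitude spikes, inter-channel correlation structure, alpha
non-stationarity beyond the per-trial gain, individual alpha-frequency
differences, or behavioral response distributions. Passing tests therefore
demonstrate that the pipeline recovers what it assumes — programmed
band-power changes in stationary colored noise — not that it would perform
identically on human EEG.

Datasets written to disk use the package's text dialects (recording CSV,
events TSV, scores CSV) plus a YAML sidecar with the generator parameters,
the behavioral clock offset and the recording start time (the CSV dialect
itself carries no clock metadata). Identical seeds produce byte-identical
files.

## Numerical and degenerate-input conventions

- All-zero epochs scale to all-zero (no division by zero); encoder output
  for x = 0 is silent.
- Band powers must be strictly positive to enter the log; zero power
  raises a domain error rather than returning −inf.
- The EDF writer digitizes against the header's string-rounded physical
  range so that write → read round-trips exactly at 16-bit precision, and
  pads the signal with zeros to whole 1-s records.
- Stratified folds that lose a class raise; training data with fewer than
  two classes raises; a non-finite loss aborts with the offending logit
  range.

## Problem sizes used in the checks

The bundled verification (`scripts/acceptance.py` and the test suite) uses
the full 504-sample design for cross-validation, 100 trials per point for
TRP recovery (5 programmed Δ values), T = 10,000 timesteps for encoder
rate statistics, and T = 16 scalar simulations for IF dynamics. These
sizes give sampling errors comfortably inside the asserted tolerances
(e.g. the TRP recovery slope tolerance [0.85, 1.15] is ≈6 standard errors
wide at 100 trials/point).

## Known limitations

- The terminal-step surrogate ignores resets in the gradient; IF-block
  kernels therefore receive biased gradients, and most of the fitting
  burden falls on the analog blocks. This is the intended training rule,
  not an approximation bug.
- Pooled (non-subject-wise) cross-validation overstates generalization to
  new participants.
- The amplitude-threshold artifact screen does not detect low-amplitude
  ocular or muscular contamination; no ICA-style correction is provided.
- Only the upper alpha band (10–12 Hz) is analyzed; the lower alpha band
  is deliberately out of scope.
- The NumPy implementation is single-core; wall-clock scales linearly in
  epochs × samples × timesteps (about 2.3 s per training epoch at the
  504-sample design).
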