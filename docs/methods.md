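# Methods

## Scope and model

The package implements both decision paths of an assistant-adjustable
one-DOF myoelectric prosthesis controller, the telemetry protocol between
controller and terminal, a synthetic surface-EMG generator, and the
trial-based evaluation protocol.  Human-subject EMG is not modeled or
reproduced; every empirical number the package reports is computed at run
time on synthetic signals.

## Signal acquisition model

The controller samples the sensor output at 2 kHz with 12-bit quantization
over 0–5 V; the analog front end biases the signal at +2.5 V.  The ADC is
modeled as `count = round(clamp(v, 0, 5)/5 · 4096)` clamped to `[0, 4095]`,
with back-conversion `v = count · 5/4096` (error ≤ 1 LSB ≈ 1.22 mV).  The
round-then-clamp mapping puts mid-scale 2.5 V exactly on count 2048;
digitize∘undigitize is idempotent.  Simulated streams pass through this
model so downstream stages see quantized voltages.

## Synthetic EMG generator

Each motion (rest, open, grasp) on each channel is zero-mean Gaussian noise
shaped in the frequency domain: the desired power spectral density is a sum
of Gaussian bumps (default width 12 Hz) at configurable band centers, the
white-noise FFT is multiplied by its square root, and the result is scaled
to a nominal RMS amplitude.  Optionally a 50 Hz sinusoid (mains
interference, phase-continuous across trial boundaries) is added, then the
+2.5 V offset, then the ADC model.  Motion transitions are instantaneous:
the evaluation protocol discards the first second of every trial anyway, so
ramp modeling would not change any score.

A slow multiplicative *effort drift* — a gain process with ~0.5 s
correlation time, unit mean and configurable coefficient of variation
(default 0.25 in the built-in models) — models the natural fluctuation of a
held contraction.  Without it a stationary synthetic subject is classified
essentially perfectly and between-session rate variance collapses to zero,
which makes the t-test against chance degenerate; with it, rates land in
the mid-to-high 90s with realistic spread.

Default amplitudes are stand-ins chosen at realistic post-amplifier levels
(the modeled front end amplifies ~47,000×): threshold model 0.02 / 0.06 /
0.15 V RMS for open / rest / grasp on one channel; pattern model 0.03 V RMS
at rest and 0.30 V RMS for the dominant channel of an active motion.  In
threshold control "open" is commanded by muscle *weakness*, so the open
level sits below rest.  The pattern model gives grasp low-to-mid-band power
(70–141 Hz) on the flexor channel and open high-band power (188–313 Hz) on
the extensor channel; a `separation` parameter in [0, 1] interpolates the
class spectra (and the cross-channel amplitude contrast) toward a common
average, producing statistically identical grasp/open classes at 0.  These
signals emulate the band-limited, amplitude-graded character of surface EMG
but none of its physiology (no motor-unit structure, no electrode-shift or
sweat artifacts, no fatigue-related spectral compression), so passing tests
demonstrate correctness of the processing chain, not expected performance
on real children.

One integer seed drives everything through `numpy` `SeedSequence`
spawning: schedule permutation, noise, effort drift and network
initialization have independent documented sub-streams, and all derived
seeds stay below 2³¹.

## Feature extraction

Preprocessing is a causal second-order Butterworth high-pass at 50 Hz
(−3 dB at the cutoff), applied in streaming form with carried filter state;
the filter family is a design choice — only "second-order IIR, 50 Hz
cutoff" is fixed by the system being modeled — and Butterworth is the
standard default.  Chunked filtering with carried state is bit-identical to
one-shot filtering.

The amplitude feature is the rectified exponential moving average
`S_0 = Y_t; S_{i+1} = a S_i + b|X_i|, i = 0..255; Y_{t+1} = S_256` with
`a = 0.9999`.  The implementation uses the algebraically identical closed
form `Y_{t+1} = a^256 Y_t + b Σ a^(255−i) |X_i|`; the literal 256-step loop
is kept in the test suite as an oracle.  The recurrence is interpreted as
running once per 10 ms cycle over a sliding window of the latest 256
samples (hop 20 samples), seeded with the previous cycle's feature value —
the only reading consistent with both the 256-sample window and the 10 ms
cadence.  The per-cycle decay is `a^256 ≈ 0.9747`, giving an envelope time
constant of roughly 0.4 s.

The spectral feature takes the 256-point FFT of each channel's latest
window (rectangular taper; periodogram `|X_k|²/256`), and averages power
over the five bins `c−2 … c+2` around band-center bins
`c ∈ {3, 6, 9, 12, 18, 24, 32, 40}` — the stated centers 23.4 … 312.5 Hz
are these bins' frequencies rounded, and ±15.6 Hz is exactly ±2 bins at the
7.8125 Hz bin width.  Two channels × 8 bands give the 16-dimensional
feature.  Features scale quadratically with input amplitude and are
invariant to time reversal of the window.

## Threshold controller

The raw motion identifier is a total step function of the envelope: open
below `θ_low`, grasp above `θ_high`, stop inside the closed dead band
(boundaries belong to the dead band).  The latched output re-issues the
motion active just before the envelope entered the dead band; the initial
latch is rest/stop, the safe state, since nothing else is defined before
the first active command.  A manual override, when set, wins over
everything.

Assistant adjustment moves each threshold by ±0.25/100 V (or holds it)
under the strict constraint `0.25 > θ_high > θ_low > 0`.  A command that
would violate the constraint is rejected whole — not clamped — leaving the
pair unchanged; rejection keeps the invariant auditable and is verified
inductively under 10,000 random commands.  The decision function of the
human assistant is out of scope; the package applies given commands, and
provides a clearly-labeled scripted surrogate (`fit_thresholds`) that
places each threshold at the midpoint between the median envelopes of
adjacent classes from short calibration holds (2 s per motion, scored on
the settled second half).  The surrogate exists so that the re-adjustment
arm of the evaluation can run unattended; it is not a model of parental
behavior.

## Pattern controller

The network is a fixed 16-32-8 sigmoid multilayer perceptron.  Weights and
biases initialize uniformly on [−0.5, 0.5] from a seed.  Training is
per-vector (online) gradient descent on squared error against 0.95/0.05
targets at learning rate 0.1, in stored order, with no shuffling, momentum
or early stopping — determinism is favored, and retraining after each new
20-vector block continues from the current weights for 200 passes over all
stored vectors.  Labels map to output neurons in first-seen order (at most
8); unused neurons are trained toward 0.05 everywhere.  Analytic gradients
are verified against central finite differences at 1e-5 relative error.

Recognition fires when the best *registered* output neuron reaches 0.65;
exact ties go to the lowest neuron index, and restricting the argmax to
registered neurons guarantees the recognizer never emits an unregistered
motion.  Below threshold the previously identified motion is held (initial
hold: rest).

The PCA diagnostic runs on mean-centered, unstandardized training vectors
(no scaling is part of the modeled procedure) via an eigendecomposition of
the sample covariance; it reports contribution ratios and PC1/PC2 scores,
cross-checked in tests against scikit-learn's PCA.

## Telemetry protocol

Threshold-mode frames (100 ms cadence) are 5 bytes: start byte, envelope
and both thresholds each quantized to 256 steps over 0–0.25 V
(floor-with-clamp over the half-open range, dequantizing to bin centers,
round-trip error ≤ half a step ≈ 0.49 mV), and a mod-256 checksum of the
three payload bytes.  Every single-bit payload corruption changes the
checksum, so detection of 1-bit errors is exhaustive.  Pattern-mode frames
(10 ms cadence) are 66 bytes: start byte, 16 little-endian IEEE-754
single-precision floats, terminator byte.  Start bytes 0xA5/0xA6 and
terminator 0x0A are configuration constants chosen here, as is the
endianness; none is dictated by the modeled system.  The resynchronizer
scans a noisy stream for start bytes and validates candidates (checksum or
terminator), consuming valid frames and advancing one byte otherwise.  The
terminal's graph is modeled as a fixed-capacity ring buffer (oldest entry
overwritten first) whose stored thresholds update only when a received
value differs; the threshold graph's 100 ms cadence is taken as decimation
(every 10th feature), not averaging.

## Evaluation protocol

Trials hold one motion for 5 s in seed-randomized order, ten per motion
(five in the child protocol).  Decisions are produced every 10 ms; each
decision is attributed to the trial containing its window-end time, and the
first second of every trial is discarded for reaction time, so a 5 s trial
scores 400 decisions.  The discrimination rate is the per-trial correct
fraction, averaged over trials (per-trial rather than per-decision
averaging is a documented choice; with equal-length trials the two
coincide).  The two-motion threshold test scores grasp vs open on the
latched output (rest is never a scored target); chance levels are explicit
parameters — 0.5 for two motions, 0.25 for three.  The one-sample t-test is
`t = (mean − chance)/(sd/√n)`, df = n−1, two-sided p, with zero-variance
input rejected as an error.

Session structure reduces to seeded replicate groups: the "re-adjusted"
arm re-runs the calibration surrogate before every session, the "fixed"
arm reuses the session-0 fit, and an optional drift map scales the signal
model's amplitudes from a given session onward — with drift, the fixed arm
collapses (the envelope no longer crosses the stale thresholds and the
latch re-issues stale commands) while the re-adjusted arm recovers, the
qualitative signature of threshold staleness.  Wall-clock structure
(1-hour intervals, two days) is not modeled.

## Problem sizes and numerical choices

The shipped evaluation runs use 3 synthetic subjects × 6 sessions × 20
five-second trials for the threshold arms, 3 subjects × 30 trials for the
pattern test, and 20 seeds × 5 separation levels × 1 subject (2 trials per
motion, 3 s) for the degradation trend — sizes chosen to estimate each
rate from hundreds of scored decisions while keeping a full run in the low
minutes on one core.  Envelope and band-power series are computed
vectorized over hop-aligned sliding windows and are bit-identical to the
per-window definitions.  Degenerate inputs are errors, not silent
defaults: empty motion sets, non-positive durations, wrong window lengths,
unstable filters, constant PCA data, zero-variance t-tests and ordering
violations all raise.

## Known limitations

Synthetic EMG is phenomenological (see above); discrimination rates on it
say nothing quantitative about human subjects.  The assistant is a
deterministic surrogate; the human decision operator has no algorithmic
model.  The threshold controller processes one channel; multi-channel
direct control is out of scope.  Training-data selection is manual by
construction — automatic selection is explicitly not implemented.  The
Bluetooth transport, servo mechanics and GUI rendering of the original
device are out of scope; the protocol runs over abstract byte streams and
graphs are exported as data series only.
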