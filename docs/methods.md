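# Methods

This note documents the models and estimators implemented in `ussync`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Frame-timing model

A scanner's displayed frame rate `f_nom` is a single number; the package
models the *true* inter-frame intervals (IFIs) as i.i.d. draws from a
two-point mixture: IFI = 1/r₁ with probability w (dominant mode) and 1/r₂
with probability 1 − w. The shipped presets encode two observed timing
behaviours:

| preset      | f_nom (fps) | modes (fps)  | w      | jitter SD | drop prob |
|-------------|-------------|--------------|--------|-----------|-----------|
| `telemed82` | 82          | 83.5 / 62.5  | 0.9272 | 0         | 0         |
| `telemed42` | 42          | 41.5 / 36    | 0.8562 | 0         | 0         |
| `sonix-drop`| 150.7       | 150.7 (const)| 1      | 27.937 µs | 0.05      |

The i.i.d. two-point form is deliberately minimal: only mode centres and
fractions are specified, so no serial-dependence structure is assumed or
exposed. Metadata timestamps are quantized to 100 ns (the resolution of
vendor frame headers); hardware trigger timings are the true times quantized
at the acquisition-card accuracy (25 µs default); software timestamps add
zero-mean Gaussian read-out jitter (27.937 µs default resolution for the
`sonix-drop` preset) and lose each frame independently with probability
`drop_prob`. Jitter that would break monotonicity is clamped by a running
maximum and the clamp count logged.

Because the mixture mean IFI, w/r₁ + (1−w)/r₂, generally differs from
1/f_nom, the constant-rate assumption accrues error linearly in time:
drift[k] = t_actual[k] − k/f_nom, the cumulative sum of per-frame IFI
errors. For the `telemed82` preset the mean drift rate is ≈ 6 ms per second
of acquisition, which is what turns a ~10 ms physiological latency into an
apparently acausal (negative) latency within tens of seconds.

## Synthetic imagery and EMG

The image model is a *speckle proxy*, not an acoustic simulation: low-pass
filtered Gaussian white noise (correlation length ≈ `grain`, default 2 px,
8-bit range) gives texture with the two properties the analysis chain needs —
dense trackable structure and sensitivity to sub-pixel warps. There is no
point-spread-function convolution, attenuation, or time-gain compensation;
conclusions about the *imaging physics* cannot be drawn from these data,
only about the *timing and tracking chain*.

A twitch evoked at stimulus time s displaces pixels by a Gaussian-windowed
field d(x) = p(t) · A · exp(−|x − c|²/2σ²) (centre c, spatial SD σ = 25 px
at 128 px frames, peak A = 3 px horizontally). The temporal profile p(t) is
an asymmetric twitch starting at s + latency (latency default 10 ms): a
half-cosine rise over `rise_time` (default 4 ms, i.e. shorter than one frame
interval) followed by a half-cosine relaxation over the remaining duration
(default 120 ms total). The asymmetry is the physiological fast-contraction
/ slow-relaxation shape, and it has a methodological consequence: the
inter-frame displacement — and therefore the motion-coherence score — peaks
at the *first* frame transition after movement onset, so detected event
times estimate twitch onset to within one frame interval. A symmetric
profile would put the coherence peak near the quarter-duration point and
systematically bias latencies late by tens of milliseconds. Frames are
rendered by inverse warping (cubic interpolation) plus per-frame Gaussian
intensity noise (SD 2 grey levels), rounded to 8 bits.

The EMG channel is generated for visual parity with a synchronized recording
only: Gaussian noise (2 kHz sampling) plus, per stimulus, a 1 ms biphasic
artifact at the stimulus and a damped-sinusoid M-wave (250 Hz, decay
150 s⁻¹, 8 ms latency) — amplitudes and shape are illustrative, and the
evaluation never uses EMG as a reference clock; the stimulus schedule is the
reference throughout.

Stimuli default to one pulse every 5 s starting at 5 s over a 40 s trial
(8 pulses). The final pulse fires at the very end of the recording, so its
twitch falls outside the captured frames and its latency is flagged missing
rather than fabricated.

## Feature tracking

Selection: every pixel is scored by the minimum eigenvalue of the local
gradient structure tensor (central-difference gradients, 15×15 px window);
candidates above `min_quality_ratio` (0.05) of the maximum are accepted by
greedy quality-sorted non-maximum suppression with an 8 px separation
radius, up to 200 features. A flat image yields no features, not an error.

Tracking: forward-additive Lucas–Kanade, pure translation, single pyramid
level. The template window and its gradients are fixed in the first frame;
each iteration solves the 2×2 normal equations for the displacement update
and resamples the second frame with cubic interpolation, until the update
drops below 0.01 px or 20 iterations. Features with near-singular normal
matrices, diverging estimates, or displacements beyond 5 px are dropped and
reflected in `tracked_fraction`. A single level suffices because evoked
twitches move tissue ≲3 px per transition; a coarse-to-fine scheme would add
cost without accuracy here. Features are re-selected at every transition, so
each transition's estimate is independent and selection drift cannot
accumulate. Against constructed integer and spectral sub-pixel shifts the
tracker is accurate to well under 0.1 px; agreement with an independent
dense iterative-LK implementation is within 0.2 px mean displacement.

## Motion-coherence statistic

For one transition, X = the feature's cell on a 4×4 spatial grid and Y = its
displacement vector quantized on an 8×8 grid of equal-width bins spanning
±5 px per axis. The score is the Miller–Madow corrected plug-in mutual
information I(X; Y) in bits, floored at 0; the correction is applied
entropy-wise, H_mm = H_plugin + (K − 1)/(2N ln 2) with K the number of
occupied bins, which makes the score mean-zero for independent X, Y and
vanish exactly when either marginal is degenerate.

Two numerical choices matter:

- **Zero-centred displacement bins.** The bin grid is offset by half a bin
  width so that zero displacement falls at a bin *centre*. Quiescent
  transitions then map essentially all features to a single displacement
  symbol (tracking noise is ≪ half a bin width) and score exactly 0, while
  twitch transitions — where centrally located features move by at least
  half a bin — score ≈ 0.6 bits. With an edge at zero, sub-pixel tracking
  noise straddles two bins per axis and the quiescent score inflates to
  ~0.2 bits with a long right tail, degrading detection.
- **Undefined ≠ zero.** A transition with fewer than two tracked vectors has
  no defined score and carries NaN; flagged values propagate through trace
  resampling and are excluded from interpolation support, never treated as
  "no motion".

Transition scores are assigned the midpoint of the two frame times. Events
are local maxima above median + 4 robust SDs (1.4826 × MAD) of the valid
scores, greedily separated by ≥ 1 s (tuned to the 5 s stimulation protocol;
set it below half the inter-stimulus interval for faster protocols), larger
score winning.

## IFI diagnostics

- `fit_bimodal`: 1-D two-class Lloyd iteration initialized at the sample
  min/max — deterministic, permutation-invariant, and exact on two-point
  data. Centres closer than max(2 × quantization, 10⁻⁹ × mean IFI) are
  reported as unimodal; the relative epsilon prevents last-ulp scatter in a
  nominally constant series from being called bimodal.
- `detect_dropped_frames`: a gap is a drop when IFI > 1.5× the dominant IFI
  (halfway between one and two frame periods); the estimated number of
  missing frames per gap is round(IFI/dominant) − 1. Exact for isolated
  single drops whenever timestamp jitter SD < 0.1 × IFI.
- `classify_variability`: drop-corrected one-sample z-test of
  mean(IFI) = 1/f_nom at α = 0.01 (flagged gaps are split into their
  estimated sub-intervals first, so lost frames are not mistaken for rate
  error). Rejection ⇒ "cumulative": assuming the nominal constant rate
  accrues error over the trial.
- `summarize` reports mean ± SD frame rate over *instantaneous* rates 1/IFI
  (the fraction-weighted mean of the mode rates for a mixture), not
  1/mean(IFI); with very short records (< 10 intervals) the bimodal
  decomposition is skipped and a single mode reported.
- `element_count_rate_model`: frame rate vs receive-element count,
  rate = anchor_rate × anchor_elements / n — acquisition time per frame is
  proportional to the number of receive lines.

## Synchronization evaluation

Latencies are measured per stimulus against the stimulus schedule.  Default
matching is *nearest event within ±2.5 s* (half the inter-stimulus
interval), which keeps acausal, negative latencies representable — necessary
to expose the constant-IFI artefact; strictly causal matching (first event
in (onset, onset + max_latency]) is available via `mode="causal"`. Each
event serves at most one stimulus, earliest first. The constant-delay
estimator scans a lag grid (default ±0.5 s, 1 ms step) and maximizes the
summed interpolated trace score at the shifted onsets; ties break toward the
smallest |lag|, negative before positive; a flat trace returns 0 with a
warning.

Because event times are quantized to frame transitions, measured latencies
carry irreducible jitter of about one IFI; the uncorrected latency drift is
therefore monotone only at that resolution, and the test suite asserts
monotonicity with a one-IFI allowance.

## Problem sizes and determinism

The full-scale reproduction in the test suite uses the package's default
trial — 40 s, 128×128 px, ≈3 270 frames — and completes in roughly a minute;
estimator-recovery checks use 218 s timing records (≈17 800 frames, 20
seeds) and 100-seed drop/jitter sweeps, which are cheap because they involve
no imagery. Every stochastic component takes an explicit seed; a
dataset-level seed fans out to per-component generators through fixed
`SeedSequence` spawn keys, and all file outputs are byte-deterministic given
config + seed.

## Known limitations

- The speckle proxy has no acoustic realism (no PSF, no attenuation, no
  out-of-plane motion); tracking performance on real B-mode data will be
  worse, particularly under probe motion or decorrelation.
- The IFI mixture has no serial dependence, while real scanners may exhibit
  correlated timing (e.g. buffer-related bursts); the diagnostics do not
  depend on independence, but the generator cannot emulate burst patterns.
- MI operand construction (spatial cell vs quantized displacement) is one
  declared choice among several reasonable ones; it is isolated in
  `motion_mutual_information` so alternatives can be swapped.
- Latency resolution is bounded below by the frame interval; the package
  cannot resolve sub-IFI timing differences, only remove accumulated drift.
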