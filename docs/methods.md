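# Methods

This note documents the models, the numerical choices and their rationale,
what the synthetic cohort does and does not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal conventions

All analysis runs on mono float waveforms in [−1, 1] at 16 kHz (integer
PCM is normalized by full scale at load; other rates are polyphase-
resampled).  Short-time analysis uses 25-ms Hann frames with a 10-ms hop
wherever a module does not state otherwise; frame *i* starts at `i·hop`
and only complete frames are produced.  Recordings are cut into
consecutive 60-s segments — the analysis unit everywhere downstream — and
a trailing remainder is dropped rather than padded, because padding would
bias every duration-derived feature.

## Denoising

Stationary background noise is removed by magnitude spectral subtraction:
the noise magnitude spectrum is the mean over the lowest-energy STFT
frames totalling 0.25 s, scaled by an over-subtraction factor (default 1)
and subtracted per frame with half-wave rectification and a spectral
floor of 0.01× the noise magnitude; phases are kept.  This estimator
needs some signal-free material in the recording (true of spontaneous
speech, which is full of pauses); on a signal with literally no quiet
region the lowest-energy frames still contain signal and the subtraction
becomes aggressive.  Denoising precedes segmentation and feature
extraction.

## Voice activity detection

A frame is **silence** when its RMS is ≥ 40 dB below the recording's peak
frame RMS *or* below −55 dB re full scale (the absolute floor catches
recordings that contain only a faint noise floor, where every frame ties
with the "peak").  A non-silent frame is **voiced** when its zero-crossing
rate is < 0.25 *and* its normalized autocorrelation peak in the 50–500 Hz
lag band is ≥ 0.45, else **unvoiced**.  Decisions are median-smoothed over
5 frames and intervals shorter than 50 ms are absorbed into the longer
neighbour; the result is a contiguous partition of [0, duration].  All
thresholds are config-exposed.  Downstream duration features pool
{unvoiced, silence} as "unvoiced": the fluency contrast of interest is
phonation vs. everything else.

## Fluency features (SSF)

"Most relevant" intervals are operationalized as the longest 20% per class
(quantile configurable); both the all-interval and relevant-only duration
means are emitted.  Duration histograms use 10 log-spaced bins from 10 ms
to 10 s (pause durations are heavy-tailed, so linear bins would waste
resolution), counted over the relevant intervals and normalized to
proportions.  "Speech evolution" is the least-squares slope of the voiced
percentage computed over consecutive 10-s windows, in percentage points
per window; it is 0 when fewer than two whole windows fit.  Short-time
energy and spectral centroid series are median-filtered (5 frames) before
their means/stds are taken; centroid frames with total magnitude below
1e-12 are treated as missing.

## Higuchi fractal dimension

The estimator follows Higuchi's construction: for scale k and offset m,

    L_m(k) = (N−1) / (⌊(N−m)/k⌋·k²) · Σᵢ |x(m+ik) − x(m+(i−1)k)|,

L(k) is the mean over m, and the dimension is the least-squares slope of
ln L(k) on ln (1/k).  `kmax = 8` by default: with 1-s windows (16,000
samples) the curve-length statistics are stable and the estimator
reproduces the closed-form anchors (line → 1, white noise → 2, fBm →
2 − H) within the tolerances asserted in the tests; the value is
configurable.  The FD is computed on raw waveform windows (1.0 s, 0.5 s
hop), not on derived feature series.  Constant windows (digital silence)
have zero curve length at every scale and are skipped; a fully constant
input is a degenerate-input error.

## Pitch, voice quality (EF)

Pitch uses per-lag energy-normalized autocorrelation (a periodic frame
scores r = 1 regardless of how many periods it holds) on 40-ms frames,
10-ms hop, search band 75–500 Hz, voicing threshold r ≥ 0.45.  Three
disambiguation steps deal with the classic failure modes, each of which
was observed to cluster within utterances rather than appear as isolated
flicker: (1) a small per-octave cost (0.02 per octave of lag) breaks the
tie between a true period and its multiples; (2) among near-maximal
candidate lags (local maxima within 85% of the peak) the one closest in
log-frequency to the recording's median f0 is selected, which resolves
formant-locked harmonic errors; (3) the voiced f0 sequence is median-
smoothed over 5 frames and frames deviating > 20% from the local median
are relabeled unvoiced.  Genuine pitch glides survive all three (the
tests include a 100→200 Hz ramp).

Jitter and shimmer are the conventional local perturbation quotients,
100·mean|ΔTᵢ|/mean Tᵢ, computed from **cycle-level pitch marks**: within
each voiced run, waveform peaks spaced ≥ 0.7 median periods seed cycle
anchors, which are then aligned to the run's average cycle template by
cross-correlation (two iterations, parabolic sub-sample refinement).
Template alignment uses the whole cycle shape, so mark noise is well
below single-peak picking under broadband noise — frame-level 1/f0
sequences were rejected for this purpose because overlapping 40-ms frames
average away most cycle-to-cycle perturbation and cannot recover a
programmed jitter.  Cycle amplitudes for shimmer are the RMS between
midpoints to neighbouring marks, for the same robustness reason.  The
aggregate `period_mean_s`/`period_std_s` features are contour-derived
(mean/std of 1/f0 over voiced frames) and therefore consistent with the
pitch statistics by construction.

HNR per voiced frame is 10·log₁₀(r/(1−r)) of the autocorrelation peak,
clamped to [−20, 40] dB; NHR is mean (1−r)/r; the scalar "autocorrelation"
feature is the mean voiced r.  Intensity is 20·log₁₀(RMS/1e-5) per frame —
the reference is an arbitrary constant offset, harmless because
classifiers only see consistent columns.  Degree of voice breaks is the
share of the span between first and last voiced frame occupied by
unvoiced gaps longer than 2 median periods.

## Emotional Temperature

Frames of 0.5 s (0.25-s hop) are each described by 6 numbers: the least-
squares slope and onset intercept of a line through the frame's voiced
pitch samples (≥ 3 samples required; 1–2 samples give slope 0 and the
median f0; none marks the frame unclassifiable), plus the percentages of
spectral energy in 0–400, 400–2000, 2000–5000 and 5000–8000 Hz.  The band
edges cover fundamental, first formants, higher formants/frication and
the residual band to the 8-kHz Nyquist; the 0.5-s frame is long enough
for a meaningful pitch regression yet gives ~240 frames per segment.

The frame classifier is an RBF-kernel SVM (C = 1, γ = 1/6 on z-scored
features) trained on frames that inherit their segment's label; the
training set is rebalanced by seeded down-sampling when classes differ by
more than 10%.  The threshold p0 is the raw non-pathological-percentage
cut that maximizes balanced accuracy of separating the training segments,
with candidate cuts at the midpoints between consecutive observed
per-segment percentages (midpoints keep every training segment strictly
off the boundary) and ties resolved by the median candidate.  The
normalization

    ET = 50·raw/p0                      for raw ≤ p0
    ET = 50 + 50·(raw − p0)/(100 − p0)  otherwise

is continuous, non-decreasing, fixes 0, 100 and maps p0 to exactly 50, so
the 50 line is readable as the pathological/non-pathological boundary.
Models persist to a single JSON archive (standardization parameters,
support vectors, dual coefficients, intercept, γ, p0); prediction after
reload evaluates the kernel expansion directly, so saved and in-memory
models vote identically.

## Classification protocol

Each named feature set is evaluated with a scikit-learn pipeline
(per-fold standardization → MLP with one hidden layer of 100 neurons,
up to 1,000 full-batch training steps, Adam with library defaults) under
stratified k-fold cross-validation, k = 10, with a fixed shuffle seed.
Rows are ordered by (label, segment id) before folding, making reports
invariant to input row order.  If the smallest class has fewer than k
rows the fold count is reduced to it with a warning (the four-class
default cohort has only 4 early-stage segments, so four-class runs fold
4-wise).  The confusion matrix is accumulated over held-out folds;
CER per class is 100 − per-class accuracy and accumulative CER their sum,
so a diagonal confusion matrix scores 0.  Both binary (CR vs. impaired)
and four-class modes are supported; binary is the default.

## Synthetic cohort

The generator emulates, with exact annotations, the contrasts that
dementia imposes on spontaneous speech: per class it programs f0 mean and
range, jitter, shimmer, voiced fraction, pause length distribution,
utterance length, voice-break rate, noise floor and spectral tilt.  The
default blocks form a monotone severity gradient (voiced fraction
0.55/0.45/0.35/0.25 for CR/ES/IS/AS, pauses 0.6→1.8 s, jitter
0.8→2.6%, shimmer 5→10%, f0 range 60→25 Hz, breaks 2→10 per minute,
tilt −6→−12 dB/oct), with class sizes 20/4/10/6 mirroring a balanced
40-subject study design.  The noise floor is 20 dB below speech RMS.

Mechanics worth knowing:

- Durations are budgeted in samples so the programmed voiced fraction is
  annotated exactly; voice breaks are budgeted outside the voiced total.
- Per-cycle period and amplitude perturbations are Gaussian with
  σ = programmed% / (2/√π), so the *expected measured* local jitter and
  shimmer equal the programmed percentages (|diff| of iid Gaussians has
  mean 2σ/√π).  Pulses are placed with fractional-sample interpolation to
  keep quantization jitter an order of magnitude below programmed values.
- The f0 contour is an AR(1) walk (correlation time 1.5 s) smoothed with
  a 100-ms Gaussian: natural intonation drifts smoothly, and without the
  smoothing the walk's cycle-scale roughness would masquerade as jitter
  comparable to the programmed value.
- Each utterance draws three formants and a one-pole spectral-tilt filter;
  the tilt mapping is qualitative (steeper tilt for severer classes), not
  a calibrated dB/octave realization.

What the cohort does **not** emulate: linguistic content, coarticulation,
speaker identity, channel/reverberation effects, non-stationary noise,
and the within-subject mixture of severity levels real recordings show.
Consequently, passing the end-to-end tests demonstrates that the pipeline
measures what the generator programs and separates classes whose
contrasts lie along the programmed dimensions — it is a correctness and
sensitivity statement about the software, not evidence about clinical
discriminability.

## Degenerate inputs and tie-breaks

Empty/unreadable audio, too-short signals and single-class training sets
raise input errors; a recording shorter than one segment yields an empty
segmentation with a warning.  All-silence segmentations give zero-valued
voiced statistics and all-zero histograms.  Segments with no classifiable
ET frame return NaN markers rather than failing.  p0 falls back to 50
when no usable candidate exists (degenerate training separation).  The
interval absorber merges the shortest sub-minimum interval into its
longer neighbour, iterating until stable.

## Limitations

- No claim of numeric parity with Praat or any other voice-analysis tool;
  definitions are standard but implementations differ in detail.
- The VAD is a threshold detector: heavy non-stationary noise or music
  will confuse it; thresholds were chosen for clean-ish single-speaker
  recordings.
- The ET frame labels inherit segment labels during training; frames of
  an impaired speaker that sound normal are still labeled pathological,
  which bounds the frame classifier's achievable accuracy.
- Four-class discrimination on only 4 early-stage segments is fragile by
  construction; treat four-class numbers on the default cohort as
  illustrative.
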