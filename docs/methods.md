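# Methods

## Signal model and the energy operator

The accelerometer arm assumes a single AP-axis thigh acceleration sampled
at a constant interval Ts (nominally 50 Hz). Each foot contact superimposes
a short high-frequency transient on a smooth stride-locked waveform; the
Teager-Kaiser operator Ψ[x] = ẋ² − x·ẍ converts such transients into sharp
energy peaks because its response scales with amplitude *and* frequency
(for a sinusoid of amplitude A and angular frequency ω, Ψ = A²ω²).

Two discrete forms are implemented. The default (`consistent`) follows
from 3-sample symmetric differences — the first derivative over spacing Ts
and the second over spacing 2·Ts — and equals

φ_n = [2x_n² + (x_{n+1} − x_{n−1})² − x_n(x_{n+2} + x_{n−2})] / (4Ts²).

A `literal` variant with (x_{n+2} − x_{n−2}) in the last term reproduces a
published rendering of the same expression that does not follow from that
derivation; the two provably differ (unit ramp: 0.5 vs 1.0 at the sample
with value 1), and the consistent form is exact for quadratics and matches
the stencil-built ẋ² − x·ẍ to machine precision, which is why it is the
default. φ is undefined at the first and last two samples; they are set to
0 and excluded from every peak search rather than extrapolated.

## Detection pipeline and its parameters

* **High-pass filter** — 0.5 Hz, 4th-order Butterworth, applied
  forward-backward. Zero-phase filtering is a deliberate choice: causal
  filtering would delay every event by the group delay, a systematic bias
  fatal to a timing method. The doubled effective order is accepted. A
  trace must span at least 3/cutoff seconds (6 s at the default cutoff) so
  start-up transients cannot dominate.
* **Energy smoothing** (`smooth_window_s`, default 0.06 s) — φ is averaged
  with a centred moving window of roughly one transient width before peak
  search. At 50 Hz a ~10 Hz contact transient spans only a few samples, so
  its raw φ peak height varies severalfold with how the burst carrier
  aligns with the sample grid; integrating the envelope removes that
  sensitivity without biasing timing (the window is symmetric). Setting 0
  disables it.
* **Stride-period estimate** — biased autocorrelation of the filtered
  trace, searched at lags 0.4–4.0 s with a 0.2 normalized-height floor
  (below it, "no periodic gait" is reported, as for white noise).
  The tallest peak is *not* taken blindly: a period of non-integer sample
  count aligns better with the grid at twice the lag, and concatenated
  cadences reinforce common multiples, so neighbouring side-lobes are
  merged (15 % lag clustering) and the smallest-lag cluster reaching half
  the tallest height is taken as the fundamental. A result below 0.8 s is
  doubled (step → stride); outside 0.8–4.0 s is an error.
* **IC detection** (`ic_rel_threshold` 0.3, `ic_min_separation_frac` 0.5) —
  local φ maxima at least 0.3× the median per-cycle maximum, at least half
  a stride apart. Equal-height candidates resolve to the earlier sample.
* **FC detection** (`mask_halfwidth_frac` 0.15, `fc_window_frac`
  (0.25, 0.75), `stride_band_frac` (0.7, 1.5)) — per consecutive
  ipsilateral IC pair: the IC neighbourhoods (±15 % of a stride) are
  zeroed, the remainder rescaled to unit maximum, and the largest remaining
  peak inside 25–75 % of the interval taken as FC. Intervals shorter than
  0.7 or longer than 1.5 strides are not treated as strides at all: the
  short case is a duplicate detection inside one cycle (e.g. a push-off
  transient mistaken for a contact), the long case a missed IC whose
  interval spans two strides; both would manufacture wrong stances, so
  they are dropped and logged instead.
* **Stance** — FC − IC per stride; pairs with non-positive stance are
  rejected and logged.

Detection contains no randomness: identical input and parameters give
bit-identical events. The numeric defaults above are this package's own
calibration choices — all exposed as `DetectorParams` fields — since peak
thresholds of this family of detectors are conventionally tuned per study.

## The reference arm

The coordinate (Zeni-style) method uses ankle-cluster position minus
pelvis position along the walking direction: IC at peak anterior, FC at
peak posterior excursion. A single ankle point serves both events (classic
implementations use heel and toe); this shifts each event by a roughly
constant amount relative to heel/toe timing but leaves stance *differences*
essentially unbiased, which is what the agreement analysis consumes.
Working in pelvis-relative coordinates makes overground walks self-
detrending and the events invariant to rigid lab-frame translation. The
walking direction comes from net pelvis displacement (≥1 m) unless
declared. Marker gaps ≤10 frames are linearly interpolated; longer gaps
stay invalid and host no events. Extrema are refined by a parabola through
the three surrounding frames because the 120 Hz frame quantum (8.3 ms) is
not negligible at the bias magnitudes of interest.

## Agreement statistics

Strides are matched greedily one-to-one on IC times within each side
(default tolerance 0.25 s). Statistics are computed over pooled
stride-level pairs; `PairedStances.per_participant_means()` provides the
participant-level alternative since the appropriate unit of analysis is a
genuinely open choice. On the differences d = accel − mocap: bias =
mean(d), limits of agreement bias ± 1.96·SD(d), bias CI via the t
distribution. The ICC is the two-way absolute-agreement single-measures
form computed from the ANOVA mean squares,

ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)),  k = 2,

with the McGraw & Wong F-based 95 % CI. The absolute-agreement form is
implemented deliberately — it penalises a constant inter-system offset,
which a consistency ICC would ignore (the offset-blind companion is
available as `icc_consistency` for contrast). In the applied literature
this model is often labelled ICC(2,1) or loosely "ICC(3,1)"; the label
matters less than the model, which is stated here precisely. With zero
between-subject variance the ICC is undefined and flagged rather than
forced. KS normality reports the statistic against N(μ̂, σ̂²) with both the
fixed-parameter p (optimistic when parameters are estimated) and the
Lilliefors-corrected p. The t test is pooled Student's by default with a
Welch flag.

## The synthetic generator

One event schedule drives both streams: per side, ICs every `cycle_s`
(default 1.37 s), sides half a cycle out of phase, FC following its IC by
`stance_fraction` (0.62) of a cycle, the paretic side's fraction shifted by
`asymmetry` (−0.05). Defaults emulate comfortable-pace hemiplegic walking
(stance ≈ 0.85 s on the non-paretic side). The acceleration is
stride-locked harmonics (amplitudes 1.0 and 0.5 m/s²) plus a
Gaussian-windowed 10 Hz burst (amplitude 3 m/s², width 0.05 s) at each IC,
a half-amplitude burst at each FC, and white noise (default SD 0.3 m/s²,
≈10 dB SNR against the clean waveform; `noise_sd_for_snr` computes the SD
for any target). The marker stream is exactly solvable: ankle-minus-pelvis
AP displacement is a piecewise cosine with crests exactly on true ICs and
troughs exactly on true FCs.

Two fields perturb only the accelerometer arm for method-comparison
experiments: `accel_stance_offset_s` shifts every FC burst (a known
systematic stance bias) and `timing_jitter_sd_s` jitters each burst centre
independently (known random timing error). Ground truth always refers to
the unperturbed schedule. Cohorts draw per-participant stride time
(N(1.37, 0.15²) s), stance fraction (N(0.62, 0.03²)) and speed
(N(0.93, 0.38²) m/s, truncated to 0.25–1.39), each participant walking two
10 m-equivalent bouts; everything derives deterministically from one master
seed.

What the generator does *not* emulate: inter-stride cadence variability
within a walk, turning, double-support asymmetries beyond the stance-
fraction shift, soft-tissue artefact, sensor drift or saturation, and
marker-swap errors. Passing tests therefore demonstrate that the
implementation is correct under the stated signal model, not that the
detector meets the same error bounds on recorded patient data.

## Numerical and validation notes

* Problem sizes used by the test suite and reproduction script — 60 s
  walks, 13-participant cohorts, 20–100 random replicates — were chosen as
  the smallest sizes at which Monte-Carlo error is clearly below the
  tolerances being checked.
* The analytic ICC used when validating injected-offset recovery is
  σ_b² / (σ_b² + δ²/2 + σ_e²): between-stride true-stance variance from
  the generated ground truth, the k=2 rater-offset component δ²/2, and a
  timing-error component combining the injected per-contact jitter with
  both arms' quantization (2σ_j² + 2·Ts²/12 for the accelerometer,
  2·Tf²/12 for mocap, averaged across arms). Measured ICCs sit slightly
  below it because occasional residual detection errors are not in the
  model.
* Validation scoring trims detected events that fall outside the span of
  the listed complete strides: a stride that begins before the recording
  still leaves its FC inside it, and such boundary events are real but
  unattributable, exactly as partial strides are excluded in laboratory
  protocols.
* Pooled stride-level differences from a simulated cohort are not reliably
  Gaussian: the accelerometer arm quantizes each participant's stance onto
  a 20 ms lattice, so the pooled differences form a mixture with
  participant-specific offsets. Normality assertions are therefore made on
  genuinely continuous constructions, and the KS machinery itself is
  verified against a brute-force ECDF oracle.
* Stance agreement between the two arms on noiseless data is bounded
  per-stride by one accelerometer sample (20 ms) — the coarser of the two
  grids — and in the mean by one mocap frame.

## Known limitations

Single-axis, straight-walking, bout-level processing only; no gyroscope
fusion, no machine-learned detection, no repeated-measures correction in
the Bland-Altman analysis, and agreement statistics treat pooled strides
as exchangeable. The FC search window (25–75 % of the cycle) assumes
stance fractions roughly in the 0.35–0.70 range; pathologies outside it
require adjusting `fc_window_frac`.
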