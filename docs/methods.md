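# Methods

This note documents the models and procedures implemented in `mousedisco`,
the parameter choices behind them, what the synthetic generators do and do
not emulate, and the numerical conventions that make results reproducible.

## Audibility profiling

A stimulus is reduced to a short-time Fourier magnitude spectrogram
(Hann window, 2048 samples ≈ 46 ms, hop 512 samples ≈ 12 ms at 44.1 kHz —
standard music-analysis settings).  Frames are taken without zero padding,
so the frame count is `floor((N - window)/hop) + 1`, and bin spacing is
`rate / window_samples`.

Two summaries are computed per hearing range:

* **Average frequency** — the magnitude-weighted mean
  `Σ f·|X(f,t)| / Σ |X(f,t)|`.  Amplitude weighting (not power) is the
  default because the statistic annotates an amplitude spectrogram; the
  weighting is switchable (`weighting="power"`) and logged, since the two
  conventions differ for broadband material.
* **Audible energy fraction** — the share of summed squared magnitude in
  bins whose *center* frequency lies inside `[low, high]`.  Bin-center
  membership at the range edges is deterministic and documented; with
  ~21.5 Hz bins the convention shifts the fraction by at most one bin of
  energy.  Built-in ranges: mouse 2–100 kHz, human 20 Hz–20 kHz.

Digital amplitudes are relative throughout.  A playback level in dB SPL is
metadata only: without a microphone-calibration path no software mapping
from sample values to SPL exists.

**Octave transposition** multiplies every component frequency by `2^k` at
unchanged playback duration: a phase-vocoder time stretch by `2^k`
(magnitude interpolation, cumulative phase advance with expected-phase
unwrapping, squared-window overlap-add resynthesis) followed by polyphase
decimation by `2^k`.  Content above `rate/2^(k+1)` cannot survive the shift;
it triggers a warning and is removed by the decimation's anti-alias filter.
On band-limited test signals the average frequency scales by `2^k` within
2% and duration is preserved to within one hop.  Downward shifts are not
implemented.

## Complexity indices

The four feature families are standard; the scalar aggregation over each is
explicit and parameterized so alternates can be swapped:

| index | feature | aggregation | zero case |
|---|---|---|---|
| spectral | per-frame, per-octave-band contrast `log(mean top-q) − log(mean bottom-q)` | mean over frames × bands | flat spectrum frame → exactly 0 |
| rhythmic | tempogram: windowed autocorrelation of the onset envelope, lag-0-normalized | mean over tempo lags of the std across time windows | metronomic train → ≈ 0 |
| harmonic | unit-sum 12-class chroma from a constant-Q transform | mean over classes of the std across frames | static chroma → 0 |
| dynamic | framewise RMS of the peak-normalized signal (50 ms non-overlapping frames) | std over frames | constant envelope → 0 |

Settings and conventions:

* **Spectral contrast**: 6 octave bands starting at 200 Hz (last band
  extends to Nyquist), quantile 0.02 (at least one bin per tail), natural
  log with a relative floor of 1e-10 applied after normalizing the
  spectrogram by its global maximum — the normalization makes the index
  *exactly* invariant to global gain rather than approximately so.
  Note that the per-frame contrast of white noise is not near zero: the
  within-band spread of per-frame noise magnitudes keeps the log peak/valley
  gap at roughly 2–3 nats.  What the index delivers — and what the tests
  assert — is the *ordering*: tonal material scores well above broadband
  noise on the same settings.
* **Onset envelope**: half-wave-rectified positive spectral flux summed
  over bins.  Before autocorrelation the envelope is smoothed with a short
  Hann kernel (9 frames ≈ 0.1 s) so that beat periods that are non-integer
  in frames still concentrate on the nearest lag; without smoothing a
  perfectly regular train can lose ~10% of its autocorrelation peak to
  lag quantization.
* **Tempogram**: 8 s windows, half-window hop, lags mapped to
  `BPM = 60/lag` and restricted to 30–300 BPM (covers the stimulus styles
  of interest).  Windows with zero envelope energy are flagged and excluded;
  an all-silent tempogram is degenerate and the rhythmic index refuses it.
  Scoring a concatenation of two internally steady tracks *inflates* the
  rhythmic index above either part — by design the index measures temporal
  instability of the rhythm profile, so multi-song material should be scored
  in segments (`segmented_complexity`, default 120 s, trailing remainder
  dropped rather than padded because padding biases RMS and contrast).
* **Chroma**: constant-Q transform with 12 bins/octave over 6 octaves from
  C2 (≈ 65.4 Hz at the default A4 = 440 Hz tuning reference), computed by
  the classic FFT-domain kernel method.  Kernels use `filter_scale = 2`
  (twice the canonical constant-Q length): the longer atoms trade time
  resolution — irrelevant for a per-class temporal std — for semitone
  separation sharp enough that a pure tone leaves almost no energy in its
  neighboring pitch classes.  Squared magnitudes (energies) are folded onto
  the 12 classes and each non-silent frame (RMS ≥ 1e-5) is normalized to
  unit sum; silent frames are flagged and excluded.
* **Recurrence matrix**: cosine similarity between frame features (chroma
  by default), sparsified by mutual k-nearest-neighbor filtering (k = 5% of
  frames by default), symmetrized by elementwise maximum, unit diagonal.
  Zero-norm frames are excluded with a warning.

All four indices are invariant to global gain, deterministic, and
bit-reproducible across runs (no stochastic steps).  Exact numeric
reproduction of published per-track index values is out of reach without
the original recordings; the package asserts orderings and invariants
instead, on fixtures constructed to realize them.

## Occupancy statistics

The analysis chain for a table of per-animal, per-chamber cumulative dwell
times (session default 3600 s; per animal the chamber times may sum to less
— tunnel time is unassigned — but never more):

1. **ROUT outliers**, per condition, at FDR level Q (default 1%).  The
   single-sample variant: center = median; robust residual scale
   RSDR = 68.27th percentile of |residuals| (linear interpolation) ×
   √(n/(n−1)); per-value two-tailed p from the t distribution of
   residual/RSDR with n−1 df; flagging by Benjamini–Hochberg step-up at
   level Q.  Flagged values are excluded from all downstream statistics but
   always reported.  On clean normal data at n = 12 the per-dataset
   false-flag rate is ≈ 1.5% (bounded by 2Q); a 10-RSDR contaminant is
   flagged in > 99% of simulations.  A zero RSDR with unequal values is a
   degeneracy error; identical values yield no flags.
2. **One-way ANOVA** on retained values: classical between/within
   sum-of-squares decomposition, p from the exact F upper tail (regularized
   incomplete beta).  Zero within-group variance returns sentinel results
   (F = 0, p = 1 for equal means; F = ∞, p = 0 flagged degenerate) instead
   of raising, so batch simulations never crash.  Degrees of freedom are
   derived from retained records.
3. **Pairwise pooled-variance t-tests**, df = nA + nB − 2, two-tailed,
   gated on omnibus significance (p < α) unless `always_posthoc` is set.
4. **Benjamini–Hochberg adjustment** over the family of all C(k,2)
   pairwise comparisons (m = 6 for four conditions):
   `q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎ m / j`, capped at 1.  The family size of six —
   not three — is what reproduces the published q-values from the published
   raw p-values (0.0051·6/2 = 0.0153 and 0.0197·6/3 = 0.0394, against
   printed 0.0152 and 0.0393; a family of three is inconsistent with both).
   `bh_adjust` accepts an explicit `m` larger than the number of supplied
   p-values for exactly this kind of partial-family computation.

The chain is exposed as `ChamberPreference(table).fit()` returning a
`PreferenceResults` with estimates, outlier reports, the pairwise family
and a `summary()` table.  Monte-Carlo calibration (4000 null simulations
through the full pipeline, including outlier exclusion and the generator's
sum constraint) puts the realized type-I error at α = 0.05 near 5.5% — the
slight excess over nominal comes from variance shrinkage after occasional
ROUT exclusions and is inherent to the exclude-then-test design.

The compositional dependence among one animal's four dwell times (they
share a 3600 s budget) is deliberately *not* modeled: the analysis is a
plain one-way ANOVA on independent groups, matching the assay's standard
analysis; a repeated-measures or mixed model is out of scope.

## Synthetic data

**Audio fixtures** (`gen_audio`) are pure functions of (spec, seed): exact
sinusoids, chord sequences, click trains (one click waveform per train —
a regular beat has identical onsets, which is what lets its tempogram
autocorrelation approach 1 — with optional Gaussian timing jitter),
Butterworth band-limited noise with optional square/sine amplitude
modulation, and composites joined by 10 ms crossfades (which prevent join
clicks from contaminating onset envelopes).

**Genre mimics** (`gen_genre_mimics`, 120 s at 22.05 kHz by default) are
four caricatures engineered so the qualitative contrasts of interest hold
by construction: *classical-like* (scale-walk melody with harmonics over
sustained triads, faint noise bed, flat dynamics, energy < 2 kHz — hence
mostly inaudible to a mouse), *edm-like* (an exactly repeated 8 s loop of
four-on-floor kicks, bright 4–9 kHz hats and a broadband 2.5–9.5 kHz pad
with sidechain-style amplitude pumping — broadly mouse-audible and strongly
block-repetitive), *pop-like* (looped chord cycle, pentatonic melody,
backbeat claps, strong verse/chorus level changes over a production noise
bed), and *rock-like* (low power chords, 300–3000 Hz riff bursts at ~120 BPM
with mild tempo wobble, moderate section dynamics).  They are caricatures:
no vocals, no reverberation, no mastering dynamics — so passing orderings
demonstrate that the indices respond to the intended structural features,
not that they reproduce any real recording's numbers.

**Occupancy tables** (`gen_occupancy`) draw each condition's dwell times
from a truncated normal on [0, session] whose *parent* parameters are
solved (two-moment root finding) so the truncated distribution hits the
requested mean and sd exactly — naive (mean, sd) parameterization would
bias heavily truncated conditions upward by tens of seconds.  Per animal a
tunnel fraction is drawn (Beta, concentration 150) and, if the four chamber
times exceed `session·(1 − tunnel)`, the animal is rescaled onto that
budget.  When the requested means nearly fill the session this rescaling
imposes a modest downward bias on realized group means (the price of
honoring the physical sum constraint with independent marginals); with
slack budgets the marginal moments converge to the targets at the usual
1/√n rate.

The **four-genre preset** (`fig4_spec`) uses the published group means
(1167.2 / 1066.0 / 487.7 / 810.5 s for EDM / pop / Mozart / rock chambers,
n = 12).  Its per-condition sds are *derived* from the published test
statistics — the three pairwise pooled variances from the reported raw
p-values and mean differences, the within-group mean square from the
reported omnibus F — which identifies all four variances
(≈ 180 / 619 / 670 / 407 s before scaling; the Mozart chamber is by far the
least variable, consistent with the reported low spread of that result).
Because drawing independently under the sum constraint compresses the
realized spread, a single common factor of 1.28 on all four sds is applied,
chosen so that the simulated mean F matches the reported 4.29; this is a
declared calibration of the preset, not an inference about the real data.
The **null preset** uses equal means (600 s, sd 250 s) with a loose budget
cap so the groups stay independent under the null.

## Problem sizes and runtimes

The shipped validation uses 4000 null-pipeline simulations for type-I
calibration, 4000 clean datasets for the ROUT false-flag bound, 1000
contaminant injections, 200 preset replications for the mean-structure
check, and 120 s mimics — sizes chosen so the complete check runs in well
under a minute per stage on a single core while keeping Monte-Carlo
standard errors a few times smaller than the tolerances being checked.

## Known limitations

* No perceptual model: audibility is a spectral-energy bookkeeping, not a
  loudness or detectability model (no audiogram weighting within the
  hearing range).
* Complexity indices are one defensible aggregation per feature family;
  published per-track values from other toolchains are not reproducible
  without the original audio and the exact settings behind them.
* The phase vocoder introduces the usual transient smearing; octave shifts
  of percussive material lose some attack sharpness.
* The occupancy generator's independent-marginals-plus-rescaling scheme is
  a modeling convenience; real dwell times are compositionally dependent in
  ways the generator only caps, and the fig4 preset's realized group means
  sit slightly below their targets as a consequence.
* ROUT here is the single-column (constant model) variant only.
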