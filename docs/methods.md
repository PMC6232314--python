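# Methods

This package analyzes cortical entrainment to music: the degree to which
multi-channel EEG tracks the amplitude envelope of a melody the listener
hears, how that tracking depends on the listener's familiarity with the tune
and on where attention is directed, and whether the attention condition
itself is decodable from the EEG.  Because the underlying human recordings
are not redistributable, the package ships a synthetic-study generator with
known ground truth; every analysis stage is exercised end to end against it.

## The measurement model

The quantity of interest is the normalized cross-correlation between the
stimulus envelope and each EEG channel *n*,

    r_n(τ) = (1/N_τ) Σ_t Envelope(t) · EEG_n(t + τ),

with both signals z-scored over the analyzed 29-s epoch, τ on a ±0.6 s grid
at the 256 Hz analysis rate (307 lags), and N_τ the overlap count at lag τ.
Positive τ means the EEG is read later than the envelope, so a peak at
positive lag is a lagged neural response.  Division by N_τ makes values
Pearson-like and averaging-safe; edges are truncated (no circular wrap), so
at ±0.6 s at most ~2 % of samples are lost.  Averaging is two-stage — trials
to participant, participants to grand mean — making the participant the unit
of analysis, consistent with the ANOVA's sample size.  The positive and
negative peaks are the argmax/argmin of the channel-averaged grand curve;
channel averaging uses the 62 true scalp electrodes (mastoids are the
reference; EOG is auxiliary).

## Synthetic study generator

The generator emulates the study conditions:

- **Stimuli.** 34-s melodies at 150 bpm (quarter-note frequency 2.5 Hz),
  44.1 kHz audio.  Each melody is a pulse train on the beat grid convolved
  with an exponentially decaying note shape (decay 0.15 s).  Per note:
  amplitude jitter (lognormal-like, sd 0.5), a 25 % chance of splitting into
  two eighth notes, and a 15 % chance of a rest.  The jitter/split/rest
  randomness is what distinguishes stimuli that share a tempo; it controls
  how much of the envelope–EEG correlation is stimulus-specific rather than
  shared periodicity, and therefore the power of the mismatch-pairing
  surrogate test.  Random draws are made per note, so the same seed gives
  rate-consistent envelopes at any sampling rate.
- **Response kernel.** The envelope-to-EEG response is a biphasic
  difference of two gamma-shaped lobes, positive lobe peaking at 130 ms
  (amplitude 1) and negative lobe at 260 ms (amplitude 0.8).  The gamma
  shape parameter (default 300) keeps each lobe nearly symmetric (skew
  2/√300 ≈ 0.12; lobe sd ≈ 7.5 ms and 15 ms).  Narrow, symmetric lobes are
  what make the *grid quantization* of the peak lags recoverable: the
  cross-correlation curve is the kernel convolved with the envelope
  autocorrelation, and broad or skewed lobes let the autocorrelation's
  sidelobes drag the detected extrema off the kernel's own grid points.
  On the 256 Hz grid the lobes quantize to sample 33 (128.9 ms) and, because
  0.260 s × 256 = 66.56, to sample 66 or 67 (257.8 or 261.7 ms) depending on
  realization — the same two values the peak tables report.
- **EEG.** 2,048 Hz, 62 scalp channels (10-10 montage) + M1/M2 mastoids +
  2 EOG.  Per trial: condition gain × fronto-central topography ⊗
  (kernel ∗ envelope), plus 1/f Gaussian background (10 µV RMS per channel,
  30 % of variance spatially shared), 50 Hz line interference (≈2 µV),
  Poisson blink transients (8/min, 150 µV on EOG, propagated frontally),
  and a task signature: occipito-parietal 8–12 Hz for the visual-active
  condition, temporal 16–24 Hz for auditory-active (8 µV RMS) — the signal
  the attention classifier decodes.  Channels are recorded against the
  amplifier average; mastoid re-referencing during preprocessing restores
  the response topography.
- **SNR.** The unit-gain response sits at −10 dB relative to the pink
  background (scalp-average power ratio).  The study does not characterize
  the physical response amplitude, so this is a free, deliberately
  conservative choice, not an estimate of the real recordings' SNR.
- **Gains.** Familiar trials have gain 1, unfamiliar gain 2 (stronger
  response to unfamiliar music), tasks unmodulated by default.  Familiarity
  is assigned per (participant, stimulus); 4-point ratings are drawn so the
  binary labeling rule (ratings 3–4 → familiar) inverts the gains exactly.
- **Formats.** EDF+C (16-bit, µV) with stimulus-onset annotations, one file
  per participant (trials concatenated, onset 1 s into each 36-s segment);
  WAV (16-bit PCM) per stimulus (envelope × 440 Hz carrier); TSV trial
  metadata.  The EDF writer is part of the package; reading goes through
  MNE, which doubles as an independent round-trip check.  A fixed header
  timestamp makes identical seeds byte-identical.

## Preprocessing

Fixed order: zero-phase 2nd-order IIR 50 Hz notch (Q = 35) and 5th-order
Butterworth 1 Hz high-pass → SOBI ocular cleaning → mastoid re-reference →
zero-phase 100 Hz low-pass, polyphase decimation to 256 Hz, 5th-order
Butterworth 1–40 Hz band-pass → epoching [onset + 1 s, onset + 30 s) →
amplitude-based trial rejection.  All filters are applied forward–backward;
zero phase is essential because the analysis reads peak *lags* as response
latencies.  Two readings were open:

- "1 s after the end of the trial" for the epoch start is read as 1 s after
  stimulus *onset* — the only reading that fits a 29-s epoch inside a 34-s
  stimulus.
- Trial rejection (a manual inspection step in the original workflow) is
  automated as a peak-to-peak threshold (default 150 µV on any scalp
  channel) and applied to the cleaned, band-passed epochs, where the
  threshold has a stable meaning; applied before ocular cleaning it would
  mostly count blinks.

SOBI whitens the data (with dimensionality reduction when the covariance is
rank-deficient, as it always is after common-average referencing) and
jointly diagonalizes symmetrized lagged covariance matrices (default lags
1–100 samples) by iterative Givens rotations; rotation stops when the
largest sine in a sweep falls below 1e-7, far below the sampling error of
the covariance estimates.  All covariances are estimated in channel space
and whitened afterwards, so memory stays O(channels²) regardless of
recording length.  Sources whose absolute Pearson correlation with either
EOG channel reaches 0.3 are zeroed before back-projection.  Long recordings
are processed in float32 with an in-place stage chain; the analysis-rate
outputs are float64.

## Surrogate statistics

The null is built by pairing a randomly drawn EEG trial with the envelope
of a *different* stimulus (never its own), preserving marginal statistics —
including the 2.5 Hz periodicity all same-tempo stimuli share — while
destroying stimulus-specific locking.  Per-lag two-sided empirical p-values
use the add-one correction p = (1 + #{|s| ≥ |r|}) / (n + 1), so p is never
zero and with 7,500 surrogates the floor is 1/7,501.  At the detected peak
lags, a Welch two-sample t-test compares real trial-level channel-averaged
values against the surrogate values at the same lag (sidedness: two-sided,
conservative given post-hoc peak selection).  The default pairing pool
spans all analyzed trials across participants and tasks.

## Attention decoding

29-s epochs are cut into seven non-overlapping 4-s segments (1-s remainder
dropped; control-task epochs excluded).  CSP is computed from
trace-normalized, class-averaged segment covariances of the 62 scalp
channels (EOG and mastoids excluded — their artifact variance corrupts
trace normalization); the six filters belong to the three largest and three
smallest generalized eigenvalues.  Features are log(varᵢ/Σⱼvarⱼ) — the
scale-invariant BCI convention.  Classification is an RBF-kernel SVM
(C = 1, kernel width 1/(6 · feature variance), i.e. scikit-learn's "scale")
under stratified 5-fold cross-validation with CSP re-fit inside each
training fold — fitting CSP before folding leaks label information and is
exactly what the shuffled-label control would expose.  The chance-level
control re-labels all segments in random balanced fashion and repeats the
identical procedure (5,000 runs at full scale; 200 at desk scale), which
must recenter accuracy at 50 %.

## Repeated-measures ANOVA

A 3 (task) × 2 (familiarity) fully-within design on one channel- and
trial-averaged peak value per participant × cell; incomplete participants
are dropped listwise.  The implementation reports the full SS decomposition
(subjects, each effect, each effect × subject error), F, Greenhouse–Geisser
ε from the covariance of cell scores through each effect's orthonormal
(Helmert) contrast, both uncorrected and GG-corrected p (the corrected p is
always reported and used for significance calls, removing a data-dependent
branch), and generalized eta squared for fully-within designs,
η²G = SS_eff / (SS_eff + SS_subj + Σ error SS).  ε is exactly 1 for the
two-level familiarity factor, so its df remain (1, n−1).  The implementation
agrees with pingouin's rm_anova to ≥4 decimals on random tables (checked in
the tests, where pingouin serves as the independent reference, and against a
hand-coded brute-force SS oracle at 1e-9 relative).
A calibration harness simulates null designs (exchangeable participant
noise) and verifies the GG-corrected type-I error stays at the nominal 5 %.

## Problem sizes used in tests and reproduction

The generator's study-scale defaults (14 participants × 30 trials/task,
2,048 Hz, 7,500 surrogates, 5,000 shuffles) are available via
`RunConfig.full()` / `synth.full_scale()`.  The bundled test suite and the
reproduction script use desk-scale sizes chosen to leave the conclusions
unchanged: one participant × 30 trials at the native 2,048 Hz for peak-lag
and surrogate recovery (500 surrogates; the empirical-p floor 1/501 is well
below the 0.01 criterion), 200 shuffle runs for the chance-level control,
512 Hz recordings for the shared test fixture (decimation to the 256 Hz
analysis rate is identical from either rate), and 6 participants × 24
trials at 256 Hz × 10 seeds for the effect-pattern recovery check.
Determinism: every random draw descends from a single integer seed; a
fixed seed reproduces every number, file and table bit-for-bit.

## What passing does and does not show

The generator produces stationary Gaussian backgrounds, template blinks, a
single fixed response topography and linear envelope-to-EEG coupling.  Real
EEG has nonstationary rhythms, idiosyncratic artifact mixtures, per-subject
latency and topography variation, and possibly nonlinear tracking.  Passing
therefore shows the *pipeline* is correct and calibrated — filters preserve
latency, SOBI removes what correlates with EOG and nothing else, the
surrogate test is valid under the null and powerful under entrainment, the
ANOVA's error control is nominal — not that the scientific conclusions
would replicate on new human data.  Absolute correlation amplitudes are
arbitrary in the synthetic world (they scale with the chosen SNR), so only
lags, significance patterns and orderings are meaningful targets.

## Known limitations

- No volume-conduction head model: topographies are weight vectors.
- The surrogate pool is not restricted within participant (configurable).
- Classical RM-ANOVA only; no mixed-model alternative for incomplete
  designs.
- The EDF writer covers the subset of EDF+C this package emits (uniform
  rate, one annotation channel).
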