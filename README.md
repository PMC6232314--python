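# entrain

Analysis of **cortical entrainment to music from EEG**: does the brain's
ongoing activity track the amplitude envelope of a melody, how does that
tracking depend on the listener's familiarity with the tune, and does it
depend on whether attention is on the music or on a competing silent movie?

The package implements the complete analysis as a reusable, tested pipeline:

1. **Stimulus envelopes** — resample audio to 8,192 Hz, Hilbert magnitude,
   zero-phase 100 Hz low-pass, decimate to 256 Hz, zero-phase 5th-order
   Butterworth 1–40 Hz band-pass (`entrain.envelope`).
2. **EEG preprocessing** — zero-phase 50 Hz notch and 1 Hz high-pass,
   SOBI blind source separation with EOG-correlated component removal,
   mastoid re-referencing, decimation to 256 Hz, 1–40 Hz band-pass, 29-s
   stimulus-locked epochs, amplitude-based trial rejection
   (`entrain.preprocess`).
3. **Cross-correlation** — for channel *n* and lag τ ∈ [−0.6, 0.6] s,

       r_n(τ) = (1/N_τ) Σ_t Envelope(t) · EEG_n(t + τ),

   both signals z-scored; trials → participant → grand averaging; the
   positive/negative peaks of the channel-averaged curve with their scalp
   topographies (`entrain.xcorr`).
4. **Surrogate statistics** — a mismatch-pairing null (EEG trials paired
   with envelopes of *other* stimuli), per-lag empirical p-values and a
   Welch t-test of real trial-level peak values against the surrogate
   distribution (`entrain.surrogate`).
5. **Attention decoding** — CSP log-variance features (3 largest + 3
   smallest eigenvalues) with an RBF-kernel SVM under stratified 5-fold
   cross-validation, plus a balanced label-shuffling chance control
   (`entrain.attnclf`).
6. **Inference** — 3 (task) × 2 (familiarity) repeated-measures ANOVA with
   Greenhouse–Geisser correction and generalized eta squared,
   `RMAnova(design).fit().summary()` style (`entrain.rmstats`).

Because the underlying human recordings are not redistributable, the
package includes a first-class synthetic-study generator
(`entrain.synth`): 34-s, 150 bpm melodies (quarter-note frequency 2.5 Hz)
and 66-channel EEG carrying an envelope-convolved biphasic response
(lobes at 130/260 ms) with familiarity-dependent gain, 1/f background,
50 Hz line, blinks, and task-specific oscillatory signatures — written as
standard EDF+/WAV/TSV so the whole pipeline runs on files.
See `docs/methods.md` for the model and every default.

## Worked example

One synthetic participant, 30 trials, full preprocessing, peak detection,
surrogate test and attention decoding:

```python
import numpy as np
from entrain import synth, xcorr, pipeline, attnclf, surrogate
from entrain.envelope import condition_envelope
from entrain.preprocess import preprocess_recording

cfg = synth.SynthConfig(n_participants=1, n_trials_per_task=10, n_stimuli=10,
                        eeg_rate=512.0, seed=7)
envs = synth.make_stimulus_envelopes(cfg, rate=cfg.eeg_rate)
rec, table = synth.make_participant(cfg, 0, envelopes=envs)
epochs, report = preprocess_recording(rec, metadata=table,
                                      sobi_lags=np.arange(1, 26), in_place=True)

cenvs = {s: xcorr.trim_envelope(condition_envelope(e)) for s, e in envs.items()}
correlograms = pipeline.correlogram_stage(epochs, cenvs)
peaks = xcorr.detect_peaks(xcorr.grand_average(correlograms))

ens = surrogate.build_surrogates(epochs, cenvs, n=500, seed=1)
ptable = xcorr.peak_values_per_trial(correlograms, peaks)
t, df, p = surrogate.peak_ttest(ptable.pos_value, ens.values_at(peaks.pos_index))

segs, labels, _ = attnclf.epoch_4s(epochs)
acc, sd = attnclf.crossval_accuracy(segs, labels, seed=0)
```

which prints (via the example's `print` statements):

```
kept 30 epochs; ocular components removed: [61]
positive peak 128.9 ms (r = 0.324), negative peak 261.7 ms (r = -0.404)
positive peak vs surrogates: t = 10.25, df = 30.5, p = 2.15e-11
attention decoding: 1.000 +/- 0.000; shuffled-label median 0.500
```

Reading the numbers: SOBI found exactly one EOG-correlated source (the
injected blink component) and removed it.  The grand-average correlogram
peaks at +128.9 ms — the 256 Hz grid point nearest the generator's 130 ms
response lobe — and the negative peak at 261.7 ms matches the 260 ms lobe's
quantization; both sit far outside the mismatch-pairing null (p ≪ 0.01),
i.e. the EEG is locked to *its own* stimulus, not merely to the shared
150 bpm pulse.  The two attention conditions are perfectly decodable from
4-s segments, while shuffling labels collapses accuracy to the 50 % chance
level — the CSP+SVM pipeline is leak-free.

The full study (14 participants × 30 trials/task, 7,500 surrogates, 5,000
shuffles) runs end to end from EDF/WAV files with

```sh
entrain run --scale full --seed 0 --out results/full
```

and `--scale small` gives a desk-sized version.  Each stage is also a CLI
subcommand (`entrain synth`, `entrain envelope`, ...).

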