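"""Synthetic study generator.

Emulates the study conditions end to end: 34-s piano-melody envelopes at
150 bpm (quarter-note frequency 2.5 Hz), and multi-channel EEG in which each
trial contains the envelope convolved with a biphasic cortical response
kernel (positive lobe near 130 ms, negative lobe near 260 ms), scaled by a
familiarity- and task-dependent gain, on top of 1/f background noise, 50 Hz
line interference, ocular (blink) artifacts mirrored on two EOG channels,
and a task-specific oscillatory signature (occipital alpha for the
visual-active condition, temporal low-beta for the auditory-active one) that
gives the attention classifier something to decode.

Every quantity is drawn from a seeded generator: an identical seed yields a
byte-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from . import edf
from .envelope import EnvelopeSignal
from .montage import (blink_topography, montage_labels, occipital_topography,
                      response_topography, temporal_topography)
from .preprocess import EEGRecording, Event

TASKS = ("visual-active", "auditory-active", "control")


class InvalidConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults follow the study design: 150 bpm 34-s stimuli, 2,048 Hz EEG with
    the 62-scalp + 2-mastoid + 2-EOG montage, response lobes at 130/260 ms.
    The small participant/trial counts are the desk-scale defaults; the full
    cohort (14 participants × 30 trials per task) is available through
    :func:`full_scale`.
    """

    n_participants: int = 6
    n_trials_per_task: int = 10
    n_stimuli: int = 10
    tempo: float = 150.0               # beats per minute
    trial_duration: float = 34.0       # s
    pre_s: float = 1.0                 # silence before stimulus onset
    post_s: float = 1.0                # silence after stimulus offset
    audio_rate: float = 44100.0        # Hz
    eeg_rate: float = 2048.0           # Hz
    n_scalp: int = 62                  # + 2 mastoids + 2 EOG
    kernel_pos_lag: float = 0.130      # s
    kernel_neg_lag: float = 0.260      # s
    kernel_shape: float = 300.0        # gamma shape of each lobe (skew = 2/sqrt)
    kernel_neg_amp: float = 0.8        # negative-lobe amplitude relative to positive
    gain_familiar: float = 1.0
    gain_unfamiliar: float = 2.0
    gain_by_task: dict = field(default_factory=lambda: {t: 1.0 for t in TASKS})
    snr_db: float = -10.0              # response power over 1/f background
    noise_rms: float = 10.0            # µV per-channel pink background
    shared_noise_frac: float = 0.3     # fraction of noise variance spatially shared
    line_amp: float = 2.0              # µV at 50 Hz
    eog_rate: float = 8.0              # blinks per minute
    blink_amp: float = 150.0           # µV on the EOG channels
    task_osc_amp: float = 8.0          # µV RMS of the task oscillation
    amp_jitter: float = 0.5            # per-note amplitude jitter (sd, relative)
    eighth_note_prob: float = 0.25     # chance a quarter note is split in two
    rest_prob: float = 0.15            # chance a quarter-note slot is silent
    note_decay: float = 0.15           # s, exponential decay of each note
    seed: int = 0

    def __post_init__(self):
        for name in ("n_participants", "n_trials_per_task", "n_stimuli", "tempo",
                     "trial_duration", "audio_rate", "eeg_rate", "n_scalp",
                     "noise_rms", "note_decay"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive")
        if not (0 < self.kernel_pos_lag < self.kernel_neg_lag < 0.6):
            raise InvalidConfigError(
                "need 0 < kernel_pos_lag < kernel_neg_lag < 0.6 s, got "
                f"{self.kernel_pos_lag}/{self.kernel_neg_lag}")

    @property
    def channel_labels(self) -> list:
        return montage_labels(self.n_scalp)

    @property
    def trial_len_s(self) -> float:
        return self.pre_s + self.trial_duration + self.post_s


def full_scale(**overrides) -> SynthConfig:
    """The full study-sized configuration: 14 participants × 30 trials/task."""
    kw = dict(n_participants=14, n_trials_per_task=30)
    kw.update(overrides)
    return SynthConfig(**kw)


def _rng(*keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in keys]))


# ------------------------------------------------------------------ envelope

def make_envelope(config: SynthConfig, seed: int, rate: float | None = None,
                  stimulus_id: str = "") -> EnvelopeSignal:
    """One melody envelope: a quarter-note pulse train with per-note amplitude
    jitter and occasional eighth-note subdivisions, convolved with an
    exponentially decaying note shape.

    The random draws are made per note, independently of ``rate``, so the
    same seed produces rate-consistent envelopes at any sampling rate.
    """
    if config.tempo <= 0 or config.trial_duration <= 0:
        raise InvalidConfigError("tempo and duration must be positive")
    rate = float(config.audio_rate if rate is None else rate)
    rng = _rng(seed, 11)
    period = 60.0 / config.tempo
    n = int(round(config.trial_duration * rate))
    impulses = np.zeros(n)
    t = 0.0
    while t < config.trial_duration - 1e-9:
        amp = max(0.15, 1.0 + config.amp_jitter * rng.standard_normal())
        split = rng.random() < config.eighth_note_prob
        rest = rng.random() < config.rest_prob
        if rest:
            pass                                  # silent slot: melodic pause
        elif split and t + period / 2 < config.trial_duration:
            amp2 = max(0.15, 1.0 + config.amp_jitter * rng.standard_normal())
            impulses[int(round(t * rate))] += 0.7 * amp
            impulses[int(round((t + period / 2) * rate))] += 0.7 * amp2
        else:
            impulses[int(round(t * rate))] += amp
        t += period
    shape_t = np.arange(0.0, 6 * config.note_decay, 1.0 / rate)
    note = np.exp(-shape_t / config.note_decay)
    env = signal.fftconvolve(impulses, note)[:n]
    env = np.maximum(env, 0.0)
    return EnvelopeSignal(samples=env, rate=rate, stage="synthetic",
                          stimulus_id=stimulus_id)


# ------------------------------------------------------------------ kernel

@dataclass
class ResponseKernel:
    """Biphasic envelope-to-EEG response kernel (difference of gamma lobes)."""

    taps: np.ndarray
    rate: float
    pos_peak_lag: float
    neg_peak_lag: float


def _gamma_lobe(t, mode, shape):
    theta = mode / (shape - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = (shape - 1) * (np.log(np.maximum(t, 1e-300)) - np.log(mode)) - (t - mode) / theta
    v = np.exp(logv)
    v[t <= 0] = 0.0
    return v  # peak value 1 at t = mode


def make_kernel(config: SynthConfig, rate: float = 256.0) -> ResponseKernel:
    """Difference-of-gamma response kernel sampled at ``rate``.

    The positive lobe peaks at ``kernel_pos_lag`` with amplitude 1, the
    negative lobe at ``kernel_neg_lag`` with amplitude ``-kernel_neg_amp``.
    A large gamma shape keeps each lobe nearly symmetric, so the sampled
    extrema sit on the grid points nearest the requested lags.
    """
    pos, neg = config.kernel_pos_lag, config.kernel_neg_lag
    if not (0 < pos < 0.6 and 0 < neg < 0.6):
        raise InvalidConfigError("kernel lags must lie inside (0, 0.6) s")
    if pos >= neg:
        raise InvalidConfigError("kernel_pos_lag must precede kernel_neg_lag")
    t = np.arange(0.0, 0.6, 1.0 / rate)
    taps = _gamma_lobe(t, pos, config.kernel_shape) \
        - config.kernel_neg_amp * _gamma_lobe(t, neg, config.kernel_shape)
    return ResponseKernel(taps=taps, rate=rate, pos_peak_lag=pos, neg_peak_lag=neg)


# ------------------------------------------------------------------ noise

def _pink_noise(rng, n_channels, n_samples, rate):
    """1/f-amplitude Gaussian noise, unit variance per channel."""
    nf = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    scale = np.zeros(nf)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_channels, nf)) + 1j * rng.standard_normal((n_channels, nf)))
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _narrowband(rng, n_samples, rate, band):
    """Unit-RMS narrow-band Gaussian oscillation."""
    x = rng.standard_normal(n_samples)
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _blink_train(rng, n_samples, rate, blinks_per_min):
    """Sum of smooth ~300 ms blink transients at Poisson onset times."""
    y = np.zeros(n_samples)
    width = int(0.3 * rate)
    template = np.hanning(width) ** 2
    expected = blinks_per_min * n_samples / rate / 60.0
    n_blinks = rng.poisson(expected)
    for _ in range(n_blinks):
        onset = rng.integers(0, max(1, n_samples - width))
        y[onset:onset + width] += template * (0.8 + 0.4 * rng.random())
    return y


# ------------------------------------------------------------------ trials

def condition_gain(config: SynthConfig, task: str, familiarity_rating: int) -> float:
    from .pipeline import label_familiarity

    fam = label_familiarity(familiarity_rating)
    g = config.gain_familiar if fam == "familiar" else config.gain_unfamiliar
    return g * config.gain_by_task.get(task, 1.0)


def _response_scale(config: SynthConfig, topography) -> float:
    """Amplitude (µV) putting the unit-gain response at ``snr_db`` relative to
    the per-channel pink background, averaged over scalp channels."""
    target_power = 10.0 ** (config.snr_db / 10.0) * config.noise_rms ** 2
    mean_sq = float(np.mean(np.square(topography[topography > 0])))
    return np.sqrt(target_power / max(mean_sq, 1e-12))


def make_trial(envelope: EnvelopeSignal, kernel: ResponseKernel, topography,
               config: SynthConfig, labels: dict, seed: int,
               include_background: bool = True) -> EEGRecording:
    """Synthesize one trial (pre_s + stimulus + post_s seconds).

    ``labels`` must provide ``task`` and ``familiarity_rating``.  The
    stimulus-locked response starts ``pre_s`` seconds into the trial; the
    single event marks that onset.
    """
    ch = config.channel_labels
    n_ch = len(ch)
    if len(topography) != config.n_scalp:
        raise ValueError(f"topography length {len(topography)} != {config.n_scalp} scalp channels")
    rate = config.eeg_rate
    if abs(envelope.duration - config.trial_duration) > 1.0 / rate:
        raise ValueError("envelope duration must equal the trial duration")
    if abs(envelope.rate - rate) > 1e-9:
        raise ValueError("envelope must be sampled at the EEG rate")
    n = int(round(config.trial_len_s * rate))
    onset = int(round(config.pre_s * rate))
    rng = _rng(seed, 23)

    data = np.zeros((n_ch, n), dtype=float)

    # envelope-convolved cortical response
    resp = signal.fftconvolve(envelope.samples, kernel.taps)[:len(envelope.samples)]
    sd = resp.std()
    if sd > 0:
        resp = (resp - resp.mean()) / sd
    gain = condition_gain(config, labels["task"], int(labels["familiarity_rating"]))
    amp = gain * _response_scale(config, np.asarray(topography))
    data[:config.n_scalp, onset:onset + len(resp)] += \
        amp * np.outer(np.asarray(topography), resp)

    # task-specific oscillatory signature
    if config.task_osc_amp > 0:
        if labels["task"] == "visual-active":
            w, band = occipital_topography(ch[:config.n_scalp]), (8.0, 12.0)
        elif labels["task"] == "auditory-active":
            w, band = temporal_topography(ch[:config.n_scalp]), (16.0, 24.0)
        else:
            w = None
        if w is not None and np.any(w > 0):
            osc = _narrowband(rng, n, rate, band)
            data[:config.n_scalp] += config.task_osc_amp * np.outer(w, osc)

    # ocular artifacts: blink train on EOG, propagated frontally
    blinks = _blink_train(rng, n, rate, config.eog_rate)
    eog1, eog2 = ch.index("EOG1"), ch.index("EOG2")
    data[eog1] += config.blink_amp * blinks
    data[eog2] += 0.8 * config.blink_amp * blinks
    data[:config.n_scalp] += config.blink_amp * np.outer(
        blink_topography(ch[:config.n_scalp]), blinks)

    if include_background:
        data += background_noise(config, n, rng)

    # amplifier average reference over the EEG inputs (scalp + mastoids)
    n_eeg = config.n_scalp + 2
    data[:n_eeg] -= data[:n_eeg].mean(axis=0, keepdims=True)

    return EEGRecording(data=data, rate=rate, channel_labels=list(ch),
                        events=[Event(onset, dict(labels))],
                        reference="amplifier-average",
                        participant=str(labels.get("participant", "")))


def background_noise(config: SynthConfig, n_samples: int, rng) -> np.ndarray:
    """Pink background (independent + shared spatial component), 50 Hz line."""
    n_ch = len(config.channel_labels)
    indep = _pink_noise(rng, n_ch, n_samples, config.eeg_rate)
    shared = _pink_noise(rng, 1, n_samples, config.eeg_rate)
    mix = rng.standard_normal(n_ch)[:, None] * shared
    f_ind = np.sqrt(1.0 - config.shared_noise_frac)
    f_sh = np.sqrt(config.shared_noise_frac)
    noise = config.noise_rms * (f_ind * indep + f_sh * mix)
    if config.line_amp > 0:
        t = np.arange(n_samples) / config.eeg_rate
        line = np.sin(2 * np.pi * 50.0 * t + 2 * np.pi * rng.random())
        noise += config.line_amp * (0.5 + rng.random(n_ch))[:, None] * line
    return noise


# ------------------------------------------------------------------ study

def stimulus_ids(config: SynthConfig) -> list:
    return [f"stim{k:02d}" for k in range(config.n_stimuli)]


def make_stimulus_envelopes(config: SynthConfig, rate: float | None = None) -> dict:
    """All stimulus envelopes keyed by id (shared by every participant)."""
    return {sid: make_envelope(config, seed=config.seed * 1000 + k, rate=rate, stimulus_id=sid)
            for k, sid in enumerate(stimulus_ids(config))}


def make_trial_table(config: SynthConfig, participant: int):
    """Trial metadata for one participant.

    Each stimulus is familiar or unfamiliar *to this participant*; the 4-point
    rating is drawn so the familiar/unfamiliar labels invert the gains exactly
    (familiar → rating 3 or 4, unfamiliar → 1 or 2).
    """
    import pandas as pd

    rng = _rng(config.seed, 37, participant)
    sids = stimulus_ids(config)
    fam_mask = np.zeros(len(sids), dtype=bool)
    fam_mask[: len(sids) // 2] = True
    rng.shuffle(fam_mask)
    fam_sids = [s for s, m in zip(sids, fam_mask) if m]
    unfam_sids = [s for s, m in zip(sids, fam_mask) if not m]
    rows = []
    trial = 0
    for task in TASKS:
        # alternate familiar/unfamiliar stimuli so every cell of the
        # task × familiarity design is populated, then shuffle within task
        order = []
        for i in range(config.n_trials_per_task):
            pool = fam_sids if i % 2 == 0 else unfam_sids
            order.append(pool[(i // 2) % len(pool)])
        rng.shuffle(order)
        for sid in order:
            fam = bool(fam_mask[sids.index(sid)])
            rating = int(rng.choice([3, 4] if fam else [1, 2]))
            rows.append({"participant": f"s{participant + 1:02d}", "trial": trial,
                         "task": task, "stimulus_id": sid, "familiarity_rating": rating})
            trial += 1
    return pd.DataFrame(rows)


def make_participant(config: SynthConfig, participant: int, envelopes: dict | None = None):
    """One participant's continuous recording plus its trial table.

    Trials are concatenated; each event marks a stimulus onset ``pre_s``
    seconds into its trial segment.
    """
    if envelopes is None:
        envelopes = make_stimulus_envelopes(config, rate=config.eeg_rate)
    table = make_trial_table(config, participant)
    kernel = make_kernel(config, rate=config.eeg_rate)
    topo = response_topography(config.channel_labels[:config.n_scalp])
    n_trial = int(round(config.trial_len_s * config.eeg_rate))
    n_ch = len(config.channel_labels)
    # float32: ample for µV-scale signals, halves the footprint of long recordings
    data = np.empty((n_ch, n_trial * len(table)), dtype=np.float32)
    events = []
    for k, row in table.iterrows():
        labels = row.to_dict()
        tr = make_trial(envelopes[row.stimulus_id], kernel, topo, config, labels,
                        seed=_participant_trial_seed(config, participant, k))
        data[:, k * n_trial:(k + 1) * n_trial] = tr.data
        events.append(Event(k * n_trial + tr.events[0].onset, labels))
    return EEGRecording(data=data, rate=config.eeg_rate,
                        channel_labels=list(config.channel_labels), events=events,
                        reference="amplifier-average",
                        participant=f"s{participant + 1:02d}"), table


def _participant_trial_seed(config: SynthConfig, participant: int, trial: int) -> int:
    return (config.seed * 100003 + participant * 1009 + trial) & 0x7FFFFFFF


# ------------------------------------------------------------------ dataset on disk

def make_dataset(config: SynthConfig, out_dir) -> dict:
    """Write the full synthetic study to ``out_dir``.

    Per participant: an EDF+ file (all channels, stimulus-onset annotations).
    Per stimulus: a 16-bit PCM WAV (envelope-modulated 440 Hz carrier).
    Plus a tab-separated trial-metadata table and a JSON echo of the config.
    Returns a manifest of written paths.
    """
    from scipy.io import wavfile
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"edf": [], "wav": [], "meta": str(out / "trials.tsv"),
                "config": str(out / "config.json")}

    carrier_hz = 440.0
    for sid, env in make_stimulus_envelopes(config, rate=config.audio_rate).items():
        t = np.arange(len(env.samples)) / config.audio_rate
        audio = env.samples * np.sin(2 * np.pi * carrier_hz * t)
        peak = np.abs(audio).max()
        pcm = np.round(audio / max(peak, 1e-12) * 0.9 * 32767).astype(np.int16)
        path = out / f"{sid}.wav"
        wavfile.write(path, int(config.audio_rate), pcm)
        manifest["wav"].append(str(path))

    eeg_envs = make_stimulus_envelopes(config, rate=config.eeg_rate)
    tables = []
    for p in range(config.n_participants):
        rec, table = make_participant(config, p, envelopes=eeg_envs)
        events = [(ev.onset / config.eeg_rate, config.trial_duration, "stimulus")
                  for ev in rec.events]
        path = out / f"{rec.participant}.edf"
        edf.write_edf(path, rec.data, config.eeg_rate, rec.channel_labels,
                      events=events, patient_id=rec.participant)
        manifest["edf"].append(str(path))
        tables.append(table)
    pd.concat(tables, ignore_index=True).to_csv(manifest["meta"], sep="\t", index=False)

    cfg = asdict(config)
    with open(manifest["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    return manifest
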