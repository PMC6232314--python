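"""Amplitude-envelope extraction for the musical stimuli.

The analysis-ready envelope of a stimulus is obtained by resampling the audio
to 8,192 Hz, taking the magnitude of the analytic (Hilbert-transformed)
signal, zero-phase low-pass filtering at 100 Hz, decimating to 256 Hz, and
zero-phase band-pass filtering between 1 and 40 Hz with a 5th-order
Butterworth filter.  All filters are applied forward-backward so the envelope
carries no group delay relative to the audio — essential because downstream
cross-correlation lags are interpreted as neural response latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

#: processing stages, in the only order transitions may occur
STAGES = ("synthetic", "raw-hilbert", "lowpassed", "downsampled-256", "bandpassed-1-40")

ANALYSIS_RATE = 256.0
HILBERT_RATE = 8192.0


class DegenerateSignalError(ValueError):
    """Raised for zero-variance or otherwise unusable input signals."""


class EdgeEffectError(ValueError):
    """Raised when the input is too short to filter without edge artifacts."""


@dataclass
class AudioStimulus:
    """Mono PCM audio with its sampling rate (44,100 Hz expected)."""

    samples: np.ndarray
    rate: float
    stimulus_id: str = ""

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @classmethod
    def from_wav(cls, path, stimulus_id: str | None = None) -> "AudioStimulus":
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / np.iinfo(data.dtype).max
        sid = stimulus_id if stimulus_id is not None else str(path)
        return cls(samples=np.asarray(data, dtype=float), rate=float(rate), stimulus_id=sid)


@dataclass
class EnvelopeSignal:
    """One-dimensional amplitude envelope with a processing-stage tag."""

    samples: np.ndarray
    rate: float
    stage: str
    stimulus_id: str = ""

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "bandpassed-1-40" and self.rate != ANALYSIS_RATE:
            raise ValueError("bandpassed-1-40 envelopes must be at 256 Hz")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def _advance(self, samples, rate, stage) -> "EnvelopeSignal":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(f"stage transition {self.stage!r} -> {stage!r} out of order")
        return EnvelopeSignal(samples=samples, rate=rate, stage=stage,
                              stimulus_id=self.stimulus_id)

    def to_csv(self, path) -> None:
        header = f"# rate={self.rate}\n# stage={self.stage}\n# stimulus_id={self.stimulus_id}\nenvelope"
        np.savetxt(path, self.samples, header=header, comments="")


def _butter_sos(order, cutoff, btype, rate):
    return signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")


def _zero_phase(sos, x):
    return signal.sosfiltfilt(sos, x)


def lowpass_100(env: EnvelopeSignal, order: int = 5) -> EnvelopeSignal:
    sos = _butter_sos(order, 100.0, "lowpass", env.rate)
    return env._advance(_zero_phase(sos, env.samples), env.rate, "lowpassed")


def downsample_256(env: EnvelopeSignal) -> EnvelopeSignal:
    from fractions import Fraction

    ratio = Fraction(int(round(ANALYSIS_RATE)), int(round(env.rate)))
    y = signal.resample_poly(env.samples, ratio.numerator, ratio.denominator)
    return env._advance(y, ANALYSIS_RATE, "downsampled-256")


def bandpass_1_40(env: EnvelopeSignal, order: int = 5) -> EnvelopeSignal:
    sos = _butter_sos(order, (1.0, 40.0), "bandpass", env.rate)
    return env._advance(_zero_phase(sos, env.samples), env.rate, "bandpassed-1-40")


def condition_envelope(env: EnvelopeSignal) -> EnvelopeSignal:
    """Take a raw envelope (any rate ≥ 256 Hz) to the analysis stage.

    Applies the 100 Hz zero-phase low-pass, decimation to 256 Hz (identity
    when already there) and the 1–40 Hz zero-phase band-pass, in that order.
    """
    if env.rate < ANALYSIS_RATE:
        raise ValueError(f"envelope rate {env.rate} too low to condition")
    return bandpass_1_40(downsample_256(lowpass_100(env)))


def extract_envelope(audio: AudioStimulus) -> EnvelopeSignal:
    """Full envelope-extraction chain for one audio stimulus.

    Returns the stage ``bandpassed-1-40`` envelope at 256 Hz.
    """
    if audio.rate < HILBERT_RATE:
        raise ValueError(f"audio rate {audio.rate} < {HILBERT_RATE}")
    if audio.duration < 2.0:
        raise EdgeEffectError("audio shorter than 2 s; filter edges would dominate")
    x = np.asarray(audio.samples, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateSignalError("zero-variance audio input")

    from fractions import Fraction

    ratio = Fraction(int(HILBERT_RATE), int(round(audio.rate)))
    x = signal.resample_poly(x, ratio.numerator, ratio.denominator)
    env = np.abs(signal.hilbert(x))
    env_sig = EnvelopeSignal(samples=env, rate=HILBERT_RATE, stage="raw-hilbert",
                             stimulus_id=audio.stimulus_id)
    return condition_envelope(env_sig)


def envelope_spectrum(envs, resolution: float = 0.25):
    """Welch power-density spectrum of one or several envelopes.

    Parameters
    ----------
    envs : EnvelopeSignal or list of EnvelopeSignal
        Band-passed (stage ``bandpassed-1-40``) envelopes.  A list is averaged.
    resolution : float
        Maximum frequency-bin spacing in Hz (default 0.25).

    Returns
    -------
    freqs, power : ndarray
        Frequencies 0–128 Hz and the averaged power density.
    """
    if isinstance(envs, EnvelopeSignal):
        envs = [envs]
    if not envs:
        raise ValueError("no envelopes to average")
    rates = {e.rate for e in envs}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates in spectrum average: {sorted(rates)}")
    rate = rates.pop()
    for e in envs:
        if e.stage != "bandpassed-1-40":
            raise ValueError(f"expected stage bandpassed-1-40, got {e.stage!r}")
    nperseg = int(2 ** np.ceil(np.log2(rate / resolution)))
    spectra = []
    freqs = None
    for e in envs:
        n = min(nperseg, len(e.samples))
        f, p = signal.welch(e.samples, fs=rate, nperseg=n)
        if freqs is None:
            freqs = f
        elif len(f) != len(freqs):
            raise ValueError("envelopes of incompatible lengths in average")
        spectra.append(p)
    return freqs, np.mean(spectra, axis=0)


def dominant_frequency(freqs, power, f_min: float = 0.5) -> float:
    """Frequency of the largest spectral peak above ``f_min`` (excludes DC)."""
    mask = freqs >= f_min
    return float(freqs[mask][np.argmax(power[mask])])
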