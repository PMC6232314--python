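"""Envelope–EEG cross-correlation, averaging, and peak detection.

For each channel *n* the correlogram is

    r_n(τ) = (1/N_τ) Σ_t Envelope(t) · EEG_n(t + τ)

over the overlapping samples N_τ, with both signals z-scored over the full
29-s epoch, on the lag grid τ ∈ [−0.6, 0.6] s at 1/256 s (307 points).
Positive τ means the EEG is taken later than the envelope, so a positive-lag
peak is a neural response that follows the stimulus.  Averaging is two-stage
(trials → participant, participants → grand) so the participant is the unit
of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .envelope import EnvelopeSignal
from .montage import scalp_labels
from .preprocess import EEGEpoch, EPOCH_START_S, EPOCH_LEN_S

RATE = 256.0
MAX_LAG = int(0.6 * RATE)            # 153 samples ≈ 0.598 s
LAG_GRID = np.arange(-MAX_LAG, MAX_LAG + 1) / RATE   # 307 points


class DegenerateSignalError(ValueError):
    pass


@dataclass
class CrossCorrelogram:
    lags: np.ndarray                 # seconds, symmetric about 0
    values: np.ndarray               # channels × lags
    channel_labels: list
    level: str                       # trial | participant | grand
    task: str | None = None
    familiarity: str | None = None
    participant: str | None = None
    trial: int | None = None

    def __post_init__(self):
        if self.values.shape != (len(self.channel_labels), len(self.lags)):
            raise ValueError("values must be channels × lags")

    @property
    def scalp_idx(self) -> np.ndarray:
        names = set(scalp_labels(self.channel_labels))
        return np.array([i for i, ch in enumerate(self.channel_labels) if ch in names])

    @property
    def channel_averaged(self) -> np.ndarray:
        """Curve averaged over the scalp channels (mastoids/EOG excluded)."""
        idx = self.scalp_idx
        if idx.size == 0:
            idx = np.arange(len(self.channel_labels))
        return self.values[idx].mean(axis=0)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values.T, columns=self.channel_labels)
        df.insert(0, "lag_ms", self.lags * 1000.0)
        return df


@dataclass
class PeakResult:
    pos_lag: float                   # s
    pos_value: float
    neg_lag: float
    neg_value: float
    pos_topography: np.ndarray
    neg_topography: np.ndarray
    channel_labels: list
    pos_index: int = 0
    neg_index: int = 0


def trim_envelope(env: EnvelopeSignal, start_s: float = EPOCH_START_S,
                  duration_s: float = EPOCH_LEN_S) -> EnvelopeSignal:
    """The [1 s, 30 s) window of a conditioned envelope, matching the epochs."""
    if env.rate != RATE:
        raise ValueError(f"expected {RATE} Hz envelope, got {env.rate}")
    a = int(round(start_s * env.rate))
    n = int(round(duration_s * env.rate))
    if a + n > len(env.samples):
        raise ValueError("envelope shorter than the requested analysis window")
    return replace(env, samples=env.samples[a:a + n])


def _zscore(x, axis=-1):
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSignalError("zero-variance signal in cross-correlation")
    return (x - x.mean(axis=axis, keepdims=True)) / sd


def _fft_xcorr(eeg_z: np.ndarray, env_z: np.ndarray) -> np.ndarray:
    """c[:, k] = Σ_t eeg_z[:, t+k] env_z[t] for k on the lag grid."""
    n = env_z.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(n + MAX_LAG)))
    E = np.fft.rfft(env_z, nfft)
    X = np.fft.rfft(eeg_z, nfft, axis=-1)
    c = np.fft.irfft(X * np.conj(E), nfft, axis=-1)
    out = np.empty(eeg_z.shape[:-1] + (2 * MAX_LAG + 1,))
    out[..., MAX_LAG:] = c[..., :MAX_LAG + 1]
    out[..., :MAX_LAG] = c[..., nfft - MAX_LAG:]
    return out


def overlap_counts(n: int) -> np.ndarray:
    return n - np.abs(np.arange(-MAX_LAG, MAX_LAG + 1))


def crosscorr(env: EnvelopeSignal, epoch: EEGEpoch) -> CrossCorrelogram:
    """Per-channel normalized cross-correlogram of one trial."""
    if epoch.rate != RATE or env.rate != RATE:
        raise ValueError("both signals must be sampled at 256 Hz")
    n = epoch.data.shape[1]
    if len(env.samples) != n:
        raise ValueError(f"envelope length {len(env.samples)} != epoch length {n}")
    env_z = _zscore(np.asarray(env.samples, dtype=float))
    eeg_z = _zscore(np.asarray(epoch.data, dtype=float))
    values = _fft_xcorr(eeg_z, env_z) / overlap_counts(n)
    return CrossCorrelogram(lags=LAG_GRID.copy(), values=values,
                            channel_labels=list(epoch.channel_labels), level="trial",
                            task=epoch.task, familiarity=epoch.familiarity,
                            participant=epoch.participant, trial=epoch.trial)


def grand_average(items, by: str | None = None):
    """Two-stage mean: trials → participant, then participants → grand.

    ``by=None`` pools everything into one grand correlogram; ``by="cell"``
    returns a dict keyed by (task, familiarity).
    """
    if by == "cell":
        cells = {}
        for cg in items:
            cells.setdefault((cg.task, cg.familiarity), []).append(cg)
        if not cells:
            raise ValueError("no correlograms to average")
        return {cell: grand_average(group) for cell, group in sorted(cells.items())}
    items = list(items)
    if not items:
        raise ValueError("missing cell: no correlograms to average")
    lags0 = items[0].lags
    labels0 = items[0].channel_labels
    for cg in items:
        if not np.array_equal(cg.lags, lags0) or cg.channel_labels != labels0:
            raise ValueError("lag grids / channel sets differ across correlograms")
    levels = {cg.level for cg in items}
    if len(levels) != 1:
        raise ValueError(f"mixed correlogram levels {levels}")
    level = levels.pop()
    if level == "trial":
        per_part = {}
        for cg in items:
            per_part.setdefault(cg.participant, []).append(cg.values)
        stack = np.stack([np.mean(v, axis=0) for v in per_part.values()])
        out_level = "grand" if len(per_part) > 1 else "participant"
    else:
        stack = np.stack([cg.values for cg in items])
        out_level = "grand"
    tasks = {cg.task for cg in items}
    fams = {cg.familiarity for cg in items}
    return CrossCorrelogram(
        lags=lags0.copy(), values=stack.mean(axis=0), channel_labels=list(labels0),
        level=out_level, task=tasks.pop() if len(tasks) == 1 else None,
        familiarity=fams.pop() if len(fams) == 1 else None)


def detect_peaks(grand: CrossCorrelogram) -> PeakResult:
    """Positive peak = argmax, negative peak = argmin of the channel-averaged
    curve over the full lag grid (ties resolved to the earliest lag)."""
    curve = grand.channel_averaged
    i_pos = int(np.argmax(curve))
    i_neg = int(np.argmin(curve))
    if i_pos == i_neg:
        raise DegenerateSignalError("flat correlogram: no distinct extrema")
    return PeakResult(
        pos_lag=float(grand.lags[i_pos]), pos_value=float(curve[i_pos]),
        neg_lag=float(grand.lags[i_neg]), neg_value=float(curve[i_neg]),
        pos_topography=grand.values[:, i_pos].copy(),
        neg_topography=grand.values[:, i_neg].copy(),
        channel_labels=list(grand.channel_labels), pos_index=i_pos, neg_index=i_neg)


def peak_values_per_trial(correlograms, peaks: PeakResult):
    """Channel-averaged value of every trial's correlogram at the grand peak
    lags; one row per trial."""
    import pandas as pd

    rows = []
    for cg in correlograms:
        curve = cg.channel_averaged
        rows.append({"participant": cg.participant, "trial": cg.trial,
                     "task": cg.task, "familiarity": cg.familiarity,
                     "pos_value": float(curve[peaks.pos_index]),
                     "neg_value": float(curve[peaks.neg_index])})
    return pd.DataFrame(rows)
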