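"""EEG preprocessing chain.

The chain, in fixed order: 50 Hz notch + 1 Hz high-pass (both zero-phase) →
artifact-trial rejection → SOBI-based ocular-component removal → mastoid
re-referencing → 100 Hz low-pass, decimation to 256 Hz and 1–40 Hz band-pass
→ epoching into 29-s stimulus-locked trials.  Every filter is applied
forward–backward (zero phase) so response latencies are not distorted.

SOBI (second-order blind identification) recovers temporally structured
sources by jointly diagonalizing a set of time-lagged covariance matrices of
the whitened data; sources correlating with the EOG channels are zeroed and
the remainder back-projected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import linalg, signal

from .montage import EOG, MASTOIDS, scalp_labels

ANALYSIS_RATE = 256.0
EPOCH_START_S = 1.0   # epochs start 1 s after stimulus onset (filter-edge guard)
EPOCH_LEN_S = 29.0


class AliasingError(ValueError):
    pass


class MissingChannelError(KeyError):
    pass


@dataclass
class Event:
    onset: int          # sample index
    info: dict = field(default_factory=dict)


@dataclass
class EEGRecording:
    """Continuous multi-channel recording (channels × samples, µV)."""

    data: np.ndarray
    rate: float
    channel_labels: list
    events: list = field(default_factory=list)
    reference: str = "amplifier-average"
    participant: str = ""

    def __post_init__(self):
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be strictly increasing in onset")

    def idx(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as err:
            raise MissingChannelError(label) from err

    @property
    def scalp_idx(self) -> np.ndarray:
        names = set(scalp_labels(self.channel_labels))
        return np.array([i for i, ch in enumerate(self.channel_labels) if ch in names])

    @property
    def eog_idx(self) -> np.ndarray:
        return np.array([i for i, ch in enumerate(self.channel_labels) if ch in EOG])

    @property
    def eeg_idx(self) -> np.ndarray:
        """All non-EOG channels (scalp + mastoids)."""
        return np.array([i for i, ch in enumerate(self.channel_labels) if ch not in EOG])

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(),
                       events=[Event(e.onset, dict(e.info)) for e in self.events])


@dataclass
class EEGEpoch:
    """One stimulus-locked 29-s trial at 256 Hz after full preprocessing."""

    data: np.ndarray
    rate: float
    channel_labels: list
    task: str
    familiarity_rating: int
    participant: str = ""
    stimulus_id: str = ""
    trial: int = 0

    @property
    def familiarity(self) -> str:
        from .pipeline import label_familiarity

        return label_familiarity(self.familiarity_rating)

    @property
    def scalp_idx(self) -> np.ndarray:
        names = set(scalp_labels(self.channel_labels))
        return np.array([i for i, ch in enumerate(self.channel_labels) if ch in names])


# ---------------------------------------------------------------- filtering

def notch_highpass(rec: EEGRecording, notch_freq: float = 50.0, notch_q: float = 35.0,
                   hp_freq: float = 1.0, hp_order: int = 5,
                   copy: bool = True) -> EEGRecording:
    """Zero-phase 2nd-order IIR notch (50 Hz) and 5th-order Butterworth
    high-pass (1 Hz), applied to every channel including EOG."""
    if rec.rate <= 2 * notch_freq:
        raise AliasingError(f"rate {rec.rate} Hz cannot represent a {notch_freq} Hz notch")
    b, a = signal.iirnotch(notch_freq, notch_q, fs=rec.rate)
    sos_hp = signal.butter(hp_order, hp_freq, btype="highpass", fs=rec.rate, output="sos")
    out = rec.copy() if copy else rec
    for i in range(out.data.shape[0]):
        x = signal.filtfilt(b, a, out.data[i])
        out.data[i] = signal.sosfiltfilt(sos_hp, x)
    return out


# ---------------------------------------------------------------- rejection

def reject_trials(epochs, amp_threshold: float = 150.0):
    """Drop epochs whose peak-to-peak amplitude on any scalp channel exceeds
    ``amp_threshold`` (µV).  Automated stand-in for visual artifact
    inspection.  Returns (kept, report)."""
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    kept, report = [], []
    for ep in epochs:
        ptp = np.ptp(ep.data[ep.scalp_idx], axis=1)
        worst = int(np.argmax(ptp))
        if ptp[worst] > amp_threshold:
            ch = ep.channel_labels[ep.scalp_idx[worst]]
            report.append({"participant": ep.participant, "trial": ep.trial,
                           "channel": ch, "ptp_uv": float(ptp[worst]),
                           "reason": f"peak-to-peak {ptp[worst]:.1f} µV > {amp_threshold} µV"})
        else:
            kept.append(ep)
    return kept, report


# ---------------------------------------------------------------- SOBI

def _joint_diagonalize(mats, tol=1e-7, max_sweeps=60):
    """Orthogonal joint approximate diagonalization by Givens rotations.

    ``tol`` bounds the sine of the largest rotation in the final sweep; a
    rotation below it moves no covariance entry by more than ~tol of its
    magnitude, well under the sampling error of the covariance estimates.
    """
    M = np.array(mats, dtype=float)
    k = M.shape[1]
    V = np.eye(k)
    for _ in range(max_sweeps):
        max_s = 0.0
        for p in range(k - 1):
            for q in range(p + 1, k):
                g1 = M[:, p, p] - M[:, q, q]
                g2 = M[:, p, q] + M[:, q, p]
                ton = g1 @ g1 - g2 @ g2
                toff = 2.0 * (g1 @ g2)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= tol:
                    continue
                max_s = max(max_s, abs(s))
                mp = M[:, p, :].copy()
                M[:, p, :] = c * mp + s * M[:, q, :]
                M[:, q, :] = c * M[:, q, :] - s * mp
                mp = M[:, :, p].copy()
                M[:, :, p] = c * mp + s * M[:, :, q]
                M[:, :, q] = c * M[:, :, q] - s * mp
                vp = V[:, p].copy()
                V[:, p] = c * vp + s * V[:, q]
                V[:, q] = c * V[:, q] - s * vp
        if max_s <= tol:
            break
    return V


def sobi(data, lags=None, rank_tol: float = 1e-9, tol: float = 1e-9):
    """Second-order blind identification.

    Parameters
    ----------
    data : ndarray (channels × samples) or EEGRecording
        For a recording, the non-EOG channels are decomposed.
    lags : sequence of int
        Sample lags of the covariance matrices to diagonalize
        (default 1–100).

    Returns
    -------
    mixing : ndarray (channels × sources)
    sources : ndarray (sources × samples)
        ``data ≈ mixing @ sources`` up to numerical error (exactly, when no
        rank reduction occurs).
    """
    if isinstance(data, EEGRecording):
        data = data.data[data.eeg_idx]
    X = np.asarray(data)
    if not np.issubdtype(X.dtype, np.floating):
        X = X.astype(float)
    n, N = X.shape
    if n < 2:
        raise ValueError("SOBI needs at least 2 channels")
    lags = np.arange(1, 101) if lags is None else np.asarray(lags, dtype=int)
    if N <= 10 * lags.max():
        raise ValueError("data too short for the requested lag set")

    # all covariance matrices are estimated in channel space, then whitened:
    # keeps the memory footprint at O(n²) instead of a whitened data copy
    C0 = ((X @ X.T) / N).astype(float)
    evals, evecs = linalg.eigh(C0)
    keep = evals > rank_tol * evals.max()
    if not keep.all():
        warnings.warn(f"rank-deficient covariance: reducing to {keep.sum()} of {n} dimensions")
    evals, evecs = evals[keep], evecs[:, keep]
    whitener = (evecs / np.sqrt(evals)).T        # k × n

    covs = []
    for lag in lags:
        C = (X[:, :-lag] @ X[:, lag:].T).astype(float) / (N - lag)
        Cw = whitener @ (0.5 * (C + C.T)) @ whitener.T
        covs.append(Cw)
    V = _joint_diagonalize(covs, tol=tol)

    unmixing = V.T @ whitener                    # k × n
    sources = unmixing.astype(X.dtype) @ X
    mixing = (evecs * np.sqrt(evals)) @ V        # pinv of unmixing
    return mixing, sources


def remove_ocular(rec: EEGRecording, mixing, sources, eog_corr_threshold: float = 0.3,
                  copy: bool = True):
    """Zero sources whose |Pearson r| with either EOG channel exceeds the
    threshold and back-project; EOG channels are left untouched.

    Returns (cleaned recording, report) where the report lists removed
    component indices with their EOG correlations.
    """
    eog_idx = rec.eog_idx
    if eog_idx.size == 0:
        raise MissingChannelError("EOG")
    eog = rec.data[eog_idx].astype(float)
    S = sources - sources.mean(axis=1, keepdims=True)
    E = eog - eog.mean(axis=1, keepdims=True)
    s_sd = S.std(axis=1)
    e_sd = E.std(axis=1)
    corr = (S @ E.T) / np.outer(np.maximum(s_sd, 1e-30), np.maximum(e_sd, 1e-30)) / S.shape[1]
    worst = np.abs(corr).max(axis=1)
    bad = np.flatnonzero(worst >= eog_corr_threshold)
    report = [{"component": int(i), "max_abs_eog_corr": float(worst[i])} for i in bad]
    if bad.size == 0:
        return rec, report
    out = rec.copy() if copy else rec
    keep = np.setdiff1d(np.arange(sources.shape[0]), bad)
    out.data[rec.eeg_idx] = (mixing[:, keep].astype(sources.dtype)
                             @ sources[keep]).astype(out.data.dtype)
    return out, report


# ---------------------------------------------------------------- reference

def rereference_mastoids(rec: EEGRecording, copy: bool = True) -> EEGRecording:
    """Re-reference every non-EOG channel to the mastoid average (M1+M2)/2."""
    if rec.reference != "amplifier-average":
        raise ValueError(f"recording already referenced to {rec.reference!r}")
    m = (0.5 * (rec.data[rec.idx("M1")] + rec.data[rec.idx("M2")])).astype(rec.data.dtype)
    out = rec.copy() if copy else rec
    out.data[rec.eeg_idx] -= m
    out.reference = "mastoid-average"
    return out


# ---------------------------------------------------------------- resampling

def resample_band(rec: EEGRecording, lp_freq: float = 100.0, lp_order: int = 5,
                  band=(1.0, 40.0), band_order: int = 5,
                  copy: bool = True) -> EEGRecording:
    """Zero-phase 100 Hz low-pass → decimate to 256 Hz → zero-phase 5th-order
    Butterworth 1–40 Hz band-pass.  Event onsets are rescaled exactly when
    the decimation ratio is an integer."""
    rate = rec.rate
    out = rec.copy() if copy else rec
    if rate > 2 * lp_freq:
        sos_lp = signal.butter(lp_order, lp_freq, btype="lowpass", fs=rate, output="sos")
        for i in range(out.data.shape[0]):
            out.data[i] = signal.sosfiltfilt(sos_lp, out.data[i])
    if rate != ANALYSIS_RATE:
        frac = Fraction(int(ANALYSIS_RATE), int(round(rate)))
        if int(round(rate)) % int(ANALYSIS_RATE):
            warnings.warn(f"non-integer decimation ratio {rate}->{ANALYSIS_RATE}; "
                          "using rational polyphase resampling")
        data = np.stack([signal.resample_poly(out.data[i].astype(float),
                                              frac.numerator, frac.denominator)
                         for i in range(out.data.shape[0])])
        events = [Event(int(round(e.onset * frac)), dict(e.info)) for e in out.events]
    else:
        data, events = out.data.astype(float), out.events
    sos_bp = signal.butter(band_order, band, btype="bandpass", fs=ANALYSIS_RATE, output="sos")
    for i in range(data.shape[0]):
        data[i] = signal.sosfiltfilt(sos_bp, data[i])
    return EEGRecording(data=data, rate=ANALYSIS_RATE, channel_labels=list(out.channel_labels),
                        events=events, reference=out.reference, participant=out.participant)


# ---------------------------------------------------------------- epoching

def epoch_trials(rec: EEGRecording, metadata=None):
    """Cut one 29-s epoch per event, spanning [onset + 1 s, onset + 30 s).

    ``metadata`` is an optional DataFrame with one row per event (columns
    task, stimulus_id, familiarity_rating, trial); if omitted, each event's
    ``info`` dict supplies them.
    """
    if rec.rate != ANALYSIS_RATE:
        raise ValueError(f"epoching expects {ANALYSIS_RATE} Hz, got {rec.rate}")
    start_off = int(EPOCH_START_S * rec.rate)
    n_len = int(EPOCH_LEN_S * rec.rate)
    epochs = []
    for k, ev in enumerate(rec.events):
        info = dict(ev.info)
        if metadata is not None:
            info.update(metadata.iloc[k].to_dict())
        a = ev.onset + start_off
        if a + n_len > rec.data.shape[1]:
            warnings.warn(f"event at sample {ev.onset} too close to recording end; skipped")
            continue
        epochs.append(EEGEpoch(
            data=np.array(rec.data[:, a:a + n_len], dtype=float),
            rate=rec.rate, channel_labels=list(rec.channel_labels),
            task=str(info["task"]), familiarity_rating=int(info["familiarity_rating"]),
            participant=str(info.get("participant", rec.participant)),
            stimulus_id=str(info.get("stimulus_id", "")), trial=int(info.get("trial", k))))
    return epochs


# ---------------------------------------------------------------- chain

def preprocess_recording(rec: EEGRecording, metadata=None, amp_threshold: float = 150.0,
                         sobi_lags=None, eog_corr_threshold: float = 0.3,
                         run_sobi: bool = True, in_place: bool = False):
    """Full chain on one recording; returns (epochs, report dict).

    With ``in_place=True`` the input recording's buffer is reused across
    stages (it is consumed); use it for long high-rate recordings.
    """
    rec = notch_highpass(rec, copy=not in_place)
    report = {}
    if run_sobi:
        mixing, sources = sobi(rec, lags=sobi_lags)
        rec, report["ocular"] = remove_ocular(rec, mixing, sources, eog_corr_threshold,
                                              copy=not in_place)
        del sources
    rec = rereference_mastoids(rec, copy=not in_place)
    rec = resample_band(rec, copy=not in_place)
    epochs = epoch_trials(rec, metadata)
    epochs, report["rejected"] = reject_trials(epochs, amp_threshold)
    return epochs, report
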