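"""Mismatch-pairing surrogate null and peak significance tests.

The null distribution is built by cross-correlating EEG trials with envelopes
of *other* stimuli: a pairing never uses the envelope that belongs to its own
EEG trial.  This destroys stimulus-specific locking while preserving the
marginal statistics of both signals (including the shared 2.5 Hz periodicity
of same-tempo stimuli), so the surrogate spread is an honest null for the
question "is this EEG locked to *this* stimulus".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .xcorr import (LAG_GRID, MAX_LAG, CrossCorrelogram, _fft_xcorr, _zscore,
                    overlap_counts)


class ImpossiblePairingError(ValueError):
    pass


@dataclass
class SurrogateEnsemble:
    """Channel-averaged surrogate correlogram curves with their pairing log."""

    curves: np.ndarray               # n_surrogates × lags
    lags: np.ndarray
    seed: int
    pairing_log: list                # [(epoch trial id, envelope stimulus id), ...]

    @property
    def n_surrogates(self) -> int:
        return self.curves.shape[0]

    def values_at(self, lag_index: int) -> np.ndarray:
        return self.curves[:, lag_index]


def _mean_zscored_scalp(epoch) -> np.ndarray:
    """Mean over scalp channels of the per-channel z-scored epoch.

    Correlating the envelope with this single signal equals averaging the
    per-channel normalized correlograms over channels (both are linear).
    """
    return _zscore(np.asarray(epoch.data[epoch.scalp_idx], dtype=float)).mean(axis=0)


def build_surrogates(epochs, envelopes: dict, n: int = 7500, seed: int = 0) -> SurrogateEnsemble:
    """Draw ``n`` (random epoch, random non-matching envelope) pairings and
    store each pair's channel-averaged correlogram.

    ``envelopes`` maps stimulus_id to the *trimmed, conditioned* envelope
    (256 Hz, same window as the epochs).
    """
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    epochs = list(epochs)
    sids = sorted(envelopes)
    if len(sids) < 2:
        raise ImpossiblePairingError("need at least 2 distinct stimulus ids")
    n_samp = epochs[0].data.shape[1]
    env_z = {sid: _zscore(np.asarray(envelopes[sid].samples, dtype=float)) for sid in sids}
    for sid, z in env_z.items():
        if len(z) != n_samp:
            raise ValueError(f"envelope {sid} length {len(z)} != epoch length {n_samp}")
    counts = overlap_counts(n_samp)
    epoch_means = [_mean_zscored_scalp(ep) for ep in epochs]

    rng = np.random.default_rng(seed)
    curves = np.empty((n, 2 * MAX_LAG + 1))
    log = []
    for k in range(n):
        i = int(rng.integers(len(epochs)))
        own = epochs[i].stimulus_id
        others = [s for s in sids if s != own]
        if not others:
            raise ImpossiblePairingError(f"no alternative stimulus for trial {i}")
        sid = others[int(rng.integers(len(others)))]
        curves[k] = _fft_xcorr(epoch_means[i], env_z[sid]) / counts
        log.append((epochs[i].trial, sid))
    return SurrogateEnsemble(curves=curves, lags=LAG_GRID.copy(), seed=seed, pairing_log=log)


def lagwise_pvalues(real_grand: CrossCorrelogram, ens: SurrogateEnsemble) -> np.ndarray:
    """Two-sided empirical p at each lag with the add-one correction:
    p = (1 + #{|surrogate| ≥ |real|}) / (n + 1)."""
    if not np.array_equal(real_grand.lags, ens.lags):
        raise ValueError("lag grids differ between real and surrogate curves")
    real = np.abs(real_grand.channel_averaged)
    exceed = (np.abs(ens.curves) >= real[None, :]).sum(axis=0)
    n = ens.n_surrogates
    if n < 99:
        warnings.warn(f"only {n} surrogates: minimum attainable p is {1 / (n + 1):.3g}")
    return (1.0 + exceed) / (n + 1.0)


def peak_pvalue(real_value: float, surrogate_values) -> float:
    """Two-sided empirical p of one observed peak value against the
    surrogate values at the same lag."""
    s = np.abs(np.asarray(surrogate_values, dtype=float))
    return float((1.0 + (s >= abs(real_value)).sum()) / (len(s) + 1.0))


def peak_ttest(trial_values, surrogate_values):
    """Welch two-sample t-test of real trial-level peak values against the
    surrogate values at the same lag.  Returns (t, df, p)."""
    from scipy import stats

    a = np.asarray(trial_values, dtype=float)
    b = np.asarray(surrogate_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
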