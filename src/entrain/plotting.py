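"""Optional figures: correlogram curves and peak-value scalp maps."""

from __future__ import annotations

import numpy as np


def plot_correlogram(grand, peaks=None, ax=None, label=None):
    """Channel-averaged cross-correlation curve with optional peak markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    curve = grand.channel_averaged
    ax.plot(grand.lags * 1000.0, curve, lw=1.2, label=label)
    if peaks is not None:
        for lag in (peaks.pos_lag, peaks.neg_lag):
            ax.axvline(lag * 1000.0, color="0.4", ls="--", lw=0.8)
    ax.axhline(0.0, color="0.7", lw=0.6)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("cross-correlation")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_peak_topography(peaks, which: str = "pos", ax=None):
    """Scalp map of the per-channel correlation values at a peak lag.

    Channel positions come from MNE's standard 10-05 montage; channels
    without a position (EOG) are skipped.
    """
    import matplotlib.pyplot as plt
    import mne

    values = peaks.pos_topography if which == "pos" else peaks.neg_topography
    montage = mne.channels.make_standard_montage("standard_1005")
    pos_map = montage.get_positions()["ch_pos"]
    xy, v = [], []
    for ch, val in zip(peaks.channel_labels, values):
        p = pos_map.get(ch)
        if p is not None:
            xy.append(p[:2])
            v.append(val)
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    mne.viz.plot_topomap(np.asarray(v), np.asarray(xy), axes=ax, show=False)
    lag = peaks.pos_lag if which == "pos" else peaks.neg_lag
    ax.set_title(f"{'positive' if which == 'pos' else 'negative'} peak "
                 f"@ {lag * 1000:.1f} ms", fontsize=9)
    return ax
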