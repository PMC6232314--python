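"""Generator contracts: envelope periodicity, kernel quantization,
determinism, and the on-disk dataset."""

import numpy as np
import pytest

from entrain import synth
from entrain.envelope import condition_envelope, dominant_frequency, envelope_spectrum
from entrain.synth import InvalidConfigError, SynthConfig


def _dominant_raw(cfg, seed=0):
    """Dominant non-DC frequency of the raw (unfiltered) envelope."""
    from scipy import signal as sig

    env = synth.make_envelope(cfg, seed=seed, rate=2048.0)
    f, p = sig.welch(env.samples - env.samples.mean(), fs=2048.0, nperseg=8192)
    from entrain.envelope import dominant_frequency as dom

    return dom(f, p)


class TestEnvelope:
    def test_tempo_sets_dominant_frequency(self):
        # quarter-note frequency = tempo / 60, by construction of the pulse grid
        assert _dominant_raw(SynthConfig(tempo=150.0)) == pytest.approx(2.5, abs=0.25)
        assert _dominant_raw(SynthConfig(tempo=60.0, eighth_note_prob=0.0)) == \
            pytest.approx(1.0, abs=0.25)

    def test_envelope_nonnegative_and_deterministic(self):
        cfg = SynthConfig()
        a = synth.make_envelope(cfg, seed=5, rate=2048.0)
        b = synth.make_envelope(cfg, seed=5, rate=2048.0)
        assert np.array_equal(a.samples, b.samples)
        assert a.samples.min() >= 0.0
        c = synth.make_envelope(cfg, seed=6, rate=2048.0)
        assert not np.array_equal(a.samples, c.samples)

    def test_rate_consistent_note_pattern(self):
        # same seed at different rates: same notes, same onsets in seconds
        cfg = SynthConfig()
        lo = synth.make_envelope(cfg, seed=3, rate=512.0)
        hi = synth.make_envelope(cfg, seed=3, rate=2048.0)
        assert np.corrcoef(lo.samples, hi.samples[::4])[0, 1] > 0.99

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(tempo=-1.0)
        with pytest.raises(InvalidConfigError):
            SynthConfig(trial_duration=0.0)


class TestKernel:
    def test_extrema_on_the_256hz_grid(self):
        k = synth.make_kernel(SynthConfig(), rate=256.0)
        # 0.130 s quantizes to sample 33 (128.9 ms); 0.260 s falls between
        # samples 66 and 67, whichever the lobe shape makes lower
        assert np.argmax(k.taps) == 33
        assert np.argmin(k.taps) in (66, 67)

    def test_decays_before_lag_window_end(self):
        k = synth.make_kernel(SynthConfig(), rate=256.0)
        assert np.abs(k.taps[-8:]).max() < 0.01 * np.abs(k.taps).max()

    def test_coincident_lobes_rejected(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(kernel_pos_lag=0.2, kernel_neg_lag=0.2)
        cfg = SynthConfig()
        cfg.kernel_neg_lag = 0.7    # bypass __post_init__ to hit the op's check
        with pytest.raises(InvalidConfigError):
            synth.make_kernel(cfg)


@pytest.fixture(scope="module")
def tiny_cfg():
    return SynthConfig(n_scalp=16, eeg_rate=512.0, trial_duration=10.0,
                       n_trials_per_task=2, n_stimuli=4)


class TestTrial:
    def test_trial_deterministic(self, tiny_cfg):
        env = synth.make_envelope(tiny_cfg, seed=1, rate=512.0)
        kern = synth.make_kernel(tiny_cfg, rate=512.0)
        topo = np.ones(16)
        labels = {"task": "control", "familiarity_rating": 4}
        a = synth.make_trial(env, kern, topo, tiny_cfg, labels, seed=9)
        b = synth.make_trial(env, kern, topo, tiny_cfg, labels, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_topography_shape_checked(self, tiny_cfg):
        env = synth.make_envelope(tiny_cfg, seed=1, rate=512.0)
        kern = synth.make_kernel(tiny_cfg, rate=512.0)
        with pytest.raises(ValueError, match="topography"):
            synth.make_trial(env, kern, np.ones(5), tiny_cfg,
                             {"task": "control", "familiarity_rating": 4}, seed=0)

    def test_zero_gain_removes_envelope_locking(self, tiny_cfg):
        import dataclasses

        from entrain import xcorr
        from entrain.preprocess import EEGEpoch

        cfg = dataclasses.replace(tiny_cfg, gain_familiar=0.0, gain_unfamiliar=0.0,
                                  trial_duration=34.0)
        env = synth.make_envelope(cfg, seed=2, rate=512.0)
        kern = synth.make_kernel(cfg, rate=512.0)
        topo = np.ones(16)
        curves = []
        cenv = xcorr.trim_envelope(condition_envelope(env))
        for s in range(8):
            tr = synth.make_trial(env, kern, topo, cfg,
                                  {"task": "control", "familiarity_rating": 4}, seed=s)
            from entrain.preprocess import resample_band, epoch_trials
            rec = resample_band(tr)
            a = int(2.0 * 256)  # onset at 1 s + 1 s epoch guard
            ep = EEGEpoch(data=rec.data[:, a:a + 7424], rate=256.0,
                          channel_labels=rec.channel_labels, task="control",
                          familiarity_rating=4, participant="p", trial=s)
            curves.append(xcorr.crosscorr(cenv, ep).channel_averaged)
        mean_curve = np.mean(curves, axis=0)
        # no envelope-locked component: grand curve stays at noise level
        assert np.abs(mean_curve).max() < 0.06

    def test_higher_gain_raises_peak(self, tiny_cfg):
        import dataclasses

        from entrain import xcorr
        from entrain.preprocess import EEGEpoch, resample_band

        def peak(gain):
            cfg = dataclasses.replace(tiny_cfg, gain_familiar=gain,
                                      trial_duration=34.0, seed=77)
            env = synth.make_envelope(cfg, seed=2, rate=512.0)
            kern = synth.make_kernel(cfg, rate=512.0)
            cenv = xcorr.trim_envelope(condition_envelope(env))
            tr = synth.make_trial(env, kern, np.ones(16), cfg,
                                  {"task": "control", "familiarity_rating": 4}, seed=5)
            rec = resample_band(tr)
            a = int(2.0 * 256)
            ep = EEGEpoch(data=rec.data[:, a:a + 7424], rate=256.0,
                          channel_labels=rec.channel_labels, task="control",
                          familiarity_rating=4)
            return xcorr.crosscorr(cenv, ep).channel_averaged.max()

        assert peak(2.0) > peak(1.0) > peak(0.25)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    cfg = SynthConfig(n_participants=2, n_trials_per_task=2, n_stimuli=4,
                      n_scalp=16, eeg_rate=256.0, trial_duration=34.0, seed=3)
    out = tmp_path_factory.mktemp("ds")
    manifest = synth.make_dataset(cfg, out)
    return cfg, manifest


class TestDataset:
    def test_file_counts(self, dataset):
        cfg, manifest = dataset
        assert len(manifest["edf"]) == cfg.n_participants
        assert len(manifest["wav"]) == cfg.n_stimuli

    def test_events_per_participant(self, dataset):
        import mne

        cfg, manifest = dataset
        raw = mne.io.read_raw_edf(manifest["edf"][0], preload=False, verbose="error")
        assert len(raw.annotations) == 3 * cfg.n_trials_per_task

    def test_edf_round_trip(self, dataset):
        """Our EDF writer read back through MNE reproduces the signals
        within 16-bit quantization."""
        import mne

        cfg, manifest = dataset
        envs = synth.make_stimulus_envelopes(cfg, rate=cfg.eeg_rate)
        rec, _ = synth.make_participant(cfg, 0, envelopes=envs)
        raw = mne.io.read_raw_edf(manifest["edf"][0], preload=True, verbose="error")
        got = raw.get_data() * 1e6
        assert list(raw.ch_names) == rec.channel_labels
        span = np.ptp(rec.data, axis=1)
        err = np.abs(got - rec.data).max(axis=1)
        assert np.all(err <= span / 65535 + 1e-9)
        onsets = raw.annotations.onset
        expected = [ev.onset / cfg.eeg_rate for ev in rec.events]
        assert np.allclose(onsets, expected)

    def test_metadata_labels_match_gains(self, dataset):
        import pandas as pd

        from entrain.pipeline import label_familiarity

        _, manifest = dataset
        meta = pd.read_csv(manifest["meta"], sep="\t")
        assert set(meta.familiarity_rating) <= {1, 2, 3, 4}
        labels = meta.familiarity_rating.map(label_familiarity)
        assert set(labels) == {"familiar", "unfamiliar"}
        # familiarity is a property of (participant, stimulus)
        per_stim = meta.groupby(["participant", "stimulus_id"])["familiarity_rating"] \
            .apply(lambda r: len({label_familiarity(x) for x in r}))
        assert (per_stim == 1).all()

    def test_dataset_deterministic(self, dataset, tmp_path):
        cfg, manifest = dataset
        manifest2 = synth.make_dataset(cfg, tmp_path)
        a = open(manifest["edf"][0], "rb").read()
        b = open(manifest2["edf"][0], "rb").read()
        assert a == b
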