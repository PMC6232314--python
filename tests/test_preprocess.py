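"""Preprocessing chain: filters, SOBI, ocular cleaning, re-referencing,
rate conversion and epoching."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from entrain.montage import montage_labels
from entrain.preprocess import (AliasingError, EEGEpoch, EEGRecording, Event,
                                MissingChannelError, epoch_trials, notch_highpass,
                                reject_trials, remove_ocular, rereference_mastoids,
                                resample_band, sobi)

LABELS16 = montage_labels(12)          # 12 scalp + M1 M2 EOG1 EOG2


def make_rec(data, rate=2048.0, labels=None, events=()):
    labels = labels if labels is not None else LABELS16[:data.shape[0]]
    return EEGRecording(data=np.asarray(data, dtype=float), rate=rate,
                        channel_labels=list(labels),
                        events=[Event(o, dict(i)) for o, i in events])


def sine(freq, seconds, rate, phase=0.0):
    t = np.arange(int(seconds * rate)) / rate
    return np.sin(2 * np.pi * freq * t + phase)


class TestNotchHighpass:
    def test_notch_kills_line_frequency(self):
        x = sine(50.0, 8.0, 2048.0)
        rec = make_rec(np.tile(x, (4, 1)))
        out = notch_highpass(rec)
        mid = out.data[0, 2048:-2048]
        assert np.sqrt((mid ** 2).mean()) <= 0.01 * np.sqrt((x ** 2).mean())

    def test_dc_removed(self):
        rec = make_rec(np.full((4, 8192), 7.3))
        out = notch_highpass(rec)
        assert np.abs(out.data).max() < 1e-6

    def test_passband_amplitude_and_phase(self):
        x = sine(10.0, 8.0, 2048.0)
        rec = make_rec(np.tile(x, (4, 1)))
        y = notch_highpass(rec).data[0]
        mid = slice(2048, -2048)
        gain = np.sqrt((y[mid] ** 2).mean() / (x[mid] ** 2).mean())
        assert gain == pytest.approx(1.0, abs=0.05)
        # zero phase: cross-correlation peak at lag 0
        c = signal.correlate(y[mid], x[mid], mode="same")
        assert abs(int(np.argmax(c)) - len(c) // 2) == 0

    def test_low_rate_aliasing_rejected(self):
        rec = make_rec(np.zeros((4, 1000)), rate=80.0)
        with pytest.raises(AliasingError):
            notch_highpass(rec)


class TestRejectTrials:
    def _epoch(self, data):
        return EEGEpoch(data=data, rate=256.0, channel_labels=LABELS16,
                        task="control", familiarity_rating=4, participant="p",
                        trial=0)

    def test_transient_over_threshold_rejected(self):
        rng = np.random.default_rng(0)
        clean = 10.0 * rng.standard_normal((16, 7424))
        bad = clean.copy()
        bad[3, 1000:1100] += 500.0
        kept, report = reject_trials([self._epoch(clean), self._epoch(bad)],
                                     amp_threshold=200.0)
        assert len(kept) == 1 and len(report) == 1
        assert "peak-to-peak" in report[0]["reason"]

    def test_clean_set_untouched_and_infinite_threshold(self):
        rng = np.random.default_rng(1)
        eps = [self._epoch(5.0 * rng.standard_normal((16, 1000))) for _ in range(3)]
        kept, report = reject_trials(eps, amp_threshold=np.inf)
        assert kept == eps and report == []

    def test_empty_input_ok(self):
        kept, report = reject_trials([], amp_threshold=100.0)
        assert kept == [] and report == []


def ar_series(rng, coeff, n):
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = coeff * x[t - 1] + e[t]
    return x


class TestSobi:
    def test_recovers_ar_sources_from_random_mixing(self):
        rng = np.random.default_rng(2)
        S = np.vstack([ar_series(rng, 0.9, 20000), ar_series(rng, -0.5, 20000)])
        A = rng.standard_normal((4, 2))
        X = A @ S
        mixing, sources = sobi(X, lags=np.arange(1, 21))
        got = []
        for s_true in S:
            r = [abs(np.corrcoef(s_true, s_est)[0, 1]) for s_est in sources]
            got.append(max(r))
        assert min(got) >= 0.95

    def test_identity_mixing_recovered_up_to_permutation(self):
        rng = np.random.default_rng(3)
        S = np.vstack([ar_series(rng, c, 20000) for c in (0.8, 0.2, -0.6)])
        S /= S.std(axis=1, keepdims=True)
        mixing, sources = sobi(S, lags=np.arange(1, 21))
        # normalized |mixing| should be close to a permutation matrix
        M = np.abs(mixing) / np.abs(mixing).max(axis=0, keepdims=True)
        M[M < 0.2] = 0.0
        assert (np.count_nonzero(M > 0.8, axis=0) == 1).all()

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 5000))
        mixing, sources = sobi(X, lags=np.arange(1, 11))
        err = np.linalg.norm(X - mixing @ sources) / np.linalg.norm(X)
        assert err <= 1e-6


class TestRemoveOcular:
    def _blinky_rec(self, rng, n=20000, rate=512.0):
        n_ch = len(LABELS16)
        data = rng.standard_normal((n_ch, n))
        blink = np.zeros(n)
        for onset in range(500, n - 400, 2500):
            blink[onset:onset + 154] += np.hanning(154) ** 2
        weights = np.array([0.6, 0.5, 0.6, 0.3, 0.2, 0.2, 0.2, 0.3,
                            0.05, 0.05, 0.05, 0.05, 0.02, 0.02])
        data[:14] += 120.0 * np.outer(weights, blink)
        data[14] += 150.0 * blink        # EOG1
        data[15] += 120.0 * blink        # EOG2
        osc = np.sin(2 * np.pi * 10.0 * np.arange(n) / rate)
        data[:12] += 5.0 * osc
        return make_rec(data, rate=rate), osc

    def test_blink_removed_oscillation_kept(self):
        rng = np.random.default_rng(5)
        rec, osc = self._blinky_rec(rng)
        mixing, sources = sobi(rec, lags=np.arange(1, 31))
        out, report = remove_ocular(rec, mixing, sources, eog_corr_threshold=0.3)
        assert len(report) >= 1
        eog = out.data[rec.eog_idx]
        scalp = out.data[:12]
        c = np.corrcoef(np.vstack([scalp, eog]))[:12, 12:]
        assert np.abs(c).max() < 0.1
        # the 10 Hz test oscillation survives within 10% amplitude
        before = 5.0
        after = np.array([np.dot(ch, osc) / np.dot(osc, osc) for ch in scalp])
        assert np.all(np.abs(after - before) < 0.1 * before)

    def test_impossible_threshold_is_identity(self):
        rng = np.random.default_rng(6)
        rec, _ = self._blinky_rec(rng)
        mixing, sources = sobi(rec, lags=np.arange(1, 31))
        out, report = remove_ocular(rec, mixing, sources, eog_corr_threshold=1.01)
        assert report == []
        assert np.array_equal(out.data, rec.data)

    def test_blink_free_data_untouched(self):
        rng = np.random.default_rng(7)
        rec = make_rec(rng.standard_normal((len(LABELS16), 20000)), rate=512.0)
        mixing, sources = sobi(rec, lags=np.arange(1, 31))
        out, report = remove_ocular(rec, mixing, sources, eog_corr_threshold=0.3)
        assert report == []
        assert np.array_equal(out.data, rec.data)


class TestRereference:
    def test_zero_mastoids_leave_scalp_unchanged(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((len(LABELS16), 1000))
        data[12:14] = 0.0                # M1, M2
        rec = make_rec(data)
        out = rereference_mastoids(rec)
        assert np.allclose(out.data[:12], rec.data[:12])
        assert out.reference == "mastoid-average"

    def test_common_mode_rejected(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((len(LABELS16), 1000))
        common = rng.standard_normal(1000)
        rec_a = make_rec(base.copy())
        shifted = base.copy()
        shifted[:14] += common           # all EEG channels incl. mastoids
        rec_b = make_rec(shifted)
        a = rereference_mastoids(rec_a).data[:12]
        b = rereference_mastoids(rec_b).data[:12]
        assert np.allclose(a, b, atol=1e-10)

    def test_double_rereference_rejected(self):
        rec = make_rec(np.random.default_rng(10).standard_normal((len(LABELS16), 100)))
        out = rereference_mastoids(rec)
        with pytest.raises(ValueError, match="already referenced"):
            rereference_mastoids(out)

    def test_missing_mastoid_rejected(self):
        labels = [ch for ch in LABELS16 if ch != "M1"]
        rec = make_rec(np.zeros((len(labels), 100)), labels=labels)
        with pytest.raises(MissingChannelError):
            rereference_mastoids(rec)


class TestResampleBand:
    def test_passband_tone_preserved(self):
        x = sine(10.0, 8.0, 2048.0)
        rec = make_rec(np.tile(x, (4, 1)), events=[(2048, {})])
        out = resample_band(rec)
        assert out.rate == 256.0
        assert out.events[0].onset == 256
        mid = out.data[0, 512:-512]
        ref = sine(10.0, 8.0, 256.0)[512:-512]
        gain = np.sqrt((mid ** 2).mean() / (ref ** 2).mean())
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_attenuated(self):
        x = sine(60.0, 8.0, 2048.0)
        rec = make_rec(np.tile(x, (4, 1)))
        out = resample_band(rec)
        mid = out.data[0, 512:-512]
        atten_db = 20 * np.log10(np.sqrt((x ** 2).mean()) /
                                 max(np.sqrt((mid ** 2).mean()), 1e-12))
        assert atten_db >= 20.0


class TestEpoching:
    def _rec256(self, n_seconds, events):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((len(LABELS16), int(n_seconds * 256)))
        return make_rec(data, rate=256.0, events=events)

    def test_epoch_window_arithmetic(self):
        onset = 4 * 256
        info = {"task": "control", "familiarity_rating": 3, "stimulus_id": "s",
                "trial": 0, "participant": "p"}
        rec = self._rec256(40, [(onset, info)])
        eps = epoch_trials(rec)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.data.shape[1] == 7424          # 29 s at 256 Hz
        start = onset + 256                       # 1 s after stimulus onset
        assert np.array_equal(ep.data, rec.data[:, start:start + 7424])

    @pytest.mark.parametrize("rating,label", [(1, "unfamiliar"), (2, "unfamiliar"),
                                              (3, "familiar"), (4, "familiar")])
    def test_familiarity_rule(self, rating, label):
        info = {"task": "control", "familiarity_rating": rating}
        rec = self._rec256(40, [(256, info)])
        assert epoch_trials(rec)[0].familiarity == label

    def test_event_too_close_to_end_skipped(self):
        info = {"task": "control", "familiarity_rating": 1}
        rec = self._rec256(20, [(256, info)])
        with pytest.warns(UserWarning, match="too close"):
            eps = epoch_trials(rec)
        assert eps == []

    def test_metadata_table_joined(self):
        rec = self._rec256(40, [(0, {})])
        meta = pd.DataFrame([{"task": "visual-active", "familiarity_rating": 2,
                              "stimulus_id": "stim07", "trial": 5,
                              "participant": "s03"}])
        ep = epoch_trials(rec, meta)[0]
        assert (ep.task, ep.stimulus_id, ep.trial, ep.participant) == \
            ("visual-active", "stim07", 5, "s03")
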