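"""Shared fixtures: one moderately sized entrained synthetic study.

The session fixture runs the full generation + preprocessing + correlation
chain once at 512 Hz (instead of the recording rate of 2,048 Hz) with 30
trials and the full 62+2+2 montage, and is reused by every test that needs
realistic epochs.  Decimation to the 256 Hz analysis rate and all analysis
behavior are identical at either recording rate.
"""

from __future__ import annotations

import numpy as np
import pytest

from entrain import pipeline, synth, xcorr
from entrain.envelope import condition_envelope
from entrain.preprocess import preprocess_recording

SEED = 42


@pytest.fixture(scope="session")
def study_config():
    return synth.SynthConfig(n_participants=1, n_trials_per_task=10, n_stimuli=10,
                             eeg_rate=512.0, seed=SEED)


@pytest.fixture(scope="session")
def entrained_study(study_config):
    """dict with epochs, conditioned envelopes, trial correlograms, grand
    average and detected peaks for one fully preprocessed participant."""
    cfg = study_config
    envs = synth.make_stimulus_envelopes(cfg, rate=cfg.eeg_rate)
    rec, table = synth.make_participant(cfg, 0, envelopes=envs)
    epochs, report = preprocess_recording(rec, metadata=table,
                                          sobi_lags=np.arange(1, 26), in_place=True)
    cenvs = {sid: xcorr.trim_envelope(condition_envelope(e))
             for sid, e in envs.items()}
    correlograms = pipeline.correlogram_stage(epochs, cenvs)
    grand = xcorr.grand_average(correlograms)
    return {"config": cfg, "epochs": epochs, "envelopes": cenvs,
            "correlograms": correlograms, "grand": grand,
            "peaks": xcorr.detect_peaks(grand), "report": report}
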