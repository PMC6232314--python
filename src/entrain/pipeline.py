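"""Orchestration: configuration, standard-format I/O, and the one-command
reproduction of the full synthetic study.

``run_full`` executes every stage in order — synthesis (optional) → envelope
extraction → EEG preprocessing → cross-correlation per task × familiarity
cell → surrogate statistics → attention classification → repeated-measures
ANOVA — and writes every table as CSV with a JSON config echo, so any stage
can be audited or re-run from the previous stage's outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attnclf, rmstats, surrogate as surrogate_mod, synth, xcorr
from .envelope import AudioStimulus, EnvelopeSignal, condition_envelope, extract_envelope
from .preprocess import EEGRecording, Event, preprocess_recording

log = logging.getLogger("entrain")

RATINGS = {1: "not at all familiar", 2: "slightly familiar",
           3: "moderately familiar", 4: "very familiar"}


def label_familiarity(rating: int) -> str:
    """Binary familiarity label from the 4-point rating: {3, 4} → familiar,
    {1, 2} → unfamiliar."""
    r = int(rating)
    if r not in RATINGS:
        raise ValueError(f"familiarity rating must be 1–4, got {rating}")
    return "familiar" if r >= 3 else "unfamiliar"


@dataclass
class RunConfig:
    """Every stage's parameters, with the study's stated values as defaults
    (7,500 surrogates, 5,000 shuffle runs, 256 Hz analysis rate, 1–40 Hz
    band, ±0.6 s lag window).  ``scale='small'`` switches to desk-scale
    surrogate/shuffle counts and cohort size."""

    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    amp_threshold: float = 150.0           # µV, trial rejection
    sobi_lags: list | None = None          # default 1–100 samples
    run_sobi: bool = True
    eog_corr_threshold: float = 0.3
    n_surrogates: int = 7500
    n_shuffle_runs: int = 5000
    cv_folds: int = 5
    seed: int = 0
    scale: str = "full"

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "RunConfig":
        kw = dict(
            synth=synth.SynthConfig(n_participants=6, n_trials_per_task=10, seed=seed),
            n_surrogates=500, n_shuffle_runs=200, seed=seed, scale="small")
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def full(cls, seed: int = 0, **overrides) -> "RunConfig":
        kw = dict(synth=synth.full_scale(seed=seed), seed=seed, scale="full")
        kw.update(overrides)
        return cls(**kw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "synth" in d:
            d["synth"] = synth.SynthConfig(**d["synth"])
        return cls(**d)


@dataclass
class ResultsBundle:
    grand: xcorr.CrossCorrelogram
    cell_grands: dict
    peaks: xcorr.PeakResult
    peak_table: pd.DataFrame
    surrogates: surrogate_mod.SurrogateEnsemble
    lag_pvalues: np.ndarray
    peak_tests: dict                 # {"positive"/"negative": {...}}
    accuracy_table: pd.DataFrame
    shuffled_quartiles: dict
    anova: dict                      # {"positive"/"negative": RMAnovaResults}
    config: RunConfig
    reports: dict


# ------------------------------------------------------------------ I/O

def read_eeg(path) -> EEGRecording:
    """Load an EDF(+) recording through MNE; channels in µV, events parsed
    from the annotation channel."""
    import mne

    from .edf import validate_edf

    validate_edf(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6          # Volts → µV
    labels = list(raw.ch_names)
    known = set(synth.SynthConfig().channel_labels)
    for ch in labels:
        if ch not in known:
            log.warning("unknown channel label %r: kept but excluded from scalp set", ch)
    events = []
    for onset, _dur, _desc in zip(raw.annotations.onset, raw.annotations.duration,
                                  raw.annotations.description):
        events.append(Event(int(round(onset * raw.info["sfreq"])), {}))
    if not events:
        raise ValueError(f"{path}: no stimulus annotations found")
    return EEGRecording(data=data, rate=float(raw.info["sfreq"]), channel_labels=labels,
                        events=events, reference="amplifier-average",
                        participant=Path(path).stem)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """RFC-4180 CSV with '#'-prefixed header metadata lines."""
    with open(path, "w", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


# ------------------------------------------------------------------ stages

def conditioned_stimulus_envelopes(config: RunConfig, from_wavs: dict | None = None) -> dict:
    """Analysis-ready (256 Hz, 1–40 Hz, trimmed to the epoch window)
    envelope per stimulus id.

    ``from_wavs`` maps stimulus id → WAV path; if omitted, the generator's
    ground-truth envelopes are conditioned directly.
    """
    envs = {}
    if from_wavs is not None:
        for sid, path in from_wavs.items():
            env = extract_envelope(AudioStimulus.from_wav(path, stimulus_id=sid))
            envs[sid] = xcorr.trim_envelope(env)
    else:
        for sid, env in synth.make_stimulus_envelopes(
                config.synth, rate=config.synth.eeg_rate).items():
            envs[sid] = xcorr.trim_envelope(condition_envelope(env))
    return envs


def preprocess_participant(config: RunConfig, rec: EEGRecording,
                           table: pd.DataFrame):
    return preprocess_recording(
        rec, metadata=table, amp_threshold=config.amp_threshold,
        sobi_lags=config.sobi_lags, eog_corr_threshold=config.eog_corr_threshold,
        run_sobi=config.run_sobi)


def correlogram_stage(epochs, envelopes):
    """Trial-level correlograms (each epoch against its own envelope)."""
    return [xcorr.crosscorr(envelopes[ep.stimulus_id], ep) for ep in epochs]


def classifier_stage(config: RunConfig, epochs_by_participant: dict) -> tuple:
    rows, quartiles = [], {}
    for k, (pid, epochs) in enumerate(sorted(epochs_by_participant.items())):
        segments, labels, _ = attnclf.epoch_4s(epochs)
        if len(set(labels)) < 2:
            log.warning("participant %s lacks both attention conditions; skipped", pid)
            continue
        mean, sd = attnclf.crossval_accuracy(segments, labels, k=config.cv_folds,
                                             seed=config.seed * 100 + k)
        rows.append({"participant": pid, "accuracy_mean": mean, "accuracy_sd": sd})
        _, q = attnclf.shuffled_baseline(segments, n_runs=config.n_shuffle_runs,
                                         seed=config.seed * 100 + k, k=config.cv_folds)
        quartiles[pid] = q
    return pd.DataFrame(rows), quartiles


def anova_stage(peak_table: pd.DataFrame) -> dict:
    out = {}
    for name, col in (("positive", "pos_value"), ("negative", "neg_value")):
        design, dropped = rmstats.build_design(peak_table, value=col)
        for d in dropped:
            log.warning("ANOVA (%s): participant %s dropped, missing %s",
                        name, d["participant"], d["missing_cells"])
        out[name] = rmstats.rm_anova_2way(design)
    return out


# ------------------------------------------------------------------ full run

def run_full(config: RunConfig, out_dir, synthetic: bool = True,
             write_outputs: bool = True) -> ResultsBundle:
    """Execute the whole analysis on a synthetic study and emit all tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not synthetic:
        raise NotImplementedError("only the synthetic study is bundled; point the "
                                  "stage functions at your own EDF/WAV data instead")

    log.info("stage synthgen: writing dataset")
    manifest = synth.make_dataset(config.synth, out / "dataset")
    meta = pd.read_csv(manifest["meta"], sep="\t")

    log.info("stage envelope: extracting %d stimulus envelopes", len(manifest["wav"]))
    wavs = {Path(p).stem: p for p in manifest["wav"]}
    envelopes = conditioned_stimulus_envelopes(config, from_wavs=wavs)

    all_epochs, reports = [], {}
    for path in manifest["edf"]:
        pid = Path(path).stem
        log.info("stage preprocess: %s", pid)
        rec = read_eeg(path)
        table = meta[meta.participant == pid].reset_index(drop=True)
        if len(table) != len(rec.events):
            raise ValueError(f"{path}: {len(rec.events)} events but {len(table)} metadata rows")
        epochs, rep = preprocess_participant(config, rec, table)
        reports[pid] = rep
        all_epochs.extend(epochs)
    if not all_epochs:
        raise ValueError("no epochs survived preprocessing")

    log.info("stage xcorr: %d trials", len(all_epochs))
    correlograms = correlogram_stage(all_epochs, envelopes)
    grand = xcorr.grand_average(correlograms)
    cell_grands = xcorr.grand_average(correlograms, by="cell")
    peaks = xcorr.detect_peaks(grand)
    peak_table = xcorr.peak_values_per_trial(correlograms, peaks)

    log.info("stage surrogate: %d pairings", config.n_surrogates)
    ens = surrogate_mod.build_surrogates(all_epochs, envelopes,
                                         n=config.n_surrogates, seed=config.seed + 1)
    lag_p = surrogate_mod.lagwise_pvalues(grand, ens)
    peak_tests = {}
    for name, idx, col in (("positive", peaks.pos_index, "pos_value"),
                           ("negative", peaks.neg_index, "neg_value")):
        sv = ens.values_at(idx)
        t, df, p = surrogate_mod.peak_ttest(peak_table[col].to_numpy(), sv)
        peak_tests[name] = {"t": t, "df": df, "p_ttest": p,
                            "p_empirical": float(lag_p[idx])}

    log.info("stage attnclf")
    by_part = {}
    for ep in all_epochs:
        by_part.setdefault(ep.participant, []).append(ep)
    acc_table, quartiles = classifier_stage(config, by_part)

    log.info("stage rmstats")
    anova = anova_stage(peak_table)

    bundle = ResultsBundle(grand=grand, cell_grands=cell_grands, peaks=peaks,
                           peak_table=peak_table, surrogates=ens, lag_pvalues=lag_p,
                           peak_tests=peak_tests, accuracy_table=acc_table,
                           shuffled_quartiles=quartiles, anova=anova, config=config,
                           reports=reports)
    if write_outputs:
        _write_bundle(bundle, out)
    return bundle


def _write_bundle(b: ResultsBundle, out: Path) -> None:
    meta = {"seed": b.config.seed, "scale": b.config.scale}
    write_table(b.grand.to_frame(), out / "grand_correlogram.csv", meta)
    for (task, fam), cg in b.cell_grands.items():
        write_table(cg.to_frame(), out / f"correlogram_{task}_{fam}.csv", meta)
    write_table(b.peak_table, out / "peak_values.csv", meta)
    write_table(pd.DataFrame({"lag_ms": b.grand.lags * 1000.0, "p": b.lag_pvalues}),
                out / "lag_pvalues.csv", meta)
    topo = pd.DataFrame({"channel": b.peaks.channel_labels,
                         "pos_peak": b.peaks.pos_topography,
                         "neg_peak": b.peaks.neg_topography})
    write_table(topo, out / "peak_topographies.csv",
                {**meta, "pos_lag_ms": round(b.peaks.pos_lag * 1000, 1),
                 "neg_lag_ms": round(b.peaks.neg_lag * 1000, 1)})
    write_table(b.accuracy_table, out / "classification_accuracy.csv", meta)
    rows = [{"participant": p, "q25": q[0], "median": q[1], "q75": q[2]}
            for p, q in b.shuffled_quartiles.items()]
    write_table(pd.DataFrame(rows), out / "shuffled_baseline.csv", meta)
    for name, res in b.anova.items():
        write_table(res.table, out / f"anova_{name}_peak.csv",
                    {**meta, "ss_subjects": res.ss_subjects, "ss_total": res.ss_total})
    summary = {
        "pos_lag_ms": round(b.peaks.pos_lag * 1000, 1),
        "neg_lag_ms": round(b.peaks.neg_lag * 1000, 1),
        "pos_value": b.peaks.pos_value, "neg_value": b.peaks.neg_value,
        "peak_tests": b.peak_tests,
        "anova_p_gg": {name: dict(zip(res.table.effect, res.table.p_gg))
                       for name, res in b.anova.items()},
        "config": json.loads(b.config.to_json())}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
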