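"""Minimal EDF+C writer.

Writes multi-channel recordings as 16-bit European Data Format with an
``EDF Annotations`` channel carrying stimulus-onset markers as time-stamped
annotation lists (TALs).  The header timestamp is fixed so that identical
input produces byte-identical files.  Reading is delegated to MNE
(:func:`mne.io.read_raw_edf`), which doubles as an independent check of this
writer in the test suite.
"""

from __future__ import annotations

import numpy as np

_ANN_SAMPLES = 60  # 120 bytes of annotation payload per 1-s record


def _field(value, width) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, data, rate, labels, events=(), patient_id="X", recording_id="synthetic"):
    """Write ``data`` (channels x samples, µV) as an EDF+C file.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Physical values in µV.  ``n_samples`` must be a whole number of
        seconds at ``rate``.
    rate : float
        Sampling rate in Hz; must be an integer (samples per 1-s record).
    events : sequence of (onset_s, duration_s, text)
        Stimulus markers written as EDF+ annotations.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(round(rate))
    if abs(rate - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n_samp % spr:
        raise ValueError("recording length must be a whole number of seconds")
    n_rec = n_samp // spr
    if len(labels) != n_ch:
        raise ValueError("labels/data channel count mismatch")

    # physical scaling per channel (16-bit digital range)
    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.0001
    phys_min = -phys_max
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data - phys_min[:, None]) * scale[:, None] + dig_min),
                      dig_min, dig_max).astype("<i2")

    n_sig = n_ch + 1  # plus annotation channel
    header_bytes = 256 * (1 + n_sig)

    head = b""
    head += _field("0", 8)
    head += _field(patient_id, 80)
    head += _field(f"Startdate 01-JAN-2000 {recording_id}", 80)
    head += _field("01.01.00", 8)
    head += _field("00.00.00", 8)
    head += _field(header_bytes, 8)
    head += _field("EDF+C", 44)
    head += _field(n_rec, 8)
    head += _field(1, 8)  # record duration 1 s
    head += _field(n_sig, 4)

    def col(values, width):
        return b"".join(_field(v, width) for v in values)

    sig_labels = list(labels) + ["EDF Annotations"]
    head += col(sig_labels, 16)
    head += col([""] * n_sig, 80)                                   # transducer
    head += col(["uV"] * n_ch + [""], 8)                            # dimension
    head += col([f"{v:.8g}"[:8] for v in phys_min] + ["-32768"], 8)
    head += col([f"{v:.8g}"[:8] for v in phys_max] + ["32767"], 8)
    head += col([dig_min] * n_sig, 8)
    head += col([dig_max] * n_sig, 8)
    head += col([""] * n_sig, 80)                                   # prefilter
    head += col([spr] * n_ch + [_ANN_SAMPLES], 8)
    head += col([""] * n_sig, 32)
    assert len(head) == header_bytes

    # assign events to records by onset
    ev_by_rec: dict[int, list] = {}
    for onset, dur, text in events:
        ev_by_rec.setdefault(int(onset), []).append((onset, dur, text))

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes(order="C"))
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for onset, dur, text in ev_by_rec.get(r, []):
                tal += (f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00").encode("ascii")
            if len(tal) > 2 * _ANN_SAMPLES:
                raise ValueError("annotation payload exceeds record capacity")
            fh.write(tal.ljust(2 * _ANN_SAMPLES, b"\x00"))


def validate_edf(path) -> None:
    """Check that the file holds every record its header promises.

    Raises ValueError with the byte offset where data ends prematurely.
    """
    import os

    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header at byte {len(fixed)}")
        try:
            header_bytes = int(fixed[184:192].decode("ascii").strip())
            n_rec = int(fixed[236:244].decode("ascii").strip())
            n_sig = int(fixed[252:256].decode("ascii").strip())
        except ValueError as err:
            raise ValueError(f"{path}: unparseable EDF header") from err
        fh.seek(256 + n_sig * 216)
        spr_field = fh.read(n_sig * 8)
        if len(spr_field) < n_sig * 8:
            raise ValueError(f"{path}: truncated EDF signal header at byte "
                             f"{256 + n_sig * 216 + len(spr_field)}")
        try:
            spr = [int(spr_field[i * 8:(i + 1) * 8].decode("ascii").strip())
                   for i in range(n_sig)]
        except ValueError as err:
            raise ValueError(f"{path}: unparseable samples-per-record fields") from err
    expected = header_bytes + n_rec * 2 * sum(spr)
    actual = os.path.getsize(path)
    if actual < expected:
        raise ValueError(f"{path}: EDF data ends at byte {actual}, "
                         f"expected {expected}")
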