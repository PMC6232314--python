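"""Channel montage used throughout the package.

The recording montage is a 64-electrode 10-10 scalp set that includes the two
mastoids (M1, M2), plus two EOG channels.  Analyses that average across the
scalp use the 62 true scalp electrodes only: the mastoids serve as the
reference and the EOG channels are auxiliary.
"""

from __future__ import annotations

SCALP_62 = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2", "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6", "FC3", "FCz", "FC4",
    "C5", "C1", "C2", "C6", "CP3", "CPz", "CP4",
    "P5", "P1", "P2", "P6", "PO5", "PO3", "PO4", "PO6",
    "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
]

MASTOIDS = ["M1", "M2"]
EOG = ["EOG1", "EOG2"]

ALL_CHANNELS = SCALP_62 + MASTOIDS + EOG


def montage_labels(n_scalp: int = 62) -> list[str]:
    """Scalp subset (first ``n_scalp`` labels) plus mastoids and EOG."""
    if not 1 <= n_scalp <= len(SCALP_62):
        raise ValueError(f"n_scalp must be in [1, {len(SCALP_62)}], got {n_scalp}")
    return SCALP_62[:n_scalp] + MASTOIDS + EOG


def scalp_labels(labels: list[str]) -> list[str]:
    """The scalp channels present in ``labels`` (montage order, no M1/M2/EOG)."""
    scalp = set(SCALP_62)
    return [ch for ch in labels if ch in scalp]


def _group(label: str) -> str:
    """Longest alphabetic prefix of a 10-10 label (e.g. 'FCz' -> 'FC')."""
    out = ""
    for c in label:
        if c.isalpha() and not c.isdigit():
            out += c
        else:
            break
    return out.rstrip("z").upper() or label.upper()


# Relative blink-artifact propagation: strongest frontally, negligible posteriorly.
_BLINK_WEIGHTS = {
    "FP": 0.55, "AF": 0.35, "F": 0.20, "FT": 0.10, "FC": 0.08,
    "T": 0.04, "C": 0.03, "TP": 0.02, "CP": 0.02,
    "P": 0.01, "PO": 0.01, "O": 0.01, "M": 0.02,
}

# Fronto-central positivity of the auditory envelope-following response.
_RESPONSE_WEIGHTS = {
    "FP": 0.45, "AF": 0.60, "F": 0.85, "FT": 0.55, "FC": 1.00,
    "T": 0.45, "C": 0.95, "TP": 0.40, "CP": 0.75,
    "P": 0.55, "PO": 0.35, "O": 0.25, "M": 0.0,
}

# Spatial signatures used to make the two attention conditions separable:
# occipito-parietal alpha vs. temporal low-beta.
_OCCIPITAL_WEIGHTS = {"O": 1.0, "PO": 0.8, "P": 0.4}
_TEMPORAL_WEIGHTS = {"T": 1.0, "FT": 0.8, "TP": 0.8, "C": 0.2}


def _weights(labels: list[str], table: dict[str, float]) -> "np.ndarray":
    import numpy as np

    return np.array([table.get(_group(ch), 0.0) for ch in labels], dtype=float)


def blink_topography(labels):
    return _weights(labels, _BLINK_WEIGHTS)


def response_topography(labels):
    return _weights(labels, _RESPONSE_WEIGHTS)


def occipital_topography(labels):
    return _weights(labels, _OCCIPITAL_WEIGHTS)


def temporal_topography(labels):
    return _weights(labels, _TEMPORAL_WEIGHTS)
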