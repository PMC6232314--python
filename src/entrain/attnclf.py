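"""Attention-condition decoding: CSP log-variance features + Gaussian-kernel SVM.

The 29-s preprocessed epochs are cut into non-overlapping 4-s segments, each
labeled visual-active or auditory-active.  Common spatial patterns (CSP)
filters maximize the variance ratio between the two classes; the six filters
attached to the three largest and three smallest generalized eigenvalues
yield log-variance features classified by an RBF-kernel SVM under stratified
5-fold cross-validation.  CSP is re-fit inside each training fold — fitting
it on the full data before folding leaks class information and inflates the
shuffled-label control above chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

SEGMENT_S = 4.0
CLASSES = ("visual-active", "auditory-active")


@dataclass
class CSPModel:
    filters: np.ndarray              # 6 × channels, top-3 then bottom-3
    eigenvalues: np.ndarray          # matching generalized eigenvalues in (0,1)
    channel_labels: list
    classes: tuple
    class_counts: tuple


def epoch_4s(epochs):
    """Cut each 29-s epoch into seven 4-s segments (1-s remainder dropped).

    Control-task epochs are excluded (logged).  Returns
    (segments array m×ch×n, labels array, exclusion log).
    """
    segments, labels, excluded = [], [], []
    for ep in epochs:
        if ep.task not in CLASSES:
            excluded.append({"participant": ep.participant, "trial": ep.trial,
                             "task": ep.task})
            continue
        n_seg = int(ep.data.shape[1] / (SEGMENT_S * ep.rate))
        width = int(SEGMENT_S * ep.rate)
        idx = ep.scalp_idx if len(ep.scalp_idx) else np.arange(ep.data.shape[0])
        for k in range(n_seg):
            segments.append(ep.data[idx, k * width:(k + 1) * width])
        labels.extend([ep.task] * n_seg)
    if not segments:
        return np.empty((0, 0, 0)), np.array([], dtype=object), excluded
    return np.stack(segments), np.asarray(labels, dtype=object), excluded


def segment_covariances(segments) -> np.ndarray:
    """Trace-normalized spatial covariance of each segment."""
    covs = np.einsum("mct,mdt->mcd", segments, segments)
    tr = np.trace(covs, axis1=1, axis2=2)
    return covs / tr[:, None, None]


def _csp_from_covs(covs, labels, classes, n_pairs=3, channel_labels=None):
    masks = [np.asarray(labels) == c for c in classes]
    if not all(m.any() for m in masks):
        raise ValueError("both classes must be present to fit CSP")
    c1 = covs[masks[0]].mean(axis=0)
    c2 = covs[masks[1]].mean(axis=0)
    comp = c1 + c2
    ev = linalg.eigvalsh(comp)
    if ev[0] < 1e-10 * ev[-1]:
        warnings.warn("singular composite covariance; applying shrinkage")
        comp = comp + 1e-8 * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
    evals, evecs = linalg.eigh(c1, comp)
    evals = np.clip(evals, 0.0, 1.0)
    # eigh returns ascending order; take the 3 largest then the 3 smallest
    order = list(range(len(evals) - 1, len(evals) - 1 - n_pairs, -1)) + list(range(n_pairs))
    filters = evecs[:, order].T
    return CSPModel(filters=filters, eigenvalues=evals[order],
                    channel_labels=list(channel_labels or []),
                    classes=tuple(classes),
                    class_counts=(int(masks[0].sum()), int(masks[1].sum())))


def fit_csp(segments, labels, n_pairs: int = 3, channel_labels=None) -> CSPModel:
    """Fit CSP filters on labeled segments (class covariances averaged over
    segments and trace-normalized; whitened eigendecomposition)."""
    covs = segment_covariances(np.asarray(segments, dtype=float))
    return _csp_from_covs(covs, labels, _ordered_classes(labels), n_pairs,
                          channel_labels)


def _ordered_classes(labels):
    if set(labels) <= set(CLASSES):
        return CLASSES
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"CSP needs exactly 2 classes, got {uniq}")
    return tuple(uniq)


def _features_from_covs(model: CSPModel, covs) -> np.ndarray:
    v = np.einsum("fc,mcd,fd->mf", model.filters, covs, model.filters)
    v = np.maximum(v, np.finfo(float).tiny)
    return np.log(v / v.sum(axis=1, keepdims=True))


def csp_features(model: CSPModel, segment) -> np.ndarray:
    """log(var_i / Σ_j var_j) of the six filtered signals — scale-invariant."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 2:
        seg = seg[None]
    cov = segment_covariances(seg)
    feats = _features_from_covs(model, cov)
    return feats[0] if feats.shape[0] == 1 else feats


def _stratified_folds(labels, k, rng):
    labels = np.asarray(labels)
    folds = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(i)
    return [np.sort(np.array(f)) for f in folds]


def crossval_accuracy(segments, labels, k: int = 5, seed: int = 0,
                      svm_c: float = 1.0, gamma="scale", covs=None):
    """Stratified k-fold CV accuracy of the CSP+RBF-SVM pipeline.

    CSP is re-fit on each training fold only.  Returns (mean, sd) over folds.
    ``covs`` may supply precomputed trace-normalized segment covariances.
    """
    from sklearn.svm import SVC

    labels = np.asarray(labels, dtype=object)
    classes = _ordered_classes(labels)
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < k:
        raise ValueError(f"fold count {k} exceeds smallest class size {min(counts)}")
    if covs is None:
        covs = segment_covariances(np.asarray(segments, dtype=float))
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    accs = []
    for f in range(k):
        test_idx = folds[f]
        train_idx = np.sort(np.concatenate([folds[j] for j in range(k) if j != f]))
        model = _csp_from_covs(covs[train_idx], labels[train_idx], classes)
        clf = SVC(C=svm_c, kernel="rbf", gamma=gamma)
        clf.fit(_features_from_covs(model, covs[train_idx]), labels[train_idx])
        accs.append(clf.score(_features_from_covs(model, covs[test_idx]), labels[test_idx]))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std())


def shuffled_baseline(segments, n_runs: int = 5000, seed: int = 0, k: int = 5,
                      svm_c: float = 1.0, gamma="scale"):
    """Chance-level control: random balanced relabelings, CV accuracy each.

    Each run assigns exactly half the segments to each class at random, then
    runs the identical CSP-inside-the-fold cross-validation.  Returns the
    accuracy distribution and its quartiles.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    segments = np.asarray(segments, dtype=float)
    covs = segment_covariances(segments)
    m = covs.shape[0]
    if m % 2:
        warnings.warn("odd segment count: balanced split drops class balance by one")
    base = np.array([CLASSES[0]] * (m // 2) + [CLASSES[1]] * (m - m // 2), dtype=object)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_runs)
    for r in range(n_runs):
        labels = base.copy()
        rng.shuffle(labels)
        accs[r], _ = crossval_accuracy(None, labels, k=k, covs=covs, svm_c=svm_c,
                                       gamma=gamma, seed=int(rng.integers(2 ** 31)))
    quartiles = np.percentile(accs, [25, 50, 75])
    return accs, quartiles
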