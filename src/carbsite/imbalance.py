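"""Class-imbalance strategies for residue-level binding prediction.

Binding residues are rare (a few percent of all residues), so five standard
strategies are provided: random undersampling of the majority class, weighted
oversampling (inverse-frequency sampling probabilities), class-weighted loss,
and the SMOTE / ADASYN synthetic-minority oversamplers.  The synthetic
samplers interpolate only the continuous 2340-wide feature block; the discrete
window-index vector of a synthetic sample is copied from its seed minority
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

STRATEGIES = ("ru", "wo", "cwl", "smote", "adasyn")


@dataclass
class LabeledSet:
    """Aligned windows (N×31 int), features (N×2340 float), labels (N ∈ {0,1})."""

    windows: np.ndarray
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(np.int64)
        if not (len(self.windows) == len(self.features) == len(self.labels)):
            raise ValueError("windows / features / labels lengths differ")
        if self.labels.size and set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "LabeledSet":
        return LabeledSet(self.windows[idx], self.features[idx], self.labels[idx])


def undersample(dataset: LabeledSet, seed: int = 0) -> LabeledSet:
    """All positives plus an equal-size random negative subset (no replacement)."""
    pos = np.flatnonzero(dataset.labels == 1)
    neg = np.flatnonzero(dataset.labels == 0)
    if len(pos) > len(neg):
        raise ValueError(
            f"{len(pos)} positives exceed {len(neg)} negatives: cannot undersample"
        )
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg, size=len(pos), replace=False)
    idx = np.sort(np.concatenate([pos, keep_neg]))
    return dataset.subset(idx)


def oversample_weights(labels: np.ndarray) -> np.ndarray:
    """Per-sample sampling weights ∝ 1/class frequency, normalized to sum 1."""
    labels = np.asarray(labels)
    n = len(labels)
    freq = {c: np.count_nonzero(labels == c) / n for c in np.unique(labels)}
    w = np.array([1.0 / freq[c] for c in labels])
    return w / w.sum()


def class_loss_weights(labels: np.ndarray) -> tuple[float, float]:
    """(w_pos, w_neg) with w_neg = 1 and w_pos/w_neg the inverse frequency
    ratio freq_neg/freq_pos."""
    labels = np.asarray(labels)
    n_pos = int(np.count_nonzero(labels == 1))
    n_neg = int(np.count_nonzero(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_neg / n_pos, 1.0


def _minority_majority(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.count_nonzero(labels == 1))
    n_neg = len(labels) - n_pos
    return (1, 0) if n_pos <= n_neg else (0, 1)


def smote_like(dataset: LabeledSet, k: int = 5, seed: int = 0) -> LabeledSet:
    """SMOTE: synthesize minority samples on segments between each seed
    minority sample and one of its k nearest minority neighbors, until the
    class counts are equal."""
    minority, majority = _minority_majority(dataset.labels)
    min_idx = np.flatnonzero(dataset.labels == minority)
    maj_idx = np.flatnonzero(dataset.labels == majority)
    if len(min_idx) < k + 1:
        raise ValueError(f"SMOTE needs at least {k + 1} minority samples")
    n_new = len(maj_idx) - len(min_idx)
    if n_new <= 0:
        return dataset
    rng = np.random.default_rng(seed)
    X_min = dataset.features[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(len(min_idx), size=n_new)
    pick = neighbors[base, rng.integers(k, size=n_new)]
    gap = rng.random((n_new, 1))
    synth_features = X_min[base] + gap * (X_min[pick] - X_min[base])
    synth_windows = dataset.windows[min_idx[base]]
    return LabeledSet(
        np.concatenate([dataset.windows, synth_windows]),
        np.concatenate([dataset.features, synth_features]),
        np.concatenate([dataset.labels, np.full(n_new, minority)]),
    )


def adasyn_like(dataset: LabeledSet, k: int = 5, seed: int = 0) -> LabeledSet:
    """ADASYN: like SMOTE, but the number of synthetics per seed sample grows
    with the fraction of majority samples among its k nearest neighbors, so
    harder-to-learn border samples receive more synthetic support."""
    minority, majority = _minority_majority(dataset.labels)
    min_idx = np.flatnonzero(dataset.labels == minority)
    maj_idx = np.flatnonzero(dataset.labels == majority)
    if len(min_idx) < k + 1:
        raise ValueError(f"ADASYN needs at least {k + 1} minority samples")
    n_new = len(maj_idx) - len(min_idx)
    if n_new <= 0:
        return dataset
    rng = np.random.default_rng(seed)
    X_min = dataset.features[min_idx]

    # hardness ratio: majority fraction among each minority sample's k-NN
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(dataset.features)
    neigh_all = nn_all.kneighbors(X_min, return_distance=False)[:, 1:]
    ratio = (dataset.labels[neigh_all] == majority).mean(axis=1)
    if ratio.sum() == 0:
        ratio = np.ones_like(ratio)
    ratio = ratio / ratio.sum()
    counts = np.floor(ratio * n_new).astype(int)
    # distribute the rounding remainder to the hardest samples
    short = n_new - counts.sum()
    if short > 0:
        order = np.argsort(-(ratio * n_new - counts), kind="stable")
        counts[order[:short]] += 1

    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh_min = nn_min.kneighbors(X_min, return_distance=False)[:, 1:]
    base = np.repeat(np.arange(len(min_idx)), counts)
    pick = neigh_min[base, rng.integers(k, size=len(base))]
    gap = rng.random((len(base), 1))
    synth_features = X_min[base] + gap * (X_min[pick] - X_min[base])
    synth_windows = dataset.windows[min_idx[base]]
    return LabeledSet(
        np.concatenate([dataset.windows, synth_windows]),
        np.concatenate([dataset.features, synth_features]),
        np.concatenate([dataset.labels, np.full(len(base), minority)]),
    )
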