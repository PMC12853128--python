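"""Training loops for the imbalance strategies and the weighted ensemble.

A separate network is trained per imbalance strategy; the final predictor
averages the probabilities of the undersampling (RU), weighted-oversampling
(WO) and class-weighted-loss (CWL) models with RU counted twice:

    P(ensemble) = (2·P(RU) + P(WO) + P(CWL)) / 4.

Published training defaults (Adam, binary cross-entropy, learning rate 1e-5,
batch size 2048, epochs RU:180 / WO:100 / CWL:325) are the module defaults;
desk-scale runs pass smaller ``epochs``/``batch_size`` and a larger ``lr``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imbalance import (
    LabeledSet, adasyn_like, class_loss_weights, oversample_weights, smote_like,
    undersample,
)
from .nn import Adam, NetConfig, ResNetFNN, bce_loss_and_grad

DEFAULT_EPOCHS = {"ru": 180, "wo": 100, "cwl": 325, "smote": 100, "adasyn": 100}
DEFAULT_BATCH_SIZE = 2048
DEFAULT_LR = 1e-5
ENSEMBLE_WEIGHTS = (2.0, 1.0, 1.0)


@dataclass
class TrainedNet:
    """A fitted single-strategy model plus its training-loss trajectory."""

    net: ResNetFNN
    strategy_tag: str
    loss_trajectory: list[float]

    def predict(self, windows: np.ndarray, features: np.ndarray) -> np.ndarray:
        return self.net.predict(windows, features)


def train(
    dataset: LabeledSet,
    strategy: str,
    config: NetConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    lr: float = DEFAULT_LR,
    smote_k: int = 5,
) -> TrainedNet:
    """Fit one network under the named imbalance strategy.

    ``strategy`` ∈ {ru, wo, cwl, smote, adasyn}.  All randomness (resampling,
    initialization, dropout, batch order) derives from ``seed``; repeated runs
    on CPU give bitwise-identical loss trajectories.  ``epochs=0`` returns the
    freshly initialized network unchanged.
    """
    strategy = strategy.lower()
    if strategy not in DEFAULT_EPOCHS:
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("degenerate labels: need both classes to train")
    epochs = DEFAULT_EPOCHS[strategy] if epochs is None else epochs

    rng = np.random.default_rng(seed)
    net = ResNetFNN(config, seed=seed)
    if epochs == 0:
        return TrainedNet(net=net, strategy_tag=strategy, loss_trajectory=[])

    if strategy == "ru":
        work = undersample(dataset, seed=seed)
    elif strategy == "smote":
        work = smote_like(dataset, k=smote_k, seed=seed)
    elif strategy == "adasyn":
        work = adasyn_like(dataset, k=smote_k, seed=seed)
    else:
        work = dataset

    sample_weights = None
    if strategy == "cwl":
        w_pos, w_neg = class_loss_weights(work.labels)
        sample_weights = np.where(work.labels == 1, w_pos, w_neg)
    draw_p = oversample_weights(work.labels) if strategy == "wo" else None

    optimizer = Adam(net.params(), lr=lr)
    n = len(work)
    trajectory: list[float] = []
    for epoch in range(epochs):
        if strategy == "wo":
            order = rng.choice(n, size=n, replace=True, p=draw_p)
        else:
            order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for k in range(0, n, batch_size):
            idx = order[k:k + batch_size]
            if len(idx) < 2:
                continue  # batch statistics need at least two samples
            net.zero_grad()
            _, logits = net.forward(
                work.windows[idx], work.features[idx], training=True
            )
            w = sample_weights[idx] if sample_weights is not None else None
            loss, dlogits = bce_loss_and_grad(logits, work.labels[idx], w)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (strategy {strategy}, lr {lr})"
                )
            net.backward(dlogits)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        trajectory.append(epoch_loss / max(n_batches, 1))
    return TrainedNet(net=net, strategy_tag=strategy, loss_trajectory=trajectory)


def ensemble_predict(
    p_ru: np.ndarray, p_wo: np.ndarray, p_cwl: np.ndarray
) -> np.ndarray:
    """Weighted average of component probabilities: (2·RU + WO + CWL)/4."""
    w = ENSEMBLE_WEIGHTS
    return (w[0] * np.asarray(p_ru) + w[1] * np.asarray(p_wo)
            + w[2] * np.asarray(p_cwl)) / sum(w)


@dataclass
class EnsembleModel:
    """Three strategy models combined 2:1:1 (RU counted twice)."""

    m_ru: TrainedNet
    m_wo: TrainedNet
    m_cwl: TrainedNet

    def predict(self, windows: np.ndarray, features: np.ndarray) -> np.ndarray:
        return ensemble_predict(
            self.m_ru.predict(windows, features),
            self.m_wo.predict(windows, features),
            self.m_cwl.predict(windows, features),
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tag, model in (("ru", self.m_ru), ("wo", self.m_wo), ("cwl", self.m_cwl)):
            model.net.save(directory / f"model_{tag}.npz")
            (directory / f"model_{tag}.json").write_text(
                json.dumps({"strategy": model.strategy_tag,
                            "loss_trajectory": model.loss_trajectory})
            )

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        models = {}
        for tag in ("ru", "wo", "cwl"):
            meta = json.loads((directory / f"model_{tag}.json").read_text())
            models[tag] = TrainedNet(
                net=ResNetFNN.load(directory / f"model_{tag}.npz"),
                strategy_tag=meta["strategy"],
                loss_trajectory=meta["loss_trajectory"],
            )
        return cls(m_ru=models["ru"], m_wo=models["wo"], m_cwl=models["cwl"])


def build_ensemble(
    dataset: LabeledSet,
    config: NetConfig | None = None,
    seeds: tuple[int, int, int] = (0, 1, 2),
    **train_kwargs,
) -> EnsembleModel:
    """Train the RU, WO and CWL models and wire the 2:1:1 combination."""
    m_ru = train(dataset, "ru", config, seed=seeds[0], **train_kwargs)
    m_wo = train(dataset, "wo", config, seed=seeds[1], **train_kwargs)
    m_cwl = train(dataset, "cwl", config, seed=seeds[2], **train_kwargs)
    return EnsembleModel(m_ru=m_ru, m_wo=m_wo, m_cwl=m_cwl)
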