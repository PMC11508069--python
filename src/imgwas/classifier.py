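"""Slice classifiers and their training protocol.

The reference model is a deliberately small CNN — three conv blocks with 8,
16 and 32 filters (3x3 kernels, ReLU, 2x2 max pooling), a dense-128 ReLU
layer with 0.5 dropout and a two-unit softmax head — trained with Adam at
learning rate 1e-4 for at most 30 epochs, early-stopped when the validation
loss has not improved for 10 epochs, and restored to the best-validation
epoch. The architecture is kept identical across all SNP tasks so their
performance values are comparable.

A fast pluggable alternative, ridge regression on flattened pixels, serves
the same train/evaluate contract for scans where training hundreds of CNNs
would be wasteful. Each ridge fit uses a seeded random subsample of the
training scans so that repeated "retrains" exhibit the run-to-run
variability the fine-tuning statistic relies on (the CNN gets this from its
random initialization and batch order).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, SmallCNNNet
from .genotypes import MonomorphicTaskError
from .metrics import ConfusionCounts, MetricPair, confusion_counts, macro_f1_from_counts, mcc
from .splitting import LabeledSlices


@dataclass(frozen=True)
class CNNSpec:
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    kernel: int = 3
    dense_units: int = 128
    dropout: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("the reference model has exactly 3 conv blocks")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 30
    learning_rate: float = 1e-4
    early_stop_patience: int = 10
    batch_size: int = 32
    seed: int = 0
    selection: str = "val_loss"  # or "val_mcc"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.selection not in ("val_loss", "val_mcc"):
            raise ValueError("selection must be 'val_loss' or 'val_mcc'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mcc: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_mcc": self.val_mcc,
            }
        )


def _check_task(train: LabeledSlices, val: LabeledSlices) -> None:
    if len(train) == 0 or len(np.unique(train.labels)) < 2:
        raise MonomorphicTaskError("training set must contain both classes")
    if len(val) == 0:
        raise ValueError("validation set must be non-empty")


class CNNClassifier:
    """Fitted reference CNN (see module docstring for the protocol)."""

    supports_saliency = True

    def __init__(self, spec: CNNSpec = CNNSpec(), cfg: TrainConfig = TrainConfig()):
        self.spec = spec
        self.cfg = cfg
        self.net: SmallCNNNet | None = None
        self.history = TrainHistory()

    def fit(self, train: LabeledSlices, val: LabeledSlices) -> "CNNClassifier":
        _check_task(train, val)
        shapes = {img.shape for img in train.images} | {img.shape for img in val.images}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent image shapes: {shapes}")
        cfg, spec = self.cfg, self.spec
        init_rng = np.random.default_rng(cfg.seed)
        order_rng = np.random.default_rng(cfg.seed + 1)
        drop_rng = np.random.default_rng(cfg.seed + 2)
        net = SmallCNNNet(
            train.images.shape[1:3],
            conv_filters=spec.conv_filters,
            kernel=spec.kernel,
            dense_units=spec.dense_units,
            dropout=spec.dropout,
            n_classes=spec.n_classes,
            rng=init_rng,
        )
        opt = Adam(net.params, lr=cfg.learning_rate)
        x, y = train.images, train.labels
        best_score = -np.inf
        best_params = None
        best_epoch = 0
        for epoch in range(cfg.max_epochs):
            perm = order_rng.permutation(len(y))
            losses = []
            for start in range(0, len(y), cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                loss, grads = net.loss_and_grads(x[idx], y[idx], drop_rng)
                opt.step(net.params, grads)
                losses.append(loss)
            vloss = net.loss(val.images, val.labels)
            vpred = net.predict_proba(val.images).argmax(axis=1)
            if len(np.unique(val.labels)) < 2:
                vmcc = 0.0
            else:
                vmcc = mcc(confusion_counts(val.labels, vpred))
            self.history.train_loss.append(float(np.mean(losses)))
            self.history.val_loss.append(vloss)
            self.history.val_mcc.append(vmcc)
            score = -vloss if cfg.selection == "val_loss" else vmcc
            if score > best_score:
                best_score = score
                best_params = copy.deepcopy(net.params)
                best_epoch = epoch
            if epoch - best_epoch >= cfg.early_stop_patience:
                break
        net.params = best_params
        self.history.best_epoch = best_epoch
        self.net = net
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("classifier is not fitted")
        return self.net.predict_proba(np.asarray(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def conv_maps_and_grads(self, images: np.ndarray, class_index: int):
        """Last-conv post-activation maps and gradients of the linear class
        score with respect to them (softmax head bypassed)."""
        if self.net is None:
            raise RuntimeError("classifier is not fitted")
        return self.net.last_conv_maps_and_grads(np.asarray(images), class_index)


class LinearSliceClassifier:
    """L2-regularized linear model on flattened pixels.

    Satisfies the same fit/predict contract as the CNN. ``subsample`` < 1
    fits each run on a seeded random fraction of the training scans
    (bagging-style half-sampling by default), giving retrains the
    stochastic behavior the fine-tuning test assumes; the fit is otherwise
    deterministic. The retrain variability must dominate the chance
    alignment of any single labeling for the fine-tuning t-test to be
    calibrated, which is what the default fraction is chosen for.
    """

    supports_saliency = False

    def __init__(self, alpha: float = 1.0, subsample: float = 0.5, seed: int = 0):
        if not 0.0 < subsample <= 1.0:
            raise ValueError("subsample must be in (0, 1]")
        self.alpha = alpha
        self.subsample = subsample
        self.seed = seed
        self._model = None

    def fit(self, train: LabeledSlices, val: LabeledSlices | None = None) -> "LinearSliceClassifier":
        from sklearn.linear_model import RidgeClassifier

        if len(train) == 0 or len(np.unique(train.labels)) < 2:
            raise MonomorphicTaskError("training set must contain both classes")
        x = train.images.reshape(len(train), -1)
        y = train.labels
        if self.subsample < 1.0:
            rng = np.random.default_rng(self.seed)
            n_keep = max(2, int(round(self.subsample * len(y))))
            for _ in range(50):  # redraw until both classes survive
                idx = rng.choice(len(y), size=n_keep, replace=False)
                if len(np.unique(y[idx])) == 2:
                    break
            x, y = x[idx], y[idx]
        self._model = RidgeClassifier(alpha=self.alpha).fit(x, y)
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        imgs = np.asarray(images)
        return self._model.predict(imgs.reshape(len(imgs), -1))


def train_classifier(
    train: LabeledSlices,
    val: LabeledSlices,
    spec: CNNSpec = CNNSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> CNNClassifier:
    """Train the reference CNN, returning the model restored to the best
    validation epoch."""
    return CNNClassifier(spec=spec, cfg=cfg).fit(train, val)


def fit_classifier(kind: str, train: LabeledSlices, val: LabeledSlices,
                   spec: CNNSpec, cfg: TrainConfig):
    """Dispatch on classifier kind ('cnn' or 'linear')."""
    if kind == "cnn":
        return train_classifier(train, val, spec=spec, cfg=cfg)
    if kind == "linear":
        return LinearSliceClassifier(seed=cfg.seed).fit(train, val)
    raise ValueError(f"unknown classifier kind {kind!r}")


def evaluate(model, test: LabeledSlices) -> tuple[ConfusionCounts, MetricPair]:
    """Confusion counts and the MCC / macro F1 pair on a held-out test set."""
    if len(test) == 0:
        raise ValueError("test set must be non-empty")
    pred = model.predict(test.images)
    counts = confusion_counts(test.labels, pred)
    return counts, MetricPair(mcc=mcc(counts), macro_f1=macro_f1_from_counts(counts))
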