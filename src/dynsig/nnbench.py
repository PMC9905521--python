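"""The two benchmark classifier families and their training/evaluation loop.

Architectures, as validated on the dataset:

* **lstm** — input (B, Y, 1) → LSTM with 4 units → dropout 0.5 → 2-unit
  dense output with sigmoid activation;
* **cnn** — input (B, Y, 1) → one block of [Conv1D(32, kernel 3) → ReLU →
  batch norm → dropout 0.5] → flatten → 2-unit dense sigmoid output;
* **cnn_deep** — the extended variant (used when training on first segments
  only): three conv blocks with 32/64/64 filters.

All models train with categorical cross-entropy, Adam at learning rate
0.001 and batch size 64; chaos is the positive class throughout.  Training
is deterministic given ``train_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .experiments import CHAOS, ConfusionCounts, LabelledSegmentSet, confusion

__all__ = ["ClassifierConfig", "TrainedClassifier", "build_lstm", "build_cnn",
           "build_classifier", "train", "evaluate", "report"]

DEEP_FILTERS = (32, 64, 64)


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture plus training hyperparameters for one benchmark model."""

    arch: str = "lstm"  # "lstm" | "cnn" | "cnn_deep"
    segment_length: int = 100
    lstm_units: int = 4
    dropout_rate: float = 0.5
    conv_blocks: int = 1
    conv_filters: int = 32
    conv_kernel: int = 3
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 30
    early_stopping_patience: int | None = 5
    validation_freq: int = 1  # used only without early stopping
    restore_best: bool = False  # without early stopping: keep best-val-accuracy weights
    output_units: int = 2
    head: str = "sigmoid"  # "sigmoid" (as printed) | "softmax"
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("lstm", "cnn", "cnn_deep"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.arch == "cnn" and self.conv_blocks != 1:
            raise ValueError("arch 'cnn' has exactly one conv block")
        if self.arch == "cnn_deep" and self.conv_blocks < 2:
            raise ValueError("arch 'cnn_deep' needs >= 2 conv blocks")


@dataclass
class TrainedClassifier:
    """Fitted network plus config and per-epoch training history."""

    config: ClassifierConfig
    network: nn.Network
    history: pd.DataFrame  # columns: epoch, train_loss, train_acc, val_loss, val_acc
    best_epoch: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict(_shape_input(X))


def _shape_input(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, :, None] if X.ndim == 2 else X


def build_lstm(cfg: ClassifierConfig) -> nn.Network:
    """Recurrent classifier: LSTM(units) → dropout → dense sigmoid (2 units)."""
    if cfg.arch != "lstm":
        raise ValueError("build_lstm requires arch='lstm'")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.train_seed, 0]))
    layers = [
        nn.LSTM(cfg.lstm_units, 1, rng),
        nn.Dropout(cfg.dropout_rate),
        nn.Dense(cfg.lstm_units, cfg.output_units, rng),
    ]
    return nn.Network(layers, head=cfg.head)


def build_cnn(cfg: ClassifierConfig) -> nn.Network:
    """Convolutional classifier: conv block(s) → flatten → dense sigmoid.

    Each block is Conv1D → ReLU → batch norm → dropout; the deep variant
    stacks ``conv_blocks`` blocks with 32/64/64 filters.
    """
    if cfg.arch not in ("cnn", "cnn_deep"):
        raise ValueError("build_cnn requires arch='cnn' or 'cnn_deep'")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.train_seed, 0]))
    if cfg.arch == "cnn":
        filters: Sequence[int] = (cfg.conv_filters,)
    else:
        filters = tuple(DEEP_FILTERS[i % len(DEEP_FILTERS)] for i in range(cfg.conv_blocks))
    layers: list[nn.Layer] = []
    length, channels = cfg.segment_length, 1
    for f in filters:
        layers += [
            nn.Conv1D(f, cfg.conv_kernel, channels, rng),
            nn.ReLU(),
            nn.BatchNorm(f),
            nn.Dropout(cfg.dropout_rate),
        ]
        length -= cfg.conv_kernel - 1
        channels = f
        if length < 1:
            raise ValueError("segment too short for the configured conv stack")
    layers += [nn.Flatten(), nn.Dense(length * channels, cfg.output_units, rng)]
    return nn.Network(layers, head=cfg.head)


def build_classifier(cfg: ClassifierConfig) -> nn.Network:
    return build_lstm(cfg) if cfg.arch == "lstm" else build_cnn(cfg)


def train(
    network: nn.Network,
    train_set: LabelledSegmentSet,
    validation_set: LabelledSegmentSet,
    cfg: ClassifierConfig,
) -> TrainedClassifier:
    """Fit with Adam/categorical cross-entropy; early-stop on validation loss.

    Keeps the weights of the best validation-loss epoch.  Raises on empty
    sets or a non-finite loss.
    """
    if len(train_set) == 0 or len(validation_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    Xtr = _shape_input(train_set.X)
    ttr = nn.one_hot(train_set.y, cfg.output_units)
    Xval = _shape_input(validation_set.X)
    tval = nn.one_hot(validation_set.y, cfg.output_units)

    opt = nn.Adam(lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.train_seed, 1]))
    n = Xtr.shape[0]
    rows = []
    early_stop = cfg.early_stopping_patience is not None
    checkpoint = not early_stop and cfg.restore_best
    # early stopping needs the validation loss every epoch; checkpointing can
    # monitor on the configured cadence
    val_freq = 1 if early_stop else max(1, cfg.validation_freq)
    best_loss, best_weights, best_epoch, since_best = np.inf, None, 0, 0
    best_acc = -1.0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, correct = network.train_step(Xtr[idx], ttr[idx], opt, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            n_correct += correct
        train_loss = float(np.mean(losses))
        train_acc = n_correct / n  # streaming accuracy over the epoch's batches
        if (epoch + 1) % val_freq == 0 or epoch == cfg.epochs - 1:
            val_loss, val_acc = network.loss_and_accuracy(Xval, tval)
        else:
            val_loss = val_acc = float("nan")
        rows.append({"epoch": epoch, "train_loss": train_loss, "train_acc": train_acc,
                     "val_loss": val_loss, "val_acc": val_acc})
        if early_stop:
            if val_loss < best_loss:
                best_loss, best_epoch, since_best = val_loss, epoch, 0
                best_weights = network.get_weights()
            else:
                since_best += 1
                if since_best >= cfg.early_stopping_patience:
                    break
        elif checkpoint:
            if not np.isnan(val_acc) and val_acc > best_acc:
                best_acc, best_epoch = val_acc, epoch
                best_weights = network.get_weights()
        else:
            best_epoch = epoch
    if (early_stop or checkpoint) and best_weights is not None:
        network.set_weights(best_weights)
    return TrainedClassifier(cfg, network, pd.DataFrame(rows), best_epoch)


def evaluate(classifier: TrainedClassifier, test_set: LabelledSegmentSet) -> ConfusionCounts:
    """Confusion counts on a test set; argmax over the 2 scores, chaos positive."""
    pred = classifier.predict(test_set.X)
    return confusion(test_set.y, pred)


def save_classifier(classifier: TrainedClassifier, directory) -> None:
    """Persist a trained model: weights (.npz), history (CSV) and a summary.

    The summary is backend-neutral JSON: layer list, parameter counts and the
    full configuration.
    """
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = classifier.network.get_weights()
    np.savez(directory / "weights.npz", **{f"p{i}": w for i, w in enumerate(weights)})
    classifier.history.to_csv(directory / "history.csv", index=False)
    summary = {
        "layers": [type(layer).__name__ for layer in classifier.network.layers],
        "n_params": classifier.network.n_params,
        "best_epoch": classifier.best_epoch,
        "config": dataclasses.asdict(classifier.config),
    }
    (directory / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")


def load_classifier(directory) -> TrainedClassifier:
    """Rebuild a classifier from :func:`save_classifier` output."""
    import json
    from pathlib import Path

    directory = Path(directory)
    summary = json.loads((directory / "summary.json").read_text())
    cfg = ClassifierConfig(**summary["config"])
    network = build_classifier(cfg)
    with np.load(directory / "weights.npz") as npz:
        network.set_weights([npz[f"p{i}"] for i in range(len(npz.files))])
    history = pd.read_csv(directory / "history.csv")
    return TrainedClassifier(cfg, network, history, summary["best_epoch"])


def report(results: dict[tuple[str, int], ConfusionCounts]) -> pd.DataFrame:
    """Benchmark-style table: (arch, segment length) rows × accuracy/TP/FN/TN/FP."""
    rows = []
    for (arch, y), cc in sorted(results.items()):
        rows.append({"model": arch.upper(), "segment": y, "accuracy": round(cc.accuracy, 3),
                     "TP": cc.tp, "FN": cc.fn, "TN": cc.tn, "FP": cc.fp})
    return pd.DataFrame(rows)
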