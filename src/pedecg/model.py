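"""The beat classifier: architecture specification, construction,
training and evaluation.

The canonical architecture is a four-block 1D CNN over a 300-sample
beat: blocks of (128, 16, 8, 128) filters, kernel 3, stride 1,
length-preserving padding, activations ReLU / sigmoid / ReLU (with
batch norm) / sigmoid and dropouts 0.45 / 0.1 / 0.05 / 0.4, followed by
a flatten (300 × 128 = 38,400 units), a 32-unit dense block and a
2-class softmax.  The flatten width printed for this network is what
pins down the padding: only "same" padding at stride 1 keeps the length
at 300 through all four blocks.

Training: Adam at 1e-3, batch size 200, categorical cross-entropy on
one-hot labels, Xavier weight init, zero biases, early stopping with a
patience of 30 evaluations of the monitored validation metric
(validation accuracy by default; the patience unit can be switched from
epochs to optimisation batches), restoring the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn

CLASS_NAMES = ("normal", "obese")
INPUT_LENGTH = 300


# ----------------------------------------------------------------------
# Specs
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    filters: int
    kernel_size: int = 3
    stride: int = 1
    activation: str = "relu"          # "relu" | "sigmoid"
    batch_norm: bool = False
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.stride != 1:
            raise ValueError("only stride 1 (length-preserving) is supported")


@dataclass(frozen=True)
class ModelSpec:
    blocks: tuple[ConvBlockSpec, ...]
    input_length: int = INPUT_LENGTH
    dense_units: int = 32
    dense_activation: str = "relu"
    output_classes: int = 2

    def flatten_width(self) -> int:
        """Units after the flatten, by shape propagation: stride-1
        same-padded convs preserve the length, so this is
        input_length × last-block filters."""
        length = self.input_length
        channels = 1
        for b in self.blocks:
            channels = b.filters     # length unchanged: stride 1, same pad
        return length * channels

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("at least one convolutional block required")
        if self.input_length < max(b.kernel_size for b in self.blocks):
            raise ValueError("input shorter than a kernel")


def canonical_spec() -> ModelSpec:
    """The reference four-block architecture used throughout the analysis."""
    return ModelSpec(blocks=(
        ConvBlockSpec(128, 3, 1, "relu", False, 0.45),
        ConvBlockSpec(16, 3, 1, "sigmoid", False, 0.10),
        ConvBlockSpec(8, 3, 1, "relu", True, 0.05),
        ConvBlockSpec(128, 3, 1, "sigmoid", False, 0.40),
    ))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 200
    early_stop_patience: int = 30
    patience_unit: str = "epochs"     # "epochs" | "batches"
    monitor: str = "val_accuracy"     # "val_accuracy" | "val_loss"
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size,
               self.early_stop_patience, self.max_epochs) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.patience_unit not in ("epochs", "batches"):
            raise ValueError("patience_unit must be 'epochs' or 'batches'")


# ----------------------------------------------------------------------
# Construction
# ----------------------------------------------------------------------

def build_model(spec: ModelSpec, config: TrainConfig | None = None
                ) -> nn.Network:
    """Instantiate an untrained network from a spec.

    Block order inside each conv block: convolution → batch norm (if
    present) → activation → dropout.  The tap for class-activation
    mapping is the last block's activation output.
    """
    spec.validate()
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    channels = 1
    tap_index = None
    for bi, b in enumerate(spec.blocks):
        layers.append(nn.Conv1dSame(channels, b.filters, b.kernel_size, rng))
        if b.batch_norm:
            layers.append(nn.BatchNorm1d(b.filters))
        layers.append(nn.ReLU() if b.activation == "relu" else nn.Sigmoid())
        if bi == len(spec.blocks) - 1:
            tap_index = len(layers) - 1
        if b.dropout_rate > 0:
            layers.append(nn.Dropout(b.dropout_rate, rng))
        channels = b.filters
    layers.append(nn.Flatten())
    layers.append(nn.Dense(spec.flatten_width(), spec.dense_units, rng))
    layers.append(nn.ReLU() if spec.dense_activation == "relu"
                  else nn.Sigmoid())
    layers.append(nn.Dense(spec.dense_units, spec.output_classes, rng))
    net = nn.Network(layers, tap_index=tap_index)
    net.spec = spec
    return net


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------

def one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((y.size, n_classes), dtype=nn.DTYPE)
    out[np.arange(y.size), y] = 1.0
    return out


@dataclass
class TrainedModel:
    net: nn.Network
    spec: ModelSpec
    config: TrainConfig
    history: pd.DataFrame
    best_epoch: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(_as_nc_l(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def _as_nc_l(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=nn.DTYPE)
    if x.ndim == 2:                       # (N, L) -> (N, 1, L)
        x = x[:, None, :]
    return x


def _accuracy(net: nn.Network, x: np.ndarray, y: np.ndarray,
              batch: int = 512) -> tuple[float, float]:
    """(accuracy, mean loss) in inference mode, batched."""
    losses, correct = [], 0
    onehot = one_hot(y)
    for i in range(0, len(y), batch):
        logits = net.forward(x[i:i + batch], train=False)
        probs = nn.softmax(logits)
        losses.append(nn.cross_entropy(probs, onehot[i:i + batch])
                      * (len(probs)))
        correct += int((probs.argmax(axis=1) == y[i:i + batch]).sum())
    return correct / len(y), float(np.sum(losses) / len(y))


def train(net: nn.Network, train_split, val_split,
          config: TrainConfig | None = None) -> TrainedModel:
    """Train with Adam + early stopping; restores best-validation weights.

    ``train_split`` and ``val_split`` are ``(X, y)`` with X of shape
    (N, 300) or (N, 1, 300) and integer labels y in {0, 1}.
    """
    config = config or TrainConfig()
    x_tr, y_tr = _as_nc_l(train_split[0]), np.asarray(train_split[1])
    x_va, y_va = _as_nc_l(val_split[0]), np.asarray(val_split[1])
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("train and validation splits must be non-empty")
    if np.unique(y_tr).size < 2:
        raise ValueError("training split must contain both classes")

    rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam(net, lr=config.learning_rate)
    onehot_tr = one_hot(y_tr)

    sign = 1.0 if config.monitor == "val_accuracy" else -1.0
    best_metric = -np.inf
    best_state = net.get_state()
    best_epoch = 0
    patience_left = config.early_stop_patience
    history: list[dict] = []

    def validate(epoch, batches_seen, train_loss, train_acc):
        nonlocal best_metric, best_state, best_epoch, patience_left
        val_acc, val_loss = _accuracy(net, x_va, y_va)
        metric = sign * (val_acc if config.monitor == "val_accuracy"
                         else val_loss)
        history.append({"epoch": epoch, "batches_seen": batches_seen,
                        "train_loss": train_loss, "train_accuracy": train_acc,
                        "val_loss": val_loss, "val_accuracy": val_acc})
        if metric > best_metric:
            best_metric = metric
            best_state = net.get_state()
            best_epoch = epoch
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
        return patience_left <= 0

    stop = False
    batches_seen = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(y_tr))
        epoch_losses, epoch_correct = [], 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, hb = x_tr[idx], y_tr[idx], onehot_tr[idx]
            logits = net.forward(xb, train=True)
            probs = nn.softmax(logits)
            loss = nn.cross_entropy(probs, hb)
            epoch_losses.append(loss * len(idx))
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
            net.backward_from_logits((probs - hb) / len(idx))
            optimizer.step()
            batches_seen += 1
            if config.patience_unit == "batches":
                stop = validate(epoch, batches_seen,
                                float(np.sum(epoch_losses) / (start + len(idx))),
                                epoch_correct / (start + len(idx)))
                if stop:
                    break
        if config.patience_unit == "epochs":
            stop = validate(epoch, batches_seen,
                            float(np.sum(epoch_losses) / len(order)),
                            epoch_correct / len(order))
        if stop:
            break

    net.set_state(best_state)
    return TrainedModel(net=net, spec=getattr(net, "spec", None),
                        config=config, history=pd.DataFrame(history),
                        best_epoch=best_epoch)


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted; classes (normal, obese)."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal_sum(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_accuracy(matrix: ConfusionMatrix) -> tuple[float, int]:
    """(accuracy fraction, rounded percent) from a confusion matrix."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    fraction = matrix.diagonal_sum / matrix.total
    return fraction, int(round(fraction * 100))


def evaluate(model, split) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and accuracy of a (trained) model on a split."""
    x, y = _as_nc_l(split[0]), np.asarray(split[1])
    if len(y) == 0:
        raise ValueError("split must be non-empty")
    net = model.net if isinstance(model, TrainedModel) else model
    pred = nn.softmax(_batched_logits(net, x)).argmax(axis=1)
    k = 2
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y, pred), 1)
    cm = ConfusionMatrix(counts)
    return cm, cm.diagonal_sum / cm.total


def _batched_logits(net: nn.Network, x: np.ndarray,
                    batch: int = 512) -> np.ndarray:
    return np.concatenate([net.forward(x[i:i + batch], train=False)
                           for i in range(0, len(x), batch)])
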