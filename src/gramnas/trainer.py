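"""Materialize topology specs as trainable networks and score them.

Provides the weighted F1 metric, the abbreviated proxy-fitness protocol
(5 epochs, each on a fresh 5% sample of the training windows) used during
evolution, and full training of hall-of-fame topologies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .grammar import TopologySpec, phenotype_from_text, phenotype_to_text
from .preprocess import WindowedDataset

__all__ = [
    "InfeasibleTopologyError",
    "NetworkModel",
    "TrainedModel",
    "EvalScore",
    "build_model",
    "weighted_f1",
    "proxy_fitness",
    "full_train",
    "predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

DEFAULT_PARAM_CEILING = 5_000_000
REG_LAMBDA = 1e-4


class InfeasibleTopologyError(Exception):
    """The spec cannot be materialized (time axis collapses, or the
    parameter count exceeds the resource ceiling)."""


@dataclass(frozen=True)
class EvalScore:
    """Weighted F1 with the per-class quantities it was computed from."""

    f1: float
    precision: np.ndarray   # per class
    recall: np.ndarray      # per class
    support: np.ndarray     # per class true-label counts
    n_samples: int


def weighted_f1(true_labels, predicted_labels) -> EvalScore:
    """Support-weighted F1: ``2 * sum_c (n_c / N) * p_c r_c / (p_c + r_c)``.

    Classes are weighted by true-label support; a class with
    ``precision + recall == 0`` contributes 0.
    """
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if len(y_true) == 0:
        raise ValueError("at least one sample required")
    n_classes = int(max(y_true.max(), y_pred.max())) + 1
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (y_true, y_pred), 1.0)
    tp = np.diag(counts)
    pred_totals = counts.sum(axis=0)
    true_totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(true_totals > 0, tp / true_totals, 0.0)
    denom = precision + recall
    per_class = np.where(denom > 0, precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    N = len(y_true)
    f1 = 2.0 * float(np.sum(true_totals / N * per_class))
    return EvalScore(
        f1=f1,
        precision=precision,
        recall=recall,
        support=true_totals.astype(int),
        n_samples=N,
    )


class NetworkModel:
    """A built network: conv stack, dense stack, softmax head, optimizer."""

    def __init__(
        self,
        spec: TopologySpec,
        layers: list,
        classifier: nn.SoftmaxClassifier,
        n_channels: int,
        n_classes: int,
    ):
        self.spec = spec
        self.layers = layers
        self.classifier = classifier
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.optimizer = nn.make_optimizer(spec.optimizer, spec.learning_rate)

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return self.classifier.forward(out, train)

    def n_params(self) -> int:
        total = self.classifier.n_params()
        return total + sum(layer.n_params() for layer in self.layers)

    def param_checksum(self) -> float:
        total = float(np.sum(np.abs(self.classifier.params[0])))
        for layer in self.layers:
            for p in layer.params:
                total += float(np.sum(np.abs(p)))
        return total

    def loss(self, x: np.ndarray, y: np.ndarray, *, train: bool = False) -> float:
        """Mean cross-entropy plus regularization penalties."""
        probs = self._forward(x, train)
        ce = -np.log(probs[np.arange(len(y)), y] + 1e-12).mean()
        reg = sum(layer.reg_penalty() for layer in self.layers)
        return float(ce + reg)

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self._forward(x, train=True)
        loss = -np.log(probs[np.arange(len(y)), y] + 1e-12).mean()
        d = self.classifier.backward_from_labels(y)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        for layer in self.layers:
            layer.add_reg_grads()
        params, grads = [], []
        for layer in [*self.layers, self.classifier]:
            params.extend(layer.params)
            grads.extend(layer.grads)
        self.optimizer.step(params, grads)
        return float(loss)

    def fit_epoch(self, windows: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator) -> float:
        """One shuffled pass at batch size B; returns the mean batch loss."""
        N = len(labels)
        order = rng.permutation(N)
        B = self.spec.batch_size
        losses = []
        seqs = windows[:, 0, :, :]  # (N, w, C)
        for start in range(0, N, B):
            idx = order[start : start + B]
            losses.append(self.train_batch(seqs[idx], labels[idx]))
        return float(np.mean(losses)) if losses else 0.0

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        if windows.ndim != 4 or windows.shape[2] != self.spec.window_size \
                or windows.shape[3] != self.n_channels:
            raise ValueError(
                f"window tensor shape {windows.shape} does not match model input "
                f"(w={self.spec.window_size}, C={self.n_channels})"
            )
        if len(windows) == 0:
            return np.empty((0, self.n_classes))
        B = self.spec.batch_size
        seqs = windows[:, 0, :, :]
        chunks = [
            self._forward(seqs[start : start + B], train=False)
            for start in range(0, len(seqs), B)
        ]
        return np.concatenate(chunks, axis=0)


def build_model(
    spec: TopologySpec,
    n_channels: int,
    n_classes: int,
    rng: np.random.Generator,
    *,
    param_ceiling: int = DEFAULT_PARAM_CEILING,
) -> NetworkModel:
    """Assemble the network a spec describes.

    Raises :class:`InfeasibleTopologyError` when the time axis shrinks below
    one position in the conv stack or the parameter count exceeds
    ``param_ceiling`` (the caller maps either to fitness 0).
    """
    layers: list = []
    t, f = spec.window_size, n_channels
    for conv in spec.conv_layers:
        if t < conv.kernel_size:
            raise InfeasibleTopologyError(
                f"time axis {t} shorter than kernel size {conv.kernel_size}"
            )
        layers.append(nn.Conv1D(f, conv.kernels, conv.kernel_size,
                                conv.activation, rng))
        t = t - conv.kernel_size + 1
        f = conv.kernels
        if conv.pooling > 1:
            if t // conv.pooling < 1:
                raise InfeasibleTopologyError(
                    f"pooling {conv.pooling} collapses time axis {t}"
                )
            layers.append(nn.MaxPool1D(conv.pooling))
            t = t // conv.pooling
    for dense in spec.dense_layers:
        kwargs = dict(
            units=dense.units,
            activation=dense.activation,
            dropout=dense.dropout,
            regularizer=dense.regularizer,
            reg_lambda=REG_LAMBDA,
            rng=rng,
        )
        if dense.layer_type == "feedforward":
            layers.append(nn.FeedForward(t, f, **kwargs))
        elif dense.layer_type == "LSTM":
            layers.append(nn.LSTM(f, **kwargs))
        else:
            layers.append(nn.GRU(f, **kwargs))
        t, f = 1, dense.units
    classifier = nn.SoftmaxClassifier(t, f, n_classes, rng)
    model = NetworkModel(spec, layers, classifier, n_channels, n_classes)
    if model.n_params() > param_ceiling:
        raise InfeasibleTopologyError(
            f"{model.n_params()} parameters exceed ceiling {param_ceiling}"
        )
    return model


@dataclass
class TrainedModel:
    topology: TopologySpec
    model: NetworkModel
    training_log: list[float] = field(default_factory=list)  # per-epoch loss
    validation_f1: float | None = None


def predict(model: NetworkModel, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels plus full probability rows."""
    probs = model.predict_proba(windows)
    labels = probs.argmax(axis=1) if len(probs) else np.empty((0,), dtype=int)
    return labels.astype(int), probs


def proxy_fitness(
    spec: TopologySpec,
    train_windows: WindowedDataset,
    val_windows: WindowedDataset,
    rng: np.random.Generator,
    *,
    epochs: int = 5,
    sample_fraction: float = 0.05,
    param_ceiling: int = DEFAULT_PARAM_CEILING,
) -> float:
    """Abbreviated-training fitness estimate in [0, 1].

    Trains for ``epochs`` epochs, each on a fresh uniform ``sample_fraction``
    sample of the training windows, and returns the weighted F1 on the
    validation windows.  Any infeasibility or numerical failure maps to 0.
    """
    try:
        model = build_model(
            spec, train_windows.n_channels, int(train_windows.labels.max()) + 1,
            rng, param_ceiling=param_ceiling,
        )
        N = train_windows.n_windows
        sample_size = max(1, int(round(sample_fraction * N)))
        for _ in range(epochs):
            idx = rng.choice(N, size=sample_size, replace=False)
            model.fit_epoch(train_windows.tensor[idx], train_windows.labels[idx], rng)
        labels, _ = predict(model, val_windows.tensor)
        score = weighted_f1(val_windows.labels, labels)
        if not np.isfinite(score.f1):
            raise FloatingPointError("non-finite fitness")
        return float(score.f1)
    except InfeasibleTopologyError as exc:
        logger.info("infeasible topology scored 0: %s", exc)
        return 0.0
    except FloatingPointError as exc:
        logger.warning("numerical failure scored 0: %s", exc)
        return 0.0


def full_train(
    spec: TopologySpec,
    train_windows: WindowedDataset,
    rng: np.random.Generator,
    *,
    epochs: int = 30,
    val_windows: WindowedDataset | None = None,
    param_ceiling: int = DEFAULT_PARAM_CEILING,
) -> TrainedModel:
    """Train on the full window set for ``epochs`` epochs.

    Raises :class:`InfeasibleTopologyError` for unbuildable specs.
    """
    n_classes = int(train_windows.labels.max()) + 1
    model = build_model(
        spec, train_windows.n_channels, n_classes, rng, param_ceiling=param_ceiling
    )
    log: list[float] = []
    for _ in range(epochs):
        log.append(model.fit_epoch(train_windows.tensor, train_windows.labels, rng))
    val_f1 = None
    if val_windows is not None:
        labels, _ = predict(model, val_windows.tensor)
        val_f1 = weighted_f1(val_windows.labels, labels).f1
    return TrainedModel(
        topology=spec, model=model, training_log=log, validation_f1=val_f1
    )


def _all_params(model: NetworkModel) -> list[np.ndarray]:
    params: list[np.ndarray] = []
    for layer in [*model.layers, model.classifier]:
        params.extend(layer.params)
    return params


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Checkpoint parameters plus a sidecar phenotype text (``<path>.spec``)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(_all_params(trained.model))}
    arrays["training_log"] = np.asarray(trained.training_log)
    arrays["validation_f1"] = np.asarray(
        np.nan if trained.validation_f1 is None else trained.validation_f1
    )
    arrays["n_channels"] = np.asarray(trained.model.n_channels)
    arrays["n_classes"] = np.asarray(trained.model.n_classes)
    np.savez(path, **arrays)
    path.with_suffix(path.suffix + ".spec").write_text(
        phenotype_to_text(trained.topology) + "\n"
    )


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a checkpointed model (architecture from the sidecar spec)."""
    path = Path(path)
    spec = phenotype_from_text(
        path.with_suffix(path.suffix + ".spec").read_text().strip()
    )
    with np.load(path) as data:
        n_channels = int(data["n_channels"])
        n_classes = int(data["n_classes"])
        model = build_model(
            spec, n_channels, n_classes, np.random.default_rng(0),
            param_ceiling=np.inf,
        )
        for i, p in enumerate(_all_params(model)):
            p[...] = data[f"p{i}"]
        log = [float(x) for x in data["training_log"]]
        val = float(data["validation_f1"])
    return TrainedModel(
        topology=spec,
        model=model,
        training_log=log,
        validation_f1=None if np.isnan(val) else val,
    )
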