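"""The three benchmark architectures and their training loop.

* :func:`build_lstm_model` — embedding -> 12-unit LSTM -> 1 sigmoid unit,
  mean-absolute-error loss (peptide-affinity regression).
* :func:`build_cnn_lstm_model` — the same with a 36-filter, width-9,
  stride-1 convolution between embedding and LSTM.
* :func:`build_siamese_ppi_model` — a shared four-module convolutional
  branch (conv -> ReLU -> batch-norm -> average pooling, global average
  pooling in the last module) applied to both proteins, plus a
  feed-forward head ending in one sigmoid unit, binary cross-entropy loss.

All models are parameterised by an :class:`EmbeddingSpec` choosing between
a trainable embedding and a frozen classical / random matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from . import nn
from .encodings import (
    EncodingMatrix,
    build_blosum62,
    build_one_hot,
    build_random_frozen,
    build_vhse8,
    init_learned,
)


class ModelConfigError(ValueError):
    """An embedding spec or model config that violates its contract."""


@dataclass(frozen=True)
class EmbeddingSpec:
    """How to build the first layer: a learned or frozen token embedding."""

    mode: str  # "learned" | "frozen"
    source: EncodingMatrix | str | None = None  # matrix or scheme name (frozen)
    dim: int | None = None  # required for learned / random_frozen-by-name
    seed: int = 0

    def resolve(self) -> EncodingMatrix:
        if self.mode == "learned":
            if self.dim is None:
                raise ModelConfigError("learned embedding requires dim")
            return init_learned(self.dim, self.seed)
        if self.mode != "frozen":
            raise ModelConfigError(f"unknown embedding mode {self.mode!r}")
        if isinstance(self.source, EncodingMatrix):
            if self.source.trainable:
                raise ModelConfigError("frozen spec given a trainable matrix")
            return self.source
        builders: dict[str, Callable[[], EncodingMatrix]] = {
            "one_hot": build_one_hot,
            "blosum62": build_blosum62,
            "vhse8": build_vhse8,
        }
        if self.source in builders:
            return builders[self.source]()
        if self.source == "random_frozen":
            if self.dim is None:
                raise ModelConfigError("random_frozen by name requires dim")
            return build_random_frozen(self.dim, self.seed)
        raise ModelConfigError(f"frozen spec needs a matrix or scheme name, got {self.source!r}")


@dataclass
class LSTMModelConfig:
    lstm_units: int = 12
    input_length: int = 26
    batch_size: int = 256
    epochs: int = 3000
    learning_rate: float = 1e-3


@dataclass
class CNNLSTMModelConfig(LSTMModelConfig):
    conv_filters: int = 36
    kernel_size: int = 9
    stride: int = 1

    def __post_init__(self) -> None:
        if self.kernel_size > self.input_length:
            raise ModelConfigError("kernel size exceeds input length")


@dataclass
class SiamesePPIConfig:
    """Four conv modules; per-module (filters, kernel) are a documented
    stand-in for unpublished values and fully configurable."""

    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    conv_kernels: tuple[int, ...] = (9, 7, 5, 5)
    pool_width: int = 3
    hidden_units: int = 128
    combiner: str = "concat"  # "concat" | "symmetric"
    input_length: int = 1000
    batch_size: int = 1024
    epochs: int = 50
    learning_rate: float = 1e-3
    bn_momentum: float = 0.9  # faster-adapting running stats for small batches

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ModelConfigError("conv_filters and conv_kernels must align")
        if self.combiner not in ("concat", "symmetric"):
            raise ModelConfigError(f"unknown combiner {self.combiner!r}")


@dataclass
class TrainingHistory:
    """Per-epoch train/validation metrics plus the run's seeds/config."""

    metric_name: str
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    seed: int | None = None
    config: dict | None = None

    def __len__(self) -> int:
        return len(self.train_loss)

    @property
    def best_val_metric(self) -> float:
        return max(self.val_metric)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, (tl, vl, vm) in enumerate(
            zip(self.train_loss, self.val_loss, self.val_metric), start=1
        ):
            rows.append((e, "train", "loss", tl))
            rows.append((e, "val", "loss", vl))
            rows.append((e, "val", self.metric_name, vm))
        return pd.DataFrame(rows, columns=["epoch", "split", "metric", "value"])


def build_embedding_layer(spec: EmbeddingSpec) -> nn.Embedding:
    matrix = spec.resolve()
    return nn.Embedding(matrix.values, trainable=matrix.trainable)


class SequenceRegressor:
    """Single-sequence affinity model: layers -> 1 logit -> sigmoid."""

    loss = "mae"

    def __init__(self, layers: list[nn.Layer], embedding: nn.Embedding,
                 config, embedding_scheme: str):
        self.net = nn.Sequential(layers)
        self.embedding = embedding
        self.config = config
        self.embedding_scheme = embedding_scheme

    def params(self) -> list[nn.Parameter]:
        return self.net.params()

    def forward_logits(self, tokens: np.ndarray, training: bool) -> np.ndarray:
        return self.net.forward(tokens, training)[:, 0]

    def predict(self, tokens: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward_logits(np.asarray(tokens), training=False))

    def train_batch(self, tokens, targets, optimizer) -> float:
        logits = self.forward_logits(tokens, training=True)
        pred = nn.sigmoid(logits)
        loss, dpred = nn.mae_loss(pred, targets)
        dlogits = dpred * pred * (1.0 - pred)
        optimizer.zero_grad()
        self.net.backward(dlogits[:, None])
        optimizer.step()
        return loss

    def eval_loss(self, tokens, targets) -> float:
        return float(np.mean(np.abs(self.predict(tokens) - targets)))


def _check_tokens(tokens: np.ndarray, expected_length: int, what: str) -> np.ndarray:
    tokens = np.asarray(tokens)
    if tokens.ndim != 2 or tokens.shape[1] != expected_length:
        raise ModelConfigError(
            f"{what}: expected token array of shape (n, {expected_length}), got {tokens.shape}"
        )
    return tokens


def build_lstm_model(embedding_spec: EmbeddingSpec,
                     config: LSTMModelConfig | None = None,
                     seed: int = 0) -> SequenceRegressor:
    config = config or LSTMModelConfig()
    rng = np.random.default_rng(seed)
    emb = build_embedding_layer(embedding_spec)
    dim = emb.W.value.shape[1]
    layers: list[nn.Layer] = [
        emb,
        nn.LSTM(dim, config.lstm_units, rng),
        nn.Dense(config.lstm_units, 1, rng),
    ]
    return SequenceRegressor(layers, emb, config, _scheme_of(embedding_spec))


def build_cnn_lstm_model(embedding_spec: EmbeddingSpec,
                         config: CNNLSTMModelConfig | None = None,
                         seed: int = 0) -> SequenceRegressor:
    config = config or CNNLSTMModelConfig()
    rng = np.random.default_rng(seed)
    emb = build_embedding_layer(embedding_spec)
    dim = emb.W.value.shape[1]
    layers: list[nn.Layer] = [
        emb,
        nn.Conv1D(dim, config.conv_filters, config.kernel_size, config.stride, rng),
        nn.LSTM(config.conv_filters, config.lstm_units, rng),
        nn.Dense(config.lstm_units, 1, rng),
    ]
    return SequenceRegressor(layers, emb, config, _scheme_of(embedding_spec))


def _scheme_of(spec: EmbeddingSpec) -> str:
    if spec.mode == "learned":
        return "learned"
    if isinstance(spec.source, EncodingMatrix):
        return spec.source.scheme
    return str(spec.source)


class SiamesePPIModel:
    """Weight-shared convolutional branch over both proteins + MLP head.

    The two proteins are pushed through the branch as one concatenated
    batch, so batch-norm statistics are computed over both members of each
    pair jointly.
    """

    loss = "bce"

    def __init__(self, branch: nn.Sequential, head: nn.Sequential,
                 embedding: nn.Embedding, config: SiamesePPIConfig,
                 embedding_scheme: str):
        self.branch = branch
        self.head = head
        self.embedding = embedding
        self.config = config
        self.embedding_scheme = embedding_scheme

    def params(self) -> list[nn.Parameter]:
        return self.branch.params() + self.head.params()

    def _combine(self, za: np.ndarray, zb: np.ndarray) -> np.ndarray:
        if self.config.combiner == "concat":
            return np.concatenate([za, zb], axis=1)
        return np.concatenate([za * zb, np.abs(za - zb)], axis=1)

    def forward_logits(self, tokens_a, tokens_b, training: bool) -> np.ndarray:
        both = np.concatenate([tokens_a, tokens_b], axis=0)
        z = self.branch.forward(both, training)
        za, zb = np.split(z, 2, axis=0)
        self._za, self._zb = za, zb
        return self.head.forward(self._combine(za, zb), training)[:, 0]

    def _backward(self, dlogits: np.ndarray) -> None:
        dcomb = self.head.backward(dlogits[:, None])
        za, zb = self._za, self._zb
        k = za.shape[1]
        if self.config.combiner == "concat":
            dza, dzb = dcomb[:, :k], dcomb[:, k:]
        else:
            dprod, ddiff = dcomb[:, :k], dcomb[:, k:]
            sgn = np.sign(za - zb)
            dza = dprod * zb + ddiff * sgn
            dzb = dprod * za - ddiff * sgn
        self.branch.backward(np.concatenate([dza, dzb], axis=0))

    def predict(self, tokens_a, tokens_b) -> np.ndarray:
        return nn.sigmoid(
            self.forward_logits(np.asarray(tokens_a), np.asarray(tokens_b), training=False)
        )

    def train_batch(self, inputs, targets, optimizer) -> float:
        tokens_a, tokens_b = inputs
        logits = self.forward_logits(tokens_a, tokens_b, training=True)
        loss, dlogits = nn.bce_loss_from_logits(logits, targets)
        optimizer.zero_grad()
        self._backward(dlogits)
        optimizer.step()
        return loss

    def eval_loss(self, inputs, targets) -> float:
        p = self.predict(*inputs)
        eps = 1e-12
        return float(-np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)))


def build_siamese_ppi_model(embedding_spec: EmbeddingSpec,
                            config: SiamesePPIConfig | None = None,
                            seed: int = 0) -> SiamesePPIModel:
    config = config or SiamesePPIConfig()
    rng = np.random.default_rng(seed)
    emb = build_embedding_layer(embedding_spec)
    dim = emb.W.value.shape[1]
    layers: list[nn.Layer] = [emb]
    in_ch = dim
    n_modules = len(config.conv_filters)
    for m, (filt, kern) in enumerate(zip(config.conv_filters, config.conv_kernels)):
        layers.append(nn.Conv1D(in_ch, filt, kern, stride=1, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.BatchNorm(filt, momentum=config.bn_momentum))
        if m < n_modules - 1:
            layers.append(nn.AvgPool(config.pool_width))
        else:
            layers.append(nn.GlobalAvgPool())
        in_ch = filt
    branch = nn.Sequential(layers)
    head = nn.Sequential([
        nn.Dense(2 * in_ch, config.hidden_units, rng),
        nn.ReLU(),
        nn.Dense(config.hidden_units, 1, rng),
    ])
    return SiamesePPIModel(branch, head, emb, config, _scheme_of(embedding_spec))


def _metric_fn(name: str) -> Callable[[np.ndarray, np.ndarray], float]:
    from .evaluation import compute_accuracy, compute_auc

    if name == "auc":
        from .prep import BINDER_THRESHOLD

        return lambda scores, targets: compute_auc(
            scores, (np.asarray(targets) >= BINDER_THRESHOLD).astype(int)
        )
    if name == "accuracy":
        return lambda scores, targets: compute_accuracy(scores, np.asarray(targets).astype(int))
    raise ValueError(f"unknown metric {name!r}")


def _as_inputs(data) -> tuple:
    """Accepts (inputs, targets) where inputs is an array or a pair."""
    inputs, targets = data
    return inputs, np.asarray(targets, dtype=float)


def train_model(model, train_data, val_data, epochs: int, seed: int = 0,
                batch_size: int | None = None, metric: str | None = None,
                stop_threshold: float | None = None) -> TrainingHistory:
    """Seeded mini-batch training; records val loss and metric per epoch.

    ``metric`` defaults to AUC for affinity regressors (targets binarised
    at the binder threshold) and accuracy for pair classifiers.
    ``stop_threshold`` optionally ends training early once the validation
    metric reaches the given value (used by scaled-down test profiles).
    """
    if metric is None:
        metric = "auc" if model.loss == "mae" else "accuracy"
    metric_fn = _metric_fn(metric)
    batch_size = batch_size or model.config.batch_size
    train_inputs, train_targets = _as_inputs(train_data)
    val_inputs, val_targets = _as_inputs(val_data)
    paired = isinstance(model, SiamesePPIModel)
    if paired:
        if not (isinstance(train_inputs, (tuple, list)) and len(train_inputs) == 2):
            raise ModelConfigError("PPI model expects inputs as a (tokens_a, tokens_b) pair")
        ta = _check_tokens(train_inputs[0], model.config.input_length, "train tokens_a")
        tb = _check_tokens(train_inputs[1], model.config.input_length, "train tokens_b")
        train_inputs = (ta, tb)
        val_inputs = (
            _check_tokens(val_inputs[0], model.config.input_length, "val tokens_a"),
            _check_tokens(val_inputs[1], model.config.input_length, "val tokens_b"),
        )
        n = ta.shape[0]
    else:
        train_inputs = _check_tokens(train_inputs, model.config.input_length, "train tokens")
        val_inputs = _check_tokens(val_inputs, model.config.input_length, "val tokens")
        n = train_inputs.shape[0]
    if len(train_targets) != n:
        raise ModelConfigError(f"{n} inputs but {len(train_targets)} targets")

    optimizer = nn.Adam(model.params(), lr=model.config.learning_rate)
    rng = np.random.default_rng(seed)
    history = TrainingHistory(metric_name=metric, seed=seed, config=asdict(model.config))
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if paired:
                batch_in = (train_inputs[0][idx], train_inputs[1][idx])
            else:
                batch_in = train_inputs[idx]
            losses.append(model.train_batch(batch_in, train_targets[idx], optimizer))
        val_scores = model.predict(*val_inputs) if paired else model.predict(val_inputs)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(model.eval_loss(val_inputs, val_targets))
        history.val_metric.append(float(metric_fn(val_scores, val_targets)))
        if stop_threshold is not None and history.val_metric[-1] >= stop_threshold:
            break
    return history


def extract_embedding(model) -> EncodingMatrix:
    """The model's current 21 x d embedding matrix, tagged by scheme."""
    emb = getattr(model, "embedding", None)
    if emb is None:
        raise ModelConfigError("model has no embedding layer")
    scheme = model.embedding_scheme
    return EncodingMatrix(scheme, emb.W.value.copy(), trainable=emb.W.trainable)
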