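"""The five call classifiers and their training protocol.

Every network consumes one call's fixed-size feature matrix (110x513,
110x160 or 110x52 - the builders are shape-agnostic) and emits a single
sigmoid probability of "cock".  All share the same fully-connected head:
dense 64 -> dropout 0.2 -> dense 32 -> 1-unit sigmoid output.

* cnn       three [3x3 conv (64 filters) -> 3x3 max-pool] blocks, flattened;
* gru       two stacked 64-unit GRU layers, last time step;
* crnn      the conv stack, re-arranged time-first, feeding the GRU stack;
* twostream conv branch and GRU branch side by side, concatenated;
* resnet50  the standard 4-stage bottleneck residual network (3/4/6/3
            blocks), input replicated to 3 channels, with a width
            multiplier for desk-scale variants and optional externally
            sourced pretrained weights.

Training is Adam on binary cross-entropy with early stopping monitored on
validation accuracy (patience 100 epochs by default); the best epoch's
parameters are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chickcall.errors import ParameterError, ShapeError
from chickcall.nn.autograd import concat
from chickcall.nn.layers import (
    BatchNorm2d, Conv2d, Dense, Dropout, Flatten, GRU, MaxPool2d, Module, ReLU, Sequential,
)
from chickcall.nn.training import TrainHistory, fit, predict_logits

ARCHITECTURES = ("cnn", "gru", "crnn", "twostream", "resnet50")


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``width_multiplier`` scales conv-filter and GRU-unit counts (minimum 1)
    so the same topologies run at desk scale; 1.0 reproduces the full sizes.
    """

    architecture: str = "cnn"
    conv_filters: int = 64
    conv_kernel: int = 3
    pool: int = 3
    gru_units: int = 64
    head: tuple[int, int] = (64, 32)
    dropout: float = 0.2
    width_multiplier: float = 1.0
    pretrained_weights: str | None = None  # resnet50 only; optional npz
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ParameterError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if not 0 < self.width_multiplier <= 1:
            raise ParameterError("width_multiplier must be in (0, 1]")

    def scaled(self, n: int) -> int:
        return max(1, int(round(n * self.width_multiplier)))


@dataclass
class TrainConfig:
    """Optimization protocol (Adam; early stopping on validation accuracy)."""

    patience: int = 100
    max_epochs: int = 2000
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")


class Head(Module):
    """dense 64 -> dropout 0.2 -> dense 32 -> 1-unit output (logit)."""

    def __init__(self, n_in: int, config: ModelConfig, rng):
        super().__init__()
        h1, h2 = config.head
        self.fc1 = Dense(n_in, h1, rng)
        self.drop = Dropout(config.dropout, rng)
        self.fc2 = Dense(h1, h2, rng)
        self.out = Dense(h2, 1, rng)

    def forward(self, x):
        x = self.fc1(x).relu()
        x = self.drop(x)
        x = self.fc2(x).relu()
        return self.out(x)


def _conv_stack(config: ModelConfig, rng) -> tuple[Sequential, int]:
    """Three same-padded conv(3x3) + pool(3x3) blocks; returns (stack, filters)."""
    f = config.scaled(config.conv_filters)
    pad = config.conv_kernel // 2
    layers, c_in = [], 1
    for _ in range(3):
        layers += [Conv2d(c_in, f, config.conv_kernel, rng, pad=pad), ReLU(),
                   MaxPool2d(config.pool)]
        c_in = f
    return Sequential(*layers), f


def _pooled_dims(t: int, d: int, pool: int, n_blocks: int = 3) -> tuple[int, int]:
    for _ in range(n_blocks):
        t, d = t // pool, d // pool
        if t < 1 or d < 1:
            raise ShapeError(
                f"feature shape too small for {n_blocks} {pool}x{pool} pool stages"
            )
    return t, d


class CNNClassifier(Module):
    def __init__(self, config: ModelConfig, feature_shape: tuple[int, int]):
        super().__init__()
        self.config, self.feature_shape = config, tuple(feature_shape)
        rng = np.random.default_rng(config.seed)
        t, d = feature_shape
        self.conv, f = _conv_stack(config, rng)
        to, do = _pooled_dims(t, d, config.pool)
        self.flatten = Flatten()
        self.head = Head(f * to * do, config, rng)

    def forward(self, x):
        n, t, d = x.shape
        h = self.conv(x.reshape(n, 1, t, d))
        return self.head(self.flatten(h))


class GRUClassifier(Module):
    def __init__(self, config: ModelConfig, feature_shape: tuple[int, int]):
        super().__init__()
        self.config, self.feature_shape = config, tuple(feature_shape)
        rng = np.random.default_rng(config.seed)
        u = config.scaled(config.gru_units)
        self.gru1 = GRU(feature_shape[1], u, rng, return_sequences=True)
        self.gru2 = GRU(u, u, rng, return_sequences=False)  # last time step
        self.head = Head(u, config, rng)

    def forward(self, x):
        return self.head(self.gru2(self.gru1(x)))


class CRNNClassifier(Module):
    """Conv stack, then the pooled map re-arranged time-first for the GRUs."""

    def __init__(self, config: ModelConfig, feature_shape: tuple[int, int]):
        super().__init__()
        self.config, self.feature_shape = config, tuple(feature_shape)
        rng = np.random.default_rng(config.seed)
        t, d = feature_shape
        self.conv, f = _conv_stack(config, rng)
        to, do = _pooled_dims(t, d, config.pool)
        u = config.scaled(config.gru_units)
        self.gru1 = GRU(f * do, u, rng, return_sequences=True)
        self.gru2 = GRU(u, u, rng, return_sequences=False)
        self.head = Head(u, config, rng)

    def forward(self, x):
        n, t, d = x.shape
        h = self.conv(x.reshape(n, 1, t, d))  # (N, F, T', D')
        _, f, to, do = h.shape
        # time-flatten: keep temporal order, fold channels x frequency
        h = h.transpose((0, 2, 1, 3)).reshape(n, to, f * do)
        return self.head(self.gru2(self.gru1(h)))


class TwoStreamClassifier(Module):
    """Independent conv and GRU branches, concatenated before the head."""

    def __init__(self, config: ModelConfig, feature_shape: tuple[int, int]):
        super().__init__()
        self.config, self.feature_shape = config, tuple(feature_shape)
        rng = np.random.default_rng(config.seed)
        t, d = feature_shape
        self.conv, f = _conv_stack(config, rng)
        to, do = _pooled_dims(t, d, config.pool)
        self.flatten = Flatten()
        u = config.scaled(config.gru_units)
        self.gru1 = GRU(d, u, rng, return_sequences=True)
        self.gru2 = GRU(u, u, rng, return_sequences=False)
        self.head = Head(f * to * do + u, config, rng)

    def forward(self, x):
        n, t, d = x.shape
        conv_out = self.flatten(self.conv(x.reshape(n, 1, t, d)))
        gru_out = self.gru2(self.gru1(x))
        return self.head(concat([conv_out, gru_out], axis=1))


class Bottleneck(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand, batch-normalized, with shortcut."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, stride: int, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_mid, 1, rng, stride=stride)
        self.bn1 = BatchNorm2d(c_mid)
        self.conv2 = Conv2d(c_mid, c_mid, 3, rng, pad=1)
        self.bn2 = BatchNorm2d(c_mid)
        self.conv3 = Conv2d(c_mid, c_out, 1, rng)
        self.bn3 = BatchNorm2d(c_out)
        self.downsample = None
        if stride != 1 or c_in != c_out:
            self.downsample = Sequential(Conv2d(c_in, c_out, 1, rng, stride=stride),
                                         BatchNorm2d(c_out))

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        shortcut = x if self.downsample is None else self.downsample(x)
        return (h + shortcut).relu()


class ResNet50Classifier(Module):
    """4-stage bottleneck residual network (3/4/6/3 blocks), width-scalable."""

    block_counts = (3, 4, 6, 3)

    def __init__(self, config: ModelConfig, feature_shape: tuple[int, int]):
        super().__init__()
        self.config, self.feature_shape = config, tuple(feature_shape)
        rng = np.random.default_rng(config.seed)
        c0 = config.scaled(64)
        self.stem_conv = Conv2d(3, c0, 7, rng, stride=2, pad=3)
        self.stem_bn = BatchNorm2d(c0)
        self.stem_pool = MaxPool2d(3, stride=2, pad=1)
        stages = []
        c_in = c0
        for stage, (n_blocks, base) in enumerate(zip(self.block_counts, (64, 128, 256, 512))):
            c_mid, c_out = config.scaled(base), 4 * config.scaled(base)
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                stages.append(Bottleneck(c_in, c_mid, c_out, stride, rng))
                c_in = c_out
        self.stages = stages
        self.head = Head(c_in, config, rng)
        if config.pretrained_weights:
            self.load_weights(config.pretrained_weights)

    def forward(self, x):
        n, t, d = x.shape
        h = x.reshape(n, 1, t, d)
        h = concat([h, h, h], axis=1)  # replicate to three channels
        h = self.stem_pool(self.stem_bn(self.stem_conv(h)).relu())
        for block in self.stages:
            h = block(h)
        h = h.mean(axis=(2, 3))  # global average pool
        return self.head(h)


_BUILDERS = {
    "cnn": CNNClassifier,
    "gru": GRUClassifier,
    "crnn": CRNNClassifier,
    "twostream": TwoStreamClassifier,
    "resnet50": ResNet50Classifier,
}


def build_model(config: ModelConfig, feature_shape: tuple[int, int]) -> Module:
    """Construct a classifier for (T, D) feature matrices, seeded from config."""
    if len(feature_shape) != 2:
        raise ShapeError(f"feature_shape must be (T, D), got {feature_shape}")
    return _BUILDERS[config.architecture](config, feature_shape)


def train(
    classifier: Module,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> tuple[Module, TrainHistory]:
    """Adam + early-stopping training; labels are binary (cock=1, hen=0)."""
    if config is None:
        config = TrainConfig()
    history = fit(
        classifier, train_set, val_set,
        max_epochs=config.max_epochs, patience=config.patience,
        batch_size=config.batch_size, lr=config.learning_rate,
        seed=config.seed, verbose=config.verbose,
    )
    return classifier, history


def predict_calls(classifier: Module, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-call sigmoid probabilities and hard labels (1 = cock)."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or tuple(x.shape[1:]) != tuple(classifier.feature_shape):
        raise ShapeError(
            f"features of shape {x.shape} do not match classifier input "
            f"{classifier.feature_shape}"
        )
    logits = predict_logits(classifier, x)
    probs = 0.5 * (1.0 + np.tanh(0.5 * logits))
    return probs, (probs > 0.5).astype(int)
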