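"""Binary window classifiers: configuration, construction and training.

A :class:`ModelConfig` is one point in the hyperparameter search space: the
dense stack (depth, units, tanh/selu activations), optional 1-D convolution
(filters, window, selu/sigmoid activation, optional max pooling), optional
LSTM, the optimizer family and learning rate, batch size, history length and
the selected sensor channels.  :func:`build_network` wires it into a network
accepting ``(batch, window_length, n_channels)`` input:

    [conv (+ pooling)] -> [LSTM] -> dense stack -> 1-unit sigmoid head

When no LSTM is present the dense layers act time-distributed over the
window and the result is flattened before the head.

Training minimises binary cross-entropy with dropout after each hidden dense
layer and early stopping on validation loss (best-epoch weights restored);
the model's figure of merit is its validation AUC.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy.special import expit

from gaitcascade import _net
from gaitcascade.events import CHANNELS
from gaitcascade.windowing import (
    BinarySplit,
    ChannelSelector,
    MAX_WINDOW,
    MIN_WINDOW,
    WindowSample,
)

EPSILON = 1e-7  # probability clip for the loss

ACTIVATIONS = ("tanh", "selu")
CONV_ACTIVATIONS = ("selu", "sigmoid")
OPTIMIZERS = ("sgd", "adam", "rmsprop")
LEARNING_RATES = (0.1, 0.01, 0.001)


class ConfigError(ValueError):
    """A ModelConfig violates the search-space constraints."""


@dataclass(frozen=True)
class ModelConfig:
    """One point in the architecture / training-hyperparameter search space."""

    n_dense_layers: int
    units_per_layer: tuple[int, ...]
    activation_per_layer: tuple[str, ...]
    use_conv: bool = False
    conv_filters: int = 1
    conv_window: int = 2
    conv_activation: str = "selu"
    use_pooling: bool = False
    use_lstm: bool = False
    lstm_units: int = 1
    learning_rate: float = 0.001
    optimizer: str = "adam"
    batch_size: int = 32
    window_length: int = 32
    selected_channels: tuple[str, ...] = CHANNELS
    dropout: float = 0.2

    def __post_init__(self):
        object.__setattr__(self, "units_per_layer", tuple(self.units_per_layer))
        object.__setattr__(
            self, "activation_per_layer", tuple(self.activation_per_layer)
        )
        object.__setattr__(
            self, "selected_channels", tuple(self.selected_channels)
        )
        self.validate()

    def validate(self) -> None:
        if not (1 <= self.n_dense_layers <= 11):
            raise ConfigError(f"n_dense_layers must be in [1, 11], got {self.n_dense_layers}")
        if len(self.units_per_layer) != self.n_dense_layers:
            raise ConfigError(
                f"units_per_layer has {len(self.units_per_layer)} entries for "
                f"{self.n_dense_layers} layers"
            )
        if len(self.activation_per_layer) != self.n_dense_layers:
            raise ConfigError(
                f"activation_per_layer has {len(self.activation_per_layer)} entries "
                f"for {self.n_dense_layers} layers"
            )
        if any(not (1 <= u <= 64) for u in self.units_per_layer):
            raise ConfigError(f"units must be in [1, 64], got {self.units_per_layer}")
        if any(a not in ACTIVATIONS for a in self.activation_per_layer):
            raise ConfigError(f"activations must be in {ACTIVATIONS}")
        if self.use_conv:
            if not (1 <= self.conv_filters <= 50):
                raise ConfigError(f"conv_filters must be in [1, 50], got {self.conv_filters}")
            if not (2 <= self.conv_window <= 32):
                raise ConfigError(f"conv_window must be in [2, 32], got {self.conv_window}")
            if self.conv_activation not in CONV_ACTIVATIONS:
                raise ConfigError(f"conv_activation must be in {CONV_ACTIVATIONS}")
        if self.use_lstm and not (1 <= self.lstm_units <= 50):
            raise ConfigError(f"lstm_units must be in [1, 50], got {self.lstm_units}")
        if self.optimizer not in OPTIMIZERS:
            raise ConfigError(f"optimizer must be in {OPTIMIZERS}")
        if not (1 <= self.batch_size <= 50):
            raise ConfigError(f"batch_size must be in [1, 50], got {self.batch_size}")
        if not (MIN_WINDOW <= self.window_length <= MAX_WINDOW):
            raise ConfigError(
                f"window_length must be in [{MIN_WINDOW}, {MAX_WINDOW}], "
                f"got {self.window_length}"
            )
        if not self.selected_channels:
            raise ConfigError("selected_channels must be non-empty")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def selector(self) -> ChannelSelector:
        return ChannelSelector(
            selected=self.selected_channels, window_length=self.window_length
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units_per_layer"] = list(self.units_per_layer)
        d["activation_per_layer"] = list(self.activation_per_layer)
        d["selected_channels"] = list(self.selected_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def cross_entropy(
    labels: Sequence[int], probabilities: Sequence[float], eps: float = EPSILON
) -> float:
    """Mean binary cross-entropy, natural log, probabilities clipped to [eps, 1-eps].

    E = -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    if y.size == 0:
        raise ValueError("cross_entropy needs at least one observation")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def build_network(config: ModelConfig, seed: int = 0) -> _net.Network:
    """Assemble an untrained network for the configured input shape.

    Raises :class:`ConfigError` when the conv window exceeds the window
    length (such a convolution has no valid placement).
    """
    w = config.window_length
    c = len(config.selected_channels)
    if config.use_conv and config.conv_window > w:
        raise ConfigError(
            f"conv_window {config.conv_window} exceeds window_length {w}"
        )
    rng = np.random.default_rng(seed)
    layers: list[_net.Layer] = []
    time_steps: int | None = w
    features = c

    if config.use_conv:
        layers.append(
            _net.Conv1D(features, config.conv_filters, config.conv_window,
                        config.conv_activation, rng)
        )
        time_steps = w - config.conv_window + 1
        features = config.conv_filters
        if config.use_pooling and time_steps >= 2:
            layers.append(_net.MaxPool1D(2))
            time_steps //= 2

    if config.use_lstm:
        layers.append(_net.LSTM(features, config.lstm_units, rng))
        time_steps = None
        features = config.lstm_units

    for units, act in zip(config.units_per_layer, config.activation_per_layer):
        layers.append(_net.Dense(features, units, act, rng))
        features = units
        if config.dropout > 0:
            layers.append(_net.Dropout(config.dropout))

    if time_steps is not None:
        layers.append(_net.Flatten())
        features = features * time_steps

    layers.append(_net.Dense(features, 1, "linear", rng))
    return _net.Network(layers, input_shape=(w, c))


@dataclass
class ChannelScaler:
    """Per-channel standardisation fitted on the training windows."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "ChannelScaler":
        mean = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        return cls(mean=mean, std=np.maximum(std, 1e-8))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


@dataclass
class TrainedModel:
    """A trained binary classifier plus everything needed to reuse it."""

    config: ModelConfig
    network: _net.Network
    scaler: ChannelScaler
    training_history: dict[str, list[float]]
    validation_auc: float
    node_name: str = ""

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """Class-1 probabilities for raw (unstandardised) windows.

        Accepts a single ``(w, c)`` window or a ``(batch, w, c)`` stack.
        """
        x = np.asarray(windows, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        p = self.network.predict_proba(self.scaler.transform(x))
        return float(p[0]) if single else p

    def predict_sample(self, sample: WindowSample) -> float:
        return self.predict_proba(sample.view(self.config.selector))


def _to_arrays(
    pairs: Sequence[tuple[WindowSample, int]], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    sel = config.selector
    X = np.stack([s.view(sel) for s, _ in pairs])
    y = np.array([label for _, label in pairs], dtype=float)
    return X, y


def train(
    network: _net.Network,
    split: BinarySplit,
    config: ModelConfig,
    patience: int = 10,
    max_epochs: int = 100,
    seed: int = 0,
) -> TrainedModel:
    """Train one binary node model with early stopping on validation loss.

    Expects a :class:`BinarySplit` (a DatasetSplit relabelled for one cascade
    node).  Optimises cross-entropy with the configured optimizer, learning
    rate and batch size; stops once validation loss has not improved for
    ``patience`` epochs and restores the best-epoch weights; then records the
    validation AUC exactly once.

    Raises ``ValueError`` naming the node when the training set contains a
    single class.
    """
    from gaitcascade.evaluation import auc as _auc

    if not split.train or not split.validation:
        raise ValueError(f"node {split.node_name!r}: empty train or validation set")
    X_train, y_train = _to_arrays(split.train, config)
    X_val, y_val = _to_arrays(split.validation, config)
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            f"node {split.node_name!r}: training set contains a single class"
        )

    scaler = ChannelScaler.fit(X_train)
    X_train = scaler.transform(X_train)
    X_val = scaler.transform(X_val)

    rng = np.random.default_rng(seed)
    optimizer = _net.make_optimizer(config.optimizer, config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = network.get_weights()
    epochs_since_best = 0

    n = len(y_train)
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            logits = network.forward(xb, training=True, rng=rng)
            p = expit(logits)
            epoch_loss += cross_entropy(yb, p) * len(idx)
            network.backward((p - yb) / len(idx))
            optimizer.step(network)
        history["train_loss"].append(epoch_loss / n)

        val_loss = cross_entropy(y_val, network.predict_proba(X_val))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = network.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= patience:
                break

    network.set_weights(best_weights)
    val_scores = network.predict_proba(X_val)
    try:
        validation_auc = _auc(y_val.astype(int), val_scores)
    except ValueError:
        validation_auc = float("nan")  # validation set degenerate (single class)

    return TrainedModel(
        config=config,
        network=network,
        scaler=scaler,
        training_history=history,
        validation_auc=validation_auc,
        node_name=split.node_name,
    )


# --- bundled best-model configurations --------------------------------------

FIXTURE_NAMES = (
    "standing_vs_seated",
    "moving_vs_still",
    "stumbling_vs_not",
    "unbalanced_vs_stable",
    "running_vs_walking",
)


@dataclass
class FixtureConfig:
    """A bundled best-model configuration plus integrity flags.

    ``flags`` lists the inconsistencies found in the published configuration
    as printed (they are reported, never silently cleared); ``config`` is the
    buildable form after the documented repairs.
    """

    name: str
    config: ModelConfig
    flags: list[str] = field(default_factory=list)
    raw: dict = field(default_factory=dict)


def load_fixture_config(name: str) -> FixtureConfig:
    """Load one of the five bundled node configurations by name.

    Two of the published configurations are internally inconsistent and are
    flagged here: the unbalanced model's printed units list has 9 entries for
    11 layers (with values outside the [1, 64] search bound); building uses
    the documented comma-split repair stored alongside the printed list.  The
    stumbling model's conv window (10) exceeds its window length (4) and is
    clamped to the window length.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = importlib.resources.files("gaitcascade") / "fixtures" / f"{name}.yaml"
    raw = yaml.safe_load(ref.read_text())

    flags: list[str] = []
    units = raw["units_per_layer"]
    if "units_per_layer_repaired" in raw:
        flags.append(
            "units_list_length_mismatch: printed units list "
            f"{units} has {len(units)} entries for {raw['n_dense_layers']} layers; "
            "building with the documented repaired variant "
            f"{raw['units_per_layer_repaired']}"
        )
        units = raw["units_per_layer_repaired"]

    conv_window = raw.get("conv_window", 2)
    if raw.get("use_conv") and conv_window > raw["window_length"]:
        flags.append(
            f"conv_window_exceeds_window_length: printed conv window {conv_window} "
            f"> window length {raw['window_length']}; clamped to the window length"
        )
        conv_window = raw["window_length"]

    config = ModelConfig(
        n_dense_layers=raw["n_dense_layers"],
        units_per_layer=tuple(units),
        activation_per_layer=tuple(raw["activation_per_layer"]),
        use_conv=raw.get("use_conv", False),
        conv_filters=raw.get("conv_filters", 1),
        conv_window=conv_window,
        conv_activation=raw.get("conv_activation", "selu"),
        use_pooling=raw.get("use_pooling", False),
        use_lstm=raw.get("use_lstm", False),
        lstm_units=raw.get("lstm_units", 1),
        learning_rate=raw["learning_rate"],
        optimizer=raw["optimizer"],
        batch_size=raw["batch_size"],
        window_length=raw["window_length"],
        selected_channels=tuple(raw["selected_channels"]),
    )
    return FixtureConfig(name=name, config=config, flags=flags, raw=raw)


def load_all_fixture_configs() -> dict[str, FixtureConfig]:
    return {name: load_fixture_config(name) for name in FIXTURE_NAMES}
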