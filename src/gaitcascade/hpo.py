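"""Hyperparameter search per cascade node and the ranked model registry.

The search space covers the dense-stack depth and per-layer units and
activations, optional convolution/pooling/LSTM blocks with their own
hyperparameters, the optimizer family and learning rate, batch size, the
history length (4–32 previous timestamps) and a free subset of the 20 sensor
channels.  Candidates are drawn either uniformly at random or by a
tree-structured Parzen estimator (TPE): after a random start-up phase each
parameter is sampled from a density fitted to the best-performing fraction
of past trials and scored against the density of the rest, preferring values
that look like past winners.

Every trained trial is inserted into a :class:`ModelRegistry` that keeps,
per node, all models sorted by validation AUC (stable: ties keep trial
order).  The registry is what keeps the detector alive when hardware fails:
:func:`best_without` returns the best-ranked model that does not read any
failed channel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from gaitcascade.ann import (
    ACTIVATIONS,
    CONV_ACTIVATIONS,
    LEARNING_RATES,
    OPTIMIZERS,
    ModelConfig,
    TrainedModel,
    build_network,
    train,
)
from gaitcascade.events import CHANNELS
from gaitcascade.windowing import BinarySplit, DatasetSplit, relabel_split

logger = logging.getLogger(__name__)


class NodeUnavailableError(RuntimeError):
    """No registered model for a node avoids the failed channels."""

    def __init__(self, node: str, failed_channels: Iterable[str]):
        self.node = node
        self.failed_channels = frozenset(failed_channels)
        super().__init__(
            f"node {node!r} unavailable: every registered model reads one of "
            f"the failed channels {sorted(self.failed_channels)}"
        )


@dataclass(frozen=True)
class SearchSpec:
    """One node's search request: trial budget, sampler and seed."""

    node_name: str
    n_trials: int = 50
    sampler: str = "tpe"
    seed: int = 0
    max_epochs: int = 30
    patience: int = 5

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sampler not in ("tpe", "random"):
            raise ValueError(f"sampler must be 'tpe' or 'random', got {self.sampler!r}")


# --- samplers ----------------------------------------------------------------

def sample_config(rng: np.random.Generator, max_window: int = 32) -> ModelConfig:
    """Draw one configuration uniformly from the search space.

    Each of the 20 channels is toggled independently with probability 1/2,
    with at least one forced on; the conv window is drawn from [2, window]
    so every sampled configuration is buildable.
    """
    n_dense = int(rng.integers(1, 12))
    units = tuple(int(u) for u in rng.integers(1, 65, n_dense))
    acts = tuple(str(rng.choice(ACTIVATIONS)) for _ in range(n_dense))
    window = int(rng.integers(4, max_window + 1))
    use_conv = bool(rng.integers(2))
    use_lstm = bool(rng.integers(2))
    mask = rng.random(len(CHANNELS)) < 0.5
    if not mask.any():
        mask[rng.integers(len(CHANNELS))] = True
    channels = tuple(c for c, m in zip(CHANNELS, mask) if m)
    return ModelConfig(
        n_dense_layers=n_dense,
        units_per_layer=units,
        activation_per_layer=acts,
        use_conv=use_conv,
        conv_filters=int(rng.integers(1, 51)),
        conv_window=int(rng.integers(2, window + 1)),
        conv_activation=str(rng.choice(CONV_ACTIVATIONS)),
        use_pooling=bool(rng.integers(2)),
        use_lstm=use_lstm,
        lstm_units=int(rng.integers(1, 51)),
        learning_rate=float(rng.choice(LEARNING_RATES)),
        optimizer=str(rng.choice(OPTIMIZERS)),
        batch_size=int(rng.integers(1, 51)),
        window_length=window,
        selected_channels=channels,
    )


class TPESampler:
    """Univariate tree-structured Parzen estimator over the search space.

    Completed trials are split into the best ``gamma`` fraction ("good") and
    the rest ("bad").  For each scalar parameter, candidates are drawn from a
    Parzen (kernel-density) model of the good values and ranked by the
    likelihood ratio good/bad; categorical parameters use smoothed category
    frequencies.  The first ``n_startup`` trials are uniform random.
    """

    def __init__(self, seed: int = 0, n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24, max_window: int = 32):
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.max_window = max_window
        self.history: list[tuple[ModelConfig, float]] = []

    def tell(self, config: ModelConfig, value: float) -> None:
        self.history.append((config, value))

    # numeric helper: sample candidates from good KDE, score by l/g
    def _numeric(self, good: np.ndarray, bad: np.ndarray, lo: int, hi: int) -> int:
        bw = max(good.std(), (hi - lo) / 10.0, 1.0)
        centers = self.rng.choice(good, self.n_candidates)
        cand = np.clip(
            np.rint(centers + self.rng.normal(0, bw, self.n_candidates)), lo, hi
        )

        def dens(xs, x):
            return np.mean(np.exp(-0.5 * ((x[:, None] - xs[None, :]) / bw) ** 2), axis=1) + 1e-12

        score = dens(good, cand) / dens(bad, cand) if bad.size else dens(good, cand)
        return int(cand[int(np.argmax(score))])

    def _categorical(self, good: list, bad: list, choices: Sequence):
        def weights(values):
            w = np.array([1.0 + sum(v == c for v in values) for c in choices])
            return w / w.sum()

        score = weights(good) / weights(bad)
        return choices[int(np.argmax(score))]

    def suggest(self) -> ModelConfig:
        done = [(c, v) for c, v in self.history if np.isfinite(v)]
        if len(done) < self.n_startup:
            return sample_config(self.rng, self.max_window)
        done.sort(key=lambda cv: -cv[1])
        n_good = max(1, int(np.ceil(self.gamma * len(done))))
        good = [c for c, _ in done[:n_good]]
        bad = [c for c, _ in done[n_good:]] or good

        def num(attr, lo, hi):
            return self._numeric(
                np.array([getattr(c, attr) for c in good], dtype=float),
                np.array([getattr(c, attr) for c in bad], dtype=float),
                lo, hi,
            )

        def cat(attr, choices):
            return self._categorical(
                [getattr(c, attr) for c in good],
                [getattr(c, attr) for c in bad],
                choices,
            )

        n_dense = num("n_dense_layers", 1, 11)
        window = num("window_length", 4, self.max_window)
        # per-layer fields beyond observed depth fall back to uniform draws
        units = tuple(int(self.rng.integers(1, 65)) for _ in range(n_dense))
        acts = tuple(str(self.rng.choice(ACTIVATIONS)) for _ in range(n_dense))
        # channel toggles: smoothed per-channel inclusion frequency among good trials
        probs = np.array(
            [
                (1.0 + sum(ch in c.selected_channels for c in good))
                / (2.0 + len(good))
                for ch in CHANNELS
            ]
        )
        mask = self.rng.random(len(CHANNELS)) < probs
        if not mask.any():
            mask[self.rng.integers(len(CHANNELS))] = True
        return ModelConfig(
            n_dense_layers=n_dense,
            units_per_layer=units,
            activation_per_layer=acts,
            use_conv=cat("use_conv", (False, True)),
            conv_filters=num("conv_filters", 1, 50),
            conv_window=min(num("conv_window", 2, 32), window),
            conv_activation=cat("conv_activation", CONV_ACTIVATIONS),
            use_pooling=cat("use_pooling", (False, True)),
            use_lstm=cat("use_lstm", (False, True)),
            lstm_units=num("lstm_units", 1, 50),
            learning_rate=cat("learning_rate", LEARNING_RATES),
            optimizer=cat("optimizer", OPTIMIZERS),
            batch_size=num("batch_size", 1, 50),
            window_length=window,
            selected_channels=tuple(c for c, m in zip(CHANNELS, mask) if m),
        )


# --- registry ----------------------------------------------------------------

class ModelRegistry:
    """Per-node lists of trained models, kept sorted by validation AUC.

    The sort is stable and descending: on equal AUC the earlier insertion
    wins.  This ordering backs sensor-failure fallback.
    """

    def __init__(self):
        self._entries: dict[str, list[TrainedModel]] = {}

    def insert(self, node: str, model: TrainedModel) -> None:
        entries = self._entries.setdefault(node, [])
        entries.append(model)
        entries.sort(key=lambda m: -(m.validation_auc if np.isfinite(m.validation_auc) else -1.0))

    def entries(self, node: str) -> list[TrainedModel]:
        return list(self._entries.get(node, []))

    def nodes(self) -> list[str]:
        return list(self._entries)

    def best(self, node: str) -> TrainedModel:
        return self.best_without(node, frozenset())

    def best_without(self, node: str, failed_channels: Iterable[str]) -> TrainedModel:
        """Highest-ranked model whose inputs avoid every failed channel."""
        failed = frozenset(failed_channels)
        for model in self._entries.get(node, []):
            if not failed.intersection(model.config.selected_channels):
                return model
        raise NodeUnavailableError(node, failed)

    def save(self, path) -> None:
        """Persist as a directory tree: node/rank_NNN/{config.yaml, weights.npz, metrics.json}."""
        root = Path(path)
        for node, entries in self._entries.items():
            for rank, model in enumerate(entries):
                d = root / node / f"rank_{rank:03d}"
                d.mkdir(parents=True, exist_ok=True)
                (d / "config.yaml").write_text(yaml.safe_dump(model.config.to_dict()))
                np.savez(
                    d / "weights.npz",
                    scaler_mean=model.scaler.mean,
                    scaler_std=model.scaler.std,
                    **model.network.get_weights(),
                )
                (d / "metrics.json").write_text(
                    json.dumps(
                        {
                            "validation_auc": model.validation_auc,
                            "node": node,
                            "history": model.training_history,
                        },
                        indent=2,
                    )
                )

    @classmethod
    def load(cls, path) -> "ModelRegistry":
        from gaitcascade.ann import ChannelScaler

        root = Path(path)
        registry = cls()
        for node_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for rank_dir in sorted(node_dir.iterdir()):
                config = ModelConfig.from_dict(
                    yaml.safe_load((rank_dir / "config.yaml").read_text())
                )
                data = np.load(rank_dir / "weights.npz")
                network = build_network(config, seed=0)
                network.set_weights({k: data[k] for k in data.files if "." in k})
                metrics = json.loads((rank_dir / "metrics.json").read_text())
                registry.insert(
                    node_dir.name,
                    TrainedModel(
                        config=config,
                        network=network,
                        scaler=ChannelScaler(
                            mean=data["scaler_mean"], std=data["scaler_std"]
                        ),
                        training_history=metrics.get("history", {}),
                        validation_auc=metrics["validation_auc"],
                        node_name=node_dir.name,
                    ),
                )
        return registry


def best_without(
    registry: ModelRegistry, node: str, failed_channels: Iterable[str]
) -> TrainedModel:
    """Module-level alias of :meth:`ModelRegistry.best_without`."""
    return registry.best_without(node, failed_channels)


# --- search driver -----------------------------------------------------------

@dataclass
class TrialRecord:
    number: int
    config: ModelConfig
    validation_auc: float
    error: str | None = None


def run_search(
    spec: SearchSpec,
    split: DatasetSplit | BinarySplit,
    node=None,
    registry: ModelRegistry | None = None,
    log_path=None,
) -> tuple[ModelRegistry, list[TrialRecord]]:
    """Sample, train and register ``n_trials`` configurations for one node.

    ``split`` is either a :class:`BinarySplit` already relabelled for the
    node, or a full :class:`DatasetSplit` plus the ``node`` spec to relabel
    with.  The split must be built at the maximal window length with all
    channels; every trial derives its own view (window suffix and channel
    subset), so partition membership is identical across trials.

    Failed trials are recorded with their diagnostics; if every trial fails,
    an error carrying all diagnostics is raised.
    """
    if isinstance(split, DatasetSplit):
        if node is None:
            raise ValueError("pass the node spec when providing an unlabelled split")
        split = relabel_split(split, node)
    registry = registry if registry is not None else ModelRegistry()

    max_window = min(
        (min(s.values.shape[0] for s, _ in part) for part in
         (split.train, split.validation) if part),
        default=32,
    )
    sampler = TPESampler(seed=spec.seed, max_window=max_window) \
        if spec.sampler == "tpe" else None
    rng = np.random.default_rng(spec.seed)

    records: list[TrialRecord] = []
    log_fh = open(log_path, "w") if log_path else None
    try:
        for trial in range(spec.n_trials):
            config = sampler.suggest() if sampler else sample_config(rng, max_window)
            try:
                network = build_network(config, seed=spec.seed + trial)
                model = train(
                    network, split, config,
                    patience=spec.patience, max_epochs=spec.max_epochs,
                    seed=spec.seed + trial,
                )
                registry.insert(spec.node_name, model)
                record = TrialRecord(trial, config, model.validation_auc)
            except (ValueError, FloatingPointError) as exc:
                record = TrialRecord(trial, config, float("-inf"), error=str(exc))
                logger.warning("trial %d failed: %s", trial, exc)
            records.append(record)
            if sampler:
                sampler.tell(config, record.validation_auc)
            if log_fh:
                log_fh.write(json.dumps({
                    "trial": record.number,
                    "validation_auc": record.validation_auc,
                    "error": record.error,
                    "config": record.config.to_dict(),
                }) + "\n")
    finally:
        if log_fh:
            log_fh.close()

    if not registry.entries(spec.node_name):
        diagnostics = "; ".join(f"trial {r.number}: {r.error}" for r in records)
        raise RuntimeError(
            f"all {spec.n_trials} trials failed for node {spec.node_name!r}: {diagnostics}"
        )
    return registry, records
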