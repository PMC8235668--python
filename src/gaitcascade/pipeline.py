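"""End-to-end convenience pipeline: simulate, window, split, train, evaluate.

This module binds the stages together with one small fixed training
configuration per cascade node (shallow time-distributed dense stacks over a
16- or 32-frame history of all 20 channels).  These baselines are not the
published best architectures — those ship as fixtures in ``ann`` — but a
compact, CPU-friendly setup under which the synthetic learning problems are
comfortably solvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gaitcascade.ann import ModelConfig, TrainedModel, build_network, train
from gaitcascade.cascade import (
    DEFAULT_NODES,
    CascadeTree,
    predict_sample,
)
from gaitcascade.events import CHANNELS, EventLabel
from gaitcascade.evaluation import (
    CascadeReport,
    ConfusionCounts,
    MetricsReport,
    auc,
    binary_metrics,
    cascade_metrics,
)
from gaitcascade.hpo import ModelRegistry
from gaitcascade.synthetic import GaitSimConfig, simulate_dataset
from gaitcascade.windowing import (
    BinarySplit,
    ChannelSelector,
    DatasetSplit,
    build_dataset,
    relabel_split,
    stratified_split,
)

logger = logging.getLogger(__name__)

#: Recordings per event for the baseline run: roughly the cohort's class mix,
#: compressed so every node sees enough minority samples to train on.
BASELINE_COUNTS: dict[EventLabel, int] = {
    EventLabel.SITTING: 5,
    EventLabel.STANDING_STILL: 6,
    EventLabel.STANDING_IMBALANCE: 6,
    EventLabel.WALKING: 8,
    EventLabel.RUNNING: 5,
    EventLabel.STUMBLING: 5,
}


def baseline_node_config(node_name: str) -> ModelConfig:
    """The small fixed per-node training configuration used by the baseline.

    Two time-distributed dense layers over all 20 channels; a 32-frame
    history for the running-vs-walking node (cadence lives in longer
    context), 16 frames elsewhere.
    """
    window = 32 if node_name == "running_vs_walking" else 16
    return ModelConfig(
        n_dense_layers=2,
        units_per_layer=(24, 12),
        activation_per_layer=("tanh", "tanh"),
        learning_rate=0.001,
        optimizer="adam",
        batch_size=32,
        window_length=window,
        selected_channels=CHANNELS,
        dropout=0.1,
    )


@dataclass
class PipelineResult:
    """Everything a baseline run produces."""

    registry: ModelRegistry
    tree: CascadeTree
    split: DatasetSplit
    node_models: dict[str, TrainedModel]
    node_validation_auc: dict[str, float]
    node_test_reports: dict[str, MetricsReport]
    cascade_report: CascadeReport
    binary_splits: dict[str, BinarySplit] = field(default_factory=dict)


def make_split(
    seed: int,
    counts: dict[EventLabel, int] | None = None,
    duration: float = 60.0,
    stride: int = 2,
    unit: str = "window",
) -> DatasetSplit:
    """Simulate recordings and build the master 60/20/20 split.

    Windows are cut at the maximal length (32 frames, all 20 channels) so
    each node model can derive its own shorter/narrower view.
    """
    config = GaitSimConfig(seed=seed, duration=duration)
    recordings = simulate_dataset(config, counts or BASELINE_COUNTS)
    samples = build_dataset(recordings, ChannelSelector.all_channels(32), stride=stride)
    return stratified_split(samples, seed=seed, unit=unit)


def train_nodes(
    split: DatasetSplit,
    seed: int,
    max_epochs: int = 30,
    patience: int = 6,
) -> tuple[ModelRegistry, dict[str, TrainedModel], dict[str, BinarySplit]]:
    """Train the five baseline node models and register them."""
    registry = ModelRegistry()
    models: dict[str, TrainedModel] = {}
    binary_splits: dict[str, BinarySplit] = {}
    for name, node in DEFAULT_NODES.items():
        config = baseline_node_config(name)
        bsplit = relabel_split(split, node)
        binary_splits[name] = bsplit
        network = build_network(config, seed=seed)
        model = train(
            network, bsplit, config,
            patience=patience, max_epochs=max_epochs, seed=seed,
        )
        registry.insert(name, model)
        models[name] = model
        logger.info("node %s: validation AUC %.3f", name, model.validation_auc)
    return registry, models, binary_splits


def evaluate_nodes(
    models: dict[str, TrainedModel],
    binary_splits: dict[str, BinarySplit],
    threshold: float = 0.5,
) -> dict[str, MetricsReport]:
    """Held-out test metrics (confusion counts + AUC) per binary node."""
    reports = {}
    for name, model in models.items():
        pairs = binary_splits[name].test
        if not pairs:
            continue
        y = np.array([label for _, label in pairs])
        scores = np.array([model.predict_sample(s) for s, _ in pairs])
        preds = (scores >= threshold).astype(int)
        report = binary_metrics(
            ConfusionCounts.from_predictions(y, preds), scope=name
        )
        try:
            report.auc = auc(y, scores)
        except ValueError:
            report.undefined.add("auc")
        reports[name] = report
    return reports


def evaluate_cascade(tree: CascadeTree, split: DatasetSplit) -> CascadeReport:
    """Run the full cascade over the held-out test windows."""
    pairs = [(s.label, predict_sample(tree, s)) for s in split.test]
    return cascade_metrics(pairs)


def run_baseline(
    seed: int,
    counts: dict[EventLabel, int] | None = None,
    duration: float = 60.0,
    stride: int = 2,
    max_epochs: int = 30,
) -> PipelineResult:
    """The whole pipeline under one seed: data to trained cascade to metrics."""
    split = make_split(seed, counts=counts, duration=duration, stride=stride)
    registry, models, binary_splits = train_nodes(split, seed, max_epochs=max_epochs)
    tree = CascadeTree(registry=registry)
    node_reports = evaluate_nodes(models, binary_splits)
    report = evaluate_cascade(tree, split)
    return PipelineResult(
        registry=registry,
        tree=tree,
        split=split,
        node_models=models,
        node_validation_auc={n: m.validation_auc for n, m in models.items()},
        node_test_reports=node_reports,
        cascade_report=report,
        binary_splits=binary_splits,
    )


def shuffled_label_control(
    split: DatasetSplit,
    node_name: str = "moving_vs_still",
    seed: int = 0,
    max_epochs: int = 15,
) -> float:
    """Train one node on label-shuffled data; its validation AUC should hover
    near chance.  A sanity check that reported skill is not an artefact of the
    training loop."""
    node = DEFAULT_NODES[node_name]
    bsplit = relabel_split(split, node)
    rng = np.random.default_rng(seed)
    shuffled_train = [
        (s, int(y)) for (s, _), y in zip(
            bsplit.train, rng.permutation([y for _, y in bsplit.train])
        )
    ]
    shuffled_val = [
        (s, int(y)) for (s, _), y in zip(
            bsplit.validation, rng.permutation([y for _, y in bsplit.validation])
        )
    ]
    control = BinarySplit(
        node_name=f"{node_name}-shuffled",
        train=shuffled_train,
        validation=shuffled_val,
        test=[],
    )
    config = baseline_node_config(node_name)
    model = train(
        build_network(config, seed=seed), control, config,
        patience=30, max_epochs=max_epochs, seed=seed,
    )
    return model.validation_auc
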