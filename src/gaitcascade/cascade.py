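"""Hierarchical inference: route a window through five binary decisions.

The decision tree::

    standing_vs_seated ──0──> sitting
            │1
    moving_vs_still ──0──> unbalanced_vs_stable ──0──> standing_still
            │1                      └──1──> standing_imbalance
    stumbling_vs_not ──1──> stumbling
            │0
    running_vs_walking ──0──> walking
            └──1──> running

Class polarity at every node: class 0 is the "calmer" side (sitting, still,
stable, not-stumbling, walking).  Each node is served by the best registered
model that avoids any failed sensor channel, so the detector degrades
gracefully instead of dying with a sensor.  A result whose terminal event is
a fall-risk indicator (imbalance or stumbling) is flagged and forwarded to an
alert sink.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from gaitcascade.events import CHANNELS, EventLabel, RISK_EVENTS
from gaitcascade.hpo import ModelRegistry, NodeUnavailableError
from gaitcascade.ingest import SensorFrame
from gaitcascade.windowing import WindowSample

logger = logging.getLogger(__name__)


class CascadeWarmupError(RuntimeError):
    """Not enough frame history yet for a node's window length."""

    def __init__(self, node: str, needed: int, available: int):
        self.node = node
        super().__init__(
            f"node {node!r} needs {needed} frames of history, only {available} available"
        )


@dataclass(frozen=True)
class BinaryNodeSpec:
    """One binary decision: which events fall on each side, and what follows.

    ``child_on_0`` / ``child_on_1`` are either another node's name or a
    terminal :class:`EventLabel`.
    """

    name: str
    class0_events: frozenset[EventLabel]
    class1_events: frozenset[EventLabel]
    child_on_0: "str | EventLabel"
    child_on_1: "str | EventLabel"

    def __post_init__(self):
        if self.class0_events & self.class1_events:
            raise ValueError(f"node {self.name!r}: class event sets overlap")


_ALL_STANDING = frozenset(
    {
        EventLabel.STANDING_STILL,
        EventLabel.STANDING_IMBALANCE,
        EventLabel.WALKING,
        EventLabel.RUNNING,
        EventLabel.STUMBLING,
    }
)

#: The five-node decision tree with its fixed topology and class polarities.
DEFAULT_NODES: dict[str, BinaryNodeSpec] = {
    "standing_vs_seated": BinaryNodeSpec(
        name="standing_vs_seated",
        class0_events=frozenset({EventLabel.SITTING}),
        class1_events=_ALL_STANDING,
        child_on_0=EventLabel.SITTING,
        child_on_1="moving_vs_still",
    ),
    "moving_vs_still": BinaryNodeSpec(
        name="moving_vs_still",
        class0_events=frozenset({EventLabel.STANDING_STILL, EventLabel.STANDING_IMBALANCE}),
        class1_events=frozenset({EventLabel.STUMBLING, EventLabel.WALKING, EventLabel.RUNNING}),
        child_on_0="unbalanced_vs_stable",
        child_on_1="stumbling_vs_not",
    ),
    "unbalanced_vs_stable": BinaryNodeSpec(
        name="unbalanced_vs_stable",
        class0_events=frozenset({EventLabel.STANDING_STILL}),
        class1_events=frozenset({EventLabel.STANDING_IMBALANCE}),
        child_on_0=EventLabel.STANDING_STILL,
        child_on_1=EventLabel.STANDING_IMBALANCE,
    ),
    "stumbling_vs_not": BinaryNodeSpec(
        name="stumbling_vs_not",
        class0_events=frozenset({EventLabel.WALKING, EventLabel.RUNNING}),
        class1_events=frozenset({EventLabel.STUMBLING}),
        child_on_0="running_vs_walking",
        child_on_1=EventLabel.STUMBLING,
    ),
    "running_vs_walking": BinaryNodeSpec(
        name="running_vs_walking",
        class0_events=frozenset({EventLabel.WALKING}),
        class1_events=frozenset({EventLabel.RUNNING}),
        child_on_0=EventLabel.WALKING,
        child_on_1=EventLabel.RUNNING,
    ),
}

ROOT_NODE = "standing_vs_seated"


@dataclass
class PathStep:
    node: str
    probability: float  # model's class-1 probability at this node
    decision: int       # 0 or 1, after thresholding


@dataclass
class CascadeResult:
    """The cascade's answer for one prediction instant."""

    event: EventLabel
    path: list[PathStep]
    path_probability: float
    risk_flag: bool
    event_scores: dict[EventLabel, float] | None = None
    degraded_nodes: list[str] = field(default_factory=list)
    timestamp: object = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": str(self.timestamp) if self.timestamp else None,
                "event": str(self.event),
                "path": [
                    {"node": s.node, "probability": s.probability, "decision": s.decision}
                    for s in self.path
                ],
                "path_probability": self.path_probability,
                "risk_flag": self.risk_flag,
            }
        )


@dataclass
class CascadeTree:
    """The node topology bound to a model registry and decision thresholds."""

    registry: ModelRegistry
    nodes: Mapping[str, BinaryNodeSpec] = field(default_factory=lambda: dict(DEFAULT_NODES))
    root: str = ROOT_NODE
    threshold: float = 0.5

    def __post_init__(self):
        leaves = _collect_leaves(self.nodes, self.root)
        if sorted(leaves, key=int) != sorted(EventLabel, key=int):
            raise ValueError(
                f"cascade leaves {sorted(map(str, leaves))} do not cover the six events"
            )


def _collect_leaves(nodes, root) -> list[EventLabel]:
    leaves = []

    def walk(ref):
        if isinstance(ref, EventLabel):
            leaves.append(ref)
        else:
            spec = nodes[ref]
            walk(spec.child_on_0)
            walk(spec.child_on_1)

    walk(root)
    return leaves


class _HistoryView:
    """Normalises any window source into an (n, 20) canonical-channel matrix."""

    def __init__(self, source):
        if isinstance(source, WindowSample):
            self.matrix = np.asarray(source.values, dtype=float)
            self.channels = source.channels
        elif isinstance(source, np.ndarray):
            self.matrix = np.asarray(source, dtype=float)
            self.channels = CHANNELS
        else:  # sequence of SensorFrame
            frames = list(source)
            self.matrix = (
                np.stack([f.values() for f in frames])
                if frames else np.empty((0, len(CHANNELS)))
            )
            self.channels = CHANNELS
        self._index = {c: i for i, c in enumerate(self.channels)}

    def window(self, node: str, w: int, selected: Sequence[str]) -> np.ndarray:
        if self.matrix.shape[0] < w:
            raise CascadeWarmupError(node, w, self.matrix.shape[0])
        cols = [self._index[c] for c in selected]
        return self.matrix[-w:, cols]


def _node_probability(
    tree: CascadeTree, history: _HistoryView, node: str, failed: frozenset[str]
):
    model = tree.registry.best_without(node, failed)
    window = history.window(
        node, model.config.window_length, model.config.selected_channels
    )
    return float(model.predict_proba(window))


def predict(
    tree: CascadeTree,
    frame_history,
    failed_channels: Iterable[str] = (),
    timestamp=None,
) -> CascadeResult:
    """Classify the current instant from its recent frame history.

    ``frame_history`` may be a sequence of :class:`SensorFrame`, an
    ``(n, 20)`` array in canonical channel order, or a :class:`WindowSample`.
    At each visited node the best failure-compatible model is selected, the
    node's own window (its length and channel subset) is sliced from the
    history, and the decision is class 1 iff probability >= threshold.

    All five node probabilities are evaluated so the result also carries a
    score for every leaf event (the product of branch probabilities along the
    path to that leaf), used for one-vs-rest evaluation.  Nodes that cannot
    run (exhausted fallback) off the taken path are recorded in
    ``degraded_nodes``; on the taken path they raise.

    Raises :class:`CascadeWarmupError` when history is shorter than a visited
    node's window, and :class:`NodeUnavailableError` when fallback is
    exhausted at a visited node.
    """
    failed = frozenset(failed_channels)
    history = _HistoryView(frame_history)

    probs: dict[str, float] = {}
    degraded: list[str] = []
    for name in tree.nodes:
        try:
            probs[name] = _node_probability(tree, history, name, failed)
        except (NodeUnavailableError, CascadeWarmupError):
            degraded.append(name)

    # walk the taken path; a missing probability on the path is fatal
    path: list[PathStep] = []
    ref: str | EventLabel = tree.root
    path_probability = 1.0
    while not isinstance(ref, EventLabel):
        if ref not in probs:
            # re-raise the specific condition for the visited node
            _node_probability(tree, history, ref, failed)
            raise AssertionError("unreachable")  # pragma: no cover
        p = probs[ref]
        decision = int(p >= tree.threshold)
        path.append(PathStep(node=ref, probability=p, decision=decision))
        path_probability *= p if decision else (1.0 - p)
        spec = tree.nodes[ref]
        ref = spec.child_on_1 if decision else spec.child_on_0

    event_scores = None
    if not degraded:
        event_scores = {}

        def walk(node_ref, score):
            if isinstance(node_ref, EventLabel):
                event_scores[node_ref] = score
            else:
                p = probs[node_ref]
                spec = tree.nodes[node_ref]
                walk(spec.child_on_0, score * (1.0 - p))
                walk(spec.child_on_1, score * p)

        walk(tree.root, 1.0)

    return CascadeResult(
        event=ref,
        path=path,
        path_probability=path_probability,
        risk_flag=ref in RISK_EVENTS,
        event_scores=event_scores,
        degraded_nodes=degraded,
        timestamp=timestamp,
    )


def predict_sample(
    tree: CascadeTree, sample: WindowSample, failed_channels: Iterable[str] = ()
) -> CascadeResult:
    """Classify one pre-built window sample (evaluation convenience)."""
    return predict(tree, sample, failed_channels=failed_channels)


# --- alert sinks -------------------------------------------------------------

class AlertSink:
    """Destination for risk-flagged results (abstract notification channel)."""

    def send(self, result: CascadeResult) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class ConsoleAlertSink(AlertSink):
    def send(self, result: CascadeResult) -> None:
        print(f"ALERT: {result.event} (p={result.path_probability:.3f})")


class FileAlertSink(AlertSink):
    """Appends one JSON line per alert to a file."""

    def __init__(self, path):
        self.path = path

    def send(self, result: CascadeResult) -> None:
        with open(self.path, "a") as fh:
            fh.write(result.to_json() + "\n")


class CollectingSink(AlertSink):
    """Keeps alerts in memory (tests, dashboards)."""

    def __init__(self):
        self.alerts: list[CascadeResult] = []

    def send(self, result: CascadeResult) -> None:
        self.alerts.append(result)


def predict_stream(
    tree: CascadeTree,
    frame_stream: Iterable[SensorFrame],
    alert_sink: AlertSink | None = None,
    stride: int = 1,
    failed_channels: Iterable[str] = (),
    buffer_length: int = 32,
) -> Iterator[CascadeResult]:
    """Near-real-time inference over an ordered stream of frames.

    Maintains a rolling buffer of ``buffer_length`` frames (the maximal node
    window; each node slices its own suffix), emits one result every
    ``stride`` frames once the buffer can serve the visited nodes, and
    forwards each risk-flagged result to the alert sink exactly once.
    Malformed stream items are logged and skipped without disturbing the
    buffer.
    """
    buffer: deque[SensorFrame] = deque(maxlen=buffer_length)
    since_emit = stride - 1
    for item in frame_stream:
        if not isinstance(item, SensorFrame):
            logger.warning("skipping malformed stream item of type %s", type(item).__name__)
            continue
        buffer.append(item)
        since_emit += 1
        if since_emit < stride:
            continue
        try:
            result = predict(
                tree, list(buffer), failed_channels=failed_channels,
                timestamp=item.timestamp,
            )
        except CascadeWarmupError:
            continue  # still warming up; do not reset the stride counter
        since_emit = 0
        if result.risk_flag and alert_sink is not None:
            alert_sink.send(result)
        yield result


# --- oracle models (topology validation) -------------------------------------

class OracleNodeModel:
    """A stand-in node model that answers from a known true event.

    Used to validate that the tree topology loses no information: with one
    oracle per node, the cascade must reproduce any true label exactly.  Set
    ``current_event`` before each prediction.
    """

    @dataclass(frozen=True)
    class _Config:
        window_length: int = 4
        selected_channels: tuple[str, ...] = CHANNELS

    def __init__(self, spec: BinaryNodeSpec):
        self.spec = spec
        self.config = self._Config()
        self.validation_auc = 1.0
        self.current_event: EventLabel | None = None

    def predict_proba(self, window) -> float:
        if self.current_event is None:
            raise RuntimeError("set current_event before predicting")
        if self.current_event in self.spec.class1_events:
            return 1.0
        return 0.0


def oracle_registry(nodes: Mapping[str, BinaryNodeSpec] = DEFAULT_NODES):
    """A registry of oracle models plus a setter for the current true event."""
    registry = ModelRegistry()
    oracles = {}
    for name, spec in nodes.items():
        oracle = OracleNodeModel(spec)
        oracles[name] = oracle
        registry._entries.setdefault(name, []).append(oracle)

    def set_event(event: EventLabel):
        for oracle in oracles.values():
            oracle.current_event = event

    return registry, set_event
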