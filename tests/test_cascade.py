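"""Tree topology, path probabilities, fallback and streaming inference."""

from types import SimpleNamespace

import numpy as np
import pytest

from gaitcascade.cascade import (
    DEFAULT_NODES,
    CascadeResult,
    CascadeTree,
    CascadeWarmupError,
    CollectingSink,
    oracle_registry,
    predict,
    predict_sample,
    predict_stream,
)
from gaitcascade.events import CHANNELS, EventLabel
from gaitcascade.hpo import ModelRegistry, NodeUnavailableError
from gaitcascade.synthetic import GaitSimConfig, simulate_recording


class FixedModel:
    """A node model that always reports the same class-1 probability."""

    def __init__(self, prob, channels=CHANNELS, window=4):
        self.config = SimpleNamespace(
            selected_channels=tuple(channels), window_length=window
        )
        self.validation_auc = 1.0
        self._prob = prob

    def predict_proba(self, window):
        return self._prob


def fixed_tree(probs: dict[str, float], threshold=0.5) -> CascadeTree:
    registry = ModelRegistry()
    for name, p in probs.items():
        registry.insert(name, FixedModel(p))
    return CascadeTree(registry=registry, threshold=threshold)


HISTORY = np.zeros((32, 20))


class TestTopology:
    def test_all_decision_vectors_cover_exactly_six_events(self):
        # enumeration oracle: drive every node deterministically to 0 or 1
        reached = []
        for bits in range(32):  # all assignments of the five node decisions
            decisions = {
                name: float((bits >> i) & 1)
                for i, name in enumerate(DEFAULT_NODES)
            }
            result = predict(fixed_tree(decisions), HISTORY)
            reached.append(result.event)
        assert set(reached) == set(EventLabel)
        # sitting is the only single-decision leaf: reached for all 16 root-0 vectors
        assert reached.count(EventLabel.SITTING) == 16

    def test_root_low_probability_is_sitting_path_length_one(self):
        result = predict(fixed_tree({n: 0.1 for n in DEFAULT_NODES}), HISTORY)
        assert result.event == EventLabel.SITTING
        assert len(result.path) == 1
        assert not result.risk_flag

    def test_hand_traversed_path_probability(self):
        # standing 0.9 -> moving 0.8 -> not-stumbling (p=0.2, 0-branch: 0.8)
        # -> running 0.9; product 0.9*0.8*0.8*0.9
        tree = fixed_tree({
            "standing_vs_seated": 0.9,
            "moving_vs_still": 0.8,
            "stumbling_vs_not": 0.2,
            "running_vs_walking": 0.9,
            "unbalanced_vs_stable": 0.5,
        })
        result = predict(tree, HISTORY)
        assert result.event == EventLabel.RUNNING
        assert result.path_probability == pytest.approx(0.5184)
        assert [s.node for s in result.path] == [
            "standing_vs_seated", "moving_vs_still",
            "stumbling_vs_not", "running_vs_walking",
        ]

    def test_flipping_root_always_changes_terminal_event(self):
        for others in (0.1, 0.9):
            probs = {n: others for n in DEFAULT_NODES}
            low = predict(fixed_tree({**probs, "standing_vs_seated": 0.0}), HISTORY)
            high = predict(fixed_tree({**probs, "standing_vs_seated": 1.0}), HISTORY)
            assert low.event == EventLabel.SITTING
            assert high.event != EventLabel.SITTING

    def test_risk_flag_for_imbalance_and_stumbling(self):
        stumble = predict(fixed_tree({n: 0.9 for n in DEFAULT_NODES}), HISTORY)
        assert stumble.event == EventLabel.STUMBLING
        assert stumble.risk_flag
        imbalance = predict(
            fixed_tree({
                "standing_vs_seated": 0.9, "moving_vs_still": 0.1,
                "unbalanced_vs_stable": 0.9, "stumbling_vs_not": 0.1,
                "running_vs_walking": 0.1,
            }),
            HISTORY,
        )
        assert imbalance.event == EventLabel.STANDING_IMBALANCE
        assert imbalance.risk_flag

    def test_event_scores_sum_to_at_most_one(self):
        tree = fixed_tree({n: 0.3 + 0.1 * i for i, n in enumerate(DEFAULT_NODES)})
        result = predict(tree, HISTORY)
        total = sum(result.event_scores.values())
        assert total == pytest.approx(1.0)  # thresholded tree partitions mass


class TestOracleModels:
    def test_oracle_cascade_has_perfect_accuracy(self, tiny_recordings):
        registry, set_event = oracle_registry()
        tree = CascadeTree(registry=registry)
        correct = 0
        total = 0
        for rec in tiny_recordings:
            set_event(rec.event)
            result = predict(tree, rec.frames[:32])
            total += 1
            correct += result.event == rec.event
            assert result.event_scores[rec.event] == 1.0
        assert correct == total


class TestFallbackAndDegradation:
    def test_failed_channel_routes_to_fallback_model(self):
        registry = ModelRegistry()
        primary = FixedModel(0.9, channels=("P0", "A0"))
        backup = FixedModel(0.1, channels=("P5",))
        registry.insert("standing_vs_seated", primary)
        registry.insert("standing_vs_seated", backup)
        for other in set(DEFAULT_NODES) - {"standing_vs_seated"}:
            registry.insert(other, FixedModel(0.5, channels=("P5",)))
        tree = CascadeTree(registry=registry)
        assert predict(tree, HISTORY).event != EventLabel.SITTING  # primary: 0.9
        degraded = predict(tree, HISTORY, failed_channels={"P0"})
        assert degraded.event == EventLabel.SITTING  # backup: 0.1

    def test_exhausted_fallback_on_visited_node_raises(self):
        tree = fixed_tree({n: 0.9 for n in DEFAULT_NODES})
        with pytest.raises(NodeUnavailableError, match="standing_vs_seated"):
            predict(tree, HISTORY, failed_channels={"P0"})

    def test_insufficient_history_raises_warmup(self):
        tree = fixed_tree({n: 0.9 for n in DEFAULT_NODES})
        with pytest.raises(CascadeWarmupError):
            predict(tree, np.zeros((2, 20)))

    def test_off_path_degraded_node_recorded_not_fatal(self):
        registry = ModelRegistry()
        for name in DEFAULT_NODES:
            if name == "unbalanced_vs_stable":
                registry.insert(name, FixedModel(0.5, channels=("P9",)))
            else:
                registry.insert(name, FixedModel(0.9, channels=("P1",)))
        tree = CascadeTree(registry=registry)
        result = predict(tree, HISTORY, failed_channels={"P9"})
        assert result.event == EventLabel.STUMBLING  # path avoids the dead node
        assert result.degraded_nodes == ["unbalanced_vs_stable"]
        assert result.event_scores is None


def _stream_frames(n, event=EventLabel.STANDING_STILL):
    cfg = GaitSimConfig(seed=77, duration=max(1.0, n / 4.0))
    return simulate_recording(cfg, event, "stream").frames[:n]


class TestPredictStream:
    def test_stream_shorter_than_warmup_yields_nothing(self):
        tree = fixed_tree({n: 0.9 for n in DEFAULT_NODES}, threshold=0.5)
        results = list(predict_stream(tree, _stream_frames(3)))
        assert results == []

    def test_alert_accounting_exactly_once_per_risk_result(self):
        tree = fixed_tree({n: 0.9 for n in DEFAULT_NODES})  # always stumbling
        sink = CollectingSink()
        results = list(predict_stream(tree, _stream_frames(20), alert_sink=sink))
        assert len(results) > 0
        assert len(sink.alerts) == sum(r.risk_flag for r in results)

    def test_stride_thins_emissions(self):
        tree = fixed_tree({n: 0.1 for n in DEFAULT_NODES})
        dense = list(predict_stream(tree, _stream_frames(24), stride=1))
        sparse = list(predict_stream(tree, _stream_frames(24), stride=4))
        assert len(dense) > len(sparse) > 0

    def test_malformed_items_skipped_buffer_intact(self, caplog):
        tree = fixed_tree({n: 0.1 for n in DEFAULT_NODES})
        frames = _stream_frames(12)
        corrupted = frames[:6] + ["garbage"] + frames[6:]
        with caplog.at_level("WARNING"):
            results = list(predict_stream(tree, corrupted))
        clean = list(predict_stream(tree, frames))
        assert len(results) == len(clean)
        assert "malformed" in caplog.text


class TestEndToEndTrainedCascade:
    def test_trained_cascade_detects_stumbles_in_stream(self, baseline_result):
        tree = baseline_result.tree
        cfg = GaitSimConfig(seed=99, duration=30.0)
        frames = simulate_recording(cfg, EventLabel.STUMBLING, "live").frames
        sink = CollectingSink()
        results = list(predict_stream(tree, frames, alert_sink=sink))
        assert len(results) > 0
        assert len(sink.alerts) >= 1  # at least one risk alert delivered
        assert all(isinstance(r, CascadeResult) for r in results)

    def test_predict_sample_agrees_with_predict(self, baseline_result):
        sample = baseline_result.split.test[0]
        r1 = predict_sample(baseline_result.tree, sample)
        r2 = predict(baseline_result.tree, sample.values)
        assert r1.event == r2.event
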