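"""Window construction, stratified splitting and binary relabelling."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitcascade.cascade import DEFAULT_NODES
from gaitcascade.events import EventLabel
from gaitcascade.ingest import Recording, SensorFrame
from gaitcascade.windowing import (
    ChannelSelector,
    WindowSample,
    build_windows,
    relabel_binary,
    stratified_split,
)


def make_recording(n, event=EventLabel.WALKING, rid="r0"):
    """Frames whose pressure values encode the frame index (oracle-friendly)."""
    frames = [
        SensorFrame(
            timestamp=datetime(2021, 1, 1) + timedelta(seconds=0.25 * i),
            pressures=(float(i),) * 16,
            temperature=1000.0 + i,
            acceleration=(float(i), -float(i), 0.5 * i),
        )
        for i in range(n)
    ]
    return Recording(rid, "s", event, frames)


def enumerate_windows(n, w, stride):
    """Independent oracle: all valid (start, end) index pairs."""
    return [(t - w, t) for t in range(w, n + 1, stride)]


class TestBuildWindows:
    def test_exact_boundary_single_window(self):
        rec = make_recording(32)
        out = build_windows(rec, ChannelSelector.all_channels(32), stride=1)
        assert len(out) == 1
        assert out[0].values.shape == (32, 20)

    def test_count_matches_enumeration(self):
        rec = make_recording(40)
        out = build_windows(rec, ChannelSelector.all_channels(32), stride=1)
        assert len(out) == 9 == len(enumerate_windows(40, 32, 1))

    def test_nine_channel_short_window_selector(self):
        # 9-channel, 4-frame configuration on a 10-frame recording
        sel = ChannelSelector(
            selected=("P0", "P1", "P4", "P7", "P10", "P11", "P12", "P14", "A1"),
            window_length=4,
        )
        out = build_windows(make_recording(10), sel, stride=1)
        assert len(out) == 7
        assert all(s.values.shape == (4, 9) for s in out)

    def test_contents_match_enumeration_oracle(self):
        rec = make_recording(20)
        sel = ChannelSelector(selected=("P0", "T0", "A2"), window_length=4)
        out = build_windows(rec, sel, stride=3)
        expected = enumerate_windows(20, 4, 3)
        assert len(out) == len(expected)
        for sample, (lo, hi) in zip(out, expected):
            np.testing.assert_array_equal(sample.values[:, 0], np.arange(lo, hi))
            np.testing.assert_array_equal(sample.values[:, 1], 1000.0 + np.arange(lo, hi))
            np.testing.assert_array_equal(sample.values[:, 2], 0.5 * np.arange(lo, hi))
            assert sample.t_index == hi

    def test_short_recording_yields_nothing(self):
        out = build_windows(make_recording(3), ChannelSelector.all_channels(4))
        assert out == []

    def test_windows_never_cross_recordings(self):
        # adversarial: two recordings with contiguous timestamps
        a = make_recording(10, EventLabel.WALKING, "a")
        b = make_recording(10, EventLabel.RUNNING, "b")
        sel = ChannelSelector.all_channels(4)
        for rec in (a, b):
            for s in build_windows(rec, sel):
                assert s.recording_id == rec.recording_id
                assert s.label == rec.event
                # rows are a contiguous slice of that recording alone
                np.testing.assert_array_equal(
                    s.values[:, 0], np.arange(s.t_index - 4, s.t_index)
                )

    @given(
        n=st.integers(min_value=1, max_value=50),
        w=st.sampled_from([4, 8, 16, 32]),
        stride=st.integers(min_value=1, max_value=5),
    )
    def test_window_count_formula(self, n, w, stride):
        out = build_windows(make_recording(n), ChannelSelector.all_channels(w), stride)
        assert len(out) == len(enumerate_windows(n, w, stride))
        if stride == 1 and n >= w:
            assert len(out) == n - w + 1

    def test_view_slices_suffix_and_channels(self):
        rec = make_recording(12)
        [sample] = build_windows(rec, ChannelSelector.all_channels(12), stride=12)
        view = sample.view(ChannelSelector(selected=("P3", "A0"), window_length=4))
        np.testing.assert_array_equal(view[:, 0], np.arange(8, 12))
        np.testing.assert_array_equal(view[:, 1], np.arange(8, 12))


def fake_samples(counts: dict[EventLabel, int]):
    out = []
    for label, n in counts.items():
        for i in range(n):
            out.append(
                WindowSample(
                    values=np.zeros((4, 1)),
                    label=label,
                    recording_id=f"{label.name}-{i % 3}",
                    t_index=i,
                    channels=("P0",),
                )
            )
    return out


class TestStratifiedSplit:
    def test_ten_samples_split_6_2_2(self):
        split = stratified_split(fake_samples({EventLabel.SITTING: 10}), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    def test_per_class_proportions_counting_oracle(self):
        split = stratified_split(
            fake_samples({EventLabel.WALKING: 100, EventLabel.RUNNING: 50}), seed=1
        )
        assert (len(split.train), len(split.validation), len(split.test)) == (90, 30, 30)
        for part, expect_w, expect_r in [
            (split.train, 60, 30), (split.validation, 20, 10), (split.test, 20, 10)
        ]:
            labels = [s.label for s in part]
            assert labels.count(EventLabel.WALKING) == expect_w
            assert labels.count(EventLabel.RUNNING) == expect_r

    def test_deterministic_under_seed(self):
        samples = fake_samples({EventLabel.WALKING: 40, EventLabel.SITTING: 25})
        key = lambda split: [
            sorted((s.label, s.t_index) for s in part)
            for part in (split.train, split.validation, split.test)
        ]
        assert key(stratified_split(samples, seed=5)) == key(stratified_split(samples, seed=5))
        assert key(stratified_split(samples, seed=5)) != key(stratified_split(samples, seed=6))

    def test_partitions_disjoint_and_exhaustive(self):
        samples = fake_samples({EventLabel.WALKING: 23, EventLabel.STUMBLING: 17})
        split = stratified_split(samples, seed=2)
        ids = lambda part: {id(s) for s in part}
        assert not ids(split.train) & ids(split.validation)
        assert not ids(split.train) & ids(split.test)
        assert not ids(split.validation) & ids(split.test)
        assert len(split.train) + len(split.validation) + len(split.test) == len(samples)

    def test_small_class_raises_naming_class(self):
        samples = fake_samples({EventLabel.WALKING: 10, EventLabel.STUMBLING: 2})
        with pytest.raises(ValueError, match="stumbling"):
            stratified_split(samples, seed=0)

    def test_recording_unit_keeps_recordings_together(self):
        samples = fake_samples({EventLabel.WALKING: 30})  # 3 recording ids
        split = stratified_split(samples, seed=0, unit="recording")
        for part in (split.train, split.validation, split.test):
            rids = {s.recording_id for s in part}
            for other in (split.train, split.validation, split.test):
                if other is not part:
                    assert not rids & {s.recording_id for s in other}


class TestRelabelBinary:
    def test_root_node_keeps_all_and_sets_polarity(self):
        samples = fake_samples({e: 2 for e in EventLabel})
        pairs = relabel_binary(samples, DEFAULT_NODES["standing_vs_seated"])
        assert len(pairs) == len(samples)
        for s, y in pairs:
            assert y == (0 if s.label == EventLabel.SITTING else 1)

    def test_out_of_domain_samples_excluded(self):
        samples = fake_samples({EventLabel.SITTING: 5})
        assert relabel_binary(samples, DEFAULT_NODES["running_vs_walking"]) == []

    def test_unbalanced_node_retains_only_standing_events(self):
        samples = fake_samples({e: 2 for e in EventLabel})
        pairs = relabel_binary(samples, DEFAULT_NODES["unbalanced_vs_stable"])
        assert {s.label for s, _ in pairs} == {
            EventLabel.STANDING_STILL, EventLabel.STANDING_IMBALANCE,
        }
        for s, y in pairs:
            assert y == (1 if s.label == EventLabel.STANDING_IMBALANCE else 0)

    @pytest.mark.parametrize("name,node", DEFAULT_NODES.items())
    def test_all_nodes_emit_both_polarities_on_full_mix(self, name, node):
        samples = fake_samples({e: 1 for e in EventLabel})
        labels = {y for _, y in relabel_binary(samples, node)}
        assert labels == {0, 1}
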