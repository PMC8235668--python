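"""Telemetry parsing, timestamp dialects, channel alignment and recording IO."""

import json
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitcascade.events import CHANNELS, EventLabel
from gaitcascade.ingest import (
    Recording,
    SchemaError,
    SensorFrame,
    SensorMessage,
    align_channels,
    load_recordings,
    parse_message,
    parse_timestamp,
    save_recordings,
    serialize_message,
)


def _msg(ts="2020-10-25T17:12:24:6847", data=None):
    return json.dumps({"timestamp": ts, "data": data if data is not None else [0] * 16})


class TestParseMessage:
    def test_wire_example_with_colon_fraction(self):
        msg = parse_message(_msg())
        assert msg.pressures == (0.0,) * 16
        assert msg.timestamp == datetime(2020, 10, 25, 17, 12, 24, 684700)

    def test_colon_and_dot_dialects_agree(self):
        a = parse_timestamp("2020-10-25T17:12:24:6847")
        b = parse_timestamp("2020-10-25T17:12:24.6847")
        assert a == b
        # time-only forms parse too
        assert parse_timestamp("17:12:24:6847").microsecond == 684700

    @pytest.mark.parametrize(
        "raw, bad_field",
        [
            (_msg(data=[0] * 15), "data"),
            (_msg(data=[0] * 17), "data"),
            (json.dumps({"data": [0] * 16}), "timestamp"),
            (json.dumps({"timestamp": "17:12:24"}), "data"),
            (_msg(ts="not-a-time"), "timestamp"),
            ("{broken", "message"),
        ],
    )
    def test_schema_errors_name_the_field(self, raw, bad_field):
        with pytest.raises(SchemaError) as err:
            parse_message(raw)
        assert err.value.field == bad_field

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1023, allow_nan=False),
            min_size=16, max_size=16,
        ),
        st.integers(min_value=0, max_value=86_399_000),
    )
    def test_roundtrip_is_value_identical(self, pressures, millis):
        ts = datetime(2021, 3, 1) + timedelta(milliseconds=millis)
        original = SensorMessage(timestamp=ts, pressures=tuple(pressures))
        recovered = parse_message(serialize_message(original))
        assert recovered.pressures == original.pressures
        assert recovered.timestamp == original.timestamp


def _pressure_stream(n, start=datetime(2021, 1, 1), dt=0.25):
    return [
        SensorMessage(
            timestamp=start + timedelta(seconds=i * dt), pressures=(float(i),) * 16
        )
        for i in range(n)
    ]


class TestAlignChannels:
    def test_identical_timestamps_pair_one_to_one(self):
        msgs = _pressure_stream(8)
        aux = [(m.timestamp, 300.0 + i, (1.0, 2.0, 3.0)) for i, m in enumerate(msgs)]
        frames = align_channels(msgs, aux)
        assert len(frames) == 8
        for i, f in enumerate(frames):
            assert f.temperature == 300.0 + i
            assert f.pressures == msgs[i].pressures

    def test_constant_delay_takes_previous_reading_vs_bruteforce(self):
        msgs = _pressure_stream(20)
        aux = [
            (m.timestamp + timedelta(milliseconds=100), float(i), (0.0, 0.0, 0.0))
            for i, m in enumerate(msgs)
        ]
        frames = align_channels(msgs, aux)
        # brute-force nearest-predecessor oracle over all pairs
        for msg in msgs:
            eligible = [(t, temp) for t, temp, _ in aux if t <= msg.timestamp]
            frame = next((f for f in frames if f.timestamp == msg.timestamp), None)
            if not eligible:
                assert frame is None
            else:
                assert frame.temperature == max(eligible)[1]
        # the 100 ms delayed stream shifts everything by exactly one reading
        assert [f.temperature for f in frames] == [float(i) for i in range(19)]

    def test_single_message_single_earlier_aux(self):
        msgs = _pressure_stream(1, start=datetime(2021, 1, 1, 0, 0, 1))
        aux = [(datetime(2021, 1, 1), 295.0, (0.0, 0.0, 9.8))]
        frames = align_channels(msgs, aux)
        assert len(frames) == 1
        assert frames[0].temperature == 295.0

    def test_empty_pressure_stream(self):
        assert align_channels([], [(datetime(2021, 1, 1), 0.0, (0, 0, 0))]) == []

    def test_head_frames_without_aux_are_dropped(self, caplog):
        msgs = _pressure_stream(5)
        aux = [(msgs[2].timestamp, 1.0, (0.0, 0.0, 0.0))]
        with caplog.at_level("WARNING"):
            frames = align_channels(msgs, aux)
        assert len(frames) == 3  # messages 2, 3, 4
        assert "2" in caplog.text

    def test_output_never_exceeds_pressure_stream(self, rng):
        msgs = _pressure_stream(int(rng.integers(1, 30)))
        aux = [(msgs[0].timestamp, 0.0, (0.0, 0.0, 0.0))]
        assert len(align_channels(msgs, aux)) <= len(msgs)


class TestChannelOrder:
    def test_frame_vector_follows_canonical_order(self):
        frame = SensorFrame(
            timestamp=datetime(2021, 1, 1),
            pressures=tuple(float(i) for i in range(16)),
            temperature=99.0,
            acceleration=(101.0, 102.0, 103.0),
        )
        values = frame.values()
        assert values.shape == (20,)
        for i in range(16):
            assert values[CHANNELS.index(f"P{i}")] == float(i)
        assert values[CHANNELS.index("T0")] == 99.0
        assert values[CHANNELS.index("A0")] == 101.0
        assert values[CHANNELS.index("A2")] == 103.0


def _frames(n, start=datetime(2021, 1, 1)):
    return [
        SensorFrame(
            timestamp=start + timedelta(seconds=0.25 * i),
            pressures=(float(i),) * 16,
            temperature=300.0,
            acceleration=(0.0, 0.0, 0.0),
        )
        for i in range(n)
    ]


class TestRecordingIO:
    def test_single_recording_roundtrip(self, tmp_path):
        rec = Recording("r1", "s1", EventLabel.WALKING, _frames(240))
        path = tmp_path / "data.csv"
        save_recordings([rec], path)
        loaded = load_recordings(path)
        assert len(loaded) == 1
        assert len(loaded[0]) == 240
        assert loaded[0].event == EventLabel.WALKING
        np.testing.assert_allclose(loaded[0].to_matrix(), rec.to_matrix())

    def test_interleaved_recordings_grouped_and_sorted(self, tmp_path):
        a = Recording("a", "s1", EventLabel.SITTING, _frames(6))
        b = Recording("b", "s1", EventLabel.RUNNING, _frames(6))
        path = tmp_path / "data.csv"
        save_recordings([a, b], path)
        # interleave and shuffle rows, then reload
        import pandas as pd

        df = pd.read_csv(path).sample(frac=1.0, random_state=0)
        df.to_csv(path, index=False)
        loaded = {r.recording_id: r for r in load_recordings(path)}
        assert set(loaded) == {"a", "b"}
        for rec in loaded.values():  # oracle: group then sort
            ts = [f.timestamp for f in rec.frames]
            assert ts == sorted(ts)

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert load_recordings(path) == []

    def test_unknown_event_label_names_value(self, tmp_path):
        rec = Recording("r1", "s1", EventLabel.WALKING, _frames(4))
        path = tmp_path / "data.csv"
        save_recordings([rec], path)
        import pandas as pd

        df = pd.read_csv(path)
        df["event"] = "moonwalking"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="moonwalking"):
            load_recordings(path)

    def test_duplicate_timestamps_name_recording(self, tmp_path):
        rec = Recording("dup-rec", "s1", EventLabel.WALKING, _frames(4))
        path = tmp_path / "data.csv"
        save_recordings([rec], path)
        import pandas as pd

        df = pd.read_csv(path)
        df.loc[1, "timestamp"] = df.loc[0, "timestamp"]
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="dup-rec"):
            load_recordings(path)

    def test_recording_rejects_unordered_frames(self):
        frames = _frames(3)
        with pytest.raises(ValueError, match="strictly increasing"):
            Recording("r", "s", EventLabel.SITTING, [frames[1], frames[0], frames[2]])
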