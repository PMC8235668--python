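"""Window tensors, channel selection, stratified splits and binary relabelling.

A classifier never sees a single frame: its input is the matrix of the ``w``
frames preceding the prediction instant ``t`` (rows t-w .. t-1, oldest first),
restricted to the channels the model selected.  ``w`` ranges from 4 to 32.
Windows never cross recording boundaries, and the first ``w`` frames of a
recording yield no window because they lack sufficient history.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from gaitcascade.events import CHANNELS, CHANNEL_INDEX, EventLabel
from gaitcascade.ingest import Recording

logger = logging.getLogger(__name__)

MIN_WINDOW = 4
MAX_WINDOW = 32


@dataclass(frozen=True)
class ChannelSelector:
    """A subset of the 20 channels plus a history length ``w``."""

    selected: tuple[str, ...]
    window_length: int

    def __post_init__(self):
        if not self.selected:
            raise ValueError("channel selection must be non-empty")
        unknown = [c for c in self.selected if c not in CHANNEL_INDEX]
        if unknown:
            raise ValueError(f"unknown channel names: {unknown}")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate channel names in selection")
        if not (MIN_WINDOW <= self.window_length <= MAX_WINDOW):
            raise ValueError(
                f"window_length must be in [{MIN_WINDOW}, {MAX_WINDOW}], "
                f"got {self.window_length}"
            )

    @property
    def indices(self) -> np.ndarray:
        return np.array([CHANNEL_INDEX[c] for c in self.selected])

    @classmethod
    def all_channels(cls, window_length: int) -> "ChannelSelector":
        return cls(selected=CHANNELS, window_length=window_length)


@dataclass
class WindowSample:
    """One classifier input: a ``w x c`` matrix of recent history plus its label.

    ``t_index`` is the frame index of the prediction instant within its
    recording; rows are frames ``t_index - w .. t_index - 1``, oldest first.
    """

    values: np.ndarray
    label: EventLabel
    recording_id: str
    t_index: int
    channels: tuple[str, ...]

    def view(self, selector: ChannelSelector) -> np.ndarray:
        """Slice this window down to a selector's suffix length and channels.

        A window built at the maximal length with all channels contains every
        shorter-suffix, fewer-channel view, which lets one master split serve
        models with differing window lengths and sensor subsets.
        """
        w = selector.window_length
        if w > self.values.shape[0]:
            raise ValueError(
                f"window of length {self.values.shape[0]} cannot provide "
                f"a suffix of length {w}"
            )
        col_index = {c: i for i, c in enumerate(self.channels)}
        missing = [c for c in selector.selected if c not in col_index]
        if missing:
            raise ValueError(f"window lacks channels {missing}")
        cols = [col_index[c] for c in selector.selected]
        return self.values[-w:, cols]


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of window samples."""

    train: list[WindowSample]
    validation: list[WindowSample]
    test: list[WindowSample]
    proportions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0


def build_windows(
    recording: Recording,
    selector: ChannelSelector,
    stride: int = 1,
) -> list[WindowSample]:
    """Cut sliding windows of length ``w`` from one recording.

    Prediction instants are ``w, w + stride, w + 2*stride, ...`` (frame
    indices); with stride 1 a recording of ``n`` frames yields ``n - w + 1``
    windows.  A recording shorter than ``w`` yields no windows (logged, not an
    error).  All windows inherit the recording's event label.
    """
    if stride < 1:
        raise ValueError(f"stride must be positive, got {stride}")
    w = selector.window_length
    n = len(recording)
    if n < w:
        logger.info(
            "recording %s has %d frames < window %d; no windows produced",
            recording.recording_id, n, w,
        )
        return []
    matrix = recording.to_matrix()[:, selector.indices]
    samples = []
    for t in range(w, n + 1, stride):
        samples.append(
            WindowSample(
                values=matrix[t - w : t].copy(),
                label=recording.event,
                recording_id=recording.recording_id,
                t_index=t,
                channels=tuple(selector.selected),
            )
        )
    return samples


def build_dataset(
    recordings: Iterable[Recording],
    selector: ChannelSelector,
    stride: int = 1,
) -> list[WindowSample]:
    """Windows from many recordings; windows never cross recording boundaries."""
    out: list[WindowSample] = []
    for rec in recordings:
        out.extend(build_windows(rec, selector, stride))
    return out


def stratified_split(
    samples: Sequence[WindowSample],
    proportions: tuple[float, float, float] = (0.60, 0.20, 0.20),
    seed: int = 0,
    unit: str = "window",
) -> DatasetSplit:
    """Partition samples into train/validation/test preserving class mix.

    Per class: validation and test receive ``round(p * n)`` samples each and
    train takes the rest, so every partition's count stays within one sample
    of its exact share for each class.  Deterministic under ``seed``.

    ``unit="window"`` stratifies individual windows (adjacent, overlapping
    windows of one recording can land in different partitions — evaluation is
    optimistic about temporal generalisation but matches a sample-level
    protocol).  ``unit="recording"`` keeps all windows of a recording in one
    partition, the stricter protocol when enough recordings per class exist.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions}")
    if unit not in ("window", "recording"):
        raise ValueError(f"unit must be 'window' or 'recording', got {unit!r}")

    rng = np.random.default_rng(seed)
    train: list[WindowSample] = []
    val: list[WindowSample] = []
    test: list[WindowSample] = []

    by_class: dict[EventLabel, list[WindowSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)

    for label in sorted(by_class, key=int):
        members = by_class[label]
        if unit == "window":
            groups = [[s] for s in members]
        else:
            by_rec: dict[str, list[WindowSample]] = {}
            for s in members:
                by_rec.setdefault(s.recording_id, []).append(s)
            groups = [by_rec[r] for r in sorted(by_rec)]
        if len(groups) < 3:
            raise ValueError(
                f"class {label} has only {len(groups)} {unit}(s); "
                "need at least 3 to populate all partitions"
            )
        order = rng.permutation(len(groups))
        n = len(groups)
        n_val = math.floor(proportions[1] * n + 0.5)
        n_test = math.floor(proportions[2] * n + 0.5)
        n_train = n - n_val - n_test
        for pos, gi in enumerate(order):
            if pos < n_train:
                train.extend(groups[gi])
            elif pos < n_train + n_val:
                val.extend(groups[gi])
            else:
                test.extend(groups[gi])

    return DatasetSplit(
        train=train, validation=val, test=test, proportions=proportions, seed=seed
    )


def relabel_binary(samples, node) -> list[tuple[WindowSample, int]]:
    """Project six-event samples onto one cascade node's binary problem.

    ``node`` is any object exposing disjoint ``class0_events`` and
    ``class1_events`` sets.  Samples whose event lies outside the node's
    domain are excluded; the rest carry 0/1 according to the partition.
    """
    domain0 = set(node.class0_events)
    domain1 = set(node.class1_events)
    out = []
    for s in samples:
        if s.label in domain0:
            out.append((s, 0))
        elif s.label in domain1:
            out.append((s, 1))
    return out


@dataclass
class BinarySplit:
    """A DatasetSplit relabelled for one cascade node."""

    node_name: str
    train: list[tuple[WindowSample, int]] = field(default_factory=list)
    validation: list[tuple[WindowSample, int]] = field(default_factory=list)
    test: list[tuple[WindowSample, int]] = field(default_factory=list)


def relabel_split(split: DatasetSplit, node) -> BinarySplit:
    """Apply :func:`relabel_binary` to every partition of a split."""
    return BinarySplit(
        node_name=getattr(node, "name", "node"),
        train=relabel_binary(split.train, node),
        validation=relabel_binary(split.validation, node),
        test=relabel_binary(split.test, node),
    )
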