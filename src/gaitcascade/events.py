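"""Gait-event taxonomy and the fixed sensor-channel order.

Every data structure in the package lays channels out in the same order:
the 16 plantar-pressure sensors P0..P15 (heel-to-toe indices of the insole
layout), the temperature channel T0, then the three accelerometer axes
A0, A1, A2.  Windows, CSV files and model channel selections all refer to
channels by these names.
"""

from __future__ import annotations

from enum import IntEnum


class EventLabel(IntEnum):
    """The six gait events the cascade can emit.

    Ordinal codes are stable across the package (they index confusion
    matrices and seed streams); do not reorder.
    """

    SITTING = 0
    STANDING_STILL = 1
    STANDING_IMBALANCE = 2
    WALKING = 3
    RUNNING = 4
    STUMBLING = 5

    @classmethod
    def from_string(cls, value: str) -> "EventLabel":
        try:
            return cls[value.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown event label {value!r}; expected one of "
                f"{[e.name.lower() for e in cls]}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


#: Events whose detection should raise an alert (fall-risk indicators).
RISK_EVENTS = frozenset({EventLabel.STANDING_IMBALANCE, EventLabel.STUMBLING})

PRESSURE_CHANNELS: tuple[str, ...] = tuple(f"P{i}" for i in range(16))
TEMPERATURE_CHANNELS: tuple[str, ...] = ("T0",)
ACCEL_CHANNELS: tuple[str, ...] = ("A0", "A1", "A2")

#: Canonical channel order used by every window matrix.
CHANNELS: tuple[str, ...] = PRESSURE_CHANNELS + TEMPERATURE_CHANNELS + ACCEL_CHANNELS

CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNELS)}

#: CSV header names for the 20 channels, in canonical order.
CSV_CHANNEL_COLUMNS: tuple[str, ...] = tuple(
    [f"p{i}" for i in range(16)] + ["temp", "ax", "ay", "az"]
)
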