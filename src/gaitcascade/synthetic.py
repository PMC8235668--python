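"""Seeded generator of labelled insole telemetry for the six gait events.

The original recordings behind this problem were never deposited, so this
module emulates them: ~4 Hz traces over 16 plantar-pressure channels, one
temperature channel and a 3-axis accelerometer, with event-distinguishing
temporal structure.  The signal families are deliberately simple —
rectified-sinusoid gait waves sweeping heel to toe, Gaussian sensor noise,
Poisson-timed transient bursts, a random-walk temperature drift — which is
enough to make every downstream learning problem well-posed while remaining
fully seeded and reproducible.

Signal model per event (all levels in opaque device units):

* ``sitting`` — low constant pressure plus noise, with occasional brief
  foot-shift bursts on a random sensor band.
* ``standing_still`` — static moderate heel + forefoot load, near-zero
  acceleration variance, occasional small foot taps.
* ``standing_imbalance`` — the standing baseline modulated by a slow sway
  oscillation that alternates load between the medial and lateral sensor
  bands, with a matched acceleration oscillation.
* ``walking`` — a periodic gait cycle at the walking cadence: a pressure wave
  sweeps heel to toe with per-sensor phase offsets, plus periodic
  acceleration.
* ``running`` — the same wave at the running cadence and higher amplitude,
  with flight-phase frames in which total pressure collapses to near zero.
* ``stumbling`` — the walking signal with injected transient anomalies
  (acceleration spike plus irregular pressure) at a Poisson burst rate.

Geometry: sensor indices are grouped heel {0..3}, midfoot {4..9}, toe
{10..15}; odd indices form the medial band and even indices the lateral band.
The heel fires first in the gait cycle; per-sensor activation offsets grow
linearly heel to toe.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from datetime import datetime, timedelta
from typing import Mapping

import numpy as np

from gaitcascade.events import EventLabel
from gaitcascade.ingest import Recording, SensorFrame, SensorMessage

HEEL = tuple(range(0, 4))
MIDFOOT = tuple(range(4, 10))
TOE = tuple(range(10, 16))
MEDIAL = tuple(i for i in range(16) if i % 2 == 1)
LATERAL = tuple(i for i in range(16) if i % 2 == 0)

#: Fraction of the gait cycle by which each sensor's activation lags the heel.
GAIT_PHASE_OFFSETS = np.arange(16) / 16.0 * 0.4

_EPOCH = datetime(2021, 1, 1, 12, 0, 0)


@dataclass(frozen=True)
class GaitSimConfig:
    """All tunable parameters of the telemetry generator (device units / Hz / s)."""

    seed: int = 0
    rate: float = 4.0          # sampling frequency, Hz
    duration: float = 60.0     # seconds per recording

    # resting / static levels
    sitting_base: float = 30.0
    sitting_noise: float = 5.0
    standing_heel: float = 220.0
    standing_toe: float = 160.0
    standing_midfoot: float = 90.0
    standing_noise: float = 6.0

    # postural sway (imbalance)
    sway_freq: float = 0.4         # Hz, well below the 2 Hz Nyquist of 4 Hz sampling
    sway_amp: float = 90.0
    sway_accel_amp: float = 40.0

    # gait cycles
    walk_cadence: float = 1.0      # steps/s of the instrumented foot
    walk_amp: float = 320.0
    walk_accel_amp: float = 60.0
    run_cadence: float = 2.5
    run_amp: float = 560.0
    run_accel_amp: float = 180.0
    run_duty: float = 0.65         # fraction of the cycle in ground contact
    gait_rest: float = 10.0        # residual pressure during swing/flight
    gait_noise: float = 12.0

    # transient events
    stumble_rate: float = 0.15     # burst starts per frame
    stumble_frames: int = 3        # frames per burst
    stumble_accel_amp: float = 420.0
    stumble_pressure_sd: float = 180.0
    foot_shift_rate: float = 0.02  # sitting: occasional leg/foot shifts
    foot_shift_amp: float = 45.0
    tap_rate: float = 0.03         # standing: small foot taps
    tap_amp: float = 35.0

    # auxiliary channels
    accel_gravity: float = 250.0   # constant component on axis 0
    accel_noise: float = 3.0
    temp_base: float = 300.0
    temp_drift_sd: float = 0.05

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.run_cadence <= self.walk_cadence:
            raise ValueError("running cadence must exceed walking cadence")
        for name in ("sway_amp", "walk_amp", "run_amp", "stumble_accel_amp",
                     "foot_shift_amp", "tap_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def manifest(self) -> dict:
        """Parameters plus the sensor-geometry grouping, for provenance files."""
        out = asdict(self)
        out["geometry"] = {
            "heel": list(HEEL), "midfoot": list(MIDFOOT), "toe": list(TOE),
            "medial": list(MEDIAL), "lateral": list(LATERAL),
            "gait_phase_offsets": GAIT_PHASE_OFFSETS.tolist(),
        }
        return out


def _rng_for(config: GaitSimConfig, event: EventLabel, recording_id: str) -> np.random.Generator:
    # crc32 keeps the recording-id contribution deterministic across runs
    return np.random.default_rng(
        [config.seed, int(event), zlib.crc32(str(recording_id).encode())]
    )


def _gait_pressures(
    t: np.ndarray, cadence: float, amp: float, duty: float, cfg: GaitSimConfig
) -> np.ndarray:
    """Heel-to-toe pressure wave for one gait at the given cadence.

    Each sensor sees a rectified-sinusoid activation bump delayed by its
    phase offset; outside the contact fraction of the cycle (running flight
    phase) all pressures drop to the residual level.
    """
    phase = np.outer(t * cadence, np.ones(16)) - GAIT_PHASE_OFFSETS  # (n, 16)
    activation = np.maximum(0.0, np.sin(2 * np.pi * phase)) ** 2
    contact = (np.mod(t * cadence, 1.0) < duty).astype(float)[:, None]
    return cfg.gait_rest + amp * activation * contact


def _standing_baseline(cfg: GaitSimConfig, n: int) -> np.ndarray:
    base = np.empty((n, 16))
    base[:, list(HEEL)] = cfg.standing_heel
    base[:, list(MIDFOOT)] = cfg.standing_midfoot
    base[:, list(TOE)] = cfg.standing_toe
    return base


def _bursts(rng: np.random.Generator, n: int, rate: float, length: int) -> np.ndarray:
    """Boolean mask of Poisson-timed bursts of the given frame length."""
    starts = rng.random(n) < rate
    mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(starts):
        mask[i : i + length] = True
    return mask


def simulate_recording(
    config: GaitSimConfig,
    event: EventLabel,
    recording_id: str,
    subject_id: str = "sim-subject",
) -> Recording:
    """Generate one labelled recording of ``round(rate * duration)`` frames.

    Bitwise deterministic given (config.seed, event, recording_id).
    """
    if config.duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng_for(config, event, recording_id)
    n = int(round(config.rate * config.duration))
    t = np.arange(n) / config.rate

    accel = np.zeros((n, 3))
    accel[:, 0] = config.accel_gravity

    if event == EventLabel.SITTING:
        pressures = np.full((n, 16), config.sitting_base)
        pressures += rng.normal(0, config.sitting_noise, (n, 16))
        shift = _bursts(rng, n, config.foot_shift_rate, 3)
        band = [HEEL, MIDFOOT, TOE][rng.integers(3)]
        pressures[np.ix_(shift, list(band))] += config.foot_shift_amp
        accel += rng.normal(0, config.accel_noise, (n, 3))

    elif event == EventLabel.STANDING_STILL:
        pressures = _standing_baseline(config, n)
        pressures += rng.normal(0, config.standing_noise, (n, 16))
        taps = _bursts(rng, n, config.tap_rate, 2)
        pressures[np.ix_(taps, list(TOE))] += config.tap_amp
        accel += rng.normal(0, config.accel_noise * 0.5, (n, 3))

    elif event == EventLabel.STANDING_IMBALANCE:
        pressures = _standing_baseline(config, n)
        sway = np.sin(2 * np.pi * config.sway_freq * t)
        pressures[:, list(MEDIAL)] += config.sway_amp * sway[:, None]
        pressures[:, list(LATERAL)] -= config.sway_amp * sway[:, None]
        pressures += rng.normal(0, config.standing_noise, (n, 16))
        accel[:, 1] += config.sway_accel_amp * sway
        accel[:, 2] += config.sway_accel_amp * 0.5 * np.sin(
            2 * np.pi * config.sway_freq * t + 0.8
        )
        accel += rng.normal(0, config.accel_noise, (n, 3))

    elif event in (EventLabel.WALKING, EventLabel.RUNNING, EventLabel.STUMBLING):
        if event == EventLabel.RUNNING:
            cadence, amp, acc_amp, duty = (
                config.run_cadence, config.run_amp, config.run_accel_amp, config.run_duty,
            )
        else:
            cadence, amp, acc_amp, duty = (
                config.walk_cadence, config.walk_amp, config.walk_accel_amp, 1.0,
            )
        pressures = _gait_pressures(t, cadence, amp, duty, config)
        pressures += rng.normal(0, config.gait_noise, (n, 16))
        accel[:, 0] += acc_amp * np.sin(2 * np.pi * cadence * t)
        accel[:, 1] += acc_amp * 0.6 * np.sin(4 * np.pi * cadence * t + 1.0)
        accel[:, 2] += acc_amp * 0.3 * np.sin(2 * np.pi * cadence * t + 2.0)
        accel += rng.normal(0, config.accel_noise, (n, 3))

        if event == EventLabel.STUMBLING:
            burst = _bursts(rng, n, config.stumble_rate, config.stumble_frames)
            k = int(burst.sum())
            if k:
                spikes = config.stumble_accel_amp * rng.choice([-1.0, 1.0], (k, 3))
                spikes *= rng.uniform(0.6, 1.0, (k, 3))
                accel[burst] += spikes
                pressures[burst] += np.abs(
                    rng.normal(0, config.stumble_pressure_sd, (k, 16))
                )
    else:  # pragma: no cover - closed enum
        raise ValueError(f"unknown event {event!r}")

    pressures = np.clip(pressures, 0.0, None)
    temperature = config.temp_base + np.cumsum(
        rng.normal(0, config.temp_drift_sd, n)
    )

    dt = timedelta(seconds=1.0 / config.rate)
    frames = [
        SensorFrame(
            timestamp=_EPOCH + i * dt,
            pressures=tuple(pressures[i]),
            temperature=float(temperature[i]),
            acceleration=tuple(accel[i]),
        )
        for i in range(n)
    ]
    return Recording(
        recording_id=recording_id,
        subject_id=subject_id,
        event=event,
        frames=frames,
        nominal_rate=config.rate,
    )


#: Relative per-event recording frequencies matching the class mix of the
#: cohort the generator emulates (scaled counts; use with ``scale_counts``).
DEFAULT_EVENT_MIX: dict[EventLabel, int] = {
    EventLabel.SITTING: 30,
    EventLabel.STANDING_STILL: 69,
    EventLabel.STANDING_IMBALANCE: 52,
    EventLabel.WALKING: 96,
    EventLabel.RUNNING: 35,
    EventLabel.STUMBLING: 8,
}


def simulate_dataset(
    config: GaitSimConfig,
    counts: Mapping[EventLabel, int],
) -> list[Recording]:
    """Generate independent recordings per event with deterministic sub-seeds.

    Each recording draws from its own seed stream derived from the master
    seed, the event code and the recording id, so recordings are mutually
    independent yet bitwise reproducible.
    """
    recordings = []
    for event in sorted(counts, key=int):
        c = counts[event]
        if c < 0:
            raise ValueError(f"negative count for {event}")
        for i in range(c):
            rid = f"{event.name.lower()}-{i:03d}"
            recordings.append(simulate_recording(config, event, rid))
    return recordings


def recording_to_messages(recording: Recording) -> list[SensorMessage]:
    """The pressure-only wire view of a recording (the device's own payload)."""
    return [
        SensorMessage(timestamp=f.timestamp, pressures=f.pressures)
        for f in recording.frames
    ]
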