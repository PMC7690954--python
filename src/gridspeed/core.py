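"""Shared in-memory containers for one recording session.

All downstream analysis consumes these containers; the synthetic generator and
the session-bundle reader both produce them.  Units: cm, seconds, Hz, degrees
(headings in [0, 360), zero along +x, counter-clockwise positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Cleaned animal tracking for one session.

    ``hd_deg`` is NaN at samples where heading could not be measured (fewer
    than two tracking LEDs visible); such samples are excluded from
    head-direction analysis rather than interpolated.
    """

    timestamps: np.ndarray  # s, uniform
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    hd_deg: np.ndarray  # deg in [0, 360), NaN where undefined
    interpolated: np.ndarray = None  # bool per sample

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd_deg = np.asarray(self.hd_deg, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.timestamps.size, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = self.timestamps.size
        for name in ("x", "y", "hd_deg", "interpolated"):
            if getattr(self, name).size != n:
                raise ValueError(f"trajectory field {name!r} length mismatch")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("trajectory timestamps must be nondecreasing")

    @property
    def duration(self) -> float:
        if self.timestamps.size < 2:
            return 0.0
        dt = float(np.median(np.diff(self.timestamps)))
        return float(self.timestamps[-1] - self.timestamps[0] + dt)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class SpeedSeries:
    """Running speed on a uniform time binning of the session.

    Bins faster than ``SPEED_CUTOFF_CM_S`` are flagged ``excluded`` (treated
    as tracking errors) and dropped from every speed-dependent analysis.
    """

    bin_start: np.ndarray  # s
    bin_width: float  # s
    speed: np.ndarray  # cm/s
    excluded: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.bin_start = np.asarray(self.bin_start, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if np.any(self.speed[np.isfinite(self.speed)] < 0):
            raise ValueError("speeds must be nonnegative")

    @property
    def bin_center(self) -> np.ndarray:
        return self.bin_start + 0.5 * self.bin_width


#: Tracking-artefact cutoff: speed bins above this are excluded everywhere.
SPEED_CUTOFF_CM_S = 50.0


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one unit plus its waveform half-width."""

    unit_id: str
    spike_times: np.ndarray  # s, sorted, within [0, duration]
    duration: float  # s, recording length
    half_width_ms: float | None = None  # waveform peak-to-trough half width

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times not sorted")
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] > self.duration
        ):
            raise ValueError(
                f"unit {self.unit_id}: spike times outside [0, duration]"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class LFPSignal:
    """One continuous local-field-potential trace (mV), typically 2 kHz."""

    fs: float  # Hz
    samples: np.ndarray  # mV

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Session:
    """A complete session: behaviour, spike trains, and (optionally) LFP."""

    trajectory: Trajectory
    spike_trains: list[SpikeTrain] = field(default_factory=list)
    lfp: LFPSignal | None = None
    ground_truth: dict | None = None

    @property
    def duration(self) -> float:
        return self.trajectory.duration
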