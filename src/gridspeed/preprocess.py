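"""Tracking cleanup, heading derivation, and running-speed estimation.

Raw tracking comes from two head-mounted LEDs sampled at ~25 Hz by an
overhead camera.  Samples where no LED crossed the light threshold are
invalid: their position is linearly interpolated from the nearest valid
neighbours.  Heading requires both LEDs, and samples with fewer are discarded
from the heading series (never interpolated).  Running speed is computed on
binned positions, and bins above 50 cm/s are flagged as tracking errors and
excluded everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gridspeed.core import SPEED_CUTOFF_CM_S, SpeedSeries, Trajectory


class UnusableSessionError(ValueError):
    """Raised when tracking has too few valid samples to analyse."""


@dataclass
class RawTracking:
    """Timestamped positions of the two headstage LEDs; NaN where a LED was
    not detected."""

    timestamps: np.ndarray  # s
    led1: np.ndarray  # (n, 2) cm, NaN rows where missing
    led2: np.ndarray  # (n, 2) cm

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.led1 = np.asarray(self.led1, dtype=float).reshape(-1, 2)
        self.led2 = np.asarray(self.led2, dtype=float).reshape(-1, 2)
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be nondecreasing")
        if not (self.timestamps.size == len(self.led1) == len(self.led2)):
            raise ValueError("LED arrays must match timestamps in length")

    @property
    def led1_valid(self) -> np.ndarray:
        return np.all(np.isfinite(self.led1), axis=1)

    @property
    def led2_valid(self) -> np.ndarray:
        return np.all(np.isfinite(self.led2), axis=1)


def _fill_series(t: np.ndarray, v: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid stretches; edges held at the nearest
    valid value."""
    out = np.array(v, dtype=float)
    if valid.all():
        return out
    tv = t[valid]
    vv = v[valid]
    out[~valid] = np.interp(t[~valid], tv, vv)  # np.interp clamps at edges
    return out


def compute_heading(raw: RawTracking) -> np.ndarray:
    """Heading (deg, [0, 360)) from the LED1 -> LED2 vector.

    Zero along +x, counter-clockwise positive.  NaN wherever either LED is
    missing: those samples are discarded from head-direction analysis.
    """
    hd = np.full(raw.timestamps.size, np.nan)
    both = raw.led1_valid & raw.led2_valid
    d = raw.led2[both] - raw.led1[both]
    hd[both] = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    return hd


def clean_tracking(raw: RawTracking) -> Trajectory:
    """Replace invalid tracking points by interpolation; derive heading.

    Position is the midpoint of the visible LEDs (a single visible LED is
    used alone).  Invalid samples are linearly interpolated between the
    nearest valid neighbours, with leading/trailing gaps held at the nearest
    valid position; interpolated samples are flagged.
    """
    n = raw.timestamps.size
    l1v, l2v = raw.led1_valid, raw.led2_valid
    valid = l1v | l2v
    if valid.sum() < 2:
        raise UnusableSessionError("fewer than 2 valid tracking samples")
    pos = np.full((n, 2), np.nan)
    both = l1v & l2v
    pos[both] = 0.5 * (raw.led1[both] + raw.led2[both])
    only1 = l1v & ~l2v
    pos[only1] = raw.led1[only1]
    only2 = l2v & ~l1v
    pos[only2] = raw.led2[only2]
    x = _fill_series(raw.timestamps, pos[:, 0], valid)
    y = _fill_series(raw.timestamps, pos[:, 1], valid)
    hd = compute_heading(raw)
    return Trajectory(raw.timestamps, x, y, hd, interpolated=~valid)


def compute_speed(traj: Trajectory, bin_width: float) -> SpeedSeries:
    """Running speed on a uniform binning of the session.

    Per-bin speed is the straight-line displacement between the positions at
    the bin edges divided by the bin width — robust to sample-to-sample pixel
    jitter.  Bins above 50 cm/s are flagged excluded (tracking errors).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0 = traj.timestamps[0]
    T = traj.duration
    n_bins = max(int(np.floor(T / bin_width + 1e-9)), 1)
    edges = t0 + np.arange(n_bins + 1) * bin_width
    # positions at bin edges, clamped to the recorded range; the last bin may
    # extend past the final sample, so divide by the covered span, not the
    # nominal width
    xe = np.interp(edges, traj.timestamps, traj.x)
    ye = np.interp(edges, traj.timestamps, traj.y)
    disp = np.hypot(np.diff(xe), np.diff(ye))
    clamped = np.clip(edges, traj.timestamps[0], traj.timestamps[-1])
    span = np.maximum(np.diff(clamped), 1e-12)
    speed = disp / span
    return SpeedSeries(
        bin_start=edges[:-1],
        bin_width=float(bin_width),
        speed=speed,
        excluded=speed > SPEED_CUTOFF_CM_S,
    )
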