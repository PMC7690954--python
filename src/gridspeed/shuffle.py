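"""Wrapped time-shift shuffle nulls and percentile thresholds.

Each shuffle forward-shifts every spike of a unit by one pseudorandom period
drawn uniformly between 20 s and the trial length minus 20 s, wrapping the
end of the trial to the beginning.  This breaks the spike-behaviour coupling
while preserving the spike count, the mean rate, and (up to one wrap point)
the inter-spike-interval structure.  Metric scores from at least 250 shuffles
per unit are pooled across the units of a group ("global distribution") and
empirical percentiles of the pool serve as classification thresholds: 95th
one-sided for grid / HD / spatial information, 5th-95th two-sided for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gridspeed.core import SpikeTrain

MIN_SHIFT_S = 20.0
DEFAULT_N_SHUFFLES = 250


def shuffle_spike_train(train: SpikeTrain, seed=None,
                        shift: float | None = None) -> SpikeTrain:
    """Circularly time-shift all spikes by one uniform draw in
    [20 s, T - 20 s].  ``seed`` may be an int, a Generator, or omitted when
    an explicit ``shift`` is given."""
    T = train.duration
    if T <= 2 * MIN_SHIFT_S:
        raise ValueError("session too short to shuffle (need > 40 s)")
    if shift is None:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        shift = rng.uniform(MIN_SHIFT_S, T - MIN_SHIFT_S)
    times = np.sort((train.spike_times + shift) % T)
    return SpikeTrain(train.unit_id, times, T, train.half_width_ms)


@dataclass
class ShuffleDistribution:
    """Pooled null scores for one metric over a group of units."""

    metric: str
    values: np.ndarray  # pooled, NaN = metric undefined on that draw
    n_shuffles: int  # per unit
    n_units: int
    seed: int

    def percentile(self, q: float) -> float:
        return float(np.nanpercentile(self.values, q))

    @property
    def threshold_95(self) -> float:
        return self.percentile(95.0)

    @property
    def threshold_5(self) -> float:
        return self.percentile(5.0)


def _unit_rng(global_seed: int, unit_index: int, shuffle_index: int
              ) -> np.random.Generator:
    # independent stream per (seed, unit, shuffle) draw
    return np.random.default_rng(
        np.random.SeedSequence(entropy=global_seed,
                               spawn_key=(unit_index, shuffle_index)))


def null_distribution(metric_fn, trains: list, metric: str = "metric",
                      n_shuffles: int = DEFAULT_N_SHUFFLES,
                      seed: int = 0) -> ShuffleDistribution:
    """Pooled shuffle-null distribution of ``metric_fn`` over ``trains``.

    ``metric_fn(train) -> float`` is evaluated on each shuffled train (the
    behaviour stays unshuffled inside the closure).  Draws on which the
    metric is undefined are recorded as NaN, not zero.
    """
    if n_shuffles < DEFAULT_N_SHUFFLES:
        warnings.warn(
            f"n_shuffles={n_shuffles} is below the recommended minimum of "
            f"{DEFAULT_N_SHUFFLES}", stacklevel=2)
    values = np.full((len(trains), n_shuffles), np.nan)
    for ui, train in enumerate(trains):
        for k in range(n_shuffles):
            shuffled = shuffle_spike_train(train, _unit_rng(seed, ui, k))
            try:
                v = metric_fn(shuffled)
            except (ValueError, FloatingPointError):
                v = np.nan
            values[ui, k] = np.nan if v is None else v
    return ShuffleDistribution(metric=metric, values=values.ravel(),
                               n_shuffles=n_shuffles, n_units=len(trains),
                               seed=seed)


#: Sidedness of each metric's classification rule.
SIDEDNESS = {"grid": "greater", "si": "greater", "hd": "greater",
             "speed": "two-sided"}


def apply_thresholds(observed: dict, dists: dict) -> dict:
    """Classification flags from observed scores and pooled nulls.

    ``observed`` maps metric name ('grid', 'si', 'hd', 'speed') to the unit's
    score; ``dists`` maps the same names to ShuffleDistribution.  Speed is
    two-sided (above the 95th or below the 5th percentile); the others are
    one-sided.  A unit is "spatially modulated (non-grid)" only if its SI
    passes while the grid criterion does not.
    """
    flags = {}
    for name, score in observed.items():
        if name not in dists:
            continue
        d = dists[name]
        if score is None or not np.isfinite(score):
            flags[name] = False
        elif SIDEDNESS.get(name, "greater") == "two-sided":
            flags[name] = bool(score > d.threshold_95 or score < d.threshold_5)
        else:
            flags[name] = bool(score > d.threshold_95)
    if "si" in flags and "grid" in flags:
        flags["spatial_nongrid"] = flags["si"] and not flags["grid"]
    return flags
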