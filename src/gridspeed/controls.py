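"""Robustness controls: split-half stability and incremental downsampling.

Split-half: every tuning metric is recomputed independently on the two
temporal halves of a session (split at the wall-clock midpoint) and compared.
Downsampling: spike trains are Bernoulli-thinned at retention 1/k for factors
k spanning 1-100, and the score-versus-mean-rate curve shows how far firing
rate can fall before a metric collapses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gridspeed.core import SpikeTrain


def slice_train(train: SpikeTrain, t0: float, t1: float,
                rezero: bool = True) -> SpikeTrain:
    """Restrict a train to [t0, t1); optionally shift times to start at 0."""
    sel = (train.spike_times >= t0) & (train.spike_times < t1)
    times = train.spike_times[sel]
    if rezero:
        times = times - t0
    return SpikeTrain(train.unit_id, times, t1 - t0, train.half_width_ms)


def split_half_scores(train: SpikeTrain, duration: float, metric_fn) -> dict:
    """Metric on each temporal half of the session and their difference.

    ``metric_fn(sub_train, t0, t1) -> float`` receives the half-restricted
    train (times re-zeroed) plus the absolute half interval so it can
    restrict the behaviour to the same window.  A half on which the metric is
    undefined yields NaN and is flagged.
    """
    mid = duration / 2.0
    out = {}
    for name, (t0, t1) in (("first", (0.0, mid)), ("second", (mid, duration))):
        sub = slice_train(train, t0, t1)
        try:
            out[name] = float(metric_fn(sub, t0, t1))
        except (ValueError, FloatingPointError):
            out[name] = np.nan
    out["difference"] = out["second"] - out["first"]
    out["defined"] = bool(np.isfinite(out["first"])
                          and np.isfinite(out["second"]))
    return out


def downsample_spike_train(train: SpikeTrain, factor: float,
                           rng) -> SpikeTrain:
    """Bernoulli thinning keeping each spike with probability 1/factor."""
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    if factor == 1:
        return SpikeTrain(train.unit_id, train.spike_times.copy(),
                          train.duration, train.half_width_ms)
    keep = rng.uniform(size=train.n_spikes) < 1.0 / factor
    return SpikeTrain(train.unit_id, train.spike_times[keep],
                      train.duration, train.half_width_ms)


def downsample_factors(n: int = 20, max_factor: float = 100.0) -> np.ndarray:
    """Log-spaced grid of thinning factors spanning 1-100."""
    return np.unique(np.round(np.geomspace(1.0, max_factor, n), 3))


def downsample_robustness(train: SpikeTrain, metric_fn,
                          factors=None, n_seeds: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Score-versus-mean-rate curve under incremental thinning.

    ``metric_fn(thinned_train) -> float``; undefined scores become NaN.
    Returns a long-format table (factor, seed, n_spikes, mean_rate, score).
    """
    if factors is None:
        factors = downsample_factors()
    rows = []
    for fi, factor in enumerate(factors):
        for s in range(n_seeds if factor > 1 else 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(fi, s)))
            thinned = downsample_spike_train(train, factor, rng)
            try:
                score = float(metric_fn(thinned))
            except (ValueError, FloatingPointError):
                score = np.nan
            rows.append({
                "factor": float(factor), "seed": s,
                "n_spikes": thinned.n_spikes,
                "mean_rate": thinned.n_spikes / train.duration,
                "score": score,
            })
    return pd.DataFrame(rows)
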