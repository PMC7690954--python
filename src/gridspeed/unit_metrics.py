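"""Per-unit firing statistics: mean rate, waveform class, theta modulation.

The theta modulation index (TMI) is computed from the spike-train
autocorrelogram (lags within +-500 ms, 2 ms bins): the zero-lag peak is
reduced to the next maximal value, the function is mean-subtracted, tapered
with a Hamming window, and Fourier-transformed at length 2^16; power is the
squared transform scaled by the autocorrelogram length.  TMI is the mean
power within 1 Hz of the spectral peak inside 5-12 Hz divided by the mean
power over 0-125 Hz; units with TMI > 5 count as theta modulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gridspeed.core import SpikeTrain

#: Waveform half-width boundary (ms): narrower units are putative
#: interneurons.  Exactly at the boundary a unit is assigned excitatory.
INTERNEURON_HALF_WIDTH_MS = 0.35
#: Mean-rate threshold (Hz) for the fast-spiking flag.
FAST_SPIKING_RATE_HZ = 10.0
#: TMI threshold defining "theta modulated".
TMI_THRESHOLD = 5.0

THETA_BAND = (5.0, 12.0)


class UndefinedTMIError(ValueError):
    """TMI needs at least two spikes."""


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count divided by session duration (Hz)."""
    if train.duration <= 0:
        raise ValueError("session duration must be positive")
    return train.n_spikes / train.duration


def classify_waveform(train: SpikeTrain) -> tuple:
    """(putative class, fast_spiking flag) from half-width and mean rate.

    Returns class ``None`` when the half-width was not recorded.
    """
    fast = mean_firing_rate(train) > FAST_SPIKING_RATE_HZ
    if train.half_width_ms is None or not np.isfinite(train.half_width_ms):
        return None, fast
    cls = ("putative_interneuron"
           if train.half_width_ms < INTERNEURON_HALF_WIDTH_MS
           else "putative_excitatory")
    return cls, fast


def spike_autocorrelogram(spike_times: np.ndarray, max_lag: float = 0.5,
                          bin_width: float = 0.002) -> tuple:
    """Spike-train autocorrelogram over lags in [-max_lag, max_lag].

    Counts ordered spike pairs per lag bin; bins are centred on multiples of
    ``bin_width`` so the function is exactly symmetric, with the self-pair
    counts excluded from the zero-lag bin.  Returns (lags, counts).
    """
    t = np.asarray(spike_times, dtype=float)
    n_half = int(round(max_lag / bin_width))
    lags = np.arange(-n_half, n_half + 1) * bin_width
    pos = np.zeros(n_half + 1)  # bins centred at 0, dt, 2 dt, ...
    hi_edge = (n_half + 0.5) * bin_width
    # iterate over neighbour offsets k (i, i+k): cheap because the number of
    # spikes within the lag window is small relative to the train
    k = 1
    while k < t.size:
        d = t[k:] - t[:-k]
        d = d[d < hi_edge]
        if d.size == 0:
            break
        pos += np.bincount(np.round(d / bin_width).astype(int),
                           minlength=n_half + 1)[: n_half + 1]
        k += 1
    counts = np.concatenate([pos[::-1][:-1], pos])
    counts[n_half] = 2 * pos[0]  # coincident pairs, once per direction
    return lags, counts


@dataclass
class TMIResult:
    tmi: float
    theta_peak_freq: float  # Hz
    is_theta_modulated: bool
    power: np.ndarray = None  # spectrum (diagnostic)
    freqs: np.ndarray = None


def theta_modulation_index(train: SpikeTrain, max_lag: float = 0.5,
                           bin_width: float = 0.002,
                           nfft: int = 2 ** 16) -> TMIResult:
    """TMI of one unit from its autocorrelogram spectrum (see module doc)."""
    if train.n_spikes < 2:
        raise UndefinedTMIError(f"unit {train.unit_id}: fewer than 2 spikes")
    lags, ac = spike_autocorrelogram(train.spike_times, max_lag, bin_width)
    n = ac.size  # 501
    center = n // 2
    side = np.delete(ac, center)
    next_max = side.max() if side.size else 0.0
    ac = ac.copy()
    ac[center] = min(ac[center], next_max)
    ac = ac - ac.mean()
    ac = ac * np.hamming(n)
    spec = np.fft.rfft(ac, n=nfft)
    power = (spec.real ** 2 + spec.imag ** 2) / n
    freqs = np.fft.rfftfreq(nfft, d=bin_width)
    in_theta = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    pk = freqs[in_theta][np.argmax(power[in_theta])]
    around = (freqs >= pk - 1.0) & (freqs <= pk + 1.0)
    broad = (freqs >= 0.0) & (freqs <= 125.0)
    tmi = float(power[around].mean() / power[broad].mean())
    return TMIResult(tmi=tmi, theta_peak_freq=float(pk),
                     is_theta_modulated=tmi > TMI_THRESHOLD,
                     power=power[broad], freqs=freqs[broad])
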