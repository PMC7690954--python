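"""LFP oscillation-running speed coupling.

Band power and peak frequency are estimated on non-overlapping 0.5 s windows
with a multitaper (DPSS) estimator, paired with running speed from the same
windows, averaged in 1 cm/s speed bins (1-30 cm/s), normalised to immobility
(< 1 cm/s), and summarised by an ordinary least-squares regression on the
speed-bin centres with a Fisher z-transformed correlation.

Bands: theta 5-12 Hz, slow gamma 30-50 Hz, fast gamma 60-120 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

from gridspeed.core import LFPSignal, SpeedSeries


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float  # Hz
    hi: float  # Hz

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("band limits must satisfy 0 <= lo < hi")


THETA = BandDefinition("theta", 5.0, 12.0)
SLOW_GAMMA = BandDefinition("slow_gamma", 30.0, 50.0)
FAST_GAMMA = BandDefinition("fast_gamma", 60.0, 120.0)
BANDS = {"theta": THETA, "slow_gamma": SLOW_GAMMA, "fast_gamma": FAST_GAMMA}


@dataclass
class WindowedBandMetrics:
    """Per-window band power and spectral peak frequency."""

    band: BandDefinition
    window: float  # s
    t_start: np.ndarray  # s, window starts
    power: np.ndarray  # mean in-band PSD per window (mV^2/Hz)
    peak_freq: np.ndarray  # Hz


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    fisher_z: float
    n: int


@dataclass
class BandSpeedTuning:
    band: BandDefinition
    speed_bin_centers: np.ndarray  # cm/s
    normalized_power: np.ndarray  # immobility == 1; NaN where unoccupied
    peak_freq: np.ndarray  # Hz; NaN where unoccupied
    n_windows: np.ndarray  # windows per speed bin
    immobility_power: float  # raw power at < 1 cm/s
    power_regression: RegressionResult | None = None
    freq_regression: RegressionResult | None = None


class NormalizationError(ValueError):
    """No immobility (< 1 cm/s) windows: tuning cannot be normalised."""


class InsufficientDataError(ValueError):
    pass


def fisher_z(r: float, clamp: float = 1.0 - 1e-12) -> float:
    """atanh with |r| clamped just inside 1 so degenerate perfect fits on
    synthetic data stay finite."""
    return float(np.arctanh(np.clip(r, -clamp, clamp)))


def windowed_band_metrics(lfp: LFPSignal, band: BandDefinition,
                          window: float = 0.5, nw: float = 2.0,
                          n_tapers: int = 3, nfft: int = 2 ** 14,
                          ) -> WindowedBandMetrics:
    """Multitaper band power and peak frequency on non-overlapping windows.

    Time-bandwidth NW=2 with 3 tapers per 0.5 s window (Chronux-style
    defaults).  Windows are zero-padded to ``nfft`` so the spectral peak can
    be located well below the 1/window raw resolution.
    """
    nper = int(round(window * lfp.fs))
    n_win = lfp.samples.size // nper
    if n_win < 1:
        raise ValueError("window longer than the signal")
    tapers = dpss(nper, nw, Kmax=n_tapers)  # (K, nper), unit-energy rows
    freqs = np.fft.rfftfreq(nfft, d=1.0 / lfp.fs)
    in_band = (freqs >= band.lo) & (freqs <= band.hi)
    if not np.any(in_band):
        raise ValueError("band empty at this resolution")
    band_idx = np.flatnonzero(in_band)

    power = np.empty(n_win)
    peak = np.empty(n_win)
    chunk = 256
    segs = lfp.samples[: n_win * nper].reshape(n_win, nper)
    segs = segs - segs.mean(axis=1, keepdims=True)
    for start in range(0, n_win, chunk):
        blk = segs[start:start + chunk]  # (m, nper)
        psd = np.zeros((blk.shape[0], band_idx.size))
        psd0 = None
        for tap in tapers:
            spec = np.fft.rfft(blk * tap, n=nfft, axis=1)[:, band_idx]
            p = spec.real ** 2 + spec.imag ** 2
            if psd0 is None:
                psd0 = p  # most concentrated taper: sharpest peak
            psd += p
        # one-sided PSD, averaged over tapers
        psd *= 2.0 / (n_tapers * lfp.fs)
        power[start:start + chunk] = psd.mean(axis=1)
        # peak located on the first-taper spectrum: the taper average is
        # flat-topped over the 2W bandwidth and its argmax rides the lobe
        # edges, while taper 0 is maximally concentrated at the line
        peak[start:start + chunk] = freqs[band_idx][np.argmax(psd0, axis=1)]
    t_start = np.arange(n_win) * window
    return WindowedBandMetrics(band, window, t_start, power, peak)


def speed_binned_tuning(metrics: WindowedBandMetrics, speeds: SpeedSeries,
                        lo: float = 1.0, hi: float = 30.0,
                        immobility_below: float = 1.0) -> BandSpeedTuning:
    """Average windowed metrics in 1 cm/s speed bins, normalised to immobility.

    Speed bins must share the window timebase (same width and origin).
    Windows paired with an excluded (> 50 cm/s) speed bin are dropped.  Bins
    the animal never visited are NaN (absent), not zero.
    """
    if abs(speeds.bin_width - metrics.window) > 1e-9:
        raise ValueError("speed series must be binned at the analysis window")
    n = min(metrics.power.size, speeds.speed.size)
    sp = speeds.speed[:n]
    ok = ~speeds.excluded[:n]
    pw = metrics.power[:n]
    pf = metrics.peak_freq[:n]

    immob = ok & (sp < immobility_below)
    if not np.any(immob):
        raise NormalizationError(
            "no immobility windows (< %.0f cm/s): cannot normalise band power"
            % immobility_below)
    p0 = float(pw[immob].mean())

    edges = np.arange(lo, hi + 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    npow = np.full(centers.size, np.nan)
    pkf = np.full(centers.size, np.nan)
    cnt = np.zeros(centers.size, dtype=int)
    which = np.digitize(sp, edges) - 1
    for b in range(centers.size):
        m = ok & (which == b) & (sp >= lo) & (sp < hi)
        cnt[b] = int(m.sum())
        if cnt[b]:
            npow[b] = pw[m].mean() / p0
            pkf[b] = pf[m].mean()
    return BandSpeedTuning(metrics.band, centers, npow, pkf, cnt, p0)


def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), r2=float(res.rvalue ** 2),
        p=float(res.pvalue), fisher_z=fisher_z(res.rvalue), n=int(x.size))


def tuning_regression(tuning: BandSpeedTuning) -> BandSpeedTuning:
    """OLS of normalised power and of peak frequency on speed-bin centres.

    Fills the regression fields in place (and returns the tuning).  Requires
    at least 3 occupied speed bins.
    """
    occ = np.isfinite(tuning.normalized_power)
    if occ.sum() < 3:
        raise InsufficientDataError("fewer than 3 occupied speed bins")
    x = tuning.speed_bin_centers[occ]
    tuning.power_regression = _regress(x, tuning.normalized_power[occ])
    occf = np.isfinite(tuning.peak_freq)
    tuning.freq_regression = _regress(tuning.speed_bin_centers[occf],
                                      tuning.peak_freq[occf])
    return tuning


def band_speed_analysis(lfp: LFPSignal, speeds: SpeedSeries,
                        band: BandDefinition = THETA,
                        window: float = 0.5) -> BandSpeedTuning:
    """Full pipeline for one band: windowed metrics -> tuning -> regression."""
    metrics = windowed_band_metrics(lfp, band, window=window)
    tuning = speed_binned_tuning(metrics, speeds)
    return tuning_regression(tuning)
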