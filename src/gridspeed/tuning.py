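"""Tuning metrics for spatially- and behaviourally-modulated units.

Implements the four scores used to classify functional cell types in
MEC-style recordings:

* grid score — rotational-symmetry statistic on the annulus of the 2D
  rate-map autocorrelation (min of the 60/120 deg correlations minus the max
  of 30/90/150 deg);
* spatial information — Skaggs information rate, bits/spike;
* HD score — mean vector length of the smoothed circular firing-rate
  histogram (3 deg bins, Gaussian window over 14 deg);
* speed score — Fisher z of the Pearson correlation between instantaneous
  firing rate and running speed (40 ms bins, both series smoothed with a
  500 ms Gaussian window, speeds restricted to 2-30 cm/s bins holding more
  than 0.5% of the session).

Rate maps use 3 x 3 cm spatial bins smoothed with a 2D Gaussian of
sigma = 1.5 bins, renormalised over visited bins only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from gridspeed.core import SpeedSeries, SpikeTrain, Trajectory
from gridspeed.lfp import fisher_z

SPATIAL_BIN_CM = 3.0
RATE_MAP_SIGMA_BINS = 1.5
HD_BIN_DEG = 3.0
HD_WINDOW_DEG = 14.0
SPEED_BIN_S = 0.040
SPEED_SMOOTH_WINDOW_S = 0.5
SPEED_RANGE_CM_S = (2.0, 30.0)
SPEED_MIN_OCCUPANCY_FRAC = 0.005


# ---------------------------------------------------------------------------
# Rate maps
# ---------------------------------------------------------------------------

@dataclass
class RateMap:
    x_edges: np.ndarray  # cm
    y_edges: np.ndarray
    occupancy: np.ndarray  # s per bin, (ny, nx)
    spike_counts: np.ndarray
    rate: np.ndarray  # Hz, NaN on unvisited bins
    smoothed_rate: np.ndarray  # Hz, NaN on unvisited bins
    visited: np.ndarray  # bool


def _masked_smooth(values: np.ndarray, mask: np.ndarray,
                   sigma: float) -> np.ndarray:
    """Gaussian smoothing renormalised over valid bins only."""
    v = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(v, sigma, mode="constant")
    den = ndimage.gaussian_filter(mask.astype(float), sigma, mode="constant")
    out = np.full(values.shape, np.nan)
    ok = mask & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


def spike_position_indices(train: SpikeTrain, traj: Trajectory) -> np.ndarray:
    """Index of the nearest-in-time trajectory sample for each spike."""
    ts = traj.timestamps
    idx = np.clip(np.searchsorted(ts, train.spike_times), 0, ts.size - 1)
    left = np.clip(idx - 1, 0, ts.size - 1)
    use_left = np.abs(ts[left] - train.spike_times) < \
        np.abs(ts[idx] - train.spike_times)
    return np.where(use_left, left, idx)


class SpatialBinning:
    """Precomputed spatial binning of a trajectory.

    Caches the per-sample bin index and the occupancy map so the rate map of
    a (possibly time-shuffled) spike train reduces to one searchsorted plus
    one bincount — the hot path of the shuffle null.
    """

    def __init__(self, traj: Trajectory, extent: tuple | None = None,
                 bin_size: float = SPATIAL_BIN_CM):
        self.traj = traj
        self.bin_size = float(bin_size)
        if extent is None:
            extent = (float(np.nanmax(traj.x)), float(np.nanmax(traj.y)))
        nx = max(int(math.ceil(extent[0] / bin_size)), 1)
        ny = max(int(math.ceil(extent[1] / bin_size)), 1)
        self.x_edges = np.arange(nx + 1) * bin_size
        self.y_edges = np.arange(ny + 1) * bin_size
        ix = np.clip(np.floor(traj.x / bin_size).astype(int), 0, nx - 1)
        iy = np.clip(np.floor(traj.y / bin_size).astype(int), 0, ny - 1)
        self.flat_idx = iy * nx + ix
        self.shape = (ny, nx)
        dt = 1.0 / traj.sample_rate
        self.occupancy = np.bincount(
            self.flat_idx, minlength=nx * ny).reshape(ny, nx) * dt
        self.visited = self.occupancy > 0

    def rate_map(self, train: SpikeTrain, sigma_bins: float = RATE_MAP_SIGMA_BINS,
                 ) -> RateMap:
        sidx = spike_position_indices(train, self.traj)
        counts = np.bincount(self.flat_idx[sidx],
                             minlength=self.occupancy.size
                             ).reshape(self.shape).astype(float)
        rate = np.full(self.shape, np.nan)
        rate[self.visited] = counts[self.visited] / self.occupancy[self.visited]
        smoothed = _masked_smooth(rate, self.visited, sigma_bins)
        return RateMap(self.x_edges, self.y_edges, self.occupancy, counts,
                       rate, smoothed, self.visited)


def build_rate_map(train: SpikeTrain, traj: Trajectory,
                   extent: tuple | None = None,
                   bin_size: float = SPATIAL_BIN_CM,
                   sigma_bins: float = RATE_MAP_SIGMA_BINS) -> RateMap:
    """Occupancy-normalised, Gaussian-smoothed firing-rate map (3x3 cm)."""
    binning = SpatialBinning(traj, extent, bin_size)
    if not binning.visited.any():
        raise ValueError("zero occupancy everywhere")
    return binning.rate_map(train, sigma_bins)


# ---------------------------------------------------------------------------
# Spatial autocorrelation and grid score
# ---------------------------------------------------------------------------

@dataclass
class AutocorrMap:
    values: np.ndarray  # Pearson r per spatial lag, NaN where unsupported
    n_overlap: np.ndarray  # overlapping visited bins per lag

    @property
    def center(self) -> tuple:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def spatial_autocorrelation(rate_map: RateMap | np.ndarray,
                            mask: np.ndarray | None = None,
                            min_overlap: int = 20) -> AutocorrMap:
    """Pearson correlation of the smoothed map with itself at every integer
    bin offset, computed over mutually visited bins (FFT-accelerated)."""
    if isinstance(rate_map, RateMap):
        z = rate_map.smoothed_rate
        mask = rate_map.visited
    else:
        z = np.asarray(rate_map, dtype=float)
        if mask is None:
            mask = np.isfinite(z)
    m = mask.astype(float)
    zz = np.where(mask, z, 0.0)

    def corr(a, b):
        return signal.fftconvolve(a, b[::-1, ::-1], mode="full")

    n = corr(m, m)
    sx = corr(zz, m)
    sy = corr(m, zz)
    sxx = corr(zz * zz, m)
    syy = corr(m, zz * zz)
    sxy = corr(zz, zz)
    n_round = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(np.clip(varx, 0, None) * np.clip(vary, 0, None))
    r[n_round < min_overlap] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return AutocorrMap(r, n_round.astype(int))


@dataclass
class GridScore:
    g: float
    rotation_corr: dict  # angle deg -> Pearson r on the annulus
    inner_radius: float  # bins
    outer_radius: float  # bins
    n_peaks: int
    used_fallback_annulus: bool


def _autocorr_peaks(ac: AutocorrMap) -> tuple:
    """Central-field radius and surrounding local maxima of the autocorr.

    The central peak is the contiguous region around zero lag with r > 0.5;
    local maxima outside it are candidate grid fields.
    """
    v = ac.values
    cy, cx = ac.center
    finite = np.isfinite(v)
    high = finite & (v > 0.5)
    lab, _ = ndimage.label(high)
    central = lab[cy, cx]
    if central == 0:
        inner = 1.0
        central_mask = np.zeros_like(high)
    else:
        central_mask = lab == central
        ys, xs = np.nonzero(central_mask)
        inner = float(np.max(np.hypot(ys - cy, xs - cx))) + 0.5
    filled = np.where(finite, v, -np.inf)
    local_max = (ndimage.maximum_filter(filled, size=3) == filled) & finite
    local_max &= ~central_mask
    # genuine grid fields correlate clearly; near-zero maxima are boundary
    # artefacts of the finite map support
    local_max &= v > 0.1
    ys, xs = np.nonzero(local_max)
    d = np.hypot(ys - cy, xs - cx)
    keep = d > inner
    order = np.argsort(d[keep])
    dists = d[keep][order]
    return inner, dists


def _annulus_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    ok = mask & np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def grid_score(ac: AutocorrMap, min_overlap_used: int = 20) -> GridScore:
    """Rotational grid score g = min(r60, r120) - max(r30, r90, r150).

    The correlation annulus runs from the edge of the central peak to a ring
    enclosing the six local maxima closest to the centre; when fewer than six
    peaks are detectable a fallback annulus (twice the median peak distance,
    or half the map radius if no peaks exist) is used and flagged.
    """
    v = ac.values
    cy, cx = ac.center
    inner, dists = _autocorr_peaks(ac)
    # keep the annulus inside the well-supported central part of the map:
    # lags close to the map size rest on few bins and carry edge structure
    max_r = 0.9 * min(cy, cx)
    dists = dists[dists <= max_r]
    fallback = dists.size < 6
    if not fallback:
        outer = min(float(dists[5]) * 1.25, float(max_r))
    elif dists.size:
        outer = min(2.0 * float(np.median(dists)), float(max_r))
    else:
        outer = 0.5 * float(max_r)
    outer = max(outer, inner + 2.0)

    yy, xx = np.indices(v.shape)
    rr = np.hypot(yy - cy, xx - cx)
    annulus = (rr > inner) & (rr <= outer)
    base = np.where(np.isfinite(v), v, 0.0)
    valid = np.isfinite(v).astype(float)
    corrs = {}
    for ang in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(base, ang, reshape=False, order=1)
        rot_valid = ndimage.rotate(valid, ang, reshape=False, order=1)
        ok = annulus & (rot_valid > 0.99) & np.isfinite(v)
        corrs[ang] = _annulus_pearson(v, rot, ok)
    g = float(min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150]))
    return GridScore(g=g, rotation_corr=corrs, inner_radius=inner,
                     outer_radius=outer, n_peaks=int(dists.size),
                     used_fallback_annulus=fallback)


def grid_score_from_map(rate_map: RateMap) -> GridScore:
    return grid_score(spatial_autocorrelation(rate_map))


# ---------------------------------------------------------------------------
# Spatial information (Skaggs, bits/spike)
# ---------------------------------------------------------------------------

class UndefinedSIError(ValueError):
    pass


def spatial_information(rate_map: RateMap, use_smoothed: bool = True) -> float:
    """SI = sum_i p_i (l_i / L) log2(l_i / L), L = sum_i p_i l_i.

    p_i is the occupancy share of visited bin i, l_i its firing rate;
    zero-rate bins contribute nothing.
    """
    vis = rate_map.visited
    lam = (rate_map.smoothed_rate if use_smoothed else rate_map.rate)[vis]
    p = rate_map.occupancy[vis]
    p = p / p.sum()
    mean_rate = float(np.sum(p * lam))
    if not mean_rate > 0:
        raise UndefinedSIError("mean firing rate is zero")
    ratio = lam / mean_rate
    nz = ratio > 0
    return float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))


# ---------------------------------------------------------------------------
# Head-direction tuning
# ---------------------------------------------------------------------------

@dataclass
class HDTuning:
    bin_centers_deg: np.ndarray
    rate: np.ndarray  # Hz, occupancy-normalised
    smoothed_rate: np.ndarray  # Hz
    mvl: float  # mean vector length in [0, 1]
    preferred_deg: float


def _circular_masked_smooth(values, mask, sigma_bins):
    v = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter1d(v, sigma_bins, mode="wrap")
    den = ndimage.gaussian_filter1d(mask.astype(float), sigma_bins, mode="wrap")
    out = np.full(values.shape, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def hd_score(train: SpikeTrain, traj: Trajectory,
             bin_deg: float = HD_BIN_DEG,
             window_deg: float = HD_WINDOW_DEG) -> HDTuning:
    """Mean vector length of the smoothed HD firing-rate histogram.

    Heading is binned at 3 deg; the occupancy-normalised rate histogram is
    smoothed with a circular Gaussian window spanning 14 deg (sigma = 3.5
    deg); the score is R = |sum_j r_j e^{i theta_j}| / sum_j r_j.
    """
    hd = traj.hd_deg
    has_hd = np.isfinite(hd)
    if not has_hd.any():
        raise ValueError("empty head-direction series")
    n_bins = int(round(360.0 / bin_deg))
    dt = 1.0 / traj.sample_rate
    hbin = np.full(hd.size, -1)
    hbin[has_hd] = np.clip((hd[has_hd] / bin_deg).astype(int), 0, n_bins - 1)
    occ = np.bincount(hbin[has_hd], minlength=n_bins) * dt
    sidx = spike_position_indices(train, traj)
    sbin = hbin[sidx]
    counts = np.bincount(sbin[sbin >= 0], minlength=n_bins).astype(float)
    visited = occ > 0
    rate = np.full(n_bins, np.nan)
    rate[visited] = counts[visited] / occ[visited]
    sigma_bins = (window_deg / 4.0) / bin_deg  # total window = 4 sigma
    sm = _circular_masked_smooth(rate, visited, sigma_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_deg
    ok = np.isfinite(sm)
    w = sm[ok]
    th = np.radians(centers[ok])
    total = w.sum()
    if total <= 0:
        return HDTuning(centers, rate, sm, 0.0, np.nan)
    vec = np.sum(w * np.exp(1j * th)) / total
    return HDTuning(centers, rate, sm, float(np.abs(vec)),
                    float(np.degrees(np.angle(vec)) % 360.0))


# ---------------------------------------------------------------------------
# Speed score
# ---------------------------------------------------------------------------

@dataclass
class SpeedScoreResult:
    r: float
    z: float
    valid: bool
    n_bins: int
    slope: float = np.nan  # Hz per cm/s, OLS on retained bins


class SpeedScoringContext:
    """Precomputed behaviour side of speed scoring (40 ms bins).

    Holds the smoothed speed series and the retained-bin mask (speeds in
    2-30 cm/s whose 1 cm/s bin holds > 0.5% of the session), so scoring a
    shuffled train costs one histogram and one 1D smoothing pass.
    """

    def __init__(self, speeds: SpeedSeries,
                 smooth_window_s: float = SPEED_SMOOTH_WINDOW_S,
                 speed_range: tuple = SPEED_RANGE_CM_S,
                 min_occupancy_frac: float = SPEED_MIN_OCCUPANCY_FRAC):
        self.bin_width = float(speeds.bin_width)
        self.edges = np.append(speeds.bin_start,
                               speeds.bin_start[-1] + self.bin_width)
        self.sigma_bins = (smooth_window_s / 4.0) / self.bin_width
        sm_speed = ndimage.gaussian_filter1d(speeds.speed, self.sigma_bins)
        lo, hi = speed_range
        in_range = (~speeds.excluded) & (sm_speed >= lo) & (sm_speed <= hi)
        # occupancy filter on 1 cm/s speed bins
        which = np.floor(sm_speed).astype(int)
        duration = speeds.speed.size * self.bin_width
        min_bins = min_occupancy_frac * duration / self.bin_width
        bin_ok = np.zeros(int(max(np.max(which[in_range], initial=0) + 1, 1)),
                          dtype=bool)
        counts = np.bincount(which[in_range], minlength=bin_ok.size)
        bin_ok = counts > min_bins
        self.retained = in_range & bin_ok[np.clip(which, 0, bin_ok.size - 1)]
        self.smoothed_speed = sm_speed

    def firing_rate(self, train: SpikeTrain) -> np.ndarray:
        counts, _ = np.histogram(train.spike_times, self.edges)
        rate = counts / self.bin_width
        return ndimage.gaussian_filter1d(rate.astype(float), self.sigma_bins)

    def score(self, train: SpikeTrain) -> SpeedScoreResult:
        rate = self.firing_rate(train)
        m = self.retained
        n = int(m.sum())
        if n < 10:
            return SpeedScoreResult(np.nan, np.nan, False, n)
        x = self.smoothed_speed[m]
        y = rate[m]
        if x.std() == 0 or y.std() == 0:
            return SpeedScoreResult(np.nan, np.nan, False, n)
        r = float(np.corrcoef(x, y)[0, 1])
        slope = r * y.std() / x.std()
        return SpeedScoreResult(r, fisher_z(r), True, n, slope=float(slope))


def speed_score(train: SpikeTrain, speeds: SpeedSeries,
                **kwargs) -> SpeedScoreResult:
    """Fisher-z speed score of one unit against a 40 ms speed series."""
    return SpeedScoringContext(speeds, **kwargs).score(train)


def speed_tuning_curve(train: SpikeTrain, speeds: SpeedSeries,
                       ctx: SpeedScoringContext | None = None) -> tuple:
    """Mean firing rate in 1 cm/s speed bins over retained bins."""
    ctx = ctx or SpeedScoringContext(speeds)
    rate = ctx.firing_rate(train)
    m = ctx.retained
    sp = ctx.smoothed_speed[m]
    rt = rate[m]
    lo = int(np.floor(sp.min()))
    hi = int(np.ceil(sp.max()))
    edges = np.arange(lo, hi + 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean_rate = np.full(centers.size, np.nan)
    which = np.digitize(sp, edges) - 1
    for b in range(centers.size):
        sel = which == b
        if sel.any():
            mean_rate[b] = rt[sel].mean()
    ok = np.isfinite(mean_rate)
    return centers[ok], mean_rate[ok]


def classify_speed_relationship(train: SpikeTrain, speeds: SpeedSeries,
                                ctx: SpeedScoringContext | None = None) -> dict:
    """Classify a speed-modulated unit as linear vs saturating, +/-.

    The 1 cm/s tuning curve is fit with OLS against speed and against
    log(speed); the better R^2 decides the form (a saturating rate is nearly
    affine in log speed).  The sign is the sign of the speed correlation.
    """
    ctx = ctx or SpeedScoringContext(speeds)
    sc = ctx.score(train)
    centers, mean_rate = speed_tuning_curve(train, speeds, ctx)
    if centers.size < 3 or not sc.valid:
        return {"form": None, "sign": None, "r2_linear": np.nan,
                "r2_log": np.nan}
    lin = stats.linregress(centers, mean_rate)
    logf = stats.linregress(np.log(centers), mean_rate)
    form = "linear" if lin.rvalue ** 2 >= logf.rvalue ** 2 else "saturating"
    sign = "positive" if sc.r >= 0 else "negative"
    return {"form": form, "sign": sign,
            "r2_linear": float(lin.rvalue ** 2),
            "r2_log": float(logf.rvalue ** 2)}


# ---------------------------------------------------------------------------
# Per-unit result container
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    """All tuning metrics of one unit (NaN where undefined)."""

    unit_id: str
    grid_score: float = np.nan
    si: float = np.nan
    hd_score: float = np.nan
    speed_r: float = np.nan
    speed_z: float = np.nan
    speed_valid: bool = False
    speed_form: str | None = None
    speed_sign: str | None = None
    tmi: float = np.nan
    mean_rate: float = np.nan
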