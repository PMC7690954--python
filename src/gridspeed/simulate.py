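"""Synthetic session generator with full ground truth.

Produces open-field / track trajectories, tuned spike trains (grid,
head-direction, speed, place, conjunctive, theta-modulated, untuned) by
inhomogeneous-Poisson thinning, and an LFP whose theta amplitude and frequency
scale linearly with running speed, on top of slow/fast gamma and 1/f noise.

The generator exists so that every downstream estimator can be validated
against known generative parameters (parameter-recovery and null-calibration
tests); it emulates the statistical structure of freely-moving rodent
recordings, not their biophysics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from gridspeed.core import LFPSignal, Session, SpeedSeries, SpikeTrain, Trajectory


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

ARENA_SHAPES = ("square_open_field", "linear_track", "l_track")


@dataclass(frozen=True)
class ArenaSpec:
    """Recording environment: 80x80 cm open field or 150 cm track."""

    shape: str = "square_open_field"
    extent: tuple = (80.0, 80.0)  # cm per dimension
    track_width: float = 10.0  # cm, for linear/L tracks

    def __post_init__(self) -> None:
        if self.shape not in ARENA_SHAPES:
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if any(e <= 0 for e in self.extent):
            raise ValueError("arena extents must be strictly positive")


def open_field() -> ArenaSpec:
    return ArenaSpec("square_open_field", (80.0, 80.0))


def linear_track() -> ArenaSpec:
    return ArenaSpec("linear_track", (150.0,))


def l_track(arm: float = 100.0) -> ArenaSpec:
    return ArenaSpec("l_track", (arm, arm))


@dataclass(frozen=True)
class TrajectoryParams:
    """Mean-reverting (OU) velocity random walk parameters.

    ``mean_speed_target`` is the stationary mean of |v|; the open-field
    process is an isotropic 2D OU velocity, so speeds are Rayleigh-distributed
    and span roughly (0, 3x target) — covering the 1-30 cm/s analysis range
    for the default 8 cm/s target.
    """

    duration: float = 1200.0  # s
    sample_rate: float = 25.0  # Hz (overhead camera rate)
    mean_speed_target: float = 8.0  # cm/s
    speed_persistence: float = 1.0  # s, velocity autocorrelation time
    turning_persistence: float = 0.5  # s, angular-velocity correlation time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if not (0 < self.mean_speed_target < 50):
            raise ValueError("mean_speed_target must lie in (0, 50) cm/s")


SPEED_FORMS = ("linear", "saturating")
UNIT_KINDS = ("grid", "hd", "speed", "place", "conjunctive", "untuned")


@dataclass(frozen=True)
class UnitModel:
    """Generative firing model for one unit.

    ``base_rate`` is the peak rate for spatially/directionally tuned kinds and
    the intercept for speed kinds.  Theta modulation multiplies any kind's
    rate by ``1 + theta_mod_depth * cos(2 pi theta_freq t)``.
    """

    kind: str = "untuned"
    base_rate: float = 5.0  # Hz
    # grid / place geometry
    grid_spacing: float = 30.0  # cm
    grid_orientation: float = 0.0  # deg
    grid_phase: tuple = (0.0, 0.0)  # cm offset
    place_sigma: float = 10.0  # cm, place-field width
    # head direction
    hd_mu: float = 0.0  # deg
    hd_kappa: float = 2.0
    # speed tuning
    speed_slope: float = 0.5  # Hz per cm/s (initial slope)
    speed_form: str = "linear"
    speed_sign: str = "positive"
    saturation_constant: float = 5.0  # cm/s
    # theta
    theta_mod_depth: float = 0.0  # in [0, 1]
    theta_freq: float = 8.0  # Hz
    # waveform summary
    half_width_ms: float = 0.45

    def __post_init__(self) -> None:
        if self.kind not in UNIT_KINDS:
            raise ValueError(f"unknown unit kind {self.kind!r}")
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        if not (0 <= self.theta_mod_depth <= 1):
            raise ValueError("theta_mod_depth must lie in [0, 1]")
        if self.kind == "grid" and self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive for grid units")
        if self.speed_form not in SPEED_FORMS:
            raise ValueError(f"unknown speed_form {self.speed_form!r}")


@dataclass(frozen=True)
class LFPModel:
    """Speed-coupled LFP: theta whose amplitude/frequency follow running
    speed linearly, slow and fast gamma, pink (1/f) plus white noise."""

    theta_base_amp: float = 0.15  # mV at immobility
    theta_amp_slope: float = 0.01  # mV per cm/s
    theta_base_freq: float = 7.5  # Hz
    theta_freq_slope: float = 0.045  # Hz per cm/s (WT-like coupling)
    slow_gamma_amp: float = 0.03  # mV
    slow_gamma_freq: float = 40.0  # Hz
    slow_gamma_amp_slope: float = 0.001  # mV per cm/s
    fast_gamma_amp: float = 0.02  # mV
    fast_gamma_freq: float = 90.0  # Hz
    fast_gamma_amp_slope: float = 0.0015  # mV per cm/s
    noise_exponent: float = 1.0  # 1/f slope of background
    noise_scale: float = 0.05  # mV rms of pink background
    white_scale: float = 0.01  # mV rms of white noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_base_amp", "slow_gamma_amp", "fast_gamma_amp",
                     "noise_scale", "white_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (5.0 <= self.theta_base_freq <= 12.0):
            raise ValueError("theta_base_freq must lie in [5, 12] Hz")


@dataclass
class SyntheticGroundTruth:
    """Generative parameters of a simulated session (per-unit models, LFP
    model, trajectory parameters, and every seed used)."""

    arena: ArenaSpec
    trajectory_params: TrajectoryParams
    unit_models: dict = field(default_factory=dict)  # unit_id -> UnitModel
    lfp_model: LFPModel | None = None
    spike_seeds: dict = field(default_factory=dict)  # unit_id -> int

    def to_dict(self) -> dict:
        def plain(obj):  # YAML/JSON-safe: tuples become lists
            d = asdict(obj)
            return {k: list(v) if isinstance(v, tuple) else v
                    for k, v in d.items()}

        d = {
            "arena": plain(self.arena),
            "trajectory_params": plain(self.trajectory_params),
            "unit_models": {k: plain(v) for k, v in self.unit_models.items()},
            "spike_seeds": dict(self.spike_seeds),
        }
        if self.lfp_model is not None:
            d["lfp_model"] = plain(self.lfp_model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGroundTruth":
        arena_d = dict(d["arena"])
        arena_d["extent"] = tuple(arena_d["extent"])
        unit_models = {}
        for k, v in d.get("unit_models", {}).items():
            v = dict(v)
            v["grid_phase"] = tuple(v["grid_phase"])
            unit_models[k] = UnitModel(**v)
        lfp = d.get("lfp_model")
        return cls(
            arena=ArenaSpec(**arena_d),
            trajectory_params=TrajectoryParams(**d["trajectory_params"]),
            unit_models=unit_models,
            lfp_model=LFPModel(**lfp) if lfp else None,
            spike_seeds={k: int(v) for k, v in d.get("spike_seeds", {}).items()},
        )


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _ou_velocity(n: int, dt: float, target_mean_speed: float, tau_v: float,
                 tau_turn: float, rng: np.random.Generator,
                 ndim: int = 2) -> np.ndarray:
    """OU velocity process whose stationary mean |v| equals the target.

    For an isotropic d-dim OU velocity with per-axis std s, E|v| is
    s*sqrt(pi/2) in 2D and s*sqrt(2/pi) in 1D; s is set accordingly.  A slow
    angular drift (correlation time ``tau_turn``) adds realistic path
    curvature in 2D without changing the speed distribution.
    """
    if ndim == 2:
        s = target_mean_speed / math.sqrt(math.pi / 2.0)
    else:
        s = target_mean_speed / math.sqrt(2.0 / math.pi)
    a = math.exp(-dt / tau_v)
    b = s * math.sqrt(1.0 - a * a)
    v = np.empty((n, ndim))
    v[0] = rng.normal(0.0, s, size=ndim)
    noise = rng.normal(size=(n - 1, ndim))
    for i in range(1, n):
        v[i] = a * v[i - 1] + b * noise[i - 1]
    if ndim == 2 and tau_turn > 0:
        # smooth heading drift: rotate velocity by an OU angular velocity
        omega_sd = 0.8  # rad/s
        aa = math.exp(-dt / tau_turn)
        bb = omega_sd * math.sqrt(1.0 - aa * aa)
        om = np.empty(n)
        om[0] = rng.normal(0.0, omega_sd)
        wn = rng.normal(size=n - 1)
        for i in range(1, n):
            om[i] = aa * om[i - 1] + bb * wn[i - 1]
        ang = om * dt
        c, si = np.cos(ang), np.sin(ang)
        vx = c * v[:, 0] - si * v[:, 1]
        vy = si * v[:, 0] + c * v[:, 1]
        v = np.column_stack([vx, vy])
    return v


def _reflect(pos: float, lo: float, hi: float) -> tuple:
    """Reflect a scalar coordinate into [lo, hi]; returns (pos, flipped)."""
    flipped = False
    span = hi - lo
    while pos < lo or pos > hi:
        if pos < lo:
            pos = 2 * lo - pos
        else:
            pos = 2 * hi - pos
        flipped = not flipped
        if span <= 0:
            return lo, flipped
    return pos, flipped


def simulate_trajectory(arena: ArenaSpec, params: TrajectoryParams) -> Trajectory:
    """Simulate exploration of the arena; heading = direction of motion.

    Open field: 2D OU velocity with reflecting walls.  Linear / L tracks: a
    1D OU velocity along the track's arc length, reflected at the ends and
    mapped onto the track geometry.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.sample_rate
    n = int(round(params.duration * params.sample_rate))
    if n < 2:
        raise ValueError("duration too short for the given sample rate")
    t = np.arange(n) * dt

    if arena.shape == "square_open_field":
        w, h = arena.extent
        v = _ou_velocity(n, dt, params.mean_speed_target,
                         params.speed_persistence, params.turning_persistence,
                         rng, ndim=2)
        x = np.empty(n)
        y = np.empty(n)
        x[0], y[0] = rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h)
        hd = np.empty(n)
        vx, vy = v[:, 0].copy(), v[:, 1].copy()
        for i in range(1, n):
            px, fx = _reflect(x[i - 1] + vx[i] * dt, 0.0, w)
            py, fy = _reflect(y[i - 1] + vy[i] * dt, 0.0, h)
            if fx:
                vx[i:] = -vx[i:]
            if fy:
                vy[i:] = -vy[i:]
            x[i], y[i] = px, py
        hd = np.degrees(np.arctan2(vy, vx)) % 360.0
        return Trajectory(t, x, y, hd)

    # track shapes: 1D arc-length process
    if arena.shape == "linear_track":
        length = arena.extent[0]
    else:  # l_track: two perpendicular arms
        length = float(sum(arena.extent))
    v = _ou_velocity(n, dt, params.mean_speed_target,
                     params.speed_persistence, 0.0, rng, ndim=1)[:, 0]
    s_pos = np.empty(n)
    s_pos[0] = rng.uniform(0.2 * length, 0.8 * length)
    vv = v.copy()
    for i in range(1, n):
        p, f = _reflect(s_pos[i - 1] + vv[i] * dt, 0.0, length)
        if f:
            vv[i:] = -vv[i:]
        s_pos[i] = p
    y0 = arena.track_width / 2.0
    if arena.shape == "linear_track":
        x = s_pos
        y = np.full(n, y0)
        hd = np.where(vv >= 0, 0.0, 180.0)
    else:
        arm = arena.extent[0]
        x = np.where(s_pos <= arm, s_pos, arm - y0)
        y = np.where(s_pos <= arm, y0, s_pos - arm)
        hd = np.where(s_pos <= arm,
                      np.where(vv >= 0, 0.0, 180.0),
                      np.where(vv >= 0, 90.0, 270.0))
    return Trajectory(t, x, y, hd)


# ---------------------------------------------------------------------------
# Firing-rate models
# ---------------------------------------------------------------------------

class RateFunction:
    """Callable rate(x, y, hd_deg, speed, t) -> Hz, with a known upper bound.

    The bound (``upper_bound``) is what makes Poisson thinning exact: the
    state-dependent part is maximised analytically per kind and the theta
    factor is bounded by ``1 + depth``.
    """

    def __init__(self, model: UnitModel):
        self.model = model
        m = model
        if m.kind in ("grid", "conjunctive"):
            # three plane-wave gratings at 60 deg separation
            theta0 = math.radians(m.grid_orientation)
            k = 4.0 * math.pi / (math.sqrt(3.0) * m.grid_spacing)
            self._kvecs = np.array(
                [[k * math.cos(theta0 + j * math.pi / 3.0),
                  k * math.sin(theta0 + j * math.pi / 3.0)] for j in range(3)]
            )

    # -- state-dependent factor, in [0, peak] -----------------------------
    def _grid_factor(self, x, y):
        m = self.model
        dx = np.asarray(x, dtype=float) - m.grid_phase[0]
        dy = np.asarray(y, dtype=float) - m.grid_phase[1]
        s = np.zeros(np.broadcast(dx, dy).shape)
        for kx, ky in self._kvecs:
            s = s + np.cos(kx * dx + ky * dy)
        # rectified sum of gratings, scaled so lattice vertices hit 1
        return np.clip(s, 0.0, None) / 3.0

    def _hd_factor(self, hd_deg):
        m = self.model
        ang = np.radians(np.asarray(hd_deg, dtype=float) - m.hd_mu)
        return np.exp(m.hd_kappa * (np.cos(ang) - 1.0))

    def _speed_term(self, speed):
        m = self.model
        s = np.asarray(speed, dtype=float)
        if m.speed_form == "linear":
            term = m.speed_slope * s
        else:  # saturating, initial slope matched to speed_slope
            rmax = m.speed_slope * m.saturation_constant
            term = rmax * (1.0 - np.exp(-s / m.saturation_constant))
        if m.speed_sign == "negative":
            term = -term
        return term

    def state_rate(self, x, y, hd_deg, speed):
        """Rate before theta modulation (Hz)."""
        m = self.model
        if m.kind == "untuned":
            return np.broadcast_to(float(m.base_rate), np.shape(x)).copy() \
                if np.ndim(x) else float(m.base_rate)
        if m.kind == "grid":
            return m.base_rate * self._grid_factor(x, y)
        if m.kind == "hd":
            return m.base_rate * self._hd_factor(hd_deg)
        if m.kind == "place":
            dx = np.asarray(x, dtype=float) - m.grid_phase[0]
            dy = np.asarray(y, dtype=float) - m.grid_phase[1]
            return m.base_rate * np.exp(-(dx * dx + dy * dy)
                                        / (2.0 * m.place_sigma ** 2))
        if m.kind == "speed":
            return np.clip(m.base_rate + self._speed_term(speed), 0.0, None)
        if m.kind == "conjunctive":
            return m.base_rate * self._grid_factor(x, y) * self._hd_factor(hd_deg)
        raise AssertionError(m.kind)

    def __call__(self, x, y, hd_deg, speed, t):
        rate = self.state_rate(x, y, hd_deg, speed)
        m = self.model
        if m.theta_mod_depth > 0:
            rate = rate * (1.0 + m.theta_mod_depth
                           * np.cos(2.0 * math.pi * m.theta_freq
                                    * np.asarray(t, dtype=float)))
        return rate

    def upper_bound(self, max_speed: float = 60.0) -> float:
        m = self.model
        if m.kind == "speed":
            if m.speed_sign == "negative":
                peak = m.base_rate
            elif m.speed_form == "linear":
                peak = m.base_rate + m.speed_slope * max_speed
            else:
                peak = m.base_rate + m.speed_slope * m.saturation_constant
        else:
            peak = m.base_rate
        return peak * (1.0 + m.theta_mod_depth)


def unit_rate_function(model: UnitModel) -> RateFunction:
    """Build the generative rate function for a unit model."""
    return RateFunction(model)


# ---------------------------------------------------------------------------
# Spike simulation (inhomogeneous Poisson by thinning)
# ---------------------------------------------------------------------------

def _interp_behaviour(traj: Trajectory, times: np.ndarray):
    """Position / heading / speed of the animal at arbitrary times.

    Positions are linearly interpolated; heading is taken from the nearest
    tracking sample (circular quantity); speed from finite differences.
    """
    ts = traj.timestamps
    x = np.interp(times, ts, traj.x)
    y = np.interp(times, ts, traj.y)
    idx = np.clip(np.searchsorted(ts, times), 0, ts.size - 1)
    left = np.clip(idx - 1, 0, ts.size - 1)
    use_left = np.abs(ts[left] - times) < np.abs(ts[idx] - times)
    nearest = np.where(use_left, left, idx)
    hd = traj.hd_deg[nearest]
    dt = np.median(np.diff(ts))
    vx = np.gradient(traj.x, dt)
    vy = np.gradient(traj.y, dt)
    spd = np.hypot(vx, vy)[nearest]
    return x, y, hd, spd


def simulate_spikes(rate_fn, trajectory: Trajectory, seed: int,
                    rmax: float | None = None, unit_id: str = "u0",
                    half_width_ms: float | None = None) -> SpikeTrain:
    """Sample a spike train from ``rate_fn`` along the trajectory.

    Thinning: candidate spikes at rate ``rmax`` are accepted with probability
    rate/rmax, so under a constant rate the count is exactly Poisson.
    """
    if rmax is None:
        if hasattr(rate_fn, "upper_bound"):
            rmax = rate_fn.upper_bound()
        else:
            raise ValueError("rmax required for a bare rate function")
    if not np.isfinite(rmax):
        raise ValueError("rate bound must be finite")
    rng = np.random.default_rng(seed)
    T = trajectory.duration
    hw = half_width_ms
    if hw is None and hasattr(rate_fn, "model"):
        hw = rate_fn.model.half_width_ms
    if rmax <= 0:
        return SpikeTrain(unit_id, np.empty(0), T, hw)
    n_cand = rng.poisson(rmax * T)
    cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    x, y, hd, spd = _interp_behaviour(trajectory, cand)
    rates = np.asarray(rate_fn(x, y, hd, spd, cand), dtype=float)
    if np.any(rates > rmax * (1 + 1e-9)):
        raise ValueError("rate function exceeds its stated bound")
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rates / rmax
    return SpikeTrain(unit_id, cand[keep], T, hw)


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f**exponent noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def synthesize_lfp(model: LFPModel, speeds: SpeedSeries,
                   fs: float = 2000.0) -> LFPSignal:
    """Generate a speed-coupled LFP covering the span of ``speeds``.

    Instantaneous theta amplitude and frequency are affine in running speed;
    theta phase is the integral of the instantaneous frequency, so the
    windowed spectral peak tracks speed as in healthy recordings.
    """
    rng = np.random.default_rng(model.seed)
    t_end = float(speeds.bin_start[-1] + speeds.bin_width)
    n = int(round(t_end * fs))
    t = np.arange(n) / fs
    # piecewise-linear speed at LFP resolution (centres of behaviour bins)
    s = np.interp(t, speeds.bin_center, speeds.speed)

    theta_amp = model.theta_base_amp + model.theta_amp_slope * s
    theta_freq = model.theta_base_freq + model.theta_freq_slope * s
    phase = 2.0 * math.pi * np.cumsum(theta_freq) / fs
    sig = theta_amp * np.sin(phase)

    for amp0, slope, f0 in (
        (model.slow_gamma_amp, model.slow_gamma_amp_slope, model.slow_gamma_freq),
        (model.fast_gamma_amp, model.fast_gamma_amp_slope, model.fast_gamma_freq),
    ):
        if amp0 > 0 or slope > 0:
            ph0 = rng.uniform(0, 2 * math.pi)
            sig = sig + (amp0 + slope * s) * np.sin(2 * math.pi * f0 * t + ph0)

    if model.noise_scale > 0:
        sig = sig + model.noise_scale * _pink_noise(n, model.noise_exponent, rng)
    if model.white_scale > 0:
        sig = sig + model.white_scale * rng.normal(size=n)
    return LFPSignal(fs, sig)


# ---------------------------------------------------------------------------
# Whole-session convenience
# ---------------------------------------------------------------------------

def simulate_session(arena: ArenaSpec, traj_params: TrajectoryParams,
                     unit_models: dict, lfp_model: LFPModel | None = None,
                     seed: int = 0, lfp_fs: float = 2000.0) -> Session:
    """Simulate behaviour, every unit's spikes, and the LFP for one session.

    ``unit_models`` maps unit_id -> UnitModel.  Spike seeds are derived
    deterministically from ``seed`` and the unit index so the full session is
    reproducible from the ground-truth manifest alone.
    """
    from gridspeed.preprocess import compute_speed

    traj = simulate_trajectory(arena, traj_params)
    gt = SyntheticGroundTruth(arena=arena, trajectory_params=traj_params,
                              unit_models=dict(unit_models),
                              lfp_model=lfp_model)
    trains = []
    ss = np.random.SeedSequence(seed)
    unit_seeds = ss.generate_state(max(len(unit_models), 1)) % (2 ** 31)
    for i, (uid, model) in enumerate(unit_models.items()):
        sp_seed = int(unit_seeds[i])
        gt.spike_seeds[uid] = sp_seed
        rf = unit_rate_function(model)
        trains.append(simulate_spikes(rf, traj, sp_seed, unit_id=uid))
    lfp = None
    if lfp_model is not None:
        speeds = compute_speed(traj, bin_width=0.5)
        lfp = synthesize_lfp(lfp_model, speeds, fs=lfp_fs)
    return Session(trajectory=traj, spike_trains=trains, lfp=lfp,
                   ground_truth=gt.to_dict())
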