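"""Study-scale validation experiments on synthetic cohorts.

These are the package's benchmark analyses: null calibration of the shuffle
thresholds, parameter recovery for each tuned cell class, LFP-coupling
recovery, TMI discrimination, and downsampling robustness.  Both the
acceptance harness and the numbered analysis drivers run them; every
experiment takes a base seed and derives all sub-seeds from it.

Problem sizes default to what a desk-scale replication supports: 10-minute
sessions for calibration cohorts and 20-minute sessions for single-unit
parameter recovery, with 250 shuffles per unit throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from gridspeed import controls, preprocess, shuffle, simulate as sim, tuning
from gridspeed import unit_metrics
from gridspeed.core import SpikeTrain


def _sub_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=base, spawn_key=key)
               .generate_state(1)[0] % (2 ** 31))


def _session_tools(traj):
    speeds40 = preprocess.compute_speed(traj, tuning.SPEED_BIN_S)
    return (tuning.SpatialBinning(traj, extent=(80.0, 80.0)),
            tuning.SpeedScoringContext(speeds40), speeds40)


def _metric_fns(traj, binning, ctx):
    def grid_fn(tr):
        return tuning.grid_score(
            tuning.spatial_autocorrelation(binning.rate_map(tr))).g

    def si_fn(tr):
        return tuning.spatial_information(binning.rate_map(tr))

    def hd_fn(tr):
        return tuning.hd_score(tr, traj).mvl

    def speed_fn(tr):
        sc = ctx.score(tr)
        return sc.z if sc.valid else np.nan

    return {"grid": grid_fn, "si": si_fn, "hd": hd_fn, "speed": speed_fn}


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def null_calibration(n_units: int = 100, duration: float = 600.0,
                     n_shuffles: int = 250, seed: int = 0) -> dict:
    """False-positive rates of every tuning metric on untuned units.

    All units share one session's behaviour (as units of a real recording
    do) and fire homogeneously at 5 Hz; thresholds are the pooled shuffle
    percentiles.  Expected flag rates: ~5% for the one-sided metrics, ~10%
    for the two-sided speed rule.
    """
    traj = sim.simulate_trajectory(
        sim.open_field(),
        sim.TrajectoryParams(duration=duration, seed=_sub_seed(seed, 0)))
    binning, ctx, _ = _session_tools(traj)
    rf = sim.unit_rate_function(sim.UnitModel(kind="untuned", base_rate=5.0))
    trains = [sim.simulate_spikes(rf, traj, _sub_seed(seed, 1, i),
                                  unit_id=f"u{i}") for i in range(n_units)]
    fns = _metric_fns(traj, binning, ctx)
    out = {}
    for name, fn in fns.items():
        dist = shuffle.null_distribution(fn, trains, metric=name,
                                         n_shuffles=n_shuffles,
                                         seed=_sub_seed(seed, 2))
        obs = np.array([fn(tr) for tr in trains])
        if name == "speed":
            flagged = int(np.sum((obs > dist.threshold_95)
                                 | (obs < dist.threshold_5)))
            expected = 0.10
        else:
            flagged = int(np.sum(obs > dist.threshold_95))
            expected = 0.05
        out[name] = {"flagged": flagged, "n": n_units,
                     "rate": flagged / n_units, "expected": expected,
                     "threshold_95": dist.threshold_95,
                     "threshold_5": dist.threshold_5}
    return out


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def grid_recovery(n_seeds: int = 50, duration: float = 1200.0,
                  n_shuffles: int = 250, seed: int = 0) -> dict:
    """Fraction of synthetic grid units (30 cm spacing, 15 Hz peak) whose
    grid score exceeds the group-pooled shuffle threshold."""
    observed = []
    null_values = []
    for s in range(n_seeds):
        traj = sim.simulate_trajectory(
            sim.open_field(),
            sim.TrajectoryParams(duration=duration, seed=_sub_seed(seed, 0, s)))
        binning = tuning.SpatialBinning(traj, extent=(80.0, 80.0))
        model = sim.UnitModel(kind="grid", base_rate=15.0, grid_spacing=30.0,
                              grid_orientation=(s * 7.3) % 60.0,
                              grid_phase=((s * 3.1) % 30.0, (s * 5.7) % 30.0))
        train = sim.simulate_spikes(sim.unit_rate_function(model), traj,
                                    _sub_seed(seed, 1, s))

        def grid_fn(tr, binning=binning):
            return tuning.grid_score(
                tuning.spatial_autocorrelation(binning.rate_map(tr))).g

        observed.append(grid_fn(train))
        dist = shuffle.null_distribution(grid_fn, [train],
                                         n_shuffles=n_shuffles,
                                         seed=_sub_seed(seed, 2, s))
        null_values.append(dist.values)
    threshold = float(np.nanpercentile(np.concatenate(null_values), 95.0))
    observed = np.array(observed)
    return {"pass_rate": float(np.mean(observed > threshold)),
            "n": n_seeds, "threshold": threshold,
            "median_score": float(np.median(observed))}


def hd_recovery(n_seeds: int = 50, duration: float = 1200.0,
                kappa: float = 2.0, seed: int = 0) -> dict:
    """Mean vector length of von Mises units vs the Bessel ratio
    I1(kappa)/I0(kappa)."""
    mvls = []
    for s in range(n_seeds):
        traj = sim.simulate_trajectory(
            sim.open_field(),
            sim.TrajectoryParams(duration=duration, seed=_sub_seed(seed, 0, s)))
        model = sim.UnitModel(kind="hd", base_rate=10.0,
                              hd_mu=(s * 31.0) % 360.0, hd_kappa=kappa)
        train = sim.simulate_spikes(sim.unit_rate_function(model), traj,
                                    _sub_seed(seed, 1, s))
        mvls.append(tuning.hd_score(train, traj).mvl)
    expected = float(special.i1(kappa) / special.i0(kappa))
    return {"mean_mvl": float(np.mean(mvls)), "expected": expected,
            "abs_error": float(abs(np.mean(mvls) - expected)), "n": n_seeds}


def speed_slope_recovery(n_seeds: int = 50, duration: float = 1200.0,
                         slope: float = 0.5, seed: int = 0) -> dict:
    """Sign and magnitude recovery of a linear speed unit's rate slope."""
    slopes = []
    for s in range(n_seeds):
        traj = sim.simulate_trajectory(
            sim.open_field(),
            sim.TrajectoryParams(duration=duration, seed=_sub_seed(seed, 0, s)))
        speeds40 = preprocess.compute_speed(traj, tuning.SPEED_BIN_S)
        model = sim.UnitModel(kind="speed", base_rate=2.0, speed_slope=slope)
        train = sim.simulate_spikes(sim.unit_rate_function(model), traj,
                                    _sub_seed(seed, 1, s))
        slopes.append(tuning.speed_score(train, speeds40).slope)
    slopes = np.array(slopes)
    return {"sign_correct_rate": float(np.mean(np.sign(slopes)
                                               == np.sign(slope))),
            "mean_slope": float(np.mean(slopes)), "true_slope": slope,
            "rel_error": float(abs(np.mean(slopes) - slope) / abs(slope)),
            "n": n_seeds}


def speed_form_recovery(n_seeds: int = 20, duration: float = 1200.0,
                        seed: int = 0) -> dict:
    """Linear vs saturating form classification accuracy per generative form."""
    out = {}
    for form in ("linear", "saturating"):
        correct = 0
        for s in range(n_seeds):
            traj = sim.simulate_trajectory(
                sim.open_field(),
                sim.TrajectoryParams(duration=duration,
                                     seed=_sub_seed(seed, 0, s)))
            speeds40 = preprocess.compute_speed(traj, tuning.SPEED_BIN_S)
            model = sim.UnitModel(kind="speed", base_rate=2.0,
                                  speed_slope=0.8, speed_form=form,
                                  saturation_constant=5.0)
            train = sim.simulate_spikes(sim.unit_rate_function(model), traj,
                                        _sub_seed(seed, 1, form == "linear", s))
            rel = tuning.classify_speed_relationship(train, speeds40)
            correct += rel["form"] == form
        out[form] = {"recovery_rate": correct / n_seeds, "n": n_seeds}
    return out


# ---------------------------------------------------------------------------
# LFP coupling
# ---------------------------------------------------------------------------

def lfp_coupling_recovery(n_seeds: int = 20, duration: float = 600.0,
                          freq_slope: float = 0.045,
                          amp_slope: float = 0.01, seed: int = 0) -> dict:
    """Regression slopes and Fisher z of speed-coupled vs uncoupled LFP."""
    from gridspeed import lfp as glfp

    def run(n, f_slope, a_slope, key):
        rows = []
        for s in range(n):
            traj = sim.simulate_trajectory(
                sim.open_field(),
                sim.TrajectoryParams(duration=duration,
                                     seed=_sub_seed(seed, key, 0, s)))
            speeds = preprocess.compute_speed(traj, 0.5)
            model = sim.LFPModel(theta_freq_slope=f_slope,
                                 theta_amp_slope=a_slope,
                                 seed=_sub_seed(seed, key, 1, s))
            sig = sim.synthesize_lfp(model, speeds)
            tun = glfp.band_speed_analysis(sig, speeds)
            rows.append({"power_slope": tun.power_regression.slope,
                         "power_z": tun.power_regression.fisher_z,
                         "freq_slope": tun.freq_regression.slope,
                         "freq_z": tun.freq_regression.fisher_z})
        return pd.DataFrame(rows)

    coupled = run(n_seeds, freq_slope, amp_slope, 1)
    null = run(max(n_seeds // 2, 5), 0.0, 0.0, 2)
    return {
        "coupled_positive_rate": float(np.mean(
            (coupled["power_z"] > 0) & (coupled["freq_z"] > 0)
            & (coupled["power_slope"] > 0) & (coupled["freq_slope"] > 0))),
        "mean_freq_slope": float(coupled["freq_slope"].mean()),
        "true_freq_slope": freq_slope,
        "null_mean_power_z": float(null["power_z"].mean()),
        "null_frac_positive": float(np.mean(null["power_z"] > 0)),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# TMI discrimination
# ---------------------------------------------------------------------------

def _poisson_train(rate, duration, seed, depth=0.0, freq=8.0):
    rng = np.random.default_rng(seed)
    rmax = rate * (1.0 + depth)
    n = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    accept = rng.uniform(0.0, 1.0, n) < (
        rate * (1.0 + depth * np.cos(2 * np.pi * freq * cand)) / rmax)
    return SpikeTrain("u", cand[accept], duration)


def tmi_discrimination(n_seeds: int = 100, duration: float = 600.0,
                       rate: float = 10.0, depth: float = 0.8,
                       seed: int = 0) -> dict:
    """TMI > 5 for 8 Hz-modulated trains and < 5 for homogeneous ones."""
    mod = np.array([unit_metrics.theta_modulation_index(
        _poisson_train(rate, duration, _sub_seed(seed, 1, s), depth)).tmi
        for s in range(n_seeds)])
    unmod = np.array([unit_metrics.theta_modulation_index(
        _poisson_train(rate, duration, _sub_seed(seed, 2, s), 0.0)).tmi
        for s in range(n_seeds)])
    thr = unit_metrics.TMI_THRESHOLD
    return {"modulated_above_rate": float(np.mean(mod > thr)),
            "unmodulated_below_rate": float(np.mean(unmod < thr)),
            "median_modulated_tmi": float(np.median(mod)),
            "median_unmodulated_tmi": float(np.median(unmod)),
            "n": n_seeds}


# ---------------------------------------------------------------------------
# Downsampling robustness
# ---------------------------------------------------------------------------

def downsample_grid_robustness(duration: float = 1200.0, n_seeds: int = 3,
                               n_factors: int = 10, n_shuffles: int = 250,
                               seed: int = 0) -> pd.DataFrame:
    """Grid score vs thinned mean rate, with a shuffle threshold per factor.

    Returns one row per factor: median thinned rate, median grid score, the
    pooled 95th-percentile threshold recomputed from the thinned trains, and
    whether the median score stays above it.
    """
    traj = sim.simulate_trajectory(
        sim.open_field(),
        sim.TrajectoryParams(duration=duration, seed=_sub_seed(seed, 0)))
    binning = tuning.SpatialBinning(traj, extent=(80.0, 80.0))
    model = sim.UnitModel(kind="grid", base_rate=15.0, grid_spacing=30.0,
                          grid_orientation=10.0, grid_phase=(5.0, 5.0))
    train = sim.simulate_spikes(sim.unit_rate_function(model), traj,
                                _sub_seed(seed, 1))

    def grid_fn(tr):
        return tuning.grid_score(
            tuning.spatial_autocorrelation(binning.rate_map(tr))).g

    factors = controls.downsample_factors(n_factors)
    rows = []
    for fi, factor in enumerate(factors):
        thinned = [controls.downsample_spike_train(
            train, factor, np.random.default_rng(_sub_seed(seed, 2, fi, s)))
            for s in range(n_seeds)]
        scores = []
        for tr in thinned:
            try:
                scores.append(grid_fn(tr))
            except (ValueError, FloatingPointError):
                scores.append(np.nan)
        dist = shuffle.null_distribution(grid_fn, thinned,
                                         n_shuffles=n_shuffles,
                                         seed=_sub_seed(seed, 3, fi))
        med_score = float(np.nanmedian(scores))
        rows.append({
            "factor": float(factor),
            "median_rate": float(np.median([t.n_spikes / t.duration
                                            for t in thinned])),
            "median_score": med_score,
            "threshold_95": dist.threshold_95,
            "above_threshold": bool(med_score > dist.threshold_95),
        })
    return pd.DataFrame(rows)
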