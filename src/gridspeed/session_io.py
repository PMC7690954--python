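"""Session bundles on disk, pipeline configuration, and the end-to-end run.

A session bundle is one directory of plain columnar files:

* ``positions.csv`` — time_s, x_cm, y_cm, valid_flag, hd_deg (NaN = heading
  undefined at that sample);
* ``units.csv`` — unit_id, half_width_ms, mean_rate_hz;
* ``spikes/<unit_id>.txt`` — one spike timestamp (s) per line;
* ``lfp.bin`` (float32, mV) + ``lfp.yaml`` (sample rate) — optional;
* ``ground_truth.yaml`` — generative manifest for synthetic sessions.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gridspeed import preprocess, shuffle, stats, tuning, unit_metrics
from gridspeed.core import LFPSignal, Session, SpikeTrain, Trajectory
from gridspeed.simulate import SyntheticGroundTruth

log = logging.getLogger("gridspeed")


class SessionLoadError(ValueError):
    pass


def write_session(directory, session: Session) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    traj = session.trajectory
    pd.DataFrame({
        "time_s": traj.timestamps, "x_cm": traj.x, "y_cm": traj.y,
        "valid_flag": (~traj.interpolated).astype(int),
        "hd_deg": traj.hd_deg,
    }).to_csv(d / "positions.csv", index=False)
    rows = []
    (d / "spikes").mkdir(exist_ok=True)
    for tr in session.spike_trains:
        rows.append({"unit_id": tr.unit_id,
                     "half_width_ms": tr.half_width_ms,
                     "mean_rate_hz": unit_metrics.mean_firing_rate(tr)})
        np.savetxt(d / "spikes" / f"{tr.unit_id}.txt", tr.spike_times,
                   fmt="%.6f")
    pd.DataFrame(rows, columns=["unit_id", "half_width_ms", "mean_rate_hz"]
                 ).to_csv(d / "units.csv", index=False)
    if session.lfp is not None:
        session.lfp.samples.astype(np.float32).tofile(d / "lfp.bin")
        (d / "lfp.yaml").write_text(
            yaml.safe_dump({"fs_hz": float(session.lfp.fs)}))
    if session.ground_truth is not None:
        (d / "ground_truth.yaml").write_text(
            yaml.safe_dump(session.ground_truth))
    return d


def read_session(directory) -> Session:
    """Load and validate a session bundle; LFP and ground truth optional."""
    d = Path(directory)
    pos_file = d / "positions.csv"
    if not pos_file.exists():
        raise SessionLoadError(f"missing {pos_file}")
    pos = pd.read_csv(pos_file)
    for col in ("time_s", "x_cm", "y_cm"):
        if col not in pos.columns:
            raise SessionLoadError(f"positions.csv lacks column {col!r}")
    traj = Trajectory(
        pos["time_s"].to_numpy(), pos["x_cm"].to_numpy(),
        pos["y_cm"].to_numpy(),
        pos["hd_deg"].to_numpy() if "hd_deg" in pos else
        np.full(len(pos), np.nan),
        interpolated=(pos["valid_flag"].to_numpy() == 0)
        if "valid_flag" in pos else None,
    )
    trains = []
    units_file = d / "units.csv"
    if units_file.exists():
        units = pd.read_csv(units_file)
        for _, row in units.iterrows():
            uid = str(row["unit_id"])
            sp_file = d / "spikes" / f"{uid}.txt"
            if not sp_file.exists():
                raise SessionLoadError(f"missing spike file for unit {uid}")
            times = np.loadtxt(sp_file, ndmin=1)
            hw = row.get("half_width_ms")
            hw = None if pd.isna(hw) else float(hw)
            try:
                trains.append(SpikeTrain(uid, times, traj.duration, hw))
            except ValueError as e:
                raise SessionLoadError(f"invalid spike file: {e}") from e
    lfp = None
    if (d / "lfp.bin").exists():
        meta = yaml.safe_load((d / "lfp.yaml").read_text())
        samples = np.fromfile(d / "lfp.bin", dtype=np.float32).astype(float)
        lfp = LFPSignal(float(meta["fs_hz"]), samples)
    gt = None
    if (d / "ground_truth.yaml").exists():
        gt = yaml.safe_load((d / "ground_truth.yaml").read_text())
        SyntheticGroundTruth.from_dict(gt)  # validates round-trip
    return Session(trajectory=traj, spike_trains=trains, lfp=lfp,
                   ground_truth=gt)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All analysis constants, defaulting to the published procedure."""

    spatial_bin_cm: float = 3.0
    rate_map_sigma_bins: float = 1.5
    hd_bin_deg: float = 3.0
    hd_window_deg: float = 14.0
    speed_bin_s: float = 0.040
    speed_smooth_window_s: float = 0.5
    speed_range_cm_s: tuple = (2.0, 30.0)
    speed_min_occupancy_frac: float = 0.005
    lfp_window_s: float = 0.5
    theta_band: tuple = (5.0, 12.0)
    slow_gamma_band: tuple = (30.0, 50.0)
    fast_gamma_band: tuple = (60.0, 120.0)
    tmi_threshold: float = 5.0
    interneuron_half_width_ms: float = 0.35
    fast_spiking_rate_hz: float = 10.0
    n_shuffles: int = 250
    shuffle_pooling: str = "group"  # group | per-unit
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = yaml.safe_load(text)
        for k in ("speed_range_cm_s", "theta_band", "slow_gamma_band",
                  "fast_gamma_band"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def score_units(session: Session, config: PipelineConfig) -> pd.DataFrame:
    """Unit metrics + tuning scores for every unit of one session."""
    traj = session.trajectory
    speeds40 = preprocess.compute_speed(traj, config.speed_bin_s)
    ctx = tuning.SpeedScoringContext(
        speeds40, smooth_window_s=config.speed_smooth_window_s,
        speed_range=config.speed_range_cm_s,
        min_occupancy_frac=config.speed_min_occupancy_frac)
    binning = tuning.SpatialBinning(traj, bin_size=config.spatial_bin_cm)
    rows = []
    for tr in session.spike_trains:
        row = {"unit_id": tr.unit_id,
               "mean_rate": unit_metrics.mean_firing_rate(tr),
               "half_width_ms": tr.half_width_ms}
        cls, fast = unit_metrics.classify_waveform(tr)
        row["waveform_class"] = cls
        row["is_interneuron"] = cls == "putative_interneuron"
        row["is_fast_spiking"] = fast
        try:
            tmi = unit_metrics.theta_modulation_index(tr)
            row["tmi"] = tmi.tmi
            row["is_theta_modulated"] = tmi.is_theta_modulated
        except unit_metrics.UndefinedTMIError:
            row["tmi"] = np.nan
            row["is_theta_modulated"] = False
        rm = binning.rate_map(tr, config.rate_map_sigma_bins)
        row["grid_score"] = tuning.grid_score(
            tuning.spatial_autocorrelation(rm)).g
        try:
            row["si"] = tuning.spatial_information(rm)
        except tuning.UndefinedSIError:
            row["si"] = np.nan
        try:
            row["hd_score"] = tuning.hd_score(
                tr, traj, config.hd_bin_deg, config.hd_window_deg).mvl
        except ValueError:
            row["hd_score"] = np.nan
        sc = ctx.score(tr)
        row["speed_r"], row["speed_z"] = sc.r, sc.z
        row["speed_valid"] = sc.valid
        if sc.valid:
            rel = tuning.classify_speed_relationship(tr, speeds40, ctx)
            row["speed_form"], row["speed_sign"] = rel["form"], rel["sign"]
        else:
            row["speed_form"] = row["speed_sign"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def shuffle_thresholds(session: Session, config: PipelineConfig) -> dict:
    """Pooled shuffle-null distributions for grid / SI / HD / speed."""
    traj = session.trajectory
    speeds40 = preprocess.compute_speed(traj, config.speed_bin_s)
    ctx = tuning.SpeedScoringContext(
        speeds40, smooth_window_s=config.speed_smooth_window_s,
        speed_range=config.speed_range_cm_s,
        min_occupancy_frac=config.speed_min_occupancy_frac)
    binning = tuning.SpatialBinning(traj, bin_size=config.spatial_bin_cm)

    def grid_fn(tr):
        rm = binning.rate_map(tr, config.rate_map_sigma_bins)
        return tuning.grid_score(tuning.spatial_autocorrelation(rm)).g

    def si_fn(tr):
        return tuning.spatial_information(
            binning.rate_map(tr, config.rate_map_sigma_bins))

    def hd_fn(tr):
        return tuning.hd_score(tr, traj, config.hd_bin_deg,
                               config.hd_window_deg).mvl

    def speed_fn(tr):
        sc = ctx.score(tr)
        return sc.z if sc.valid else np.nan

    trains = session.spike_trains
    with warnings.catch_warnings():
        if config.n_shuffles < shuffle.DEFAULT_N_SHUFFLES:
            log.warning("n_shuffles=%d is below the recommended 250",
                        config.n_shuffles)
            warnings.simplefilter("ignore")
        return {
            name: shuffle.null_distribution(
                fn, trains, metric=name, n_shuffles=config.n_shuffles,
                seed=config.seed)
            for name, fn in (("grid", grid_fn), ("si", si_fn),
                             ("hd", hd_fn), ("speed", speed_fn))
        }


def run_pipeline(config: PipelineConfig, session_dir, out_dir) -> dict:
    """Score one session bundle end to end and write result tables.

    Writes ``unit_metrics.csv`` (per-unit scores), ``thresholds.csv``
    (pooled shuffle percentiles), ``classification.csv`` and the config
    (with its hash) under ``out_dir``; deterministic given the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: session=%s config=%s", session_dir,
             config.config_hash)
    session = read_session(session_dir)
    scored = score_units(session, config)
    dists = shuffle_thresholds(session, config)
    thr = pd.DataFrame({
        name: {"p5": d.threshold_5, "p95": d.threshold_95,
               "n_shuffles": d.n_shuffles, "n_units": d.n_units}
        for name, d in dists.items()}).T
    cls_rows = []
    for _, row in scored.iterrows():
        observed = {"grid": row["grid_score"], "si": row["si"],
                    "hd": row["hd_score"],
                    "speed": row["speed_z"] if row["speed_valid"] else np.nan}
        flags = shuffle.apply_thresholds(observed, dists)
        uc = stats.classify_unit(row["unit_id"], flags)
        cls_rows.append({"unit_id": uc.unit_id, "label": uc.label,
                         **{f"is_{k}": v for k, v in uc.flags.items()}})
    classification = pd.DataFrame(cls_rows)
    scored.round(6).to_csv(out / "unit_metrics.csv", index=False)
    thr.round(6).to_csv(out / "thresholds.csv")
    classification.to_csv(out / "classification.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "config_hash.txt").write_text(config.config_hash + "\n")
    log.info("pipeline done: %d units", len(scored))
    return {"scores": scored, "thresholds": thr,
            "classification": classification, "distributions": dists}
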