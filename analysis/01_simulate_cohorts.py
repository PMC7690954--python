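#!/usr/bin/env python
"""Simulate two synthetic cohorts of open-field sessions.

A "control-like" cohort mixes grid, HD, speed-modulated, theta-modulated and
untuned units; an "impaired-like" cohort keeps HD tuning but removes grid and
speed structure and slows mean firing — the generative contrast the group
comparison (06) is expected to detect.  Writes one session bundle per
animal-session under scratch/sessions/<cohort>/.
"""

from pathlib import Path

from gridspeed import session_io, simulate as sim

OUT = Path("scratch/sessions")
DURATION = 600.0
N_SESSIONS = 3


def control_units(rng_offset: int) -> dict:
    models = {}
    for i in range(3):
        models[f"grid{i}"] = sim.UnitModel(
            kind="grid", base_rate=15.0, grid_spacing=30.0,
            grid_orientation=7.0 * (i + rng_offset),
            grid_phase=(5.0 * i, 3.0 * i), theta_mod_depth=0.6)
    for i in range(2):
        models[f"hd{i}"] = sim.UnitModel(kind="hd", base_rate=10.0,
                                         hd_mu=120.0 * i, hd_kappa=2.0)
    for i in range(3):
        models[f"speed{i}"] = sim.UnitModel(
            kind="speed", base_rate=3.0, speed_slope=0.5,
            speed_form="linear" if i % 2 == 0 else "saturating",
            speed_sign="negative" if i == 2 else "positive",
            half_width_ms=0.3)
    for i in range(2):
        models[f"untuned{i}"] = sim.UnitModel(kind="untuned", base_rate=5.0,
                                              theta_mod_depth=0.5)
    return models


def impaired_units(rng_offset: int) -> dict:
    models = {}
    for i in range(2):
        models[f"hd{i}"] = sim.UnitModel(kind="hd", base_rate=6.0,
                                         hd_mu=120.0 * i, hd_kappa=2.5)
    for i in range(8):
        models[f"untuned{i}"] = sim.UnitModel(kind="untuned", base_rate=1.5)
    return models


def main() -> None:
    for cohort, make_units, lfp_slope, speed_target in (
        ("control", control_units, 0.045, 8.0),
        ("impaired", impaired_units, 0.0, 11.0),  # hyperactive, uncoupled
    ):
        for s in range(N_SESSIONS):
            coupled = lfp_slope > 0
            lfp = sim.LFPModel(
                theta_freq_slope=lfp_slope,
                theta_amp_slope=0.01 if coupled else 0.0,
                slow_gamma_amp_slope=0.001 if coupled else 0.0,
                fast_gamma_amp_slope=0.0015 if coupled else 0.0,
                seed=1000 + s)
            session = sim.simulate_session(
                sim.open_field(),
                sim.TrajectoryParams(duration=DURATION,
                                     mean_speed_target=speed_target,
                                     seed=100 + s),
                make_units(s), lfp_model=lfp, seed=200 + s)
            d = session_io.write_session(OUT / cohort / f"session{s}", session)
            print(f"{cohort}/session{s}: {len(session.spike_trains)} units "
                  f"-> {d}")


if __name__ == "__main__":
    main()
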