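#!/usr/bin/env python
"""Oscillation-speed coupling per session and band.

For each simulated session: 0.5 s multitaper windows, 1 cm/s speed-binned
tuning normalised to immobility, and the power/frequency regressions.  The
control-like cohort should show positive theta power and frequency slopes
(Fisher z > 0); the impaired-like cohort should not.  Writes
results/lfp_speed.csv.
"""

from pathlib import Path

import pandas as pd

from gridspeed import lfp as glfp, preprocess, session_io

SESSIONS = Path("scratch/sessions")


def main() -> None:
    rows = []
    for sdir in sorted(SESSIONS.glob("*/session*")):
        session = session_io.read_session(sdir)
        if session.lfp is None:
            continue
        speeds = preprocess.compute_speed(session.trajectory, 0.5)
        for band in (glfp.THETA, glfp.SLOW_GAMMA, glfp.FAST_GAMMA):
            tun = glfp.band_speed_analysis(session.lfp, speeds, band)
            rows.append({
                "cohort": sdir.parent.name, "session": sdir.name,
                "band": band.name,
                "power_slope": tun.power_regression.slope,
                "power_r2": tun.power_regression.r2,
                "power_z": tun.power_regression.fisher_z,
                "freq_slope": tun.freq_regression.slope,
                "freq_r2": tun.freq_regression.r2,
            })
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/lfp_speed.csv", index=False)
    print(df.groupby(["cohort", "band"])[["power_z", "freq_slope"]]
          .mean().round(3))


if __name__ == "__main__":
    main()
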