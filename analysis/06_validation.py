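#!/usr/bin/env python
"""Full validation battery against ground truth.

Null calibration, parameter recovery for every tuned class, LFP coupling
recovery, and TMI discrimination, at the same problem sizes the acceptance
harness uses.  Writes results/validation.json.
"""

import json
from pathlib import Path

from gridspeed import experiments

SEED = 7


def main() -> None:
    out = {
        "null_calibration": experiments.null_calibration(seed=SEED),
        "grid_recovery": experiments.grid_recovery(seed=SEED),
        "hd_recovery": experiments.hd_recovery(seed=SEED),
        "speed_slope_recovery": experiments.speed_slope_recovery(seed=SEED),
        "speed_form_recovery": experiments.speed_form_recovery(seed=SEED),
        "lfp_coupling": experiments.lfp_coupling_recovery(seed=SEED),
        "tmi_discrimination": experiments.tmi_discrimination(seed=SEED),
    }
    Path("results").mkdir(exist_ok=True)
    Path("results/validation.json").write_text(json.dumps(out, indent=2))
    for k, v in out.items():
        print(k, "->", v)


if __name__ == "__main__":
    main()
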