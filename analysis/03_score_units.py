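#!/usr/bin/env python
"""Score every unit of every session: firing metrics, tuning scores,
shuffle thresholds, and functional classification.

Runs the full pipeline (250 shuffles per unit, thresholds pooled per
session) and writes per-session tables under results/scored/<cohort>/.
"""

from pathlib import Path

from gridspeed import session_io

SESSIONS = Path("scratch/sessions")


def main() -> None:
    config = session_io.PipelineConfig(n_shuffles=250, seed=7)
    for sdir in sorted(SESSIONS.glob("*/session*")):
        out = Path("results/scored") / sdir.parent.name / sdir.name
        res = session_io.run_pipeline(config, sdir, out)
        n_classified = (res["classification"]["label"] != "unclassified").sum()
        print(f"{sdir.parent.name}/{sdir.name}: "
              f"{n_classified}/{len(res['scores'])} units classified")


if __name__ == "__main__":
    main()
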