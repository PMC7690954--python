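#!/usr/bin/env python
"""Cohort comparison: proportions per functional class, score medians with
Mann-Whitney U, and the published contingency-table statistics.

Expects 03_score_units.py outputs.  The generative contrast (grid and speed
tuning removed, HD kept, in the impaired-like cohort) should reproduce the
qualitative pattern: grid and speed proportions collapse while HD holds.
Writes results/group_report/.
"""

from pathlib import Path

import pandas as pd

from gridspeed import stats as gstats

SCORED = Path("results/scored")


def load_cohort(cohort: str) -> pd.DataFrame:
    frames = []
    for sdir in sorted((SCORED / cohort).glob("session*")):
        m = pd.read_csv(sdir / "unit_metrics.csv")
        c = pd.read_csv(sdir / "classification.csv")
        df = m.merge(c, on="unit_id")
        df["session"] = sdir.name
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    df["is_conjunctive"] = df["label"] == "conjunctive"
    return df


def main() -> None:
    a = load_cohort("control")
    b = load_cohort("impaired")
    report = gstats.group_report(a, b, labels=("control", "impaired"))
    out = Path("results/group_report")
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report.items():
        if hasattr(table, "to_csv"):
            table.to_csv(out / f"{name}.csv")
    print(report["proportions"][["pct_a", "pct_b", "chi2", "p"]].round(3))
    print()
    print(report["scores"][["U", "p"]].round(3))

    # the published contingency anchors, recomputed from printed counts
    anchors = {
        "grid 36/150 vs 3/129": [[36, 114], [3, 126]],
        "speed 85/150 vs 17/129": [[85, 65], [17, 112]],
    }
    for label, table in anchors.items():
        chi2, df, p = gstats.chi_square_2x2(table)
        print(f"{label}: chi2(1) = {chi2:.2f}, p = {p:.2g}")


if __name__ == "__main__":
    main()
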