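"""Functional-class assembly and the group statistics used to compare cohorts.

Units are labelled single-class / conjunctive / unclassified from their
shuffle-threshold flags (grid, spatial non-grid, HD, speed; a unit passing
two or more is conjunctive).  Group comparisons use the uncorrected Pearson
chi-square on 2x2 proportion tables, Mann-Whitney U for score distributions,
and the Wilcoxon signed-rank normal approximation for paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

FUNCTIONAL_FLAGS = ("grid", "spatial_nongrid", "hd", "speed")


@dataclass
class UnitClassification:
    unit_id: str
    flags: dict  # flag name -> bool
    label: str  # single-class | conjunctive | unclassified

    @property
    def n_classes(self) -> int:
        return sum(bool(self.flags.get(k)) for k in FUNCTIONAL_FLAGS)


def classify_unit(unit_id: str, flags: dict) -> UnitClassification:
    """Derive the functional label from shuffle-threshold flags.

    ``flags`` uses the convention of :func:`gridspeed.shuffle.apply_thresholds`:
    a grid pass suppresses the spatial non-grid flag, so the two are mutually
    exclusive by construction.
    """
    f = {k: bool(flags.get(k, False)) for k in FUNCTIONAL_FLAGS}
    if flags.get("grid"):
        f["spatial_nongrid"] = False
    n = sum(f.values())
    label = "unclassified" if n == 0 else (
        "single-class" if n == 1 else "conjunctive")
    return UnitClassification(unit_id, f, label)


def chi_square_2x2(table) -> tuple:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns (chi2, df=1, p).  This is the convention that reproduces the
    published proportion comparisons from their printed counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def mann_whitney_u(a, b, convention: str = "min") -> tuple:
    """Mann-Whitney U with tie-corrected p (exact for small tie-free samples).

    Returns (U, p); ``convention='min'`` reports min(U1, U2) so the statistic
    is symmetric in the group order, ``'first'`` reports U of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u1 = float(res.statistic)
    u2 = a.size * b.size - u1
    u = min(u1, u2) if convention == "min" else u1
    return u, float(res.pvalue)


def wilcoxon_signed_rank(diffs) -> tuple:
    """Signed-rank Z and two-sided p (normal approximation, zeros dropped).

    Degenerate inputs (no nonzero difference, or a single one where the
    approximation is meaningless) return (0.0, 1.0).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d) & (d != 0)]
    n = d.size
    if n < 2:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie correction on the rank variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie = np.sum(counts ** 3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie
    if var <= 0:
        return 0.0, 1.0
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _median_iqr(x) -> tuple:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


def proportion_table(n_pass_a: int, n_a: int, n_pass_b: int, n_b: int) -> dict:
    table = [[n_pass_a, n_a - n_pass_a], [n_pass_b, n_b - n_pass_b]]
    try:
        chi2, df, p = chi_square_2x2(table)
    except ValueError:
        chi2, df, p = np.nan, 1, np.nan
    return {"a": f"{n_pass_a}/{n_a}", "b": f"{n_pass_b}/{n_b}",
            "pct_a": 100.0 * n_pass_a / n_a if n_a else np.nan,
            "pct_b": 100.0 * n_pass_b / n_b if n_b else np.nan,
            "chi2": chi2, "df": df, "p": p}


SCORE_COLUMNS = ("grid_score", "si", "hd_score", "speed_z", "tmi", "mean_rate")


def group_report(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame,
                 labels: tuple = ("A", "B"),
                 session_speeds: tuple | None = None) -> dict:
    """Cohort comparison tables mirroring a two-genotype results section.

    Each cohort is a per-unit table with score columns (grid_score, si,
    hd_score, speed_z, tmi, mean_rate — missing ones are skipped), boolean
    flag columns (is_grid, is_spatial_nongrid, is_hd, is_speed,
    is_theta_modulated, is_interneuron, is_fast_spiking) and optional
    ``speed_sign``.  Returns {'proportions': ..., 'scores': ...,
    'mean_speed': ...} DataFrames.
    """
    la, lb = labels
    na, nb = len(cohort_a), len(cohort_b)
    prop_rows = {}
    for flag in ("is_grid", "is_spatial_nongrid", "is_hd", "is_speed",
                 "is_theta_modulated", "is_interneuron", "is_fast_spiking",
                 "is_conjunctive"):
        if flag in cohort_a.columns and flag in cohort_b.columns:
            prop_rows[flag] = proportion_table(
                int(cohort_a[flag].fillna(False).sum()), na,
                int(cohort_b[flag].fillna(False).sum()), nb)
    # negative speed cells among the speed-modulated
    if "speed_sign" in cohort_a.columns and "is_speed" in cohort_a.columns:
        sa = cohort_a[cohort_a["is_speed"].fillna(False)]
        sb = cohort_b[cohort_b["is_speed"].fillna(False)]
        if len(sa) and len(sb):
            prop_rows["negative_speed_of_modulated"] = proportion_table(
                int((sa["speed_sign"] == "negative").sum()), len(sa),
                int((sb["speed_sign"] == "negative").sum()), len(sb))
    proportions = pd.DataFrame(prop_rows).T

    score_rows = {}
    for col in SCORE_COLUMNS:
        if col in cohort_a.columns and col in cohort_b.columns:
            xa = cohort_a[col].to_numpy(dtype=float)
            xb = cohort_b[col].to_numpy(dtype=float)
            med_a, iqr_a = _median_iqr(xa)
            med_b, iqr_b = _median_iqr(xb)
            xa_f, xb_f = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
            if xa_f.size and xb_f.size:
                u, p = mann_whitney_u(xa_f, xb_f)
            else:
                u, p = np.nan, np.nan
            score_rows[col] = {
                f"median_{la}": med_a, f"iqr_{la}": iqr_a,
                f"median_{lb}": med_b, f"iqr_{lb}": iqr_b,
                "U": u, "p": p}
    scores = pd.DataFrame(score_rows).T

    report = {"proportions": proportions, "scores": scores}
    if session_speeds is not None:
        sa, sb = (np.asarray(s, dtype=float) for s in session_speeds)
        t, p = sps.ttest_ind(sa, sb, equal_var=True)
        report["mean_speed"] = pd.DataFrame({
            "mean": [sa.mean(), sb.mean()],
            "sem": [sa.std(ddof=1) / np.sqrt(sa.size),
                    sb.std(ddof=1) / np.sqrt(sb.size)],
        }, index=[la, lb])
        report["mean_speed_test"] = {"t": float(t), "p": float(p)}
    return report
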