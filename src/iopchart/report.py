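"""Cohort analysis report: the full analysis battery on one cohort table.

Consumes the per-patient paired-eye table produced by
:func:`iopchart.simulate.simulate_cohort` (or assembled from digitized
sheets) and emits a JSON-serializable report with four families of
sections: per-time-point right/left comparisons, progressor versus
non-progressor summaries, cut-off sensitivity/specificity plus ROC for
peak-IOP criteria, and inter-eye correlation of every recorded
parameter including paired progression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateLabels, StatisticUndefined
from .stats import (DEFAULT_NORMATIVE_SLOPE, classify_progression,
                    cutoff_metrics, logistic_or, paired_eye_phi, roc_curve,
                    spearman, wilcoxon_paired)

TIME_COLS = ("t10", "t14", "t17", "t21", "t24")
OUTPATIENT_COLS = ("t10", "t14", "t17")
SUMMARY_VARS = ("t_avg", "t_max", "t_min", "iop_var", "mopp")
SECTOR_COLS = ("g", "ts", "t", "ti")


def _mean_sd(x) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
            "n": int(len(x))}


def _progressor_flags(df: pd.DataFrame, eye: str, normative_slope: float,
                      alpha: float) -> pd.Series:
    """Stored flags when present, else the transparent slope rule."""
    col = f"progressor_{eye}"
    if col in df.columns:
        return df[col].astype(bool)
    flags = []
    for _, row in df.iterrows():
        slopes = {s.upper(): row[f"slope_{s}_{eye}"] for s in SECTOR_COLS
                  if f"slope_{s}_{eye}" in df.columns}
        flags.append(classify_progression(
            slopes, normative_slope=normative_slope, alpha=alpha).progressor)
    return pd.Series(flags, index=df.index)


def _worst_quadrants(df: pd.DataFrame, eye: str) -> pd.Series:
    out = []
    for _, row in df.iterrows():
        slopes = {s.upper(): row[f"slope_{s}_{eye}"] for s in ("ts", "t", "ti")
                  if f"slope_{s}_{eye}" in df.columns}
        out.append(classify_progression(slopes).worst_quadrant if slopes else None)
    return pd.Series(out, index=df.index)


def analyze_cohort(df: pd.DataFrame, cutoffs=(15.0, 22.0),
                   normative_slope: float = DEFAULT_NORMATIVE_SLOPE,
                   alpha: float = 0.05, analysis_eye: str = "l") -> dict:
    """Run the whole analysis battery and return the report dictionary.

    ``analysis_eye`` selects which eye's summaries drive the progression,
    cut-off and ROC sections; the inter-eye section always uses both.
    """
    eye = analysis_eye
    n_tests = 0
    report: dict = {
        "n_patients": int(len(df)),
        "analysis_eye": eye,
        "progression_rule": {
            "kind": "normative-slope",
            "normative_slope_um_per_year": normative_slope,
            "alpha": alpha,
            "note": "sector progresses when RNFL slope < normative slope; "
                    "eye progresses when any sector does",
        },
    }

    # --- right/left comparison at each protocol time -------------------
    time_section = {}
    for col in TIME_COLS:
        if f"{col}_r" not in df.columns or f"{col}_l" not in df.columns:
            continue
        entry = {"right": _mean_sd(df[f"{col}_r"]), "left": _mean_sd(df[f"{col}_l"])}
        try:
            entry["wilcoxon_p"] = wilcoxon_paired(
                df[f"{col}_r"], df[f"{col}_l"]).p_value
            n_tests += 1
        except StatisticUndefined:
            entry["wilcoxon_p"] = None
        time_section[col] = entry
    report["time_point_comparison"] = time_section

    # --- progressors vs non-progressors -------------------------------
    flags = _progressor_flags(df, eye, normative_slope, alpha)
    prog_section = {"n_progressors": int(flags.sum()),
                    "n_non_progressors": int((~flags).sum()),
                    "proportion": float(flags.mean()), "variables": {}}
    for var in SUMMARY_VARS:
        col = f"{var}_{eye}"
        if col not in df.columns:
            continue
        entry = {"progressors": _mean_sd(df.loc[flags, col]),
                 "non_progressors": _mean_sd(df.loc[~flags, col])}
        try:
            res = logistic_or(flags.to_numpy(), df[col].to_numpy())
            entry["odds_ratio"] = res.estimate
            entry["p"] = res.p_value
            n_tests += 1
        except (DegenerateLabels, StatisticUndefined):
            entry["odds_ratio"] = entry["p"] = None
        prog_section["variables"][var] = entry
    report["progressor_comparison"] = prog_section

    # --- cut-off utility and ROC ---------------------------------------
    tmax_24h = df[f"t_max_{eye}"].to_numpy(dtype=float)
    op_vals = df[[f"{c}_{eye}" for c in OUTPATIENT_COLS]].to_numpy(dtype=float)
    tmax_op = np.nanmax(op_vals, axis=1)
    iopvar_24h = df[f"iop_var_{eye}"].to_numpy(dtype=float)
    iopvar_op = tmax_op - np.nanmin(op_vals, axis=1)
    cut_section = []
    for cutoff in cutoffs:
        for source, values in (("24H", tmax_24h), ("OP-IOP", tmax_op)):
            try:
                c = cutoff_metrics(flags.to_numpy(), values, cutoff, source)
                cut_section.append(vars(c))
            except DegenerateLabels:
                pass
    report["cutoffs"] = cut_section
    roc_section = {}
    for name, scores in (("t_max_24h", tmax_24h), ("t_max_op", tmax_op),
                         ("iop_var_24h", iopvar_24h), ("iop_var_op", iopvar_op)):
        try:
            _, auc = roc_curve(flags.to_numpy(), scores)
            roc_section[name] = {"auc": auc}
        except DegenerateLabels:
            roc_section[name] = {"auc": None}
    report["roc"] = roc_section

    # --- inter-eye correlations ----------------------------------------
    inter = {}
    for var in SUMMARY_VARS + tuple(f"slope_{s}" for s in SECTOR_COLS):
        cr, cl = f"{var}_r", f"{var}_l"
        if cr not in df.columns or cl not in df.columns:
            continue
        try:
            res = spearman(df[cr].to_numpy(), df[cl].to_numpy())
            inter[var] = {"rho": res.estimate, "p": res.p_value, "n": res.n}
            n_tests += 1
        except StatisticUndefined:
            inter[var] = None
    report["inter_eye"] = inter
    if "progressor_r" in df.columns or f"slope_g_r" in df.columns:
        try:
            right = _progressor_flags(df, "r", normative_slope, alpha)
            left = _progressor_flags(df, "l", normative_slope, alpha)
            res = paired_eye_phi(left.to_numpy(), right.to_numpy())
            report["inter_eye_progression"] = {
                "phi": res.estimate, "p": res.p_value,
                "table": res.ancillary["table"]}
            n_tests += 1
        except (StatisticUndefined, DegenerateLabels):
            report["inter_eye_progression"] = None
    if f"slope_ts_r" in df.columns:
        wq_r = _worst_quadrants(df, "r")
        wq_l = _worst_quadrants(df, "l")
        same = (wq_r == wq_l) & wq_r.notna()
        dist = wq_r[same].value_counts().to_dict()
        report["worst_quadrant_concordance"] = {
            "n_same": int(same.sum()),
            "share_same": float(same.mean()),
            "distribution_among_concordant": {k: int(v) for k, v in dist.items()},
        }
    report["n_statistical_tests"] = n_tests
    report["multiple_testing_correction"] = "none (unadjusted p-values)"
    return report
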