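"""Cohort-level descriptive statistics and report/figure export.

Covers the descriptive results of the analysis: CTC positivity and timepoint
fractions, count medians and the tdEV:CTC fold-ratio, the manual-vs-automated
count relationship, paired pre/post-treatment count shifts, and simple
markdown/CSV/figure exports.  Displayed percentages are rounded half away
from zero (98/143 -> 69%); raw fractions are always retained alongside.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr, wilcoxon

__all__ = ["round_half_away", "cohort_summary", "manual_vs_automated",
           "paired_shift_tests", "write_markdown_report"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def cohort_summary(sample_counts: pd.DataFrame,
                   manual_counts: pd.Series | None = None) -> dict:
    """Descriptive cohort summary.

    Positivity = fraction of baseline samples with >= 1 CTC.  Medians and
    ranges are over all samples; the fold-ratio is median tdEV / median CTC
    (NaN when the CTC median is 0).
    """
    if len(sample_counts) == 0:
        raise ValueError("empty sample table")
    n_samples = len(sample_counts)
    by_tp = sample_counts.groupby("timepoint").size().to_dict()
    tp_frac = {tp: n / n_samples for tp, n in by_tp.items()}

    base = sample_counts[sample_counts["timepoint"] == "baseline"]
    n_base = len(base)
    n_pos = int((base["n_ctc"] >= 1).sum())
    pos_frac = n_pos / n_base if n_base else float("nan")

    med_ctc = float(sample_counts["n_ctc"].median())
    med_tdev = float(sample_counts["n_tdev"].median())
    summary = {
        "n_samples": n_samples,
        "n_patients": int(sample_counts["patient_id"].nunique()),
        "samples_by_timepoint": by_tp,
        "timepoint_fractions": tp_frac,
        "timepoint_percent_display": {tp: round_half_away(100 * f) for tp, f in tp_frac.items()},
        "n_baseline": n_base,
        "n_ctc_positive_baseline": n_pos,
        "ctc_positive_fraction": pos_frac,
        "ctc_positive_percent_display": round_half_away(100 * pos_frac) if n_base else None,
        "ctc_median": med_ctc,
        "ctc_range": [float(sample_counts["n_ctc"].min()), float(sample_counts["n_ctc"].max())],
        "tdev_median": med_tdev,
        "tdev_range": [float(sample_counts["n_tdev"].min()), float(sample_counts["n_tdev"].max())],
        "tdev_ctc_fold_ratio": med_tdev / med_ctc if med_ctc > 0 else float("nan"),
    }
    if manual_counts is not None:
        summary["manual_ctc_median"] = float(np.median(manual_counts))
        summary["manual_ctc_range"] = [float(np.min(manual_counts)), float(np.max(manual_counts))]
    return summary


def manual_vs_automated(manual: np.ndarray, automated: np.ndarray) -> dict:
    """Relationship between reviewer-based and software-based CTC counts.

    Least-squares slope/intercept, Spearman rank correlation, and a
    residual-spread summary (sd of residuals in the lower vs upper half of
    the automated-count range) quantifying the increasing variability at
    higher counts.
    """
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.size != automated.size or manual.size < 3:
        raise ValueError("need >= 3 paired counts")
    if np.std(automated) == 0:
        raise ValueError("automated counts are constant; no relationship to fit")
    fit = linregress(automated, manual)
    rho = spearmanr(automated, manual).statistic if np.std(manual) > 0 else 1.0
    resid = manual - (fit.intercept + fit.slope * automated)
    cut = float(np.median(automated))
    low, high = resid[automated <= cut], resid[automated > cut]
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue ** 2),
        "spearman_r": float(rho),
        "n_pairs": int(manual.size),
        "residual_sd_low_half": float(low.std()) if low.size else float("nan"),
        "residual_sd_high_half": float(high.std()) if high.size else float("nan"),
    }


def paired_shift_tests(sample_counts: pd.DataFrame,
                       biomarkers: tuple[str, ...] = ("n_ctc", "n_tdev")) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of paired count shifts across timepoints.

    Transitions: baseline -> follow-up (expected decrease under effective
    therapy) and follow-up -> progression (expected increase).  Two-sided
    p per biomarker per transition; p = 1 when all differences are zero.
    """
    transitions = (("baseline", "follow_up"), ("follow_up", "progression"))
    rows = []
    for marker in biomarkers:
        wide = sample_counts.pivot_table(index="patient_id", columns="timepoint",
                                         values=marker, aggfunc="first")
        for a, b in transitions:
            if a not in wide.columns or b not in wide.columns:
                continue
            paired = wide[[a, b]].dropna()
            if len(paired) == 0:
                continue
            diff = (paired[b] - paired[a]).to_numpy(dtype=float)
            if np.all(diff == 0):
                p, stat = 1.0, 0.0
            else:
                res = wilcoxon(diff[diff != 0], alternative="two-sided")
                p, stat = float(res.pvalue), float(res.statistic)
            rows.append({"biomarker": marker, "transition": f"{a}->{b}",
                         "n_pairs": int(len(diff)),
                         "median_difference": float(np.median(diff)),
                         "statistic": stat, "p_value": p})
    if not rows:
        raise ValueError("no paired observations for any transition")
    return pd.DataFrame(rows)


def write_markdown_report(path: str | Path, summary: dict,
                          shifts: pd.DataFrame | None = None,
                          mva: dict | None = None,
                          extra_sections: dict[str, str] | None = None) -> None:
    """Human-readable cohort report next to the machine-readable JSON."""
    lines = ["# Cohort report", ""]
    lines.append(f"- Samples: {summary['n_samples']} from {summary['n_patients']} patients")
    for tp, pct in summary["timepoint_percent_display"].items():
        lines.append(f"  - {tp}: {summary['samples_by_timepoint'][tp]} ({pct}%)")
    if summary.get("ctc_positive_percent_display") is not None:
        lines.append(f"- Baseline CTC-positive (>=1 CTC): {summary['n_ctc_positive_baseline']}"
                     f"/{summary['n_baseline']} ({summary['ctc_positive_percent_display']}%)")
    lines.append(f"- Automated CTC count median (range): {summary['ctc_median']:g} "
                 f"({summary['ctc_range'][0]:g}-{summary['ctc_range'][1]:g})")
    lines.append(f"- tdEV count median (range): {summary['tdev_median']:g} "
                 f"({summary['tdev_range'][0]:g}-{summary['tdev_range'][1]:g})")
    fr = summary["tdev_ctc_fold_ratio"]
    if not math.isnan(fr):
        lines.append(f"- tdEV:CTC median fold-ratio: {fr:g}")
    if mva is not None:
        lines += ["", "## Manual vs automated CTC counts", "",
                  f"- slope {mva['slope']:.3f}, intercept {mva['intercept']:.3f}, "
                  f"Spearman r {mva['spearman_r']:.3f} over {mva['n_pairs']} pairs"]
    if shifts is not None and len(shifts):
        lines += ["", "## Paired count shifts", ""]
        lines.append(shifts.to_markdown(index=False))
    for title, body in (extra_sections or {}).items():
        lines += ["", f"## {title}", "", body]
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_json(path: str | Path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
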