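"""Shannon-index quantification of per-sample CTC phenotypic diversity.

The Shannon index SI = -sum_i p_i ln p_i is computed over the cluster
composition p_i = n_i / n of each sample's CTCs, in nats by default (the
prognostic cut 0.68 and the five-cluster maximum ln 5 ~ 1.61 are mutually
consistent in nats).  Samples without CTCs have no defined composition: their
SI is NaN and their group is "undefined", and they are excluded from
SI-stratified survival.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .config import DiversityConfig

logger = logging.getLogger(__name__)

__all__ = ["shannon_index", "dichotomize_si", "diversity_table", "si_trajectory"]


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon index of a vector of cluster counts, with 0*ln 0 := 0.

    Returns NaN (undefined) for an all-zero vector - distinct from 0, which
    means "all CTCs in one cluster".  Invariant under label permutation and
    appending empty clusters; bounded by log(k_occupied) <= log(k).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    n = c.sum()
    if n == 0:
        return float("nan")
    p = c[c > 0] / n
    si = float(-(p * np.log(p)).sum())
    if base is not None:
        si /= math.log(base)
    return si


def dichotomize_si(si: float, cut: float = 0.68) -> str:
    """Prognostic SI group: unfavorable iff si >= cut; NaN -> undefined."""
    if si is None or (isinstance(si, float) and math.isnan(si)):
        return "undefined"
    return "unfavorable" if si >= cut else "favorable"


def diversity_table(composition: pd.DataFrame, config: DiversityConfig | None = None,
                    k: int = 5) -> pd.DataFrame:
    """Per-sample DiversityResult table from a cluster-composition table.

    ``composition`` is the output of :func:`ctcpheno.phenotyping.cluster_presence`
    (columns ``sample_id``, ``n_ctc``, ``n_cluster_1..k``).
    """
    config = config or DiversityConfig()
    count_cols = [f"n_cluster_{j+1}" for j in range(k)]
    counts = composition[count_cols].to_numpy()
    si = np.array([shannon_index(c, base=config.log_base) for c in counts])
    out = composition[["sample_id", "n_ctc"]].copy()
    for j in range(k):
        out[f"p_{j+1}"] = composition[f"frac_cluster_{j+1}"].to_numpy()
    out["si"] = si
    out["si_group"] = [dichotomize_si(v, config.si_cut) for v in si]
    return out


def si_trajectory(diversity: pd.DataFrame, samples: pd.DataFrame) -> dict:
    """Paired SI shifts across therapy: baseline->follow-up and
    follow-up->progression.

    For each transition, computes the paired differences (later - earlier)
    over patients with a defined SI at both timepoints and a two-sided
    Wilcoxon signed-rank p (p = 1 when every difference is zero).  Patients
    missing either timepoint are excluded with a log entry.
    """
    merged = diversity.merge(samples[["sample_id", "patient_id", "timepoint"]], on="sample_id")
    wide = merged.pivot_table(index="patient_id", columns="timepoint", values="si",
                              aggfunc="first")
    results = {}
    any_pairs = False
    for name, a, b in (("baseline_to_follow_up", "baseline", "follow_up"),
                       ("follow_up_to_progression", "follow_up", "progression")):
        if a not in wide.columns or b not in wide.columns:
            results[name] = None
            continue
        paired = wide[[a, b]].dropna()
        n_excluded = len(wide) - len(paired)
        if n_excluded:
            logger.info("si_trajectory %s: excluded %d patient(s) without both timepoints",
                        name, n_excluded)
        if len(paired) == 0:
            results[name] = None
            continue
        any_pairs = True
        diff = (paired[b] - paired[a]).to_numpy()
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(wilcoxon(diff[diff != 0], alternative="two-sided").pvalue)
        results[name] = {
            "n_pairs": int(len(diff)),
            "median_difference": float(np.median(diff)),
            "mean_difference": float(np.mean(diff)),
            "p_value": p,
        }
    if not any_pairs:
        raise ValueError("no patient has a defined SI at two consecutive timepoints")
    return results
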