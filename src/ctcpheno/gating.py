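"""Object gating: partition detected events into CTC / tdEV / other.

The gate logic follows the established CellSearch conventions: both CTCs and
tdEVs are cytokeratin-positive and CD45-negative; a CTC additionally has a
nucleus (DNA signal above a floor), sufficient size and DNA/CK co-localization,
while a tdEV is a small particle *without* a nucleus.  Counts are reported per
cartridge and interpreted as per 7.5 mL of blood (one cartridge = one draw).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import GatingConfig

logger = logging.getLogger(__name__)

__all__ = ["classify_events", "enumerate_samples", "classify_dynamics", "SchemaError"]

_REQUIRED = [
    "mean_intensity_ck", "total_intensity_dna", "mean_intensity_cd45",
    "area_ck", "overlap_dna_ck",
]


class SchemaError(ValueError):
    """An expected column is missing from an input table."""


def classify_events(events: pd.DataFrame, config: GatingConfig | None = None) -> pd.DataFrame:
    """Assign each event exactly one class in {ctc, tdev, other}.

    CTC:  CK+ and DNA total >= ``dna_total_min_ctc`` and CD45 mean <=
    ``cd45_mean_max`` and CK area >= ``ctc_area_min`` and DNA/CK overlap >=
    ``overlap_min_ctc``.  tdEV: CK+ and DNA total <= ``dna_total_max_tdev``
    and CD45 mean <= ``cd45_mean_max`` and CK area <= ``tdev_area_max``.
    Everything else (leukocytes, debris, ambiguous signals) is ``other``.
    The config validator guarantees the two gates are mutually exclusive
    (``dna_total_max_tdev < dna_total_min_ctc``).

    Returns a copy with an ``event_class`` column appended.
    """
    config = config or GatingConfig()
    missing = [c for c in _REQUIRED if c not in events.columns]
    if missing:
        raise SchemaError(f"event table is missing required column(s): {', '.join(missing)}")

    out = events.copy()
    if len(out) == 0:
        out["event_class"] = pd.Series([], dtype=str)
        return out

    ck_pos = out["mean_intensity_ck"].to_numpy() >= config.ck_mean_min
    cd45_neg = out["mean_intensity_cd45"].to_numpy() <= config.cd45_mean_max
    dna_total = out["total_intensity_dna"].to_numpy()
    area = out["area_ck"].to_numpy()
    overlap = out["overlap_dna_ck"].to_numpy()

    is_ctc = (ck_pos & cd45_neg
              & (dna_total >= config.dna_total_min_ctc)
              & (area >= config.ctc_area_min)
              & (overlap >= config.overlap_min_ctc))
    is_tdev = (ck_pos & cd45_neg
               & (dna_total <= config.dna_total_max_tdev)
               & (area <= config.tdev_area_max))
    out["event_class"] = np.select([is_ctc, is_tdev], ["ctc", "tdev"], default="other")
    return out


def enumerate_samples(classified: pd.DataFrame, samples: pd.DataFrame,
                      config: GatingConfig | None = None) -> pd.DataFrame:
    """Per-sample counts and prognostic dichotomization.

    Every sample in ``samples`` appears in the output, including those with
    zero events (all counts 0, both groups favorable).  The boundary count is
    unfavorable: ``n_ctc >= 5`` and ``n_tdev >= 105`` per 7.5 mL.
    """
    config = config or GatingConfig()
    for col in ("sample_id", "patient_id", "timepoint"):
        if col not in samples.columns:
            raise SchemaError(f"sample table is missing required column: {col}")
    if "event_class" not in classified.columns and len(classified):
        raise SchemaError("events must be classified first (missing event_class)")

    if len(classified):
        counts = (classified.groupby(["sample_id", "event_class"]).size()
                  .unstack(fill_value=0))
    else:
        counts = pd.DataFrame(index=pd.Index([], name="sample_id"))
    for cls in ("ctc", "tdev", "other"):
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts.reindex(samples["sample_id"], fill_value=0)

    out = samples[["sample_id", "patient_id", "timepoint"]].copy()
    out["n_ctc"] = counts["ctc"].to_numpy()
    out["n_tdev"] = counts["tdev"].to_numpy()
    out["n_other"] = counts["other"].to_numpy()
    out["ctc_group"] = np.where(out["n_ctc"] >= config.ctc_unfavorable_cut,
                                "unfavorable", "favorable")
    out["tdev_group"] = np.where(out["n_tdev"] >= config.tdev_unfavorable_cut,
                                 "unfavorable", "favorable")
    return out


def classify_dynamics(sample_counts: pd.DataFrame,
                      config: GatingConfig | None = None) -> pd.DataFrame:
    """CTC dynamics per patient: baseline vs follow-up count comparison.

    increasing iff follow-up > baseline, decreasing iff <, stable iff equal
    (exact equality by default; ``config.stable_band`` widens "stable" to a
    relative band).  Patients missing either sample are excluded and logged.
    """
    config = config or GatingConfig()
    wide = (sample_counts.pivot_table(index="patient_id", columns="timepoint",
                                      values="n_ctc", aggfunc="first")
            .reindex(columns=["baseline", "follow_up"]))
    paired = wide.dropna()
    n_dropped = len(wide) - len(paired)
    if n_dropped:
        logger.info("dynamics: excluded %d patient(s) without both baseline and follow-up",
                    n_dropped)
    base = paired["baseline"].to_numpy(dtype=float)
    fu = paired["follow_up"].to_numpy(dtype=float)
    if config.stable_band > 0:
        lo = base * (1.0 - config.stable_band)
        hi = base * (1.0 + config.stable_band)
        direction = np.select([fu > hi, fu < lo], ["increasing", "decreasing"], "stable")
    else:
        direction = np.select([fu > base, fu < base], ["increasing", "decreasing"], "stable")
    return pd.DataFrame({"patient_id": paired.index.to_numpy(), "direction": direction})
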