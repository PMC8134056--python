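"""Synthetic CellSearch-like cohort generator.

Produces ground-truthed inputs for every downstream stage: a per-object
fluorescence feature table (optionally rendered as multichannel images), a
sample table, and a patient cohort whose progression-free and overall
survival depend on biomarkers through a known proportional-hazards model.

The default :class:`~ctcpheno.config.ScenarioConfig` is calibrated to the
published mCRPC cohort marginals: ~170 patients contributing ~331 cartridges
(baseline, 10-12-week follow-up, progression), ~69% baseline CTC positivity,
heavily right-skewed counts (median CTC 1, median tdEV 16 per 7.5 mL, ranges
into the thousands), five phenotype clusters of unequal prevalence with
cluster 3 near-ubiquitous and cluster 5 rare, and hazards increasing with
chemotherapy pretreatment, PSA, CTC count and Shannon diversity.

All randomness flows from one `numpy.random.Generator` seeded from the
scenario config; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EVENT_FEATURE_COLUMNS, TIMEPOINTS, ConfigurationError, ScenarioConfig

__all__ = [
    "CohortData",
    "TruthTable",
    "generate_cohort",
    "render_sample_image",
    "simulate_two_arm",
    "CLUSTER_PHENOTYPES",
]


# ---------------------------------------------------------------------------
# cluster phenotype parameters
# ---------------------------------------------------------------------------
# Per-cluster generative means for the phenotype-relevant features; the
# remaining features are derived (perimeter from area+eccentricity, max and
# total intensity from mean intensity and area).  Offsets are relative to the
# "typical" cluster 3 phenotype and scale with ScenarioConfig.cluster_separation:
#   1 - large, rather oval nuclei (high DNA area + eccentricity)
#   2 - larger CTCs with high cytokeratin intensity
#   3 - typical epithelial CTC (most prevalent)
#   4 - small CTCs: intense, small DAPI signal, attenuated CK
#   5 - rare very large cells
_BASE = {
    "area_dna": (45.0, 7.0),
    "eccentricity_dna": (0.45, 0.08),
    "mean_intensity_dna": (180.0, 20.0),
    "sd_intensity_dna": (45.0, 8.0),
    "area_ck": (80.0, 12.0),
    "eccentricity_ck": (0.50, 0.08),
    "mean_intensity_ck": (150.0, 20.0),
    "sd_intensity_ck": (50.0, 10.0),
}

_OFFSETS = {
    1: {"area_dna": 65.0, "eccentricity_dna": 0.30, "mean_intensity_dna": -10.0, "area_ck": 15.0},
    2: {"area_ck": 80.0, "mean_intensity_ck": 230.0, "sd_intensity_ck": 60.0, "area_dna": 10.0},
    3: {},
    4: {"area_dna": -25.0, "mean_intensity_dna": 160.0, "area_ck": -50.0,
        "mean_intensity_ck": -75.0, "sd_intensity_ck": -30.0},
    5: {"area_dna": 105.0, "area_ck": 140.0, "mean_intensity_ck": 100.0, "eccentricity_dna": 0.15},
}

CLUSTER_PHENOTYPES = {
    c: {f: (_BASE[f][0] + _OFFSETS[c].get(f, 0.0), _BASE[f][1]) for f in _BASE}
    for c in range(1, 6)
}

# physical floors keeping every generated CTC inside the default gates
_CTC_CLIPS = {
    "area_dna": (14.0, None),
    "mean_intensity_dna": (110.0, None),
    "area_ck": (20.0, None),
    "mean_intensity_ck": (55.0, None),
    "eccentricity_dna": (0.05, 0.97),
    "eccentricity_ck": (0.05, 0.97),
    "sd_intensity_dna": (1.0, None),
    "sd_intensity_ck": (1.0, None),
}


@dataclass
class TruthTable:
    """Ground truth for a generated cohort.

    ``objects`` has one row per generated object (class, and the phenotype
    cluster for CTCs); ``patients`` carries the true linear predictors and
    uncensored event times.
    """

    objects: pd.DataFrame
    patients: pd.DataFrame


@dataclass
class CohortData:
    patients: pd.DataFrame
    samples: pd.DataFrame
    events: pd.DataFrame
    truth: TruthTable


_PATIENT_COLUMNS = [
    "patient_id", "age", "chemo_status", "prior_arsi", "metastases",
    "psa", "ldh", "pfs_time", "pfs_event", "os_time", "os_event",
]
_SAMPLE_COLUMNS = ["sample_id", "patient_id", "timepoint", "manual_ctc"]
_TRUTH_OBJECT_COLUMNS = ["event_id", "sample_id", "true_class", "true_cluster"]
_TRUTH_PATIENT_COLUMNS = [
    "patient_id", "ctc_baseline_true", "tdev_baseline_true", "si_baseline_true",
    "lp_pfs", "lp_os", "pfs_time_uncensored", "os_time_uncensored",
]


def _empty_cohort() -> CohortData:
    return CohortData(
        patients=pd.DataFrame(columns=_PATIENT_COLUMNS),
        samples=pd.DataFrame(columns=_SAMPLE_COLUMNS),
        events=pd.DataFrame(columns=EVENT_FEATURE_COLUMNS),
        truth=TruthTable(
            objects=pd.DataFrame(columns=_TRUTH_OBJECT_COLUMNS),
            patients=pd.DataFrame(columns=_TRUTH_PATIENT_COLUMNS),
        ),
    )


def _zinb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
                 structural_zero: np.ndarray) -> np.ndarray:
    """Negative-binomial draws with structural zeros; mean may vary per draw."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    live = (~structural_zero) & (mean > 0)
    if live.any():
        r = dispersion
        p = r / (r + mean[live])
        out[live] = rng.negative_binomial(r, p)
    return out


def _normalize_rows(q: np.ndarray) -> np.ndarray:
    return q / q.sum(axis=-1, keepdims=True)


def _shannon(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def generate_cohort(config: ScenarioConfig) -> CohortData:
    """Generate a full synthetic cohort under ``config``.

    Returns patients, samples, per-object event features and a
    :class:`TruthTable`.  Deterministic given ``config.seed``.
    """
    if config.n_patients == 0:
        return _empty_cohort()

    # independent child streams per concern, so that e.g. re-tuning the
    # composition model cannot reshuffle the calibrated count draws
    root = np.random.default_rng(config.seed)
    (rng_pat, rng_comp, rng_count, rng_tdev, rng_surv, rng_misc,
     rng_feat) = root.spawn(7)
    n_pat = config.n_patients
    cm, tm, hz = config.ctc_counts, config.tdev_counts, config.hazard
    prev = np.asarray(config.cluster_prevalence, dtype=float)
    k = prev.size

    # ----- patients -------------------------------------------------------
    pid = np.array([f"P{i:04d}" for i in range(n_pat)])
    age = rng_pat.normal(75.0, 8.0, n_pat)
    chemo = rng_pat.random(n_pat) < config.chemo_pretreated_prob
    arsi = rng_pat.random(n_pat) < config.prior_arsi_prob
    visceral = rng_pat.random(n_pat) < config.visceral_prob
    psa = rng_pat.lognormal(np.log(40.0), 1.3, n_pat)
    ldh = rng_pat.lognormal(np.log(250.0), 0.35, n_pat)
    frailty_z = rng_pat.normal(0.0, 1.0, n_pat)
    struct_zero = rng_pat.random(n_pat) < cm.pi_zero

    # Per-patient cluster mix.  A tumor sheds CTCs from a small *support* of
    # phenotype clusters - many patients are effectively monoclonal - so the
    # per-sample Shannon index is driven by the patient's subclonal makeup
    # rather than by how many CTCs happened to be captured.  Chemotherapy
    # pretreatment broadens the support (flattened selection weights plus a
    # chance of one extra clone), which raises baseline diversity.
    if config.cluster_concentration is None:
        q_pat = np.tile(prev, (n_pat, 1))
    else:
        support_sizes = rng_comp.choice(np.arange(1, k + 1), size=n_pat,
                                   p=np.asarray(config.support_size_probs))
        extra = rng_comp.random(n_pat) < 0.35
        support_sizes = np.where(chemo & extra, np.minimum(support_sizes + 1, k), support_sizes)
        if config.clonal_dominance > 0:
            # aggressive high-burden tumors tend to be dominated by a single
            # expanding clone, which keeps diversity ~independent of count
            collapse = rng_comp.random(n_pat) < 1.0 - np.exp(-config.clonal_dominance * np.maximum(frailty_z, 0.0))
            support_sizes = np.where(collapse, 1, support_sizes)
        sel_base = prev
        sel_flat = _normalize_rows(prev ** config.chemo_flattening)
        q_pat = np.zeros((n_pat, k))
        for i in range(n_pat):
            weights = sel_flat if chemo[i] else sel_base
            m = int(support_sizes[i])
            support = rng_comp.choice(k, size=m, replace=False, p=weights)
            w = rng_comp.dirichlet(np.full(m, config.cluster_concentration))
            q_pat[i, support] = w

    present = {tp: rng_misc.random(n_pat) < config.timepoint_probs.get(tp, 0.0) for tp in TIMEPOINTS}

    # ----- per-sample counts ---------------------------------------------
    log_frailty = cm.patient_sigma * frailty_z + cm.chemo_log_shift * chemo
    burden = np.exp(log_frailty)
    sharpen = {"baseline": 1.0, "follow_up": config.followup_sharpening,
               "progression": config.progression_sharpening}

    # baseline counts are drawn for every patient (they define the hazard);
    # a baseline *sample* is only emitted for patients with a baseline draw
    n_ctc = {}
    cluster_counts = {}
    n_tdev = {}
    for tp in TIMEPOINTS:
        mu = cm.mean * burden * cm.timepoint_multiplier.get(tp, 1.0)
        n_ctc[tp] = _zinb_counts(rng_count, mu, cm.dispersion, struct_zero)
        q_tp = _normalize_rows(q_pat ** sharpen[tp])
        cluster_counts[tp] = np.vstack(
            [rng_comp.multinomial(n, q) for n, q in zip(n_ctc[tp], q_tp)]
        )
        ratio = rng_tdev.lognormal(tm.log_ratio_mu, tm.log_ratio_sigma, n_pat)
        mu_td = tm.base_mean * burden * cm.timepoint_multiplier.get(tp, 1.0) + ratio * n_ctc[tp]
        n_tdev[tp] = _zinb_counts(rng_tdev, mu_td, tm.dispersion, np.zeros(n_pat, dtype=bool))

    # ----- survival -------------------------------------------------------
    si_base = np.array([_shannon(c) for c in cluster_counts["baseline"]])
    coef = hz.coefficients
    lp = (coef.get("chemo_pretreated", 0.0) * chemo.astype(float)
          + coef.get("psa", 0.0) * psa
          + coef.get("ctc", 0.0) * n_ctc["baseline"]
          + coef.get("log1p_ctc", 0.0) * np.log1p(n_ctc["baseline"])
          + coef.get("si", 0.0) * si_base)
    t_pfs = rng_surv.exponential(1.0 / (hz.lambda0_pfs * np.exp(lp)))
    t_os = rng_surv.exponential(1.0 / (hz.lambda0_os * np.exp(lp)))
    c_pfs = rng_surv.uniform(hz.censoring_low, hz.censoring_high, n_pat)
    c_os = rng_surv.uniform(hz.censoring_low, hz.censoring_high, n_pat)
    # OS can never precede PFS-censoring administratively; keep them independent
    pfs_time = np.minimum(t_pfs, c_pfs)
    pfs_event = (t_pfs <= c_pfs).astype(int)
    os_time = np.minimum(t_os, c_os)
    os_event = (t_os <= c_os).astype(int)
    tiny = 1e-6  # strictly positive times
    pfs_time = np.maximum(pfs_time, tiny)
    os_time = np.maximum(os_time, tiny)

    patients = pd.DataFrame({
        "patient_id": pid,
        "age": age,
        "chemo_status": np.where(chemo, "pretreated", "naive"),
        "prior_arsi": np.where(arsi, "yes", "no"),
        "metastases": np.where(visceral, "visceral", "non-visceral/nodal"),
        "psa": psa,
        "ldh": ldh,
        "pfs_time": pfs_time,
        "pfs_event": pfs_event,
        "os_time": os_time,
        "os_event": os_event,
    })

    # ----- samples + objects ---------------------------------------------
    sample_rows = []
    obj_sample = []      # sample_id per object
    obj_class = []       # class code per object
    obj_cluster = []     # cluster per object (0 = n/a)
    for i in range(n_pat):
        for tp in TIMEPOINTS:
            if not present[tp][i]:
                continue
            sid = f"{pid[i]}-{tp}"
            nc, nt = int(n_ctc[tp][i]), int(n_tdev[tp][i])
            nl = int(rng_misc.poisson(config.leukocytes_per_cartridge))
            nd = int(rng_misc.poisson(config.debris_per_cartridge))
            manual = int(round(nc * np.exp(rng_misc.normal(0.0, config.manual_count_log_sd))))
            if rng_misc.random() < 0.03:  # occasional reviewer false positive
                manual += 1
            sample_rows.append((sid, pid[i], tp, manual))
            counts = cluster_counts[tp][i]
            clusters = np.repeat(np.arange(1, k + 1), counts)
            n_obj = nc + nt + nl + nd
            obj_sample.append(np.repeat(sid, n_obj))
            obj_class.append(np.repeat(["CTC", "tdEV", "leukocyte", "debris"], [nc, nt, nl, nd]))
            obj_cluster.append(np.concatenate([clusters, np.zeros(nt + nl + nd, dtype=int)]))

    samples = pd.DataFrame(sample_rows, columns=_SAMPLE_COLUMNS)
    if obj_sample:
        obj_sample = np.concatenate(obj_sample)
        obj_class = np.concatenate(obj_class)
        obj_cluster = np.concatenate(obj_cluster)
    else:
        obj_sample = np.array([], dtype=str)
        obj_class = np.array([], dtype=str)
        obj_cluster = np.array([], dtype=int)

    events = _draw_features(rng_feat, obj_sample, obj_class, obj_cluster, config)

    truth_objects = pd.DataFrame({
        "event_id": events["event_id"] if len(events) else pd.Series([], dtype=str),
        "sample_id": obj_sample,
        "true_class": obj_class,
        "true_cluster": obj_cluster,
    })
    truth_patients = pd.DataFrame({
        "patient_id": pid,
        "ctc_baseline_true": n_ctc["baseline"],
        "tdev_baseline_true": n_tdev["baseline"],
        "si_baseline_true": si_base,
        "lp_pfs": lp,
        "lp_os": lp,
        "pfs_time_uncensored": t_pfs,
        "os_time_uncensored": t_os,
    })
    return CohortData(patients=patients, samples=samples, events=events,
                      truth=TruthTable(objects=truth_objects, patients=truth_patients))


def _clip(x: np.ndarray, lo, hi) -> np.ndarray:
    return np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)


def _draw_features(rng: np.random.Generator, sample_id: np.ndarray, klass: np.ndarray,
                   cluster: np.ndarray, config: ScenarioConfig) -> pd.DataFrame:
    """Vectorized per-object feature synthesis.

    Distributions are class-conditional with generous margins around the
    default gates, so that gating recovers the true classes; CTC features are
    additionally cluster-conditional.
    """
    n = sample_id.size
    cols = {c: np.zeros(n) for c in EVENT_FEATURE_COLUMNS if c not in ("event_id", "sample_id")}
    is_ctc = klass == "CTC"
    is_tdev = klass == "tdEV"
    is_leuk = klass == "leukocyte"
    is_debris = klass == "debris"
    sep = config.cluster_separation

    # --- CTCs: cluster-conditional phenotype features ---------------------
    mean_of = {f: np.zeros(n) for f in _BASE}
    sd_of = {f: np.zeros(n) for f in _BASE}
    for c in range(1, 6):
        sel = is_ctc & (cluster == c)
        for f, (base_m, base_s) in _BASE.items():
            m = base_m + sep * _OFFSETS[c].get(f, 0.0)
            mean_of[f][sel] = m
            sd_of[f][sel] = base_s
    for f in _BASE:
        lo, hi = _CTC_CLIPS.get(f, (None, None))
        draw = rng.normal(mean_of[f], np.maximum(sd_of[f], 1e-9))
        cols[f][is_ctc] = _clip(draw, lo, hi)[is_ctc]

    cols["overlap_dna_ck"][is_ctc] = rng.uniform(0.75, 1.0, n)[is_ctc]

    # --- tdEVs: small CK-only particles, no DNA / CD45 object -------------
    nt = int(is_tdev.sum())
    cols["area_ck"][is_tdev] = _clip(rng.normal(8.0, 3.0, nt), 2.0, 14.0)
    cols["eccentricity_ck"][is_tdev] = _clip(rng.normal(0.4, 0.15, nt), 0.02, 0.95)
    cols["mean_intensity_ck"][is_tdev] = _clip(rng.normal(120.0, 25.0, nt), 60.0, None)
    cols["sd_intensity_ck"][is_tdev] = _clip(rng.normal(30.0, 8.0, nt), 1.0, None)

    # --- leukocytes: DNA + CD45, faint unspecific CK ----------------------
    nl = int(is_leuk.sum())
    cols["area_dna"][is_leuk] = _clip(rng.normal(50.0, 8.0, nl), 20.0, None)
    cols["eccentricity_dna"][is_leuk] = _clip(rng.normal(0.35, 0.1, nl), 0.02, 0.95)
    cols["mean_intensity_dna"][is_leuk] = _clip(rng.normal(200.0, 25.0, nl), 120.0, None)
    cols["sd_intensity_dna"][is_leuk] = _clip(rng.normal(40.0, 8.0, nl), 1.0, None)
    cols["area_ck"][is_leuk] = _clip(rng.normal(30.0, 8.0, nl), 5.0, None)
    cols["eccentricity_ck"][is_leuk] = _clip(rng.normal(0.4, 0.12, nl), 0.02, 0.95)
    cols["mean_intensity_ck"][is_leuk] = _clip(rng.normal(8.0, 3.0, nl), 0.0, 18.0)
    cols["sd_intensity_ck"][is_leuk] = _clip(rng.normal(4.0, 1.5, nl), 0.5, None)
    cols["area_cd45"][is_leuk] = _clip(rng.normal(55.0, 9.0, nl), 20.0, None)
    cols["eccentricity_cd45"][is_leuk] = _clip(rng.normal(0.35, 0.1, nl), 0.02, 0.95)
    cols["mean_intensity_cd45"][is_leuk] = _clip(rng.normal(220.0, 40.0, nl), 120.0, None)
    cols["sd_intensity_cd45"][is_leuk] = _clip(rng.normal(45.0, 10.0, nl), 1.0, None)
    cols["overlap_dna_ck"][is_leuk] = rng.uniform(0.5, 1.0, n)[is_leuk]

    # --- debris: dim CK-only junk -----------------------------------------
    ndb = int(is_debris.sum())
    cols["area_ck"][is_debris] = _clip(rng.normal(25.0, 10.0, ndb), 1.0, None)
    cols["eccentricity_ck"][is_debris] = _clip(rng.normal(0.6, 0.2, ndb), 0.02, 0.97)
    cols["mean_intensity_ck"][is_debris] = _clip(rng.normal(10.0, 4.0, ndb), 0.0, 20.0)
    cols["sd_intensity_ck"][is_debris] = _clip(rng.normal(6.0, 2.0, ndb), 0.5, None)
    cols["overlap_dna_ck"][is_debris] = _clip(rng.normal(0.05, 0.05, ndb), 0.0, 0.2)

    # --- derived quantities, all channels ---------------------------------
    for ch in ("dna", "ck", "cd45"):
        area = cols[f"area_{ch}"]
        ecc = cols[f"eccentricity_{ch}"]
        mean = cols[f"mean_intensity_{ch}"]
        has = area > 0
        perim = 2.0 * np.sqrt(np.pi * np.maximum(area, 0.0)) * (1.0 + 0.25 * ecc ** 2)
        perim *= np.exp(rng.normal(0.0, 0.04, n))
        cols[f"perimeter_{ch}"] = np.where(has, perim, 0.0)
        ratio = 1.7 + np.abs(rng.normal(0.0, 0.2, n))
        cols[f"max_intensity_{ch}"] = np.where(has, mean * ratio, 0.0)
        cols[f"total_intensity_{ch}"] = mean * area  # pixel size 1 um for the table path

    cols["centroid_x"] = rng.uniform(0.0, 1000.0, n)
    cols["centroid_y"] = rng.uniform(0.0, 1000.0, n)

    events = pd.DataFrame({"sample_id": sample_id, **cols})
    # stable per-sample event ids
    idx_within = events.groupby("sample_id", sort=False).cumcount()
    events.insert(0, "event_id", events["sample_id"] + "-" + idx_within.astype(str).str.zfill(5))
    return events[EVENT_FEATURE_COLUMNS]


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedSample:
    """A rendered multichannel cartridge image with pixel-exact ground truth."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    truth_mask: np.ndarray          # integer labels, 0 = background
    truth: pd.DataFrame             # object_id, class, row, col, radius_px per channel

    def stack(self) -> np.ndarray:
        return np.stack([self.channels[c] for c in ("dna", "ck", "cd45")])


_RENDER_PARAMS = {
    # per class: (radius um, amplitude) per channel; None = channel dark
    "CTC": {"dna": (4.0, 180.0), "ck": (5.0, 150.0), "cd45": None},  # DNA covers 64% of CK footprint
    "tdEV": {"dna": None, "ck": (1.5, 120.0), "cd45": None},
    "leukocyte": {"dna": (3.8, 200.0), "ck": None, "cd45": (4.2, 220.0)},
    "debris": {"dna": None, "ck": (2.5, 60.0), "cd45": None},
}


def render_sample_image(object_classes, shape=(256, 256), pixel_size: float = 0.5,
                        seed: int = 0, background_sd: float = 1.0) -> RenderedSample:
    """Render objects as hard fluorescent discs on a noisy background.

    CTCs are co-localized DNA+CK discs, tdEVs small CK-only discs,
    leukocytes DNA+CD45 discs.  Objects are placed on a jittered grid so
    footprints never touch; the truth mask marks each object's union
    footprint with its 1-based index.

    Raises ``ConfigurationError`` listing the overflow count when more
    objects are requested than the grid can hold.
    """
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ConfigurationError(f"image shape must be 2-D positive, got {shape!r}")
    object_classes = list(object_classes)
    rng = np.random.default_rng(seed)
    h, w = shape
    max_r_px = max(
        (p[0] / pixel_size for cls in _RENDER_PARAMS.values() for p in cls.values() if p),
    )
    cell = int(np.ceil(2 * max_r_px + 4))
    rows, cols_n = h // cell, w // cell
    capacity = rows * cols_n
    if len(object_classes) > capacity:
        raise ConfigurationError(
            f"{len(object_classes) - capacity} object(s) exceed image capacity "
            f"({capacity} grid cells of {cell}px for shape {shape})"
        )

    channels = {c: np.abs(rng.normal(3.0, background_sd, shape)) for c in ("dna", "ck", "cd45")}
    truth_mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]

    slots = rng.choice(capacity, size=len(object_classes), replace=False) if object_classes else []
    records = []
    for idx, (klass, slot) in enumerate(zip(object_classes, slots), start=1):
        if klass not in _RENDER_PARAMS:
            raise ConfigurationError(f"unknown object class {klass!r}")
        gr, gc = divmod(int(slot), cols_n)
        cy = gr * cell + cell // 2 + rng.integers(-1, 2)
        cx = gc * cell + cell // 2 + rng.integers(-1, 2)
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        footprint = np.zeros(shape, dtype=bool)
        radii = {}
        for ch, spec in _RENDER_PARAMS[klass].items():
            if spec is None:
                radii[ch] = 0.0
                continue
            r_um, amp = spec
            r_px = r_um / pixel_size
            disc = dist2 <= r_px ** 2
            channels[ch][disc] += amp
            footprint |= disc
            radii[ch] = r_px
        truth_mask[footprint] = idx
        records.append({"object_id": idx, "class": klass, "row": cy, "col": cx, **{f"radius_{c}_px": radii[c] for c in ("dna", "ck", "cd45")}})

    truth = pd.DataFrame(records, columns=["object_id", "class", "row", "col",
                                           "radius_dna_px", "radius_ck_px", "radius_cd45_px"])
    return RenderedSample(channels=channels, pixel_size=pixel_size, truth_mask=truth_mask, truth=truth)


def simulate_two_arm(n: int, hr: float, lambda0: float = 0.05,
                     censoring: tuple[float, float] = (6.0, 40.0), seed: int = 0) -> pd.DataFrame:
    """Two-arm exponential survival cohort with a known hazard ratio.

    Used for power and parameter-recovery checks of the survival machinery.
    """
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 2, n)
    rate = lambda0 * hr ** arm
    t = rng.exponential(1.0 / rate)
    c = rng.uniform(*censoring, n)
    return pd.DataFrame({
        "patient_id": [f"S{i:05d}" for i in range(n)],
        "time": np.maximum(np.minimum(t, c), 1e-9),
        "event": (t <= c).astype(int),
        "arm": arm,
    })
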