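"""Configuration models for the CTC/tdEV analysis pipeline.

Every tunable of the pipeline lives in one of the pydantic models below so
that a single YAML/JSON file fully determines a run.  Validation is eager:
`validate_analysis_config` collects *all* schema problems at once instead of
failing on the first.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

TIMEPOINTS = ("baseline", "follow_up", "progression")

#: order of the feature columns shared by the generator and the image pipeline
EVENT_FEATURE_COLUMNS = [
    "event_id",
    "sample_id",
    "area_dna", "perimeter_dna", "eccentricity_dna",
    "mean_intensity_dna", "max_intensity_dna", "total_intensity_dna", "sd_intensity_dna",
    "area_ck", "perimeter_ck", "eccentricity_ck",
    "mean_intensity_ck", "max_intensity_ck", "total_intensity_ck", "sd_intensity_ck",
    "area_cd45", "perimeter_cd45", "eccentricity_cd45",
    "mean_intensity_cd45", "max_intensity_cd45", "total_intensity_cd45", "sd_intensity_cd45",
    "overlap_dna_ck",
    "centroid_x", "centroid_y",
]

#: 12-feature default used for phenotypic clustering (CD45 excluded: CTCs are
#: CD45-negative by gate, so those features carry no phenotype signal)
DEFAULT_PHENOTYPE_FEATURES = [
    "area_dna", "perimeter_dna", "eccentricity_dna",
    "mean_intensity_dna", "max_intensity_dna", "sd_intensity_dna",
    "area_ck", "perimeter_ck", "eccentricity_ck",
    "mean_intensity_ck", "max_intensity_ck", "sd_intensity_ck",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value or combination is invalid."""


class CountModel(BaseModel):
    """Zero-inflated negative-binomial CTC count model with patient frailty.

    A per-patient log-normal frailty multiplies the negative-binomial mean,
    which produces the extreme right skew seen in real cartridges (median of
    1 with a range into the thousands).  ``pi_zero`` is the probability that
    a patient sheds no detectable CTCs at all (structural zero).
    """

    pi_zero: float = Field(0.05, ge=0.0, le=1.0)
    mean: float = Field(1.7, ge=0.0)
    dispersion: float = Field(1.8, gt=0.0)
    patient_sigma: float = Field(1.35, ge=0.0)
    chemo_log_shift: float = Field(0.9, description="added to log-frailty of chemo-pretreated patients")
    timepoint_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"baseline": 1.0, "follow_up": 0.35, "progression": 1.4}
    )

    @field_validator("timepoint_multiplier")
    @classmethod
    def _nonneg_multipliers(cls, v: dict[str, float]) -> dict[str, float]:
        if any(m < 0 for m in v.values()):
            raise ValueError("timepoint multipliers must be nonnegative")
        return v


class TdevModel(BaseModel):
    """tdEV counts: CTC-linked log-normal multiplier plus an independent
    background component, reproducing the strong CTC-tdEV correlation and the
    ~16-fold count excess."""

    base_mean: float = Field(8.0, ge=0.0)
    log_ratio_mu: float = Field(2.1, description="log of the tdEV:CTC multiplier")
    log_ratio_sigma: float = Field(0.3, ge=0.0)
    dispersion: float = Field(3.0, gt=0.0)


class HazardModel(BaseModel):
    """Proportional-hazards generator: exponential baseline, log-hazard linear
    in (chemo pretreatment, PSA, baseline CTC count, baseline SI)."""

    lambda0_pfs: float = Field(0.055, gt=0.0, description="events/month for the reference patient")
    lambda0_os: float = Field(0.016, gt=0.0)
    coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "chemo_pretreated": 1.04,   # HR ~2.8 per pretreatment
            "psa": 0.0015,              # per ng/mL
            "log1p_ctc": 0.45,          # per unit log(1 + CTC/7.5 mL): burden acts on the log scale
            "si": 0.65,                 # per SI unit (nats)
        }
    )
    censoring_low: float = Field(6.0, ge=0.0, description="months; uniform censoring window")
    censoring_high: float = Field(40.0, gt=0.0)

    @model_validator(mode="after")
    def _window(self) -> "HazardModel":
        if self.censoring_high <= self.censoring_low:
            raise ValueError("censoring_high must exceed censoring_low")
        return self


class ScenarioConfig(BaseModel):
    """Full specification of a synthetic cohort scenario.

    Defaults emulate the published mCRPC cohort marginals: 170 patients with
    331 cartridges across baseline / 10-12-week follow-up / progression,
    ~69% baseline CTC positivity, median CTC 1 and median tdEV 16 per 7.5 mL,
    five phenotype clusters of unequal prevalence, and hazards increasing
    with chemo pretreatment, PSA, CTC count and diversity.
    """

    n_patients: int = Field(170, ge=0)
    timepoint_probs: dict[str, float] = Field(
        default_factory=lambda: {"baseline": 143 / 170, "follow_up": 114 / 170, "progression": 74 / 170}
    )
    ctc_counts: CountModel = Field(default_factory=CountModel)
    tdev_counts: TdevModel = Field(default_factory=TdevModel)
    cluster_prevalence: tuple[float, ...] = (0.16, 0.14, 0.53, 0.12, 0.05)
    cluster_concentration: Optional[float] = Field(
        5.0,
        gt=0.0,
        description="Dirichlet concentration within a patient's cluster support; None = every patient uses the global prevalence exactly",
    )
    support_size_probs: tuple[float, ...] = Field(
        (0.58, 0.20, 0.13, 0.06, 0.03),
        description="distribution of the number of phenotype clusters a patient's tumor actually sheds (1..k); many patients are monoclonal",
    )
    clonal_dominance: float = Field(
        1.2, ge=0.0,
        description="coupling between CTC burden and clonal dominance: high-burden patients get sharper (lower-entropy) compositions, keeping SI nearly independent of count",
    )
    followup_sharpening: float = Field(2.2, gt=0.0, description="composition exponent at follow-up (>1 lowers diversity)")
    progression_sharpening: float = Field(0.85, gt=0.0)
    chemo_flattening: float = Field(0.7, gt=0.0, le=1.0, description="prevalence exponent for chemo-pretreated patients (<1 raises diversity)")
    leukocytes_per_cartridge: float = Field(150.0, ge=0.0)
    debris_per_cartridge: float = Field(30.0, ge=0.0)
    chemo_pretreated_prob: float = Field(0.38, ge=0.0, le=1.0)
    prior_arsi_prob: float = Field(0.14, ge=0.0, le=1.0)
    visceral_prob: float = Field(0.22, ge=0.0, le=1.0)
    manual_count_log_sd: float = Field(0.15, ge=0.0)
    cluster_separation: float = Field(1.0, gt=0.0, description="scales cluster mean offsets from the typical phenotype")
    hazard: HazardModel = Field(default_factory=HazardModel)
    seed: int = Field(0, ge=0)

    @field_validator("cluster_prevalence", "support_size_probs")
    @classmethod
    def _prob_vector(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(p < 0 for p in v):
            raise ValueError("probability vector entries must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-12:
            raise ValueError(f"probability vector must sum to 1 (got {sum(v)!r})")
        return v

    @field_validator("timepoint_probs")
    @classmethod
    def _tp_probs(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if name not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"timepoint probability {name}={p} outside [0,1]")
        return v


class GatingConfig(BaseModel):
    """Thresholds used to partition events into CTC / tdEV / other.

    The numeric defaults are documented approximations of the previously
    established open-source gates for CellSearch data (the exact values live
    in that tool's supplementary material); every threshold is overridable.
    The prognostic cuts (>=5 CTC, >=105 tdEV per 7.5 mL) are the validated
    dichotomization points.
    """

    ck_mean_min: float = Field(30.0, ge=0.0)
    dna_total_min_ctc: float = Field(2000.0, ge=0.0)
    dna_total_max_tdev: float = Field(500.0, ge=0.0)
    cd45_mean_max: float = Field(40.0, ge=0.0)
    ctc_area_min: float = Field(16.0, ge=0.0, description="um^2, ~4 um diameter")
    tdev_area_max: float = Field(16.0, ge=0.0)
    overlap_min_ctc: float = Field(0.5, ge=0.0, le=1.0)
    ctc_unfavorable_cut: int = Field(5, gt=0)
    tdev_unfavorable_cut: int = Field(105, gt=0)
    stable_band: float = Field(
        0.0, ge=0.0,
        description="relative band for calling CTC dynamics 'stable'; 0 = exact count equality",
    )

    @model_validator(mode="after")
    def _unambiguous(self) -> "GatingConfig":
        if self.dna_total_max_tdev >= self.dna_total_min_ctc:
            raise ValueError(
                "dna_total_max_tdev must be < dna_total_min_ctc, otherwise an object "
                "could satisfy both the CTC and the tdEV gate (ambiguous gating)"
            )
        return self


class PhenotypingConfig(BaseModel):
    k: int = Field(5, ge=1)
    n_restarts: int = Field(10, ge=1)
    features: list[str] = Field(default_factory=lambda: list(DEFAULT_PHENOTYPE_FEATURES))
    seed: int = Field(0, ge=0)


class DiversityConfig(BaseModel):
    si_cut: float = Field(0.68, ge=0.0)
    log_base: Optional[float] = Field(None, description="None = natural log (nats)")

    @field_validator("log_base")
    @classmethod
    def _base(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and (v <= 0 or v == 1.0):
            raise ValueError("log_base must be positive and != 1")
        return v


class SurvivalConfig(BaseModel):
    endpoints: list[str] = Field(default_factory=lambda: ["pfs", "os"])
    candidate_covariates: list[str] = Field(
        default_factory=lambda: [
            "age", "chemo_pretreated", "prior_arsi_yes", "visceral_metastases",
            "psa", "ldh", "n_ctc", "si",
        ]
    )
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    ties_method: Literal["efron", "breslow"] = "efron"


class AnalysisConfig(BaseModel):
    """Top-level pipeline configuration: exactly one input mode."""

    mode: Literal["simulate", "feature_table", "images"] = "simulate"
    events_path: Optional[Path] = None
    samples_path: Optional[Path] = None
    patients_path: Optional[Path] = None
    images_dir: Optional[Path] = None
    outdir: Path = Path("results/run")
    seed: int = Field(1, ge=0)
    make_figures: bool = True
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    gating: GatingConfig = Field(default_factory=GatingConfig)
    phenotyping: PhenotypingConfig = Field(default_factory=PhenotypingConfig)
    diversity: DiversityConfig = Field(default_factory=DiversityConfig)
    survival: SurvivalConfig = Field(default_factory=SurvivalConfig)

    @model_validator(mode="after")
    def _mode_paths(self) -> "AnalysisConfig":
        if self.mode == "feature_table":
            missing = [n for n in ("events_path", "samples_path", "patients_path") if getattr(self, n) is None]
            if missing:
                raise ValueError(f"feature_table mode requires {', '.join(missing)}")
        if self.mode == "images":
            missing = [n for n in ("images_dir", "samples_path", "patients_path") if getattr(self, n) is None]
            if missing:
                raise ValueError(f"images mode requires {', '.join(missing)}")
        return self


def config_hash(cfg: BaseModel) -> str:
    """Stable SHA-256 of a config's JSON representation (reproducibility record)."""
    payload = json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Parse + validate a YAML/JSON config file.

    Raises :class:`ConfigurationError` with *every* field error listed, each
    prefixed by its dotted field path.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return AnalysisConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigurationError("invalid configuration:\n  " + "\n  ".join(lines)) from exc
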