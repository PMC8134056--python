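"""Time-to-event machinery: Kaplan-Meier, log-rank, Cox regression, Harrell's C.

Thin, opinionated wrappers around lifelines (product-limit estimation,
log-rank test), statsmodels' ``PHReg`` (Cox partial likelihood with Efron or
Breslow tie handling and Wald inference) and scikit-survival (Harrell's
concordance).  Conventions follow the published analysis: months as the time
unit, 95% CIs with multiplier 1.959964, two-sided normal Wald p-values, and
a Kaplan-Meier median reported as the smallest t with S(t) <= 0.5 or the
literal string "not reached".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import concordance_index_censored
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve", "CoxResult", "LogrankResult",
    "km_estimate", "logrank", "cox_fit", "select_multivariable",
    "concordance_index", "baseline_covariate_table",
]

Z95 = 1.959964

NOT_REACHED = "not reached"


@dataclass
class KMCurve:
    """Product-limit estimate: one row per distinct event time."""

    table: pd.DataFrame          # columns: time, n_at_risk, n_events, survival
    median: float | None         # None <-> "not reached"
    n: int
    n_events: int

    @property
    def median_label(self) -> str:
        return NOT_REACHED if self.median is None else f"{self.median:g}"

    def survival_at(self, t: float) -> float:
        tab = self.table
        past = tab[tab["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-covariate Wald summary plus fit diagnostics."""

    table: pd.DataFrame          # covariate, coef, hr, ci_low, ci_high, z, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    ties_method: str

    def hr(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "p"])


def _validate_times(time: np.ndarray) -> None:
    if (time <= 0).any() or not np.isfinite(time).all():
        raise ValueError("survival times must be finite and strictly positive")


def km_estimate(records: pd.DataFrame, time_col: str = "time",
                event_col: str = "event") -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Ties between events and censorings at the same time are resolved by the
    standard convention: events happen first (censored subjects at t remain
    in the risk set for the event at t).  Median = smallest event time with
    S(t) <= 0.5, or "not reached" (None).
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    time = records[time_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)
    _validate_times(time)

    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    mask = et["observed"] > 0
    table = pd.DataFrame({
        "time": et.index[mask].to_numpy(dtype=float),
        "n_at_risk": et.loc[mask, "at_risk"].to_numpy(dtype=int),
        "n_events": et.loc[mask, "observed"].to_numpy(dtype=int),
        "survival": surv[mask].to_numpy(dtype=float),
    }).reset_index(drop=True)

    median: float | None = None
    # tolerance guards the S(t) == 0.5 boundary against float rounding
    below = table[table["survival"] <= 0.5 + 1e-9]
    if not below.empty:
        median = float(below["time"].iloc[0])
    return KMCurve(table=table, median=median, n=len(records), n_events=int(event.sum()))


def logrank(records: pd.DataFrame, group_col: str, time_col: str = "time",
            event_col: str = "event") -> LogrankResult:
    """Standard (O-E) chi-square log-rank test across >= 2 groups."""
    groups = records[group_col].unique()
    if len(groups) < 2:
        raise ValueError(f"log-rank needs >= 2 groups, got {len(groups)}")
    if records[event_col].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    _validate_times(records[time_col].to_numpy(dtype=float))
    res = multivariate_logrank_test(records[time_col], records[group_col],
                                    records[event_col])
    return LogrankResult(statistic=float(res.test_statistic),
                         df=int(len(groups) - 1), p_value=float(res.p_value))


def cox_fit(records: pd.DataFrame, covariates: list[str], time_col: str = "time",
            event_col: str = "event", ties_method: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit with Wald inference.

    Efron tie handling by default (Breslow available).  Raises on constant
    covariates and on more covariates than events; monotone-likelihood /
    non-converged fits are returned with ``converged=False`` rather than
    silently reported.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValueError(f"unknown ties_method {ties_method!r}")
    data = records[[time_col, event_col, *covariates]].dropna()
    time = data[time_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=int)
    _validate_times(time)
    n_events = int(event.sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events cannot support {len(covariates)} covariates")
    x = data[covariates].to_numpy(dtype=float)
    const = [c for c, s in zip(covariates, x.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"constant covariate(s): {', '.join(const)}")

    model = PHReg(time, x, status=event, ties=ties_method)
    import warnings
    with warnings.catch_warnings():
        # the converged flag below reports optimizer trouble; the raw
        # statsmodels warning would only duplicate it noisily
        warnings.simplefilter("ignore")
        fit = model.fit(disp=False)
    beta = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    converged = bool(np.isfinite(beta).all() and np.isfinite(se).all()
                     and (np.abs(beta) < 50).all() and (se < 1e3).all())
    if not converged:
        logger.warning("Cox fit flagged non-converged (monotone likelihood or separation)")
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    from scipy.stats import norm
    p = 2 * norm.sf(np.abs(z))
    table = pd.DataFrame({
        "covariate": covariates,
        "coef": beta,
        "hr": np.exp(beta),
        "ci_low": np.exp(beta - Z95 * se),
        "ci_high": np.exp(beta + Z95 * se),
        "z": z,
        "p": p,
    })
    return CoxResult(table=table, log_likelihood=float(model.loglike(beta)),
                     converged=converged, n=len(data), n_events=n_events,
                     ties_method=ties_method)


def select_multivariable(uv_results: dict[str, CoxResult], alpha: float = 0.05) -> list[str]:
    """Covariates with univariable Wald p < alpha enter the multivariable model.

    ``uv_results`` maps covariate name -> its single-covariate fit.  An empty
    selection is returned with a warning (callers then report UV only).
    """
    selected = [cov for cov, res in uv_results.items() if res.p(cov) < alpha]
    if not selected:
        logger.warning("no covariate reached UV p < %g; multivariable model skipped", alpha)
    return selected


def concordance_index(risk_scores, records: pd.DataFrame, time_col: str = "time",
                      event_col: str = "event") -> float:
    """Harrell's C: higher risk score should mean earlier event.

    Tied risk scores count 1/2; pairs that cannot be ordered (the shorter
    time censored, or tied event times) are unusable.  Returns NaN (logged)
    when no usable pair exists.
    """
    scores = np.asarray(risk_scores, dtype=float)
    if len(scores) != len(records):
        raise ValueError("risk scores must align with records")
    event = records[event_col].to_numpy(dtype=bool)
    time = records[time_col].to_numpy(dtype=float)
    try:
        c, *_ = concordance_index_censored(event, time, scores)
    except Exception as exc:  # no comparable pairs
        logger.warning("concordance undefined: %s", exc)
        return float("nan")
    return float(c)


def baseline_covariate_table(patients: pd.DataFrame, sample_counts: pd.DataFrame,
                             diversity: pd.DataFrame | None = None) -> pd.DataFrame:
    """Patient-level baseline analysis table.

    Joins clinical covariates with the baseline cartridge's CTC/tdEV counts
    and (optionally) its Shannon index, recoding categorical covariates to
    0/1 indicators (pretreated=1, prior ARSi yes=1, visceral=1).  Patients
    without a baseline sample are dropped.
    """
    base = sample_counts[sample_counts["timepoint"] == "baseline"]
    cols = ["sample_id", "patient_id", "n_ctc", "n_tdev", "ctc_group", "tdev_group"]
    merged = patients.merge(base[cols], on="patient_id", how="inner")
    merged["chemo_pretreated"] = (merged["chemo_status"] == "pretreated").astype(int)
    merged["prior_arsi_yes"] = (merged["prior_arsi"] == "yes").astype(int)
    merged["visceral_metastases"] = (merged["metastases"] == "visceral").astype(int)
    if diversity is not None:
        merged = merged.merge(diversity[["sample_id", "si", "si_group"]], on="sample_id",
                              how="left")
    return merged
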