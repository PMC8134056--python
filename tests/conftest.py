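import numpy as np
import pandas as pd
import pytest

from ctcpheno.config import GatingConfig, ScenarioConfig
from ctcpheno.gating import classify_events, enumerate_samples
from ctcpheno.simulate import generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full paper-marginal scenario, seed 1 (the shipped study conditions)."""
    return generate_cohort(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def default_counts(default_cohort):
    classified = classify_events(default_cohort.events, GatingConfig())
    counts = enumerate_samples(classified, default_cohort.samples, GatingConfig())
    return classified, counts


def light_scenario(seed: int, **overrides) -> ScenarioConfig:
    """Small, fast scenario for replicate simulations: no background objects
    (leukocytes/debris do not matter for count/diversity properties)."""
    defaults = dict(n_patients=50, leukocytes_per_cartridge=0.0,
                    debris_per_cartridge=0.0, seed=seed)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def truth_sample_counts(cohort) -> pd.DataFrame:
    """Per-sample true CTC/tdEV counts (generator truth, no gating)."""
    t = cohort.truth.objects
    if len(t):
        g = t.groupby(["sample_id", "true_class"]).size().unstack(fill_value=0)
    else:
        g = pd.DataFrame()
    g = g.reindex(cohort.samples["sample_id"], fill_value=0).fillna(0)
    out = cohort.samples[["sample_id", "patient_id", "timepoint"]].copy()
    out["n_ctc"] = g["CTC"].to_numpy() if "CTC" in g else 0
    out["n_tdev"] = g["tdEV"].to_numpy() if "tdEV" in g else 0
    return out
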