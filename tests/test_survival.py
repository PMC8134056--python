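"""Survival machinery vs hand-rolled oracles: product-limit, risk-set
log-rank accumulation, explicit Cox partial likelihood, pairwise concordance."""

import numpy as np
import pandas as pd
import pytest

from ctcpheno.survival import (NOT_REACHED, baseline_covariate_table, concordance_index,
                               cox_fit, km_estimate, logrank, select_multivariable)
from ctcpheno.simulate import simulate_two_arm


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def km_oracle(time, event):
    """Brute-force product-limit: S at each distinct event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n_at_risk = int((time >= t).sum())          # censored at t still at risk
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out.append((t, n_at_risk, d, s))
    return out


def logrank_oracle_2group(time, event, group):
    """Hand risk-set accumulation of the two-group O-E chi-square."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e ** 2) / var if var > 0 else 0.0


def partial_loglik_no_ties(beta, time, event, x):
    """Explicit Cox partial log-likelihood (valid for untied event times)."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def harrell_oracle(scores, time, event):
    """Exhaustive pair enumeration; ties in score count 1/2."""
    conc = disc = ties = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable: i has the (strictly) earlier observed event
            if event[i] and time[i] < time[j]:
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] < scores[j]:
                    disc += 1
                else:
                    ties += 1
    total = conc + disc + ties
    return (conc + 0.5 * ties) / total if total else float("nan")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_worked_example():
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
    curve = km_estimate(rec)
    assert curve.survival_at(1.0) == pytest.approx(2 / 3)
    assert curve.survival_at(2.0) == pytest.approx(1 / 3)
    assert curve.median == 2.0
    assert curve.median_label == "2"


def test_km_all_censored_never_reaches_median():
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
    curve = km_estimate(rec)
    assert curve.survival_at(10.0) == 1.0
    assert curve.median is None
    assert curve.median_label == NOT_REACHED


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValueError):
        km_estimate(pd.DataFrame({"time": [0.0, 1.0], "event": [1, 1]}))
    with pytest.raises(ValueError):
        km_estimate(pd.DataFrame({"time": [], "event": []}))


def test_km_matches_brute_force_product_limit(rng):
    """Exact agreement with the hand product-limit on 1,000 random small
    instances with ties and censoring."""
    for _ in range(1000):
        n = int(rng.integers(1, 9))
        time = rng.integers(1, 6, n).astype(float)   # integer times force ties
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            continue
        curve = km_estimate(pd.DataFrame({"time": time, "event": event}))
        oracle = km_oracle(time, event)
        assert len(curve.table) == len(oracle)
        for row, (t, n_r, d, s) in zip(curve.table.itertuples(index=False), oracle):
            assert row.time == t and row.n_at_risk == n_r and row.n_events == d
            assert row.survival == pytest.approx(s, abs=1e-12)
        med_oracle = next((t for t, _, _, s in oracle if s <= 0.5 + 1e-9), None)
        assert curve.median == med_oracle


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_statistic_zero():
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0] * 2, "event": [1, 1, 0] * 2,
                        "grp": [0, 0, 0, 1, 1, 1]})
    res = logrank(rec, "grp")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_logrank_requires_two_groups_and_events():
    with pytest.raises(ValueError):
        logrank(pd.DataFrame({"time": [1.0], "event": [1], "grp": [0]}), "grp")
    with pytest.raises(ValueError):
        logrank(pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "grp": [0, 1]}), "grp")


def test_logrank_matches_manual_risk_set_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(2, 7))
        time = rng.uniform(0.5, 10, n)
        event = rng.integers(0, 2, n)
        group = rng.integers(0, 2, n)
        if event.sum() == 0 or len(set(group)) < 2:
            continue
        rec = pd.DataFrame({"time": time, "event": event, "grp": group})
        assert logrank(rec, "grp").statistic == pytest.approx(
            logrank_oracle_2group(time, event, group), abs=1e-8)


def test_logrank_power_under_designed_hazard_ratio():
    """HR 2.5 two-arm cohorts of n=200: detected (p < 0.05) in >= 80/100."""
    hits = sum(
        logrank(simulate_two_arm(200, hr=2.5, seed=seed), "arm").p_value < 0.05
        for seed in range(100))
    assert hits >= 80


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_cox_toy_matches_grid_search_oracle():
    """4 subjects, untied event times: beta-hat equals the grid maximizer of
    the explicit partial likelihood to 1e-4."""
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 1, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0])  # interleaved: finite partial-likelihood maximum
    grid = np.arange(-10.0, 10.0001, 1e-4)
    risk = [time >= t for t in time]
    ll = np.zeros_like(grid)
    for i in range(4):
        ll += x[i] * grid - np.log(np.exp(np.outer(grid, x[risk[i]])).sum(axis=1))
    beta_oracle = grid[np.argmax(ll)]
    rec = pd.DataFrame({"time": time, "event": event, "x": x})
    fit = cox_fit(rec, ["x"])
    assert fit.table["coef"].iloc[0] == pytest.approx(beta_oracle, abs=1e-4)


def test_cox_flags_monotone_likelihood():
    """Perfect separation (all x=1 subjects fail first) has no finite MLE;
    the fit is flagged rather than silently reported."""
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
                        "x": [1.0, 1.0, 0.0, 0.0]})
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cox_fit(rec, ["x"])
    assert not fit.converged


def test_cox_null_covariate_ci_contains_one():
    df = simulate_two_arm(200, hr=1.0, seed=11)
    fit = cox_fit(df, ["arm"])
    row = fit.table.iloc[0]
    assert abs(row["coef"]) < 0.5
    assert row["ci_low"] < 1.0 < row["ci_high"]
    assert row["ci_low"] < row["hr"] < row["ci_high"]


def test_cox_validation_errors():
    df = simulate_two_arm(50, hr=1.0, seed=0)
    with pytest.raises(ValueError, match="constant"):
        cox_fit(df.assign(flat=1.0), ["flat"])
    tiny = df.head(3).assign(event=[1, 0, 0])
    with pytest.raises(ValueError, match="events"):
        cox_fit(tiny, ["arm", "time"])
    with pytest.raises(ValueError, match="ties_method"):
        cox_fit(df, ["arm"], ties_method="exact")


def test_cox_loglik_at_optimum_beats_null_and_score_vanishes():
    rng = np.random.default_rng(2)
    n = 60
    x = rng.normal(0, 1, n)
    time = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x)))
    rec = pd.DataFrame({"time": time, "event": np.ones(n, dtype=int), "x": x})
    fit = cox_fit(rec, ["x"])
    beta = fit.table["coef"].iloc[0]
    ll = lambda b: partial_loglik_no_ties(b, time, rec["event"].to_numpy(), x)
    assert ll(beta) >= ll(0.0)
    eps = 1e-5
    score = (ll(beta + eps) - ll(beta - eps)) / (2 * eps)
    assert abs(score) < 1e-4
    assert fit.log_likelihood == pytest.approx(ll(beta), rel=1e-9)


def test_cox_efron_vs_breslow_differ_only_with_ties():
    df = simulate_two_arm(100, hr=2.0, seed=5)
    b_e = cox_fit(df, ["arm"], ties_method="efron").table["coef"].iloc[0]
    b_b = cox_fit(df, ["arm"], ties_method="breslow").table["coef"].iloc[0]
    assert b_e == pytest.approx(b_b, abs=1e-8)  # continuous times: no ties
    tied = df.assign(time=np.ceil(df["time"]))
    b_e = cox_fit(tied, ["arm"], ties_method="efron").table["coef"].iloc[0]
    b_b = cox_fit(tied, ["arm"], ties_method="breslow").table["coef"].iloc[0]
    assert b_e != b_b


def test_cox_recovers_generator_hazard_ratio():
    df = simulate_two_arm(1000, hr=2.0, seed=3)
    fit = cox_fit(df, ["arm"])
    assert 1.8 <= fit.table["hr"].iloc[0] <= 2.2


# ---------------------------------------------------------------------------
# covariate selection
# ---------------------------------------------------------------------------

def _mock_uv(pmap):
    out = {}
    for cov, p in pmap.items():
        table = pd.DataFrame({"covariate": [cov], "coef": [0.1], "hr": [1.1],
                              "ci_low": [0.9], "ci_high": [1.3], "z": [1.0], "p": [p]})
        from ctcpheno.survival import CoxResult
        out[cov] = CoxResult(table=table, log_likelihood=0.0, converged=True,
                             n=100, n_events=50, ties_method="efron")
    return out


def test_uv_selection_follows_alpha():
    uv = _mock_uv({"age": 0.159, "chemo_pretreated": 1e-5, "prior_arsi_yes": 0.045})
    assert select_multivariable(uv, alpha=0.05) == ["chemo_pretreated", "prior_arsi_yes"]
    assert select_multivariable(uv, alpha=1.0) == list(uv)


def test_uv_selection_empty_warns(caplog):
    uv = _mock_uv({"age": 0.9, "psa": 0.8})
    with caplog.at_level("WARNING"):
        assert select_multivariable(uv, alpha=0.05) == []
    assert any("multivariable" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_perfect_ordering():
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]})
    assert concordance_index([4.0, 3.0, 2.0, 1.0], rec) == 1.0


def test_concordance_all_tied_scores():
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
    assert concordance_index([1.0, 1.0, 1.0], rec) == 0.5


def test_concordance_no_usable_pairs_is_nan():
    rec = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
    assert np.isnan(concordance_index([1.0, 2.0], rec))


def test_concordance_matches_pair_enumeration_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(2, 9))
        time = rng.uniform(0.1, 10, n)   # continuous: no tied times
        event = rng.integers(0, 2, n)
        scores = rng.choice([0.0, 1.0, 2.0], n)  # discrete scores force score ties
        rec = pd.DataFrame({"time": time, "event": event})
        oracle = harrell_oracle(scores, time, event)
        got = concordance_index(scores, rec)
        if np.isnan(oracle):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# cohort-level integration
# ---------------------------------------------------------------------------

def test_dichotomized_ctc_strata_separate_survival(default_cohort, default_counts):
    """Patients with >= 5 baseline CTCs have elevated hazard: HR > 1 with a
    95% CI excluding 1, and a significant log-rank test."""
    _, counts = default_counts
    base = baseline_covariate_table(default_cohort.patients, counts)
    base = base.assign(unfavorable=(base["ctc_group"] == "unfavorable").astype(int))
    for endpoint in ("pfs", "os"):
        fit = cox_fit(base, ["unfavorable"], f"{endpoint}_time", f"{endpoint}_event")
        row = fit.table.iloc[0]
        assert row["hr"] > 1.0 and row["ci_low"] > 1.0
        lr = logrank(base, "unfavorable", f"{endpoint}_time", f"{endpoint}_event")
        assert lr.p_value < 0.05


def test_baseline_table_recodes_covariates(default_cohort, default_counts):
    _, counts = default_counts
    base = baseline_covariate_table(default_cohort.patients, counts)
    assert set(base["chemo_pretreated"].unique()) <= {0, 1}
    assert len(base) == (counts["timepoint"] == "baseline").sum()
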