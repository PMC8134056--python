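"""Standardization, k-means partitioning, centroid diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_score

from ctcpheno.config import CountModel, DEFAULT_PHENOTYPE_FEATURES
from ctcpheno.gating import classify_events
from ctcpheno.phenotyping import (ClusterModel, FeatureMismatchError, assign,
                                  cluster_presence, compare_centroid_distances,
                                  fit_kmeans, standardize)
from ctcpheno.simulate import generate_cohort

from conftest import light_scenario


def test_standardize_population_sd_convention():
    model, z = standardize(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
    expected = np.array([-1.224744871391589, 0.0, 1.224744871391589])  # sd = sqrt(2/3)
    assert np.allclose(z[:, 0], expected, atol=1e-12)
    assert model.scales[0] == pytest.approx(np.sqrt(2 / 3), rel=1e-12)


def test_standardize_idempotent():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": rng.normal(5, 2, 100), "b": rng.normal(-1, 0.5, 100)})
    _, z1 = standardize(df)
    _, z2 = standardize(pd.DataFrame(z1, columns=["a", "b"]))
    assert np.allclose(z1, z2, atol=1e-9)
    assert abs(z1.mean(axis=0)).max() < 1e-9
    assert abs(z1.std(axis=0) - 1).max() < 1e-9


def test_standardize_drops_constant_column_with_warning(caplog):
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
    with caplog.at_level("WARNING"):
        model, z = standardize(df)
    assert model.feature_names == ["a"] and z.shape == (3, 1)
    assert any("flat" in r.message for r in caplog.records)


def test_standardize_all_constant_errors():
    with pytest.raises(ValueError, match="zero-variance"):
        standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


def test_n_equals_k_points_get_own_clusters():
    pts = pd.DataFrame({"x": [0.0, 10.0, 20.0], "y": [0.0, 10.0, 20.0]})
    scaling, z = standardize(pts)
    model = fit_kmeans(z, scaling, k=3, seed=0)
    assert model.inertia == pytest.approx(0.0, abs=1e-12)
    labels = assign(model, z)["cluster"]
    assert labels.nunique() == 3


def test_fewer_points_than_k_errors():
    pts = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]})
    scaling, z = standardize(pts)
    with pytest.raises(ValueError):
        fit_kmeans(z, scaling, k=5, seed=0)


def test_three_well_separated_blobs_fully_recovered():
    rng = np.random.default_rng(3)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    labels_true = np.repeat([0, 1, 2], 100)
    x = centers[labels_true] + rng.normal(0, 1.0, (300, 2))
    scaling, z = standardize(pd.DataFrame(x, columns=["a", "b"]))
    model = fit_kmeans(z, scaling, k=3, seed=0)
    pred = assign(model, z)["cluster"]
    assert adjusted_rand_score(labels_true, pred) == 1.0


def test_default_synthetic_ctc_set_yields_five_nonempty_clusters(default_cohort):
    classified = classify_events(default_cohort.events)
    ctcs = classified[classified["event_class"] == "ctc"]
    scaling, z = standardize(ctcs, DEFAULT_PHENOTYPE_FEATURES)
    model = fit_kmeans(z, scaling, k=5, seed=0)
    labels = assign(model, z)["cluster"]
    assert labels.nunique() == 5


def test_final_centroids_are_cluster_means(default_cohort):
    """Lloyd fixed point: every centroid equals the mean of its points."""
    classified = classify_events(default_cohort.events)
    ctcs = classified[classified["event_class"] == "ctc"]
    scaling, z = standardize(ctcs, DEFAULT_PHENOTYPE_FEATURES)
    model = fit_kmeans(z, scaling, k=5, seed=0)
    labels = assign(model, z)["cluster"].to_numpy()
    for c in range(1, 6):
        residual = np.linalg.norm(model.centroids[c - 1] - z[labels == c].mean(axis=0))
        assert residual < 1e-6


def test_assign_exact_centroid_distance_zero():
    scaling, z = standardize(pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]}))
    model = fit_kmeans(z, scaling, k=2, seed=0)
    out = assign(model, model.centroids)
    assert np.allclose(out["distance_to_centroid"], 0.0, atol=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_assigned_distance_is_minimal(seed):
    rng = np.random.default_rng(seed)
    cents = rng.normal(0, 3, (4, 3))
    pts = rng.normal(0, 3, (12, 3))
    model = ClusterModel(k=4, centroids=cents, inertia=0.0, seed=0,
                         scaling=None)  # scaling unused by assign
    out = assign(model, pts)
    d_all = np.linalg.norm(pts[:, None, :] - cents[None], axis=2)
    assert np.allclose(out["distance_to_centroid"], d_all.min(axis=1), atol=1e-12)


def test_assign_matches_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    cents = rng.normal(0, 1, (2, 2))
    pts = rng.normal(0, 1, (8, 2))
    model = ClusterModel(k=2, centroids=cents, inertia=0.0, seed=0, scaling=None)
    got = assign(model, pts)["cluster"].to_numpy()
    # brute force, lowest index wins ties
    want = []
    for p in pts:
        best, best_d = 1, np.inf
        for j, c in enumerate(cents, start=1):
            d = float(np.sqrt(((p - c) ** 2).sum()))
            if d < best_d:
                best, best_d = j, d
        want.append(best)
    assert list(got) == want


def test_assign_feature_mismatch_errors():
    model = ClusterModel(k=2, centroids=np.zeros((2, 3)), inertia=0.0, seed=0,
                         scaling=None)
    with pytest.raises(FeatureMismatchError):
        assign(model, np.zeros((4, 2)))


def test_model_json_roundtrip(tmp_path):
    scaling, z = standardize(pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0],
                                           "y": [0.0, 2.0, -3.0, 4.0]}))
    model = fit_kmeans(z, scaling, k=2, seed=3, n_restarts=4)
    path = tmp_path / "model.json"
    model.save(path)
    back = ClusterModel.load(path)
    assert np.allclose(back.centroids, model.centroids)
    assert back.feature_names == model.feature_names
    assert back.seed == 3 and back.n_restarts == 4


def test_parameter_recovery_on_separable_scenario():
    """On well-separated generator clusters (silhouette > 0.5), k-means
    recovers the true cluster labels (ARI > 0.95) across seeds."""
    aris = []
    for seed in range(20):
        cfg = light_scenario(
            seed=seed, n_patients=25, cluster_separation=2.5,
            cluster_concentration=None,  # all clusters well represented
            ctc_counts=CountModel(pi_zero=0.0, mean=30.0, dispersion=10.0,
                                  patient_sigma=0.3))
        co = generate_cohort(cfg)
        classified = classify_events(co.events)
        ctcs = classified[classified["event_class"] == "ctc"]
        truth = co.truth.objects.set_index("event_id").loc[ctcs["event_id"], "true_cluster"]
        scaling, z = standardize(ctcs, DEFAULT_PHENOTYPE_FEATURES)
        model = fit_kmeans(z, scaling, k=5, seed=0)
        pred = assign(model, z)["cluster"]
        if silhouette_score(z, truth.to_numpy()) > 0.5:
            aris.append(adjusted_rand_score(truth, pred))
    assert len(aris) == 20  # separation 2.5 keeps every seed separable
    assert min(aris) > 0.95


def test_centroid_distance_identical_groups_not_significant():
    dist = [1.0, 1.5, 2.0, 2.5, 3.0] * 4
    assignments = pd.DataFrame({
        "event_id": [f"e{i}" for i in range(20)],
        "sample_id": ["lo"] * 10 + ["hi"] * 10,
        "cluster": 1,
        "distance_to_centroid": dist[:10] + dist[:10],
    })
    counts = pd.DataFrame({"sample_id": ["lo", "hi"], "n_ctc": [2, 50]})
    res = compare_centroid_distances(assignments, counts, count_split=10)
    assert res["p_value"] > 0.99


def test_centroid_distance_u_statistic_by_pair_counting():
    assignments = pd.DataFrame({
        "event_id": list("abcdef"),
        "sample_id": ["lo"] * 3 + ["hi"] * 3,
        "cluster": 1,
        "distance_to_centroid": [1.0, 2.0, 3.0, 101.0, 102.0, 103.0],
    })
    counts = pd.DataFrame({"sample_id": ["lo", "hi"], "n_ctc": [1, 100]})
    res = compare_centroid_distances(assignments, counts, count_split=10)
    assert res["u_statistic"] == 0.0  # all 9 pairs ordered low < high


def test_centroid_distance_null_rarely_significant(rng):
    """When distances are independent of sample counts, the test stays
    non-significant in >= 90% of replicates."""
    hits = 0
    reps = 100
    for rep in range(reps):
        r = np.random.default_rng(rep)
        n_samples = 40
        counts = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n_samples)],
                               "n_ctc": r.integers(1, 100, n_samples)})
        per = r.integers(1, 6, n_samples)
        assignments = pd.DataFrame({
            "event_id": np.arange(per.sum()).astype(str),
            "sample_id": np.repeat(counts["sample_id"], per),
            "cluster": 1,
            "distance_to_centroid": r.normal(2.0, 0.5, per.sum()),
        })
        if compare_centroid_distances(assignments, counts)["p_value"] <= 0.05:
            hits += 1
    assert reps - hits >= 90


def test_empty_group_raises():
    assignments = pd.DataFrame({"event_id": ["a"], "sample_id": ["s"],
                                "cluster": [1], "distance_to_centroid": [1.0]})
    counts = pd.DataFrame({"sample_id": ["s"], "n_ctc": [5]})
    with pytest.raises(ValueError, match="empty group"):
        compare_centroid_distances(assignments, counts, count_split=100)


def test_cluster_presence_counts_and_fractions():
    samples = pd.DataFrame({"sample_id": ["s1", "s2"]})
    assignments = pd.DataFrame({"event_id": ["a", "b", "c"], "sample_id": ["s1"] * 3,
                                "cluster": [3, 3, 1], "distance_to_centroid": 0.0})
    out = cluster_presence(assignments, samples, k=5).set_index("sample_id")
    s1 = out.loc["s1"]
    assert s1["frac_cluster_1"] == pytest.approx(1 / 3)
    assert s1["frac_cluster_3"] == pytest.approx(2 / 3)
    assert bool(s1["present_cluster_1"]) and bool(s1["present_cluster_3"])
    assert not bool(s1["present_cluster_2"])
    s2 = out.loc["s2"]
    assert s2["n_ctc"] == 0
    assert np.isnan(s2["frac_cluster_1"])
    assert not any(s2[f"present_cluster_{j}"] for j in range(1, 6))
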