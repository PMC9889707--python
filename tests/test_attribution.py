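"""Attribution mechanics: broadcasting, the k sweep, explained-variance
selection and z-threshold classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import carstim as cs
from carstim.attribution import (
    AttributionConfig,
    ClusterModel,
    argmax_k,
    classify_clusters,
    cluster_explained_variance,
    kmeans_sweep,
    standardize_events,
)
from carstim.panel import DEFAULT_MARKERS


def _toy_samples(values=(20.0, 80.0), n_events=10):
    mats = []
    for i, _ in enumerate(values):
        data = pd.DataFrame(
            np.full((n_events, len(DEFAULT_MARKERS)), 1000.0),
            columns=list(DEFAULT_MARKERS),
        )
        mats.append(cs.SingleCellMatrix(sample_id=f"p{i}", data=data))
    return mats, {f"p{i}": v for i, v in enumerate(values)}


class TestAssignment:
    def test_broadcasts_product_value_onto_each_event(self):
        mats, cyto = _toy_samples()
        pool = cs.assign_cell_cytotoxicity(mats, cyto, compartment="none")
        assert len(pool) == 20
        assert (pool.loc[pool.sample_id == "p0", "cytotoxicity"] == 20.0).all()
        assert (pool.loc[pool.sample_id == "p1", "cytotoxicity"] == 80.0).all()

    def test_missing_product_value_rejected(self):
        mats, cyto = _toy_samples()
        del cyto["p1"]
        with pytest.raises(KeyError, match="p1"):
            cs.assign_cell_cytotoxicity(mats, cyto, compartment="none")

    def test_single_product_shares_one_value(self):
        mats, cyto = _toy_samples(values=(42.0,))
        pool = cs.assign_cell_cytotoxicity(mats, cyto, compartment="none")
        assert pool["cytotoxicity"].nunique() == 1

    def test_compartment_filter_composes_with_gating(self, small_cohort):
        products = [
            m
            for sid, m in small_cohort.samples.items()
            if small_cohort.manifest.set_index("sample_id").loc[sid, "stage"]
            == "product"
        ][:3]
        cyto = {m.sample_id: 50.0 for m in products}
        strategy = cs.GatingStrategy()
        pool = cs.assign_cell_cytotoxicity(products, cyto, strategy, "CD8")
        # every pooled event is viable, CD3+, CAR+ and CD8+
        for m in products:
            sub = pool[pool.sample_id == m.sample_id]
            thr = strategy.thresholds
            assert (sub["CD8"] > thr["CD8"]).all()
            assert (sub["CAR"] > thr["CAR"]).all()
            assert (sub["Viability"] < thr["Viability"]).all()


def _blob_pool(n_blobs=2, n_per=100, seed=0):
    rng = np.random.default_rng(seed)
    markers = list(DEFAULT_MARKERS)
    frames = []
    for b in range(n_blobs):
        x = 6.0 * b + rng.standard_normal((n_per, len(markers)))
        df = pd.DataFrame(x + 10.0, columns=markers)
        df["sample_id"] = f"p{b}"
        df["cytotoxicity"] = 10.0 + 40.0 * b
        df["true_blob"] = b
        frames.append(df)
    return pd.concat(frames, ignore_index=True), markers


class TestSweep:
    def test_recovers_two_planted_blobs_exactly(self):
        pool, markers = _blob_pool()
        pool_s = standardize_events(pool, markers)
        cfg = AttributionConfig(k_grid=(2,), seed=0)
        model = kmeans_sweep(pool_s, markers, cfg)[0]
        assert adjusted_rand_score(pool["true_blob"], model.assignments) == 1.0

    def test_saturated_k_yields_singleton_scale_clusters(self):
        pool, markers = _blob_pool(n_blobs=1, n_per=10)
        cfg = AttributionConfig(k_grid=(9,), seed=0)
        model = kmeans_sweep(standardize_events(pool, markers), markers, cfg)[0]
        assert model.k == 9
        assert model.cluster_sizes.sum() == 10
        assert model.cluster_sizes.max() <= 2

    def test_k_at_or_above_event_count_skipped(self):
        pool, markers = _blob_pool(n_blobs=1, n_per=10)
        cfg = AttributionConfig(k_grid=(12,), seed=0)
        with pytest.raises(ValueError, match="k_grid"):
            kmeans_sweep(standardize_events(pool, markers), markers, cfg)

    def test_same_seed_identical_centroids(self):
        pool, markers = _blob_pool()
        pool_s = standardize_events(pool, markers)
        cfg = AttributionConfig(k_grid=(4,), seed=7)
        a = kmeans_sweep(pool_s, markers, cfg)[0]
        b = kmeans_sweep(pool_s, markers, cfg)[0]
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_event_cap_subsamples_once(self):
        pool, markers = _blob_pool(n_per=200)
        cfg = AttributionConfig(k_grid=(2,), seed=0, event_cap=150)
        model = kmeans_sweep(standardize_events(pool, markers), markers, cfg)[0]
        assert model.cluster_sizes.sum() == 150


def _manual_model(features, cytotox):
    k = len(cytotox)
    return ClusterModel(
        k=k,
        centroids=features,
        assignments=np.arange(k),
        cluster_cytotox=np.asarray(cytotox, dtype=float),
        cluster_sizes=np.ones(k, dtype=int),
        cluster_features=features,
    )


class TestExplainedVariance:
    def test_planted_functional_relationship_scores_high(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((20, 5))
        feats[:, 0] = np.linspace(-2, 2, 20)
        model = _manual_model(feats, 20 + 30 * feats[:, 0])
        ev = cluster_explained_variance(model, AttributionConfig(seed=0))
        assert ev >= 0.9

    def test_constant_cytotoxicity_flagged(self):
        feats = np.random.default_rng(0).standard_normal((5, 3))
        model = _manual_model(feats, [50.0] * 5)
        assert cluster_explained_variance(model, AttributionConfig(seed=0)) is None

    def test_pure_noise_scores_low(self):
        vals = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            feats = rng.standard_normal((20, 5))
            model = _manual_model(feats, 50 + 10 * rng.standard_normal(20))
            vals.append(cluster_explained_variance(model, AttributionConfig(seed=s)))
        assert float(np.median(vals)) <= 0.2


class TestSelection:
    def test_argmax_over_trace(self):
        assert argmax_k({2: 0.1, 4: 0.8, 8: 0.7}) == 4

    def test_ties_break_to_smaller_k(self):
        assert argmax_k({4: 0.8, 8: 0.8}) == 4

    def test_flagged_values_excluded(self):
        assert argmax_k({2: None, 4: 0.5}) == 4
        with pytest.raises(ValueError):
            argmax_k({2: None, 4: None})


class TestClassification:
    def test_closed_form_z_scores_and_classes(self):
        feats = np.eye(3)
        model = _manual_model(feats, [10.0, 50.0, 90.0])
        pool = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "m": [0.0, 0.0, 0.0]}
        )
        z, classes, frac, _ = classify_clusters(model, pool, ["m"])
        np.testing.assert_allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-9)
        assert classes == ["low", "moderate", "high"]
        assert np.allclose(frac.sum(axis=1), 1.0)

    def test_zero_sd_cytotoxicity_makes_all_moderate(self):
        model = _manual_model(np.eye(3), [50.0, 50.0, 50.0])
        pool = pd.DataFrame({"sample_id": list("abc"), "m": [0.0] * 3})
        z, classes, _, _ = classify_clusters(model, pool, ["m"])
        assert (z == 0).all()
        assert classes == ["moderate"] * 3

    def test_product_fully_in_high_clusters_has_fraction_one(self):
        model = ClusterModel(
            k=3,
            centroids=np.eye(3),
            assignments=np.array([2, 2, 0, 1]),
            cluster_cytotox=np.array([10.0, 50.0, 90.0]),
            cluster_sizes=np.array([1, 1, 2]),
            cluster_features=np.eye(3),
        )
        pool = pd.DataFrame(
            {"sample_id": ["hi", "hi", "lo", "mid"], "m": [0.0] * 4}
        )
        _, _, frac, _ = classify_clusters(model, pool, ["m"])
        assert frac.loc["hi", "high"] == 1.0
        assert frac.loc["lo", "low"] == 1.0

    def test_single_cluster_rejected(self):
        model = ClusterModel(
            k=1,
            centroids=np.zeros((1, 2)),
            assignments=np.zeros(4, dtype=int),
            cluster_cytotox=np.array([10.0]),
            cluster_sizes=np.array([4]),
            cluster_features=np.zeros((1, 2)),
        )
        pool = pd.DataFrame({"sample_id": list("aaaa"), "m": [0.0] * 4})
        with pytest.raises(ValueError):
            classify_clusters(model, pool, ["m"])
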