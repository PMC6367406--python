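"""Sparse k-means (vs brute-force oracle), orientation and the cellular
decision tree."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tnbclayers.classify import (
    cellular_workflow,
    choose_sparsity,
    immune_call,
    orient_high_low,
    sparse_kmeans,
    _bcss_per_feature,
    _soft_threshold_weights,
)


class TestWeightUpdate:
    def test_unbounded_weights_proportional_to_bcss(self, rng):
        a = rng.uniform(0.0, 5.0, size=6)
        w = _soft_threshold_weights(a, s=np.sqrt(6))
        np.testing.assert_allclose(w, a / np.linalg.norm(a), rtol=1e-10)

    def test_l1_bound_enforced_by_bisection(self, rng):
        a = rng.uniform(0.0, 5.0, size=20)
        for s in (1.2, 2.0, 3.5):
            w = _soft_threshold_weights(a, s=s)
            assert np.sum(w) <= s + 1e-6
            assert np.linalg.norm(w) == pytest.approx(1.0)
            assert np.all(w >= 0)


class TestSparseKMeans:
    def test_tight_bound_concentrates_weight_on_informative_feature(self, rng):
        n = 60
        x = rng.standard_normal((n, 4)) * 0.2
        x[: n // 2, 0] += 4.0  # clusters differ only in feature 0
        res = sparse_kmeans(x, k=2, s=1.02, n_restarts=5, seed=3)
        assert res.weights[0] > 0.99
        labels_match = (res.labels[: n // 2] == res.labels[0]).all() and (
            res.labels[n // 2 :] != res.labels[0]
        ).all()
        assert labels_match

    def test_loose_bound_equals_plain_kmeans_with_equal_weights(self, rng):
        from sklearn.cluster import KMeans

        n = 40
        x = np.vstack(
            [rng.standard_normal((n // 2, 3)) + 3.0, rng.standard_normal((n // 2, 3)) - 3.0]
        )
        res = sparse_kmeans(x, k=2, s=np.sqrt(3), n_restarts=5, seed=1)
        # symmetric well-separated data: every feature near-equally
        # informative (weights equal up to BCSS sampling noise)
        np.testing.assert_allclose(res.weights, 1.0 / np.sqrt(3), atol=0.12)
        assert res.weights.min() > 0.4
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(x)
        agree = max((km == res.labels).mean(), (km != res.labels).mean())
        assert agree == 1.0

    def test_labels_match_exhaustive_weighted_bcss_search(self, rng):
        # n=6, p=2: enumerate all 31 bipartitions, maximizing the weighted
        # BCSS with the weight vector implied by each partition
        x = rng.standard_normal((6, 2))
        x[:3] += 2.5
        s = 1.3
        best_obj, best_split = -np.inf, None
        for bits in itertools.product([0, 1], repeat=6):
            if len(set(bits)) < 2:
                continue
            labels = np.array(bits)
            a = _bcss_per_feature(x, labels)
            w = _soft_threshold_weights(a, s)
            obj = float(a @ w)
            if obj > best_obj:
                best_obj, best_split = obj, labels
        res = sparse_kmeans(x, k=2, s=s, n_restarts=20, seed=9)
        assert res.objective == pytest.approx(best_obj, rel=1e-9)
        agree = (res.labels == best_split).all() or (res.labels == 1 - best_split).all()
        assert agree

    def test_norm_invariants_hold(self, rng):
        x = rng.standard_normal((30, 8))
        res = sparse_kmeans(x, k=2, s=2.0, n_restarts=3, seed=4)
        assert np.all(res.weights >= 0)
        assert np.linalg.norm(res.weights) == pytest.approx(1.0, abs=1e-8)
        assert res.weights.sum() <= 2.0 + 1e-8

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((25, 5))
        a = sparse_kmeans(x, k=2, s=2.0, n_restarts=4, seed=11)
        b = sparse_kmeans(x, k=2, s=2.0, n_restarts=4, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_fewer_samples_than_k_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sparse_kmeans(np.zeros((1, 3)), k=2, s=1.5)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            sparse_kmeans(np.ones((10, 3)), k=2, s=1.5)

    def test_invalid_sparsity_rejected(self, rng):
        x = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="s must be"):
            sparse_kmeans(x, k=2, s=0.9)
        with pytest.raises(ValueError, match="s must be"):
            sparse_kmeans(x, k=2, s=5.0)

    def test_gap_statistic_prefers_sparse_bound_for_sparse_signal(self, rng):
        n = 80
        x = rng.standard_normal((n, 10)) * 0.3
        x[: n // 2, 0] += 3.0  # only feature 0 informative
        s = choose_sparsity(x, k=2, n_candidates=5, n_permutations=8, seed=2)
        assert s < np.sqrt(10) * 0.8


class TestOrientHighLow:
    def _result(self, labels):
        from tnbclayers.classify import SparseKMeansResult

        w = np.array([1.0])
        return SparseKMeansResult(np.asarray(labels), w, 1.5, 1.0, 1, 0)

    def test_high_cluster_has_greater_mean_activity(self):
        res = self._result([0, 0, 1, 1])
        act = pd.Series([1.0, 2.0, 8.0, 9.0], index=list("abcd"))
        calls = orient_high_low(res, act)
        assert list(calls) == ["low", "low", "high", "high"]

    def test_invariant_to_cluster_index_swap(self):
        act = pd.Series([1.0, 2.0, 8.0, 9.0], index=list("abcd"))
        a = orient_high_low(self._result([0, 0, 1, 1]), act)
        b = orient_high_low(self._result([1, 1, 0, 0]), act)
        assert list(a) == list(b)

    def test_equal_means_tie_resolves_low_with_warning(self):
        act = pd.Series([3.0, 3.0, 3.0, 3.0], index=list("abcd"))
        with pytest.warns(UserWarning, match="tie"):
            calls = orient_high_low(self._result([0, 0, 1, 1]), act)
        assert set(calls) == {"low"}


class TestCellularWorkflow:
    @pytest.mark.parametrize(
        "lum,bas,cldn,expected,ambiguous",
        [
            ("high", "low", "low", "LAR", False),
            ("high", "low", "high", "LAR", False),
            ("high", "high", "low", "LAR", True),
            ("low", "high", "high", "basal", False),
            ("low", "high", "low", "basal", False),
            ("low", "low", "high", "CLDN-high", False),
            ("low", "low", "low", "CLDN-low", False),
        ],
    )
    def test_decision_table(self, lum, bas, cldn, expected, ambiguous):
        idx = ["s1"]
        out = cellular_workflow(
            pd.Series([lum], index=idx),
            pd.Series([bas], index=idx),
            pd.Series([cldn], index=idx),
        )
        assert out.loc["s1", "cellular"] == expected
        assert bool(out.loc["s1", "ambiguous"]) is ambiguous

    def test_missing_layer_call_rejected(self):
        lum = pd.Series(["high", "low"], index=["s1", "s2"])
        bas = pd.Series(["low"], index=["s1"])
        cldn = pd.Series(["low", "low"], index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            cellular_workflow(lum, bas, cldn)

    def test_exactly_one_label_per_sample(self, rng):
        n = 50
        idx = [f"s{i}" for i in range(n)]
        choices = np.array(["high", "low"])
        out = cellular_workflow(
            pd.Series(rng.choice(choices, n), index=idx),
            pd.Series(rng.choice(choices, n), index=idx),
            pd.Series(rng.choice(choices, n), index=idx),
        )
        assert out["cellular"].isin(["LAR", "basal", "CLDN-low", "CLDN-high"]).all()
        assert len(out) == n


class TestImmuneCall:
    def test_planted_high_half_recovered(self, rng):
        n = 40
        x = np.vstack(
            [rng.standard_normal((n // 2, 5)) + 2.0, rng.standard_normal((n // 2, 5)) - 2.0]
        )
        res = sparse_kmeans(x, k=2, s=2.0, n_restarts=5, seed=6)
        act = pd.Series(x.mean(axis=1), index=[f"s{i}" for i in range(n)])
        calls = immune_call(res, act)
        assert (calls.iloc[: n // 2] == "IM+").all()
        assert (calls.iloc[n // 2 :] == "IM-").all()

    def test_label_symmetry(self, rng):
        from tnbclayers.classify import SparseKMeansResult

        act = pd.Series([5.0, 5.5, -5.0, -5.5], index=list("abcd"))
        w = np.array([1.0])
        a = immune_call(SparseKMeansResult(np.array([0, 0, 1, 1]), w, 1.5, 1.0, 1, 0), act)
        b = immune_call(SparseKMeansResult(np.array([1, 1, 0, 0]), w, 1.5, 1.0, 1, 0), act)
        assert list(a) == list(b) == ["IM+", "IM+", "IM-", "IM-"]
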