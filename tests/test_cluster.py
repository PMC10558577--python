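"""Weighted k-means++: stretch transform, seeding, Lloyd, label mapping, tuning."""

import itertools

import numpy as np
import pytest

from implantsize import cluster
from implantsize.errors import (
    CardinalityError,
    InsufficientDataError,
    ModelStateError,
)


class TestTransform:
    def test_identity_at_w1(self):
        assert cluster.transform((3.3, 8.0), 1.0).tolist() == [3.3, 8.0]

    def test_final_model_weight_two(self):
        assert cluster.transform((3.3, 8.0), 2.0).tolist() == [6.6, 8.0]

    def test_linear_scaling_leaves_length_unchanged(self):
        assert cluster.transform((4.1, 10.0), 10.0).tolist() == [41.0, 10.0]

    @pytest.mark.parametrize("w", [0.0, -1.0])
    def test_nonpositive_weight_rejected(self, w):
        with pytest.raises(ValueError):
            cluster.transform((1.0, 1.0), w)

    def test_input_not_mutated(self):
        x = np.array([[2.0, 3.0]])
        cluster.transform(x, 5.0)
        assert x.tolist() == [[2.0, 3.0]]


class TestSeeding:
    def test_k1_returns_an_input_point(self, rng):
        pts = rng.normal(size=(20, 2))
        c = cluster.kmeanspp_seed(pts, 1, rng)
        assert any(np.array_equal(c[0], p) for p in pts)

    def test_duplicates_force_the_distinct_locations(self, rng):
        # 9 distinct locations, each duplicated: after the first pick every
        # remaining duplicate has squared distance 0, so the other 8 distinct
        # locations are chosen with probability 1.
        locs = np.array([[i, j] for i in range(3) for j in range(3)], dtype=float)
        pts = np.repeat(locs, 4, axis=0)
        c = cluster.kmeanspp_seed(pts, 9, rng)
        got = sorted(map(tuple, c))
        assert got == sorted(map(tuple, locs))

    def test_too_few_distinct_points_rejected(self, rng):
        pts = np.repeat([[1.0, 2.0]], 10, axis=0)
        with pytest.raises(InsufficientDataError):
            cluster.kmeanspp_seed(pts, 2, rng)

    def test_seeding_distribution_matches_analytic_d2_law(self):
        # 3 collinear points at x = 0, 1, 3; k = 2.  First pick uniform; the
        # second is proportional to squared distance to the first.  Exact
        # enumeration of the joint law of the (first, second) index pair:
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        analytic = np.zeros((3, 3))
        for i in range(3):
            probs = d2[i] / d2[i].sum()
            analytic[i] = probs / 3.0
        n = 10_000
        counts = np.zeros((3, 3))
        root = np.random.SeedSequence(999)
        for child in root.spawn(n):
            rng = np.random.default_rng(child)
            c = cluster.kmeanspp_seed(pts, 2, rng)
            i = int(np.where((pts == c[0]).all(axis=1))[0][0])
            j = int(np.where((pts == c[1]).all(axis=1))[0][0])
            counts[i, j] += 1
        for i in range(3):
            for j in range(3):
                p = analytic[i, j]
                sigma = np.sqrt(n * p * (1 - p))
                assert abs(counts[i, j] - n * p) <= 3 * sigma + 1e-9


def _partition_cost(points, assign, k):
    """Independent oracle: sum of squared distances to cluster means."""
    cost = 0.0
    for c in range(k):
        members = points[assign == c]
        if len(members):
            cost += ((members - members.mean(axis=0)) ** 2).sum()
    return cost


def _exhaustive_optimum(points, k):
    """Brute force over all k^n assignments (chunked, vectorised)."""
    n = len(points)
    sq = (points ** 2).sum(axis=1)
    best = np.inf
    all_assign = np.array(
        list(itertools.product(range(k), repeat=n)), dtype=np.int8
    )
    for start in range(0, len(all_assign), 50_000):
        chunk = all_assign[start : start + 50_000]
        onehot = np.eye(k, dtype=float)[chunk]  # (m, n, k)
        nc = onehot.sum(axis=1)  # (m, k)
        sums = np.einsum("mnk,nd->mkd", onehot, points)  # (m, k, d)
        qs = np.einsum("mnk,n->mk", onehot, sq)  # (m, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = (sums ** 2).sum(axis=2) / nc
        shrink[nc == 0] = 0.0
        cost = (qs - shrink).sum(axis=1)
        best = min(best, float(cost.min()))
    return best


class TestLloyd:
    def test_points_equal_to_centroids_give_zero_inertia(self, rng):
        centers = rng.uniform(-10, 10, size=(9, 2))
        pts = np.repeat(centers, 3, axis=0)
        c, assign, inertia, _ = cluster.lloyd_fit(pts, centers)
        assert inertia == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(np.sort(c, axis=0), np.sort(centers, axis=0))

    def test_inertia_history_is_monotone(self, rng):
        pts = rng.normal(size=(200, 2)) + rng.integers(0, 4, size=(200, 1)) * 5
        init = cluster.kmeanspp_seed(pts, 4, rng)
        _, _, _, history = cluster.lloyd_fit(pts, init)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_attains_exhaustive_optimum_on_tiny_instance(self, rng):
        # 12 points, k=3: the best of 20 seeded restarts must match the
        # global optimum found by enumerating all 3^12 assignments.
        pts = np.vstack(
            [
                rng.normal((0, 0), 0.8, size=(4, 2)),
                rng.normal((6, 1), 0.8, size=(4, 2)),
                rng.normal((3, 7), 0.8, size=(4, 2)),
            ]
        )
        model = cluster.fit(pts, k=3, w=1.0, n_init=20, seed=7)
        assert model.inertia == pytest.approx(_exhaustive_optimum(pts, 3), rel=1e-9)


class TestFit:
    def test_same_seed_is_bit_identical(self, low_noise_dataset):
        X, _ = low_noise_dataset
        a = cluster.fit(X, k=9, w=2.0, n_init=3, seed=5)
        b = cluster.fit(X, k=9, w=2.0, n_init=3, seed=5)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.inertia == b.inertia

    def test_more_restarts_never_hurt(self, rng):
        pts = rng.normal(size=(30, 2))
        one = cluster.fit(pts, k=3, w=1.0, n_init=1, seed=0)
        many = cluster.fit(pts, k=3, w=1.0, n_init=20, seed=0)
        assert many.inertia <= one.inertia + 1e-12

    def test_centroids_near_class_means_when_separable(self, low_noise_dataset):
        # under near-separable simulation each centroid should sit on the
        # (stretched) per-class mean
        X, y = low_noise_dataset
        w = 2.0
        model = cluster.fit(X, k=9, w=w, n_init=10, seed=3)
        tx = cluster.transform(X, w)
        class_means = np.array(
            [tx[np.array(y) == c].mean(axis=0) for c in sorted(set(y))]
        )
        # match centroids to nearest class mean, require all within 0.2 mm
        for mean in class_means:
            d = np.linalg.norm(model.centroids - mean, axis=1)
            assert d.min() < 0.2

    def test_matches_reference_kmeans_inertia(self, low_noise_dataset):
        # independent cross-check against the scikit-learn implementation
        from sklearn.cluster import KMeans

        X, _ = low_noise_dataset
        tx = cluster.transform(X, 2.0)
        ours = cluster.fit(X, k=9, w=2.0, n_init=10, seed=4).inertia
        ref = KMeans(n_clusters=9, n_init=10, random_state=4).fit(tx).inertia_
        assert ours == pytest.approx(ref, rel=0.01)


def _brute_force_best_assignment(cont):
    best_total, best_perm = -1, None
    k = cont.shape[0]
    perms = np.array(list(itertools.permutations(range(k))))
    totals = cont[np.arange(k), perms].sum(axis=1)
    best_total = totals.max()
    winners = perms[totals == best_total]
    best_perm = min(map(tuple, winners))  # lexicographically smallest
    return int(best_total), list(best_perm)


class TestLabelMapping:
    def test_toy_contingency_enumeration(self):
        cont = np.array([[5, 0, 1], [0, 6, 0], [1, 0, 4]])
        perm = cluster._lexicographic_optimal_assignment(cont)
        assert perm == [0, 1, 2]
        assert sum(cont[i, perm[i]] for i in range(3)) == 15

    def test_matches_permutation_brute_force(self, rng):
        for _ in range(20):
            cont = rng.integers(0, 30, size=(9, 9))
            perm = cluster._lexicographic_optimal_assignment(cont)
            total = int(cont[np.arange(9), perm].sum())
            bf_total, bf_perm = _brute_force_best_assignment(cont)
            assert total == bf_total
            assert perm == bf_perm

    def test_all_zero_contingency_breaks_ties_lexicographically(self):
        cont = np.zeros((4, 4), dtype=int)
        assert cluster._lexicographic_optimal_assignment(cont) == [0, 1, 2, 3]

    def test_perfectly_separated_training_data_maps_unanimously(self, rng):
        centers = np.array([[float(i * 10), float(i * 10)] for i in range(9)])
        X = np.repeat(centers, 5, axis=0) + rng.normal(0, 0.01, size=(45, 2))
        codes = [c for c in sorted("ABCDEFGHI") for _ in range(5)]
        model = cluster.fit(X, k=9, w=1.0, n_init=10, seed=2)
        model = cluster.map_clusters_to_labels(model, X, codes)
        assert cluster.accuracy(codes, cluster.predict(model, X)) == 1.0

    def test_label_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        model = cluster.fit(X, k=3, w=1.0, n_init=2, seed=0)
        with pytest.raises(CardinalityError):
            cluster.map_clusters_to_labels(model, X, ["a", "b"] * 10)


class TestPredict:
    def _mapped_model(self):
        centroids = np.array([[0.0, 0.0], [10.0, 0.0]])
        return cluster.ClusterModel(
            k=2, w=1.0, centroids=centroids, inertia=0.0,
            label_map={0: "low", 1: "high"},
        )

    def test_centroid_preimage_gets_its_label(self):
        model = self._mapped_model()
        assert cluster.predict(model, [[10.0, 0.0]]) == ["high"]

    def test_exact_tie_goes_to_lower_cluster_index(self):
        model = self._mapped_model()
        assert cluster.predict(model, [[5.0, 0.0]]) == ["low"]

    def test_unmapped_model_rejected(self):
        model = cluster.ClusterModel(
            k=2, w=1.0, centroids=np.zeros((2, 2)), inertia=0.0
        )
        with pytest.raises(ModelStateError):
            cluster.predict(model, [[1.0, 1.0]])


class TestTuneWeight:
    def test_singleton_grid(self, low_noise_dataset):
        X, y = low_noise_dataset
        best_w, curve, model = cluster.tune_weight(
            X, y, X, y, w_grid=[1.0], n_init=3, seed=1
        )
        assert best_w == 1.0
        assert len(curve) == 1
        assert model.label_map is not None

    def test_upweighting_separates_overlapping_diameters(self, rng):
        # two diameter groups whose lengths overlay completely: at w=1 the
        # length noise dominates the metric and clusters cut across
        # diameters; stretching D must win the grid search
        n = 60
        X = np.vstack(
            [
                np.column_stack(
                    [rng.normal(3.3, 0.05, n), rng.normal(10.0, 2.0, n)]
                ),
                np.column_stack(
                    [rng.normal(4.8, 0.05, n), rng.normal(10.0, 2.0, n)]
                ),
            ]
        )
        y = ["thin"] * n + ["wide"] * n
        best_w, curve, model = cluster.tune_weight(
            X, y, X, y, w_grid=range(1, 11), n_init=5, seed=6
        )
        assert best_w > 1
        assert dict(curve)[best_w] > dict(curve)[1]

    def test_accuracy_ties_resolve_to_smallest_w(self, rng):
        # fully separated classes: every weight scores 1.0
        X = np.vstack([rng.normal((0, 0), 0.01, (10, 2)),
                       rng.normal((50, 50), 0.01, (10, 2))])
        y = ["a"] * 10 + ["b"] * 10
        best_w, curve, _ = cluster.tune_weight(
            X, y, X, y, w_grid=[1, 2, 3], n_init=2, seed=0
        )
        assert {acc for _, acc in curve} == {1.0}
        assert best_w == 1

    def test_empty_or_invalid_grid_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = ["a", "b"] * 5
        with pytest.raises(ValueError):
            cluster.tune_weight(X, y, X, y, w_grid=[])
        with pytest.raises(ValueError):
            cluster.tune_weight(X, y, X, y, w_grid=[1, -2])


def test_model_json_roundtrip(tmp_path, low_noise_dataset):
    X, y = low_noise_dataset
    model = cluster.fit(X, k=9, w=2.0, n_init=2, seed=9)
    model = cluster.map_clusters_to_labels(model, X, y)
    path = tmp_path / "model.json"
    cluster.save_model(model, path)
    back = cluster.load_model(path)
    assert back.k == model.k and back.w == model.w
    assert np.array_equal(back.centroids, model.centroids)
    assert back.label_map == model.label_map
    assert cluster.predict(back, X[:5]) == cluster.predict(model, X[:5])
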