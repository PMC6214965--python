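import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from spinepath.cluster import (
    CurveClusterModel,
    DegenerateDataError,
    canonicalize_labels,
    kmeans_cluster,
    mean_silhouette,
    select_k,
)

from oracles import brute_force_mean_silhouette, exhaustive_kmeans_sse


def _two_clouds(rng, n_per=20, sep=10.0, d=2, sd=0.1):
    a = rng.normal(0, sd, (n_per, d)) - sep / 2
    b = rng.normal(0, sd, (n_per, d)) + sep / 2
    return np.vstack([a, b])


class TestKMeans:
    def test_well_separated_clouds_recovered(self, rng):
        X = _two_clouds(rng)
        res = kmeans_cluster(X, k=2, restarts=10, seed=0)
        labels = res.labels
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_matches_exhaustive_optimum_small_instances(self, rng):
        """Best-of-restarts SSE equals the global optimum found by
        enumerating every set partition (n <= 8)."""
        for _ in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, min(n, 4)))
            X = rng.normal(0, 1, (n, 2))
            res = kmeans_cluster(X, k=k, restarts=50, seed=7)
            assert res.sse == pytest.approx(exhaustive_kmeans_sse(X, k), abs=1e-8)

    def test_degenerate_identical_points_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(DegenerateDataError):
            kmeans_cluster(X, k=2)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(0, 1, (3, 2)), k=4)

    def test_bit_reproducible(self, rng):
        X = rng.normal(0, 1, (40, 5))
        a = kmeans_cluster(X, k=3, restarts=20, seed=99)
        b = kmeans_cluster(X, k=3, restarts=20, seed=99)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centers, b.centers)
        assert a.sse == b.sse

    def test_centers_are_member_means(self, rng):
        X = rng.normal(0, 1, (30, 4))
        res = kmeans_cluster(X, k=3, restarts=20, seed=3)
        for j in range(1, res.k + 1):
            np.testing.assert_allclose(
                res.centers[j - 1], X[res.labels == j].mean(axis=0), atol=1e-12
            )

    def test_agrees_with_sklearn_on_easy_instance(self, rng):
        X = _two_clouds(rng, sep=8.0)
        res = kmeans_cluster(X, k=2, restarts=20, seed=0)
        sk = KMeans(n_clusters=2, n_init=20, random_state=0).fit(X)
        assert res.sse == pytest.approx(float(sk.inertia_), rel=1e-9)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        # {0, 1, 10, 11} labelled A,A,B,B:
        # s(0) = (10.5-1)/10.5, s(1) = (9.5-1)/9.5, symmetric for B
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([1, 1, 2, 2])
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert mean_silhouette(X, labels) == pytest.approx(expected, abs=1e-12)
        assert mean_silhouette(X, labels) == pytest.approx(0.8997, abs=5e-5)

    def test_coincident_clusters_nonpositive(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        X = np.vstack([pts, pts])
        labels = np.array([1] * 8 + [2] * 8)
        assert mean_silhouette(X, labels) <= 0.0

    def test_approaches_one_with_separation(self, rng):
        base = rng.normal(0, 0.01, (10, 2))
        values = []
        for sep in (1.0, 10.0, 1000.0):
            X = np.vstack([base, base + sep])
            labels = np.array([1] * 10 + [2] * 10)
            values.append(mean_silhouette(X, labels))
        assert values == sorted(values)
        assert values[-1] > 0.999

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_silhouette(rng.normal(0, 1, (5, 2)), np.ones(5, dtype=int))

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        labels = np.array([1, 1, 2])
        expected = brute_force_mean_silhouette(X, labels)
        assert mean_silhouette(X, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 31))
            k = int(rng.integers(2, 5))
            X = rng.normal(0, 1, (n, 3))
            labels = rng.integers(1, k + 1, n)
            if len(np.unique(labels)) < 2:
                continue
            assert mean_silhouette(X, labels) == pytest.approx(
                brute_force_mean_silhouette(X, labels), abs=1e-12
            )

    def test_matches_sklearn_when_no_singletons(self, rng):
        X = rng.normal(0, 1, (30, 4))
        labels = np.repeat([1, 2, 3], 10)
        assert mean_silhouette(X, labels) == pytest.approx(
            float(silhouette_score(X, labels)), abs=1e-10
        )


class TestSelectK:
    def test_three_well_separated_templates(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.05, (15, 3)) + c for c in ([0, 0, 0], [5, 0, 0], [0, 5, 0])]
        )
        res = select_k(X, range(2, 7), restarts=20, seed=1)
        assert res.k == 3
        assert set(res.silhouette_by_k) == {2, 3, 4, 5, 6}

    def test_two_clouds_select_two(self, rng):
        X = _two_clouds(rng, n_per=15)
        assert select_k(X, range(2, 6), restarts=20, seed=1).k == 2

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(0, 1, (10, 2)), [])

    def test_range_outside_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(0, 1, (5, 2)), range(2, 7))

    def test_tie_breaks_toward_smaller_k(self, rng):
        X = rng.normal(0, 1, (12, 2))
        res = select_k(X, range(2, 5), restarts=10, seed=0)
        best = max(res.silhouette_by_k.values())
        smallest_best = min(
            k for k, v in res.silhouette_by_k.items() if v == best
        )
        assert res.k == smallest_best


class TestCanonicalLabels:
    def test_labels_ordered_by_descending_size(self, rng):
        # sizes 24 / 21 / 19 must map to labels 1 / 2 / 3
        X = np.vstack(
            [
                rng.normal(0, 0.05, (24, 2)) + [0, 9],
                rng.normal(0, 0.05, (21, 2)) + [9, 0],
                rng.normal(0, 0.05, (19, 2)) + [-9, 0],
            ]
        )
        res = kmeans_cluster(X, k=3, restarts=20, seed=4)
        np.testing.assert_array_equal(res.cluster_sizes, [24, 21, 19])
        assert set(res.labels[:24]) == {1}
        assert set(res.labels[24:45]) == {2}
        assert set(res.labels[45:]) == {3}

    def test_equal_sizes_ordered_by_center(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.05, (10, 2)) + [-5, 0], rng.normal(0, 0.05, (10, 2)) + [5, 0]]
        )
        res = kmeans_cluster(X, k=2, restarts=10, seed=0)
        # lexicographically smaller center gets label 1
        assert res.centers[0][0] < res.centers[1][0]

    def test_idempotent(self, rng):
        X = rng.normal(0, 1, (20, 3))
        res = kmeans_cluster(X, k=3, restarts=10, seed=0)
        again = canonicalize_labels(res)
        np.testing.assert_array_equal(res.labels, again.labels)
        np.testing.assert_array_equal(res.centers, again.centers)


class TestModelInterface:
    def test_from_curves_and_summary(self, default_cohort):
        from spinepath import Timepoint
        from spinepath.normalize import normalize_cohort

        po = default_cohort.patient_spines(Timepoint.PO)
        curves, _ = normalize_cohort(po, list(default_cohort.controls))
        model = CurveClusterModel.from_curves(curves)
        res = model.fit(3, restarts=20, seed=11)
        assert res.timepoint is Timepoint.PO
        assert "k = 3" in res.summary()
        frame = res.to_frame()
        assert set(frame.columns) == {"patient_id", "timepoint", "cluster"}
        assert len(frame) == len(po)

    def test_plot_centers_returns_axes(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        X = np.vstack([rng.normal(0, 0.1, (10, 34)), rng.normal(1, 0.1, (10, 34))])
        res = kmeans_cluster(X, k=2, restarts=5, seed=0)
        ax = res.plot_centers()
        assert len(ax) == 2
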