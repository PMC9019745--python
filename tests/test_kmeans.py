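import itertools

import numpy as np
import pytest

from temposeg.errors import (
    AmbiguousClusterError,
    EmptySelectionError,
    ParameterError,
)
from temposeg.kmeans import (
    assign_discounted,
    auto_tune_gamma,
    fit_discounted_kmeans,
    harvest_training_set,
    identify_object_cluster,
    select_confident,
)


def two_blobs(rng, n_per=50, dim=2, sep=8.0, scale=0.5):
    a = rng.normal(size=(n_per, dim)) * scale
    b = rng.normal(size=(n_per, dim)) * scale + sep
    return np.vstack([a, b])


class TestAssignDiscounted:
    def test_worked_example_discount_flips_assignment(self):
        # D1 = 5, D2 = 4.5: nearest-centroid picks 2, but 0.8*5 = 4 < 4.5
        point = np.array([0.0])
        centroids = np.array([[5.0], [-4.5]])
        assert assign_discounted(point, centroids, gamma=1.0, discounted_index=1) == 2
        assert assign_discounted(point, centroids, gamma=0.8, discounted_index=1) == 1

    def test_gamma_one_is_nearest_centroid(self, rng):
        x = rng.normal(size=(200, 5))
        c = rng.normal(size=(2, 5))
        labels = assign_discounted(x, c, 1.0, 1)
        d = np.linalg.norm(x[:, None] - c[None], axis=2)
        np.testing.assert_array_equal(labels, np.where(d[:, 0] <= d[:, 1], 1, 2))

    def test_gamma_to_zero_limit_collects_everything(self, rng):
        x = rng.normal(size=(100, 3)) + 5
        c = np.vstack([np.zeros(3), np.full(3, 5.0)])
        labels = assign_discounted(x, c, 1e-9, 1)
        assert (labels == 1).all()

    def test_tie_goes_to_discounted_cluster(self):
        point = np.array([0.0])
        centroids = np.array([[2.0], [-2.0]])  # D1 = D2 = 2
        assert assign_discounted(point, centroids, 1.0, 1) == 1
        assert assign_discounted(point, centroids, 1.0, 2) == 2

    def test_label_symmetry_under_cluster_swap(self, rng):
        x = rng.normal(size=(300, 4))
        c = rng.normal(size=(2, 4))
        lab = assign_discounted(x, c, 0.7, 1)
        swapped = assign_discounted(x, c[::-1], 0.7, 2)
        np.testing.assert_array_equal(lab, 3 - swapped)

    def test_vectorized_matches_scalar_loop(self, rng):
        x = rng.normal(size=(500, 6))
        c = rng.normal(size=(2, 6))
        for gamma, di in [(1.0, 1), (0.8, 1), (0.5, 2)]:
            vec = assign_discounted(x, c, gamma, di)
            for i in range(0, 500, 17):
                d1 = np.linalg.norm(x[i] - c[0])
                d2 = np.linalg.norm(x[i] - c[1])
                if di == 1:
                    expect = 1 if gamma * d1 <= d2 else 2
                else:
                    expect = 2 if gamma * d2 <= d1 else 1
                assert vec[i] == expect

    @pytest.mark.parametrize("gamma", [0.0, -0.2, 1.5])
    def test_gamma_out_of_range_rejected(self, gamma):
        with pytest.raises(ParameterError):
            assign_discounted(np.zeros(2), np.eye(2), gamma, 1)


class TestFitDiscountedKmeans:
    def test_recovers_two_blobs_exactly(self, rng):
        x = two_blobs(rng)
        model = fit_discounted_kmeans(x, gamma=1.0, seed=0)
        first = model.assignments[:50]
        second = model.assignments[50:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]
        assert model.converged

    def test_optimal_partition_on_tiny_input(self, rng):
        """Brute-force oracle: over all 2-partitions of 10 points, the fitted
        partition attains the minimum within-cluster sum of squares."""
        x = two_blobs(rng, n_per=5, sep=4.0)
        best = np.inf
        for bits in itertools.product([0, 1], repeat=10):
            bits = np.array(bits)
            if bits.sum() in (0, 10):
                continue
            cost = sum(
                ((x[bits == k] - x[bits == k].mean(axis=0)) ** 2).sum() for k in (0, 1)
            )
            best = min(best, cost)
        model = fit_discounted_kmeans(x, gamma=1.0, seed=3)
        got = sum(
            ((x[model.assignments == k] - model.centroids[k - 1]) ** 2).sum()
            for k in (1, 2)
        )
        assert got == pytest.approx(best, rel=1e-9)

    def test_two_points_get_own_clusters(self):
        x = np.array([[0.0, 0.0], [3.0, 3.0]])
        model = fit_discounted_kmeans(x, gamma=1.0, seed=0)
        assert sorted(model.assignments) == [1, 2]
        assert model.iterations_run <= 2

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(120, 8))
        a = fit_discounted_kmeans(x, gamma=0.9, discounted_index=2, seed=11)
        b = fit_discounted_kmeans(x, gamma=0.9, discounted_index=2, seed=11)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.inertia == b.inertia

    def test_non_finite_features_rejected(self):
        x = np.zeros((5, 2))
        x[0, 0] = np.inf
        with pytest.raises(Exception, match="finite"):
            fit_discounted_kmeans(x, gamma=1.0)


class TestSelectConfident:
    def test_gamma_one_equals_plain_membership(self, rng):
        x = two_blobs(rng)
        model = fit_discounted_kmeans(x, gamma=1.0, discounted_index=2, seed=0)
        sel = select_confident(model, x, target_cluster=1, label=1)
        np.testing.assert_array_equal(
            sel.indices, np.flatnonzero(model.assignments == 1)
        )

    def test_monotone_in_gamma_with_fixed_centroids(self, rng):
        """Direct-enumeration oracle: the stubborn set {i : D_own < gamma*D_rival}
        shrinks as gamma decreases."""
        x = rng.normal(size=(400, 3))
        c = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        d = np.linalg.norm(x[:, None] - c[None], axis=2)
        prev = None
        for gamma in np.arange(1.0, 0.04, -0.05):
            labels = assign_discounted(x, c, gamma, 2)  # discount rival of cluster 1
            sel = set(np.flatnonzero(labels == 1))
            expect = set(np.flatnonzero(d[:, 0] < gamma * d[:, 1]))
            assert sel == expect
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_requires_discounting_the_rival(self, rng):
        x = two_blobs(rng)
        model = fit_discounted_kmeans(x, gamma=0.9, discounted_index=1, seed=0)
        with pytest.raises(ParameterError):
            select_confident(model, x, target_cluster=1, label=1)

    def test_boundary_point_is_not_confident(self):
        # a point exactly on the discounted boundary goes to the discounted
        # cluster, hence never into the confident set of the target
        c = np.array([[1.0], [-0.8]])
        point = np.array([[0.0]])  # D1 = 1, D2 = 0.8 = 0.8 * D1
        assert assign_discounted(point, c, 0.8, 1)[0] == 1


class TestIdentifyObjectCluster:
    def _model(self, c1, c2):
        from temposeg.kmeans import ClusterModel

        return ClusterModel(
            centroids=np.vstack([c1, c2]),
            gamma=1.0,
            discounted_index=1,
            assignments=np.array([1, 2]),
            iterations_run=1,
            converged=True,
            seed=0,
        )

    def test_pulse_beats_flat_noise(self, rng):
        t = np.arange(256)
        pulse = 0.2 + 0.5 * np.exp(-((t % 64) / 10.0))
        flat = 0.5 + rng.normal(scale=0.02, size=256)
        assert identify_object_cluster(self._model(pulse, flat)) == 1
        assert identify_object_cluster(self._model(flat, pulse)) == 2

    def test_identical_centroids_ambiguous(self):
        c = np.linspace(0, 1, 50)
        with pytest.raises(AmbiguousClusterError):
            identify_object_cluster(self._model(c, c))

    def test_override_wins(self, rng):
        c = np.linspace(0, 1, 50)
        assert identify_object_cluster(self._model(c, c), override=2) == 2


class TestHarvest:
    def test_gamma_one_yields_full_partition(self, small_movie):
        from temposeg.movie_io import extract_window, normalize_per_pixel

        feats = extract_window(normalize_per_pixel(small_movie.movie), 1, 64)
        ds = harvest_training_set(feats, gamma_obj=1.0, gamma_bg=1.0, seed=0)
        assert ds.m == feats.n_pixels

    def test_confident_points_exclude_border_zone(self, small_movie):
        """Harvested points are stubborn: strictly closer to their own
        centroid than gamma times the rival distance."""
        from temposeg.movie_io import extract_window, normalize_per_pixel
        from scipy.spatial.distance import cdist

        feats = extract_window(normalize_per_pixel(small_movie.movie), 1, 64)
        gamma = 0.7
        ds = harvest_training_set(feats, gamma_obj=gamma, gamma_bg=gamma, seed=0)
        base = fit_discounted_kmeans(feats, gamma=1.0, seed=0)
        obj = identify_object_cluster(base)
        model_obj = fit_discounted_kmeans(
            feats, gamma=gamma, discounted_index=3 - obj, seed=0,
            init_centroids=base.centroids,
        )
        d = cdist(feats.values[ds.pixel_indices[ds.labels == 1]], model_obj.centroids)
        d_own, d_rival = d[:, obj - 1], d[:, 2 - obj]
        assert (d_own < gamma * d_rival).all()

    def test_harvest_against_ground_truth(self, small_movie):
        from temposeg.movie_io import extract_window, normalize_per_pixel

        feats = extract_window(normalize_per_pixel(small_movie.movie), 1, 64)
        ds = harvest_training_set(feats, gamma_obj=0.8, gamma_bg=0.8, seed=0)
        truth = small_movie.truth_masks[0].values.ravel().astype(bool)
        assert truth[ds.pixel_indices[ds.labels == 1]].all()
        assert not truth[ds.pixel_indices[ds.labels == 0]].any()


class TestAutoTuneGamma:
    def test_reachable_target_returns_one(self, rng):
        x = two_blobs(rng)
        model = fit_discounted_kmeans(x, gamma=1.0, discounted_index=2, seed=0)
        count = model.cluster_size(1)
        assert auto_tune_gamma(x, target_count=count, target_cluster=1, seed=0) == 1.0

    def test_tuned_count_matches_grid_scan_oracle(self, rng):
        x = two_blobs(rng, n_per=100, sep=3.0, scale=1.0)
        target = 40
        gamma = auto_tune_gamma(x, target_count=target, target_cluster=1, seed=0)
        model = fit_discounted_kmeans(
            x, gamma=gamma, discounted_index=2, seed=0,
            init_centroids=fit_discounted_kmeans(x, 1.0, 2, seed=0).centroids,
        )
        got = model.cluster_size(1)
        # grid-scan oracle: the best achievable count over a 0.01 gamma grid
        base = fit_discounted_kmeans(x, 1.0, 2, seed=0)
        counts = []
        for g in np.arange(0.01, 1.001, 0.01):
            m = fit_discounted_kmeans(
                x, gamma=float(g), discounted_index=2, seed=0,
                init_centroids=base.centroids,
            )
            counts.append(m.cluster_size(1))
        best = min(counts, key=lambda c: abs(c - target))
        assert abs(got - target) <= max(abs(best - target), 0.05 * target)

    def test_unreachable_target_rejected(self, rng):
        x = two_blobs(rng)
        with pytest.raises(ParameterError):
            auto_tune_gamma(x, target_count=101, target_cluster=1, seed=0)
        with pytest.raises(ParameterError):
            auto_tune_gamma(x, target_count=1000, target_cluster=1, seed=0)
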