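import numpy as np
import pytest

from rfseg.cluster import (
    RobustRoughFuzzyCMeans,
    assign_regions,
    fcm_membership,
    hcm,
    objective,
    pcm_membership,
    rrfcm,
    scale_parameters,
    thresholds,
    update_centroids,
)
from rfseg.phantom import make_cloud_fixture


class TestHCM:
    def test_recovers_separated_cloud_means(self):
        X, labels = make_cloud_fixture(c=2, n_per=200, separation=20.0, sigma=1.0, seed=5)
        V = hcm(X, 2, seed=5)
        means = np.stack([X[labels == i].mean(axis=0) for i in range(2)])
        # match centroids to cloud means by nearest pairing
        d = np.linalg.norm(V[:, None] - means[None], axis=2)
        assert d.min(axis=1).max() < 3.0 / np.sqrt(200) * 3  # CLT-scale bound

    def test_n_equals_c_returns_the_objects(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        V = hcm(X, 2, seed=0)
        assert np.allclose(np.sort(V, axis=0), np.sort(X, axis=0))

    def test_duplicate_data_terminates(self):
        X = np.tile([[1.0, 2.0]], (30, 1))
        V = hcm(X, 2, seed=0)
        assert np.isfinite(V).all()

    def test_agrees_with_sklearn_on_easy_data(self):
        from sklearn.cluster import KMeans

        X, _ = make_cloud_fixture(c=3, n_per=100, separation=30.0, sigma=0.5, seed=9)
        V = hcm(X, 3, seed=9)
        ref = KMeans(n_clusters=3, n_init=5, random_state=0).fit(X).cluster_centers_
        d = np.linalg.norm(V[:, None] - ref[None], axis=2)
        assert d.min(axis=1).max() < 0.5

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            hcm(np.zeros((2, 2)), 3)


class TestMemberships:
    def test_fcm_equidistant_is_half(self):
        V = np.array([[-1.0], [1.0]])
        mu = fcm_membership(np.array([[0.0]]), V, m1=2.0)
        assert np.allclose(mu[:, 0], [0.5, 0.5])

    def test_fcm_coincident_point_one_hot(self):
        V = np.array([[0.0, 0.0], [5.0, 5.0]])
        mu = fcm_membership(V[:1], V, m1=2.0)
        assert np.array_equal(mu[:, 0], [1.0, 0.0])

    def test_fcm_inverse_distance_ratios(self):
        # squared distances (1, 2, 4) with m1=2 give mu = (4/7, 2/7, 1/7)
        x = np.array([[0.0]])
        V = np.array([[1.0], [np.sqrt(2.0)], [2.0]])
        mu = fcm_membership(x, V, m1=2.0)
        assert np.allclose(mu[:, 0], [4 / 7, 2 / 7, 1 / 7])

    def test_fcm_columns_sum_to_one(self, rng):
        X = rng.random((50, 3))
        V = rng.random((4, 3))
        mu = fcm_membership(X, V, m1=1.7)
        assert np.allclose(mu.sum(axis=0), 1.0)

    def test_pcm_half_at_eta(self):
        nu = pcm_membership(np.array([[1.0]]), np.array([[0.0]]), np.array([1.0]), m2=2.0)
        assert nu[0, 0] == pytest.approx(0.5)

    def test_pcm_one_at_centroid(self):
        nu = pcm_membership(np.array([[3.0]]), np.array([[3.0]]), np.array([2.0]))
        assert nu[0, 0] == 1.0

    def test_pcm_quarter_at_three_eta(self):
        nu = pcm_membership(
            np.array([[np.sqrt(3.0)]]), np.array([[0.0]]), np.array([1.0]), m2=2.0
        )
        assert nu[0, 0] == pytest.approx(0.25)

    def test_pcm_independent_of_other_clusters(self, rng):
        X = rng.random((20, 2))
        V2 = rng.random((2, 2))
        V3 = np.vstack([V2, rng.random((1, 2))])
        eta2 = np.array([0.5, 0.8])
        eta3 = np.append(eta2, 0.3)
        nu2 = pcm_membership(X, V2, eta2)
        nu3 = pcm_membership(X, V3, eta3)
        assert np.allclose(nu2, nu3[:2])

    def test_pcm_requires_positive_eta(self):
        with pytest.raises(ValueError):
            pcm_membership(np.zeros((1, 1)), np.zeros((1, 1)), np.array([0.0]))


class TestScaleParameters:
    def test_constant_distance_gives_k_times_r(self, rng):
        # every object at squared distance r from the centroid
        r = 4.0
        angles = rng.uniform(0, 2 * np.pi, 30)
        X = np.sqrt(r) * np.column_stack([np.cos(angles), np.sin(angles)])
        V = np.zeros((1, 2))
        W = rng.uniform(0.1, 1.0, size=(1, 30))
        eta = scale_parameters(X, V, W, m2=2.0, K=1.0)
        assert eta[0] == pytest.approx(r)
        assert scale_parameters(X, V, W, m2=2.0, K=2.0)[0] == pytest.approx(2 * r)

    def test_matches_direct_summation(self, rng):
        X = rng.random((15, 3))
        V = rng.random((2, 3))
        W = rng.uniform(0.01, 1.0, size=(2, 15))
        eta = scale_parameters(X, V, W, m2=2.0, K=1.0)
        for i in range(2):
            num = sum(
                W[i, j] ** 2 * np.sum((X[j] - V[i]) ** 2) for j in range(15)
            )
            den = sum(W[i, j] ** 2 for j in range(15))
            assert eta[i] == pytest.approx(num / den)


class TestThresholds:
    def test_identical_gap_recovered(self):
        nu = np.array([[0.9, 0.8, 0.7], [0.6, 0.5, 0.4]])  # gap 0.3 everywhere
        d1, _ = thresholds(nu)
        assert d1 == pytest.approx(0.3)

    def test_hand_computed_two_objects(self):
        # gaps 0.8 and 0.2 -> delta1 = 0.5; only object 2 (gap <= 0.5)
        # contributes its top membership 0.6 to delta2
        nu = np.array([[0.9, 0.6], [0.1, 0.4]])
        d1, d2 = thresholds(nu)
        assert d1 == pytest.approx(0.5)
        assert d2 == pytest.approx(0.6)

    def test_single_object_is_always_ambiguous(self):
        # with one object delta1 equals its own gap, and the comparison is
        # inclusive, so the object counts toward delta2
        nu = np.array([[0.8], [0.3]])
        d1, d2 = thresholds(nu)
        assert d1 == pytest.approx(0.5)
        assert d2 == pytest.approx(0.8)


class TestAssignRegions:
    def test_clear_winner_goes_to_lower(self):
        nu = np.array([[0.9], [0.05]])
        lower, boundary = assign_regions(nu, 0.5, 0.5)
        assert lower[0] == 0
        assert not boundary.any()

    def test_ambiguous_object_spans_two_boundaries(self):
        nu = np.array([[0.6], [0.55], [0.1]])
        lower, boundary = assign_regions(nu, 0.2, 0.5)
        assert lower[0] == -1
        assert boundary[:, 0].tolist() == [True, True, False]

    def test_weak_second_stays_out(self):
        nu = np.array([[0.3], [0.29]])
        lower, boundary = assign_regions(nu, 0.2, 0.5)
        assert lower[0] == -1
        assert boundary[:, 0].tolist() == [True, False]

    def test_every_object_tagged_and_regions_disjoint(self, rng):
        nu = rng.uniform(0.01, 1.0, size=(4, 60))
        lower, boundary = assign_regions(nu, 0.15, 0.4)
        in_lower = lower >= 0
        in_boundary = boundary.any(axis=0)
        assert np.all(in_lower | in_boundary)
        assert not np.any(in_lower & in_boundary)


class TestCentroidsAndObjective:
    def test_lower_only_is_possibilistic_weighted_mean(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        nu = np.array([[0.9, 0.8, 0.2, 0.1]])
        lower = np.zeros(4, dtype=int)
        boundary = np.zeros((1, 4), dtype=bool)
        mu = np.ones((1, 4))
        V = update_centroids(X, nu, mu, lower, boundary, np.zeros((1, 1)), omega=0.99)
        w = nu[0] ** 2
        assert V[0, 0] == pytest.approx((w * X[:, 0]).sum() / w.sum())

    def test_omega_one_ignores_boundary(self):
        X = np.array([[0.0], [10.0], [100.0]])
        nu = np.array([[0.9, 0.8, 0.1]])
        mu = np.array([[0.2, 0.3, 1.0]])
        lower = np.array([0, 0, -1])
        boundary = np.array([[False, False, True]])
        V1 = update_centroids(X, nu, mu, lower, boundary, np.zeros((1, 1)), omega=1.0)
        w = nu[0, :2] ** 2
        assert V1[0, 0] == pytest.approx((w * X[:2, 0]).sum() / w.sum())

    def test_hand_computed_mixed_update(self):
        X = np.array([[0.0], [2.0], [10.0], [14.0]])
        nu = np.array([[0.9, 0.7, 0.3, 0.2]])
        mu = np.array([[0.1, 0.2, 0.6, 0.8]])
        lower = np.array([0, 0, -1, -1])
        boundary = np.array([[False, False, True, True]])
        omega = 0.7
        V = update_centroids(X, nu, mu, lower, boundary, np.zeros((1, 1)), omega=omega)
        C1 = (0.81 * 0.0 + 0.49 * 2.0) / (0.81 + 0.49)
        D1 = (0.36 * 10.0 + 0.64 * 14.0) / (0.36 + 0.64)
        assert V[0, 0] == pytest.approx(omega * C1 + (1 - omega) * D1)

    def test_objective_zero_at_perfect_lower_fit(self):
        X = np.array([[1.0], [1.0], [5.0]])
        V = np.array([[1.0], [5.0]])
        nu = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        lower = np.array([0, 0, 1])
        boundary = np.zeros((2, 3), dtype=bool)
        mu = np.zeros((2, 3))
        eta = np.array([1.0, 1.0])
        J = objective(X, V, nu, mu, eta, lower, boundary)
        assert J == pytest.approx(0.0)

    def test_all_boundary_reduces_to_fcm_objective(self, rng):
        X = rng.random((12, 2))
        V = rng.random((2, 2))
        mu = fcm_membership(X, V)
        nu = np.full((2, 12), 0.5)
        eta = np.array([1.0, 1.0])
        lower = np.full(12, -1)
        boundary = np.ones((2, 12), dtype=bool)
        J = objective(X, V, nu, mu, eta, lower, boundary, omega=0.99)
        d2 = ((X[:, None] - V[None]) ** 2).sum(axis=2).T
        fcm_J = float((mu**2 * d2).sum())
        assert J == pytest.approx(fcm_J)  # bare B1 branch, no omega weight

    def test_objective_matches_term_by_term_oracle(self, rng):
        X = rng.random((10, 2))
        V = rng.random((2, 2))
        eta = np.array([0.4, 0.7])
        nu = pcm_membership(X, V, eta)
        mu = fcm_membership(X, V)
        lower = np.array([0, 1, -1, 0, -1, 1, 0, -1, 1, 0])
        boundary = np.zeros((2, 10), dtype=bool)
        boundary[:, lower < 0] = True
        omega, m1, m2 = 0.9, 2.0, 2.0
        J = objective(X, V, nu, mu, eta, lower, boundary, omega, m1, m2)
        A1 = B1 = 0.0
        for i in range(2):
            for j in range(10):
                d2 = float(((X[j] - V[i]) ** 2).sum())
                if lower[j] == i:
                    A1 += nu[i, j] ** m2 * d2 + eta[i] * (1 - nu[i, j]) ** m2
                if boundary[i, j]:
                    B1 += mu[i, j] ** m1 * d2
        assert J == pytest.approx(omega * A1 + (1 - omega) * B1)


def _fcm_reference(X, V0, m1, n_steps):
    """Plain fuzzy c-means iterations (independent reference)."""
    V = V0.copy()
    trail = []
    for _ in range(n_steps):
        mu = fcm_membership(X, V, m1)
        w = mu**m1
        V = (w @ X) / w.sum(axis=1, keepdims=True)
        trail.append(V.copy())
    return trail


class TestRRFCM:
    def test_recovers_well_separated_blobs(self):
        X, truth = make_cloud_fixture(c=3, n_per=80, separation=40.0, sigma=1.0, seed=3)
        result = rrfcm(X, c=3, seed=3)
        # adjusted agreement must be perfect up to label permutation
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, result.labels) == 1.0

    def test_fcm_limit_when_everything_is_boundary(self):
        """Forcing delta1=1, delta2=0 puts every object in every boundary;
        the centroid sequence must match plain FCM from the same init."""
        X, _ = make_cloud_fixture(c=2, n_per=40, separation=6.0, sigma=1.5, seed=11)
        V0 = hcm(X, 2, seed=11)
        steps = 6
        result = rrfcm(
            X,
            c=2,
            seed=11,
            init_centroids=V0,
            delta1_override=1.0,
            delta2_override=0.0,
            max_iter=steps,
            tol=0.0,
            record_trace=True,
        )
        ref = _fcm_reference(X, V0, m1=2.0, n_steps=steps)
        for got, want in zip(result.centroid_trace, ref):
            assert np.allclose(got, want, atol=1e-8)

    def test_pcm_limit_when_everything_is_lower(self):
        """Forcing delta1=0 sends every object to the lower approximation of
        its argmax cluster; centroids must equal the possibilistic
        nu^m2-weighted means of those objects."""
        X, _ = make_cloud_fixture(c=2, n_per=40, separation=25.0, sigma=1.0, seed=13)
        V0 = hcm(X, 2, seed=13)
        result = rrfcm(
            X,
            c=2,
            seed=13,
            init_centroids=V0,
            delta1_override=0.0,
            delta2_override=0.0,
            max_iter=1,
            tol=0.0,
            record_trace=True,
        )
        # reconstruct the expected single update by hand
        from rfseg.cluster import scale_parameters as sp

        eta = sp(X, V0, fcm_membership(X, V0, 2.0), m2=2.0)
        nu = pcm_membership(X, V0, eta, 2.0)
        best = nu.argmax(axis=0)
        expected = np.stack(
            [
                (nu[i, best == i][:, None] ** 2 * X[best == i]).sum(axis=0)
                / (nu[i, best == i] ** 2).sum()
                for i in range(2)
            ]
        )
        assert np.allclose(result.centroid_trace[0], expected, atol=1e-8)
        assert np.all(result.lower_label >= 0)

    def test_membership_constraints_hold(self):
        X, _ = make_cloud_fixture(c=3, n_per=50, separation=8.0, sigma=2.0, seed=17)
        result = rrfcm(X, c=3, seed=17)
        assert np.all(result.nu > 0) and np.all(result.nu <= 1)
        in_boundary = result.boundary.any(axis=0)
        if in_boundary.any():
            assert np.allclose(result.mu[:, in_boundary].sum(axis=0), 1.0)
        # lower regions pairwise disjoint and disjoint from boundaries
        assert not np.any((result.lower_label >= 0) & in_boundary)

    def test_duplicated_point_cloud_terminates_without_nan(self):
        X = np.tile([[2.0, 3.0]], (40, 1)) + 1e-9 * np.arange(80).reshape(40, 2)
        result = rrfcm(X, c=2, seed=1, max_iter=30)
        assert np.isfinite(result.centroids).all()
        assert np.isfinite(result.objective)

    def test_object_order_invariance(self):
        X, _ = make_cloud_fixture(c=2, n_per=60, separation=30.0, sigma=1.0, seed=19)
        V0 = hcm(X, 2, seed=19)
        perm = np.random.default_rng(0).permutation(len(X))
        r1 = rrfcm(X, c=2, init_centroids=V0)
        r2 = rrfcm(X[perm], c=2, init_centroids=V0)
        d = np.linalg.norm(r1.centroids[:, None] - r2.centroids[None], axis=2)
        assert d.min(axis=1).max() < 1e-5

    def test_deterministic_for_fixed_seed(self):
        X, _ = make_cloud_fixture(c=3, n_per=40, separation=10.0, sigma=2.0, seed=23)
        r1 = rrfcm(X, c=3, seed=23)
        r2 = rrfcm(X, c=3, seed=23)
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.centroids, r2.centroids)

    def test_input_validation(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            rrfcm(X, c=4)
        with pytest.raises(ValueError):
            rrfcm(X, c=1)
        with pytest.raises(ValueError):
            rrfcm(X, c=2, omega=0.0)


class TestEstimator:
    def test_fit_predict_roundtrip(self):
        X, truth = make_cloud_fixture(c=3, n_per=60, separation=40.0, sigma=1.0, seed=29)
        est = RobustRoughFuzzyCMeans(n_clusters=3, random_state=29).fit(X)
        assert est.labels_.shape == (180,)
        assert est.cluster_centers_.shape == (3, 3)
        # predict on the training data agrees with the hard labels for
        # well-separated clouds
        assert (est.predict(X) == est.labels_).mean() > 0.99

    def test_get_set_params(self):
        est = RobustRoughFuzzyCMeans(omega=0.95)
        assert est.get_params()["omega"] == 0.95
        est.set_params(n_clusters=4)
        assert est.n_clusters == 4
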