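"""Minimum-Mahalanobis decoder and proportional control."""

import numpy as np
import pytest

from myoarm.classifier import (CLASSES, ClassifierModel, classify,
                               compute_centers, compute_normalization,
                               load_model, mahalanobis_distances,
                               proportional_control, save_model, train)
from myoarm.features import FEATURES_PER_CHANNEL


def _toy_model(centers, normalization=None, n_features=None, eq1="squared"):
    """Hand-built model for PC arithmetic tests (identity covariance)."""
    centers = np.asarray(centers, dtype=float)
    n_classes, n_ch = centers.shape
    p = n_features or n_ch
    if normalization is None:
        normalization = np.sum(centers**2, axis=1)
    return ClassifierModel(
        classes=CLASSES[:n_classes], class_means=np.zeros((n_classes, p)),
        pooled_covariance=np.eye(p), shrinkage=0.0, centers=centers,
        normalization=np.asarray(normalization, dtype=float), n_channels=n_ch,
        feature_order=tuple(f"f{k}" for k in range(p)),
        thresholds=np.zeros(n_ch), eq1_variant=eq1,
    )


class TestCentersAndNormalization:
    def test_center_is_mean_of_training_mavs(self):
        s = compute_centers([np.array([[1.0], [2.0], [3.0]])])
        assert s[0, 0] == 2.0

    def test_single_window_center(self):
        assert compute_centers([np.array([[0.7]])])[0, 0] == 0.7

    def test_silent_channel_flagged(self):
        with pytest.warns(UserWarning, match="silent"):
            s = compute_centers([np.zeros((3, 2))])
        assert np.array_equal(s, np.zeros((1, 2)))

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="class 0"):
            compute_centers([np.empty((0, 2))])

    @pytest.mark.parametrize("row, expected", [
        ([3.0, 4.0], 25.0),
        ([1.0] * 12, 12.0),
    ])
    def test_normalization(self, row, expected):
        assert compute_normalization(np.array(row)) == expected

    def test_zero_row_flagged(self):
        with pytest.warns(UserWarning, match="unusable"):
            assert compute_normalization(np.zeros(4)) == 0.0


class TestProportionalControl:
    def test_hand_example(self):
        """S = [2], C = 4, MAV = [2]: PC = (1/4)(2·4) = 2."""
        m = _toy_model([[2.0]], normalization=[4.0])
        assert proportional_control(np.array([2.0]), m, 0) == 2.0

    def test_zero_mav_gives_zero(self):
        m = _toy_model([[2.0, 1.0]])
        assert proportional_control(np.zeros(2), m, 0) == 0.0

    def test_quadratic_intensity_scaling(self, rng):
        m = _toy_model([rng.uniform(0.1, 1.0, size=6)])
        mv = rng.uniform(0.1, 1.0, size=6)
        pc1 = proportional_control(mv, m, 0)
        pc2 = proportional_control(2.0 * mv, m, 0)
        assert pc2 == pytest.approx(4.0 * pc1)

    def test_monotone_in_each_channel(self, rng):
        m = _toy_model([rng.uniform(0.0, 1.0, size=5)])
        mv = rng.uniform(0.0, 1.0, size=5)
        pc = proportional_control(mv, m, 0)
        for j in range(5):
            bumped = mv.copy()
            bumped[j] += 0.3
            assert proportional_control(bumped, m, 0) >= pc

    def test_dot_variant_is_unity_at_center(self, rng):
        s = rng.uniform(0.2, 1.0, size=8)
        m = _toy_model([s], eq1="dot")
        assert proportional_control(s, m, 0) == pytest.approx(1.0)

    def test_zero_normalization_warns(self):
        m = _toy_model([[0.0, 0.0]])
        with pytest.warns(UserWarning):
            assert proportional_control(np.ones(2), m, 0) == 0.0


def _gaussian_classes(rng, means, n=60, sd=0.5):
    return [rng.normal(mu, sd, size=(n, len(mu))) for mu in means]


class TestTrain:
    def test_class_means_match_hand_computation(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        b = a + 10.0
        c = a - 10.0
        model = train([a, b, c], shrinkage=0.5)
        assert np.allclose(model.class_means[0], [3.0, 4.0])
        assert np.allclose(model.class_means[1], [13.0, 14.0])

    def test_pooled_covariance_against_two_loop_oracle(self, rng):
        """Pooled Σ equals the brute-force within-class scatter / (N − g)."""
        arrays = _gaussian_classes(rng, [[0, 0, 0], [2, 2, 2], [4, 0, 4]], n=5)
        model = train(arrays, shrinkage=0.0)
        p = 3
        scatter = np.zeros((p, p))
        n_total = 0
        for a in arrays:
            mu = a.mean(axis=0)
            for row in a:
                d = (row - mu)[:, None]
                scatter += d @ d.T
            n_total += a.shape[0]
        assert np.allclose(model.pooled_covariance, scatter / (n_total - 3))

    def test_separated_clusters_classify_perfectly(self, rng):
        arrays = _gaussian_classes(rng, [[0, 0], [10, 0], [0, 10]], sd=0.5)
        model = train(arrays, shrinkage=0.1)
        for i, a in enumerate(arrays):
            for x in a:
                assert classify(x, model).class_index == i

    def test_singular_covariance_suggests_more_shrinkage(self, rng):
        col = rng.normal(size=(10, 1))
        arrays = [np.hstack([col, col]),          # perfectly collinear features
                  np.hstack([col, col]) + 5.0,
                  np.hstack([col, col]) - 5.0]
        with pytest.raises(ValueError, match="shrinkage"):
            train(arrays, shrinkage=0.0)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            train([np.ones((1, 2)), np.ones((2, 2)), np.ones((2, 2))])


class TestClassify:
    def test_class_mean_has_zero_distance(self, rng):
        arrays = _gaussian_classes(rng, [[0, 0], [5, 5], [9, 0]])
        model = train(arrays)
        d = classify(model.class_means[1], model)
        assert d.class_index == 1
        assert d.distances[1] == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_matches_euclidean_oracle(self, rng):
        """With Σ = I the decision rule is nearest Euclidean mean."""
        means = rng.normal(size=(3, 4))
        model = _toy_model(np.abs(means), n_features=4)
        model.class_means = means
        for x in rng.normal(size=(100, 4)):
            euclid = int(np.argmin(np.linalg.norm(x - means, axis=1)))
            assert classify(x, model).class_index == euclid

    def test_tie_prefers_no_movement(self):
        model = _toy_model(np.ones((3, 1)))
        model.class_means = np.array([[-1.0], [1.0], [9.0]])
        assert classify(np.array([0.0]), model).class_label == "no_movement"

    def test_tie_between_movements_takes_lower_index(self):
        model = _toy_model(np.ones((3, 1)))
        model.class_means = np.array([[9.0], [-1.0], [1.0]])
        assert classify(np.array([0.0]), model).class_label == "abduction"

    def test_feature_length_mismatch_rejected(self, rng):
        model = train(_gaussian_classes(rng, [[0, 0], [5, 5], [9, 0]]))
        with pytest.raises(ValueError, match="length"):
            classify(np.zeros(5), model)

    def test_affine_rescaling_invariance(self, rng):
        """Consistently rescaling features leaves all distances unchanged."""
        arrays = _gaussian_classes(rng, [[0, 0, 0], [3, 1, 2], [1, 4, 0]], n=40)
        model = train(arrays, shrinkage=0.0)
        scale = rng.uniform(0.2, 5.0, size=3)
        model_s = train([a * scale for a in arrays], shrinkage=0.0)
        for x in rng.normal(size=(20, 3)):
            d0 = mahalanobis_distances(x, model)
            d1 = mahalanobis_distances(x * scale, model_s)
            assert np.allclose(d0, d1, rtol=1e-8)


class TestSerialization:
    def test_round_trip_identical_decisions(self, rng, tmp_path):
        n_ch = 3
        p = n_ch * FEATURES_PER_CHANNEL
        arrays = [rng.normal(mu, 1.0, size=(50, p))
                  for mu in (0.0, 3.0, -3.0)]
        model = train(arrays, shrinkage=0.1)
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        xs = rng.normal(size=(1000, p))
        for x in xs:
            a, b = classify(x, model), classify(x, loaded)
            assert a.class_index == b.class_index
            assert a.pc == pytest.approx(b.pc, rel=1e-12)
            assert np.allclose(a.distances, b.distances)
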