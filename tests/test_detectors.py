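"""One-class detectors: deep SVDD against analytic oracles, classic SVDD
against a brute-force dual solution."""

import itertools

import numpy as np
import pytest

from ecgtensor.detectors import (
    DeepSVDDConfig,
    classic_svdd_scores,
    deep_svdd_scores,
    fit_classic_svdd,
    fit_deep_svdd,
    load_deep_svdd,
    save_deep_svdd,
    score_classic_svdd,
    score_deep_svdd,
)

IDENTITY = DeepSVDDConfig(identity=True, standardize=False, center_floor=0.0)


@pytest.fixture
def gaussian_features(rng):
    return rng.normal(size=(120, 6))


class TestDeepSVDD:
    def test_identity_network_scores_distance_to_mean(self, gaussian_features):
        model = fit_deep_svdd(gaussian_features, IDENTITY)
        mean = gaussian_features.mean(axis=0)
        scores = deep_svdd_scores(model, gaussian_features)
        oracle = np.sum((gaussian_features - mean) ** 2, axis=1)
        np.testing.assert_allclose(scores, oracle, atol=1e-8)

    def test_identity_network_homogeneity(self, gaussian_features):
        model = fit_deep_svdd(gaussian_features, IDENTITY)
        mean = gaussian_features.mean(axis=0)
        x = gaussian_features[3]
        s1 = score_deep_svdd(model, x).score
        s2 = score_deep_svdd(model, mean + 2.0 * (x - mean)).score
        assert s2 == pytest.approx(4.0 * s1, rel=1e-10)

    def test_identity_ranking_matches_distance_ranking(self, gaussian_features, rng):
        model = fit_deep_svdd(gaussian_features, IDENTITY)
        probes = rng.normal(size=(50, 6))
        scores = deep_svdd_scores(model, probes)
        dists = np.sum((probes - gaussian_features.mean(0)) ** 2, axis=1)
        assert np.array_equal(np.argsort(scores), np.argsort(dists))

    def test_seeded_training_is_reproducible(self, gaussian_features):
        cfg = DeepSVDDConfig(seed=11, epochs=5)
        a = fit_deep_svdd(gaussian_features, cfg)
        b = fit_deep_svdd(gaussian_features, cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(
            deep_svdd_scores(a, gaussian_features), deep_svdd_scores(b, gaussian_features)
        )

    def test_training_objective_non_increasing_overall(self, gaussian_features):
        model = fit_deep_svdd(gaussian_features, DeepSVDDConfig(seed=0))
        hist = model.objective_history
        assert hist[-1] <= hist[0]

    def test_far_outliers_score_above_all_training_points(self, rng):
        normals = rng.normal(scale=0.1, size=(200, 2))
        radius = np.linalg.norm(normals, axis=1).max()
        directions = rng.normal(size=(20, 2))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        outliers = 10.0 * radius * directions
        model = fit_deep_svdd(normals, DeepSVDDConfig(seed=3))
        train_scores = deep_svdd_scores(model, normals)
        outlier_scores = deep_svdd_scores(model, outliers)
        assert outlier_scores.min() > train_scores.max()

    def test_scores_independent_of_batch_order(self, gaussian_features, rng):
        model = fit_deep_svdd(gaussian_features, DeepSVDDConfig(seed=1, epochs=3))
        perm = rng.permutation(len(gaussian_features))
        scores = deep_svdd_scores(model, gaussian_features)
        np.testing.assert_allclose(scores[perm],
                                   deep_svdd_scores(model, gaussian_features[perm]),
                                   atol=1e-12)

    def test_threshold_flags_scores_above_training_quantile(self, gaussian_features):
        model = fit_deep_svdd(gaussian_features, DeepSVDDConfig(seed=2, epochs=3))
        res = score_deep_svdd(model, gaussian_features[0])
        assert res.is_anomaly == (res.score > model.threshold)

    def test_invalid_inputs_rejected(self, gaussian_features):
        with pytest.raises(ValueError):
            fit_deep_svdd(np.array([[np.nan, 1.0], [0.0, 1.0]]))
        model = fit_deep_svdd(gaussian_features, DeepSVDDConfig(seed=0, epochs=1))
        with pytest.raises(ValueError):
            deep_svdd_scores(model, np.zeros((3, 9)))

    def test_persistence_roundtrip(self, tmp_path, gaussian_features):
        model = fit_deep_svdd(gaussian_features, DeepSVDDConfig(seed=4, epochs=3))
        save_deep_svdd(model, tmp_path / "m.npz")
        back = load_deep_svdd(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            deep_svdd_scores(model, gaussian_features),
            deep_svdd_scores(back, gaussian_features),
        )


def brute_force_svdd_dual(x: np.ndarray, gamma: float, sigma: float) -> np.ndarray:
    """Two-stage grid search of the 3-point SVDD dual over the simplex."""
    d2 = (x[:, None, :] - x[None, :, :]) ** 2
    kmat = np.exp(-d2.sum(-1) / (2 * sigma**2))
    diag = np.diag(kmat)

    def dual(a):
        return diag @ a - a @ kmat @ a

    best, best_val = None, -np.inf
    for step, center in [(0.01, None), (1e-4, "refine")]:
        if center is None:
            a1_range = np.arange(0, 1 + step, step)
        else:
            a1_range = np.arange(max(best[0] - 0.02, 0), min(best[0] + 0.02, 1) + step, step)
        for a1 in a1_range:
            if center is None:
                a2_range = np.arange(0, 1 - a1 + step, step)
            else:
                a2_range = np.arange(max(best[1] - 0.02, 0),
                                     min(best[1] + 0.02, 1 - a1) + step, step)
            for a2 in a2_range:
                a3 = 1.0 - a1 - a2
                if a3 < -1e-12 or a1 > gamma or a2 > gamma or a3 > gamma:
                    continue
                a = np.array([a1, a2, max(a3, 0.0)])
                v = dual(a)
                if v > best_val:
                    best_val, best = v, a
    return best


class TestClassicSVDD:
    def test_three_point_dual_matches_brute_force(self):
        x = np.array([[0.0], [1.0], [2.5]])
        sigma = 1.0
        model = fit_classic_svdd(x, gamma=1.0, sigma=sigma)
        oracle = brute_force_svdd_dual(x, 1.0, sigma)
        np.testing.assert_allclose(model.alphas, oracle, atol=1e-3)

    def test_symmetric_pair_splits_equally(self):
        x = np.array([[-1.5], [1.5]])
        model = fit_classic_svdd(x, gamma=1.0, sigma=1.0)
        np.testing.assert_allclose(model.alphas, [0.5, 0.5], atol=1e-6)
        d = classic_svdd_scores(model, x)
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_identical_points_collapse_to_zero_radius(self):
        x = np.zeros((5, 2))
        model = fit_classic_svdd(x, gamma=1.0)
        assert model.radius_sq == pytest.approx(0.0, abs=1e-9)
        assert not score_classic_svdd(model, x[0]).is_anomaly

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 1.0])
    def test_soft_margin_outside_fraction_bound(self, rng, gamma):
        x = rng.normal(size=(60, 2))
        model = fit_classic_svdd(x, gamma=gamma)
        d = classic_svdd_scores(model, x)
        outside = np.sum(d > model.radius_sq + 1e-9)
        # points strictly outside have alpha = gamma, and the alphas sum to 1
        assert outside / len(x) <= 1.0 / (gamma * len(x)) + 1e-12

    def test_scores_are_non_negative(self, rng):
        x = rng.normal(size=(30, 3))
        model = fit_classic_svdd(x, gamma=0.5)
        assert np.all(classic_svdd_scores(model, rng.normal(size=(10, 3))) >= 0)

    def test_infeasible_gamma_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_classic_svdd(x, gamma=0.05)  # gamma <= 1/N0
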