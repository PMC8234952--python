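"""Multilinear PCA: oracles (PCA, Kronecker), convergence, and feature ranking."""

import numpy as np
import pytest

from ecgtensor.mpca import (
    featurize,
    fit_mpca,
    load_mpca,
    project,
    save_mpca,
    transform,
)


def _random_tensors(rng, n=8, shape=(5, 4, 3)):
    return rng.normal(size=(n, *shape))


class TestFitProject:
    def test_full_rank_projection_reconstructs_centered_inputs(self, rng):
        x = _random_tensors(rng)
        model = fit_mpca(x, variance_keep=x.shape[1:], p=np.prod(x.shape[1:]))
        centered = x - x.mean(axis=0)
        total = 0.0
        for t, c in zip(x, centered):
            core = project(model, t)
            recon = core
            for k, u in enumerate(model.factors):
                recon = np.moveaxis(np.tensordot(u, recon, axes=(1, k)), 0, k)
            np.testing.assert_allclose(recon, c, atol=1e-10)
            total += np.sum(core**2)
        assert total == pytest.approx(np.sum(centered**2), rel=1e-10)

    def test_degenerate_one_mode_case_matches_pca(self, rng):
        vecs = rng.normal(size=(40, 6)) @ np.diag([3.0, 2.0, 1.5, 1.0, 0.5, 0.2])
        tensors = vecs[:, :, None, None]
        model = fit_mpca(tensors, variance_keep=(4, 1, 1), p=4)
        centered = vecs - vecs.mean(axis=0)
        # independent oracle: eigendecomposition of the sample scatter matrix
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        top = evecs[:, np.argsort(evals)[::-1][:4]]
        for k in range(4):
            dot = abs(model.factors[0][:, k] @ top[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_projection_matches_kronecker_oracle(self, rng):
        x = rng.normal(size=(8, 6, 6, 3))
        model = fit_mpca(x, variance_keep=(2, 3, 2), p=12)
        u1, u2, u3 = model.factors
        big = np.kron(u3.T, np.kron(u2.T, u1.T))  # acts on column-major vec
        for t in x:
            core = project(model, t)
            oracle = big @ (t - model.mean).flatten(order="F")
            np.testing.assert_allclose(core.flatten(order="F"), oracle, atol=1e-10)

    def test_shared_rank_one_structure_fully_captured(self, rng):
        u, v, w = (rng.normal(size=d) for d in (5, 4, 3))
        coeffs = rng.normal(size=12)
        x = np.stack([c * np.einsum("i,j,k->ijk", u, v, w) for c in coeffs])
        model = fit_mpca(x, variance_keep=(1, 1, 1), p=1)
        centered_norm = np.sum((x - x.mean(0)) ** 2)
        assert model.scatter_history[-1] / centered_norm >= 1 - 1e-10

    def test_mean_tensor_projects_to_zero(self, rng):
        x = _random_tensors(rng)
        model = fit_mpca(x, variance_keep=(2, 2, 2), p=4)
        np.testing.assert_allclose(project(model, model.mean), 0.0, atol=1e-12)

    def test_projection_invariant_to_mode_order(self, rng):
        x = _random_tensors(rng)
        model = fit_mpca(x, variance_keep=(3, 2, 2), p=6)
        t = rng.normal(size=x.shape[1:]) - model.mean
        orders = [(0, 1, 2), (2, 1, 0), (1, 0, 2)]
        results = []
        for order in orders:
            core = t.copy()
            for k in order:
                core = np.moveaxis(
                    np.tensordot(model.factors[k].T, core, axes=(1, k)), 0, k
                )
            results.append(core)
        for r in results[1:]:
            np.testing.assert_allclose(r, results[0], atol=1e-10)


class TestConvergenceProperties:
    def test_scatter_history_non_decreasing(self, rng):
        for _ in range(10):
            x = _random_tensors(rng, n=6)
            model = fit_mpca(x, variance_keep=(3, 2, 2), p=5)
            diffs = np.diff(model.scatter_history)
            assert np.all(diffs >= -1e-8 * model.scatter_history[0])

    def test_factors_column_orthonormal(self, rng):
        x = _random_tensors(rng, n=10)
        model = fit_mpca(x, variance_keep=0.9, p=2)
        for u in model.factors:
            np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-10)

    def test_nesting_larger_dims_capture_no_less_scatter(self, rng):
        x = _random_tensors(rng, n=6, shape=(4, 3, 2))
        big = fit_mpca(x, variance_keep=(2, 2, 2), p=1).scatter_history[-1]
        for dims in [(1, 2, 2), (2, 1, 2), (2, 2, 1), (1, 1, 1)]:
            small = fit_mpca(x, variance_keep=dims, p=1).scatter_history[-1]
            assert big >= small - 1e-10

    def test_seeded_refit_is_identical(self, rng):
        x = _random_tensors(rng)
        a = fit_mpca(x, variance_keep=(2, 2, 2), p=4)
        b = fit_mpca(x, variance_keep=(2, 2, 2), p=4)
        for ua, ub in zip(a.factors, b.factors):
            np.testing.assert_array_equal(ua, ub)


class TestFeaturize:
    def test_full_p_is_a_permutation_of_the_core(self, rng):
        x = _random_tensors(rng)
        n_core = 8
        model = fit_mpca(x, variance_keep=(2, 2, 2), p=n_core)
        core = project(model, x[0])
        feat = featurize(model, core)
        assert sorted(feat) == sorted(core.reshape(-1))

    def test_zero_core_gives_zero_features(self, rng):
        x = _random_tensors(rng)
        model = fit_mpca(x, variance_keep=(2, 2, 2), p=3)
        np.testing.assert_array_equal(featurize(model, np.zeros(model.dims)), 0.0)

    def test_ranking_keeps_the_dominant_coordinate(self, rng):
        # first axis coordinate carries ~99% of the scatter by construction
        n = 30
        x = np.zeros((n, 3, 1, 1))
        x[:, 0, 0, 0] = rng.normal(scale=10.0, size=n)
        x[:, 1, 0, 0] = rng.normal(scale=0.1, size=n)
        x[:, 2, 0, 0] = rng.normal(scale=0.1, size=n)
        model = fit_mpca(x, variance_keep=(3, 1, 1), p=1)
        feats = transform(model, x)[:, 0]
        dominant = x[:, 0, 0, 0] - x[:, 0, 0, 0].mean()
        corr = np.corrcoef(feats, dominant)[0, 1]
        assert abs(corr) > 0.999

    def test_invalid_inputs_rejected(self, rng):
        x = _random_tensors(rng)
        with pytest.raises(ValueError):
            fit_mpca(x[:1], variance_keep=(2, 2, 2), p=2)
        with pytest.raises(ValueError):
            fit_mpca(x, variance_keep=(2, 2, 2), p=100)
        model = fit_mpca(x, variance_keep=(2, 2, 2), p=4)
        with pytest.raises(ValueError):
            project(model, np.zeros((9, 9, 9)))


def test_model_persistence_roundtrip(tmp_path, rng):
    x = _random_tensors(rng)
    model = fit_mpca(x, variance_keep=(2, 2, 2), p=4)
    save_mpca(model, tmp_path / "m.npz")
    back = load_mpca(tmp_path / "m.npz")
    np.testing.assert_array_equal(transform(model, x), transform(back, x))
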