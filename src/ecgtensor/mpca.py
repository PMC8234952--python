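"""Multilinear PCA: mode-wise orthogonal projections maximizing total scatter.

Given N tensor samples A⁽ⁱ⁾ of shape I₁×I₂×I₃, MPCA finds column-orthonormal
projection matrices U⁽ᵏ⁾ ∈ R^{Iₖ×Pₖ} maximizing the total tensor scatter
Σᵢ ‖S⁽ⁱ⁾‖²_F of the projected cores

    S⁽ⁱ⁾ = (A⁽ⁱ⁾ − Ā) ×₁ U⁽¹⁾ᵀ ×₂ U⁽²⁾ᵀ ×₃ U⁽³⁾ᵀ.

The solver is the standard alternating scheme: full-projection initialization
from the leading eigenvectors of each mode's unfolding scatter matrix, then
per-mode eigenproblem updates conditioned on the other modes until the
relative scatter change falls below tolerance.  Each alternating step cannot
decrease the objective, so the recorded scatter history is non-decreasing.

Samples are centered by the mean tensor before projection.  For feature
extraction the core is vectorized and its coordinates ranked by their scatter
across the training set, descending; the first ``p`` ranked coordinates form
the feature vector ϑ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MPCAModel",
    "fit_mpca",
    "project",
    "featurize",
    "transform",
    "save_mpca",
    "load_mpca",
]


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k unfolding: rows index mode ``mode``, columns the rest."""
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def _mode_multiply(t: np.ndarray, mat: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k product t ×ₖ mat, with mat of shape (rows_out, t.shape[mode])."""
    return np.moveaxis(np.tensordot(mat, t, axes=(1, mode)), 0, mode)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (reproducible sign)."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def _leading_eigvecs(scatter: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a symmetric PSD scatter matrix, eigenvalues descending."""
    vals, vecs = np.linalg.eigh(scatter)
    order = np.argsort(vals)[::-1]
    return vals[order][:k], _fix_signs(vecs[:, order[:k]])


@dataclass
class MPCAModel:
    """Fitted projection matrices, mean tensor, and the feature ranking."""

    factors: list[np.ndarray]  # U^(k), shape (I_k, P_k)
    mean: np.ndarray  # shape (I1, I2, I3)
    dims: tuple[int, ...]  # (P1, P2, P3)
    feature_order: np.ndarray  # permutation of the vectorized core by scatter
    p: int  # number of kept features
    scatter_history: np.ndarray  # total scatter per alternation iteration
    feature_scatter: np.ndarray  # per-core-coordinate scatter, model order

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.mean.shape


def _total_scatter(tensors: np.ndarray, factors: list[np.ndarray]) -> float:
    s = 0.0
    for t in tensors:
        core = t
        for k, u in enumerate(factors):
            core = _mode_multiply(core, u.T, k)
        s += float(np.sum(core**2))
    return s


def fit_mpca(
    tensors: np.ndarray,
    variance_keep: float | tuple[int, ...] = 0.97,
    p: int = 10,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> MPCAModel:
    """Fit MPCA to ``tensors`` of shape (N, I₁, I₂, I₃).

    Parameters
    ----------
    variance_keep
        Either per-mode dimensions (P₁, P₂, P₃) or a fraction in (0, 1]: each
        Pₖ is then the smallest dimension retaining at least that fraction of
        the mode-k eigenvalue mass of the full-projection scatter matrix.
    p
        Number of kept entries of the scatter-ranked vectorized core.
    max_iter, tol
        Alternation stops when the relative change in total scatter drops
        below ``tol`` or after ``max_iter`` sweeps.
    """
    tensors = np.asarray(tensors, dtype=float)
    if tensors.ndim < 2:
        raise ValueError("expected an (N, I1, ..., IK) array")
    n = tensors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to fit MPCA")
    shape = tensors.shape[1:]
    n_modes = len(shape)

    mean = tensors.mean(axis=0)
    centered = tensors - mean

    # full-projection scatter per mode and its eigendecomposition
    mode_eigvals: list[np.ndarray] = []
    full_vecs: list[np.ndarray] = []
    for k in range(n_modes):
        unf = np.concatenate([_unfold(t, k) for t in centered], axis=1)
        scatter = unf @ unf.T
        vals, vecs = _leading_eigvecs(scatter, shape[k])
        mode_eigvals.append(np.maximum(vals, 0.0))
        full_vecs.append(vecs)

    if isinstance(variance_keep, (tuple, list)):
        dims = tuple(int(d) for d in variance_keep)
        if len(dims) != n_modes or any(not 1 <= d <= shape[k] for k, d in enumerate(dims)):
            raise ValueError(f"per-mode dims {dims} incompatible with shape {shape}")
    else:
        frac = float(variance_keep)
        if not 0 < frac <= 1:
            raise ValueError("variance_keep fraction must be in (0, 1]")
        dims = []
        for vals in mode_eigvals:
            total = vals.sum()
            if total <= 0:
                dims.append(1)
                continue
            cum = np.cumsum(vals) / total
            dims.append(int(np.searchsorted(cum, frac - 1e-12) + 1))
        dims = tuple(dims)

    n_core = int(np.prod(dims))
    if not 1 <= p <= n_core:
        raise ValueError(f"p must be in [1, {n_core}] (= P1*P2*P3), got {p}")

    factors = [full_vecs[k][:, : dims[k]] for k in range(n_modes)]
    history = [_total_scatter(centered, factors)]

    for _ in range(max_iter):
        for k in range(n_modes):
            # project every sample by all modes but k, accumulate mode-k scatter
            scatter = np.zeros((shape[k], shape[k]))
            for t in centered:
                partial = t
                for j in range(n_modes):
                    if j != k:
                        partial = _mode_multiply(partial, factors[j].T, j)
                unf = _unfold(partial, k)
                scatter += unf @ unf.T
            _, factors[k] = _leading_eigvecs(scatter, dims[k])
        history.append(_total_scatter(centered, factors))
        if history[-2] > 0 and (history[-1] - history[-2]) / history[-2] < tol:
            break

    # rank vectorized-core coordinates by scatter across training samples
    cores = np.stack(
        [
            _project_centered(t, factors)
            for t in centered
        ]
    )
    flat = cores.reshape(n, -1)
    coord_scatter = np.sum(flat**2, axis=0)
    order = np.argsort(-coord_scatter, kind="stable")

    return MPCAModel(
        factors=factors,
        mean=mean,
        dims=dims,
        feature_order=order,
        p=int(p),
        scatter_history=np.asarray(history),
        feature_scatter=coord_scatter,
    )


def _project_centered(t: np.ndarray, factors: list[np.ndarray]) -> np.ndarray:
    core = t
    for k, u in enumerate(factors):
        core = _mode_multiply(core, u.T, k)
    return core


def project(model: MPCAModel, tensor: np.ndarray) -> np.ndarray:
    """Center by the mean tensor and mode-multiply by each U⁽ᵏ⁾ᵀ."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != model.input_shape:
        raise ValueError(f"tensor shape {tensor.shape} != model {model.input_shape}")
    return _project_centered(tensor - model.mean, model.factors)


def featurize(model: MPCAModel, core: np.ndarray) -> np.ndarray:
    """Vectorize a projected core, reorder by scatter rank, keep ``model.p``."""
    core = np.asarray(core, dtype=float)
    if core.shape != model.dims:
        raise ValueError(f"core shape {core.shape} != model dims {model.dims}")
    return core.reshape(-1)[model.feature_order][: model.p]


def transform(model: MPCAModel, tensors: np.ndarray) -> np.ndarray:
    """Convenience: project + featurize a batch of (N, I₁, I₂, I₃) tensors."""
    tensors = np.asarray(tensors, dtype=float)
    return np.stack([featurize(model, project(model, t)) for t in tensors])


def save_mpca(model: MPCAModel, path: str | Path) -> None:
    """Persist a fitted model to a single ``.npz`` archive."""
    np.savez(
        path,
        format_version=1,
        n_modes=len(model.factors),
        mean=model.mean,
        dims=np.asarray(model.dims),
        feature_order=model.feature_order,
        p=model.p,
        scatter_history=model.scatter_history,
        feature_scatter=model.feature_scatter,
        **{f"factor_{k}": u for k, u in enumerate(model.factors)},
    )


def load_mpca(path: str | Path) -> MPCAModel:
    with np.load(path) as z:
        n_modes = int(z["n_modes"])
        return MPCAModel(
            factors=[z[f"factor_{k}"] for k in range(n_modes)],
            mean=z["mean"],
            dims=tuple(int(d) for d in z["dims"]),
            feature_order=z["feature_order"],
            p=int(z["p"]),
            scatter_history=z["scatter_history"],
            feature_scatter=z["feature_scatter"],
        )
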