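"""One-class anomaly scorers trained on normal feature vectors only.

Deep SVDD maps features through a small bias-free multilayer perceptron and
minimizes the mean squared distance of normal samples to a fixed center c in
the latent space,

    min_W  (1/N₀) Σᵢ ‖ϕ(ϑ⁽ⁱ⁾; W) − c‖² + (λ/2) Σ_l ‖W_l‖²_F,

by mini-batch stochastic gradient descent; the anomaly score of a new sample
is its squared latent distance to c.  Omitting biases and bounded output
activations prevents the trivial collapse where the network maps everything
onto c, and affine-free batch normalization on the hidden layers (the
convention of the reference one-class deep architectures) keeps the hidden
representation from contracting uniformly toward zero during training.  The
center is set once, to the mean initial forward pass over the training set
(small entries pushed away from zero), and never updated.

Classic SVDD finds the minimum-volume hypersphere enclosing most of the
normal data in a Gaussian-kernel feature space by solving the dual quadratic
program

    max_α Σᵢ αᵢ K(i,i) − Σᵢⱼ αᵢ αⱼ K(i,j),   0 ≤ αᵢ ≤ γ,  Σ αᵢ = 1,

with the squared kernel distance to the implicit center as the score and the
distance of an interior support vector as the radius R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

__all__ = [
    "DeepSVDDConfig",
    "DeepSVDDModel",
    "ClassicSVDDModel",
    "AnomalyScore",
    "fit_deep_svdd",
    "score_deep_svdd",
    "deep_svdd_scores",
    "fit_classic_svdd",
    "score_classic_svdd",
    "classic_svdd_scores",
    "save_deep_svdd",
    "load_deep_svdd",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class AnomalyScore:
    score: float
    threshold: float

    @property
    def is_anomaly(self) -> bool:
        return self.score > self.threshold


# ---------------------------------------------------------------------------
# Deep SVDD


@dataclass(frozen=True)
class DeepSVDDConfig:
    """Training configuration; all defaults are package choices.

    ``hidden`` lists layer widths after the input (the last entry is the
    latent dimension).  ``identity=True`` builds a single square layer fixed
    to the identity and skips training, which reduces the score to the squared
    distance to the training-feature mean — useful as an analytic reference.
    """

    hidden: tuple[int, ...] = (32, 16)
    batch_norm: bool = True  # affine-free BN on hidden layers
    leaky_slope: float = 0.1
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_decay_at: int = 20  # epoch index at which the rate is multiplied by 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-6
    center_floor: float = 0.1
    standardize: bool = True
    quantile: float = 0.95  # training-score quantile used as the default threshold
    seed: int = 0
    identity: bool = False


@dataclass
class DeepSVDDModel:
    config: DeepSVDDConfig
    weights: list[np.ndarray]
    bn_mean: list[np.ndarray]  # running BN statistics per hidden layer
    bn_var: list[np.ndarray]
    center: np.ndarray
    feat_mean: np.ndarray
    feat_std: np.ndarray
    threshold: float = 0.0
    objective_history: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_train: int = 0


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _forward_eval(model_like, x: np.ndarray) -> np.ndarray:
    """Inference forward pass using the frozen running BN statistics."""
    weights, cfg = model_like.weights, model_like.config
    h = x
    for i, w in enumerate(weights):
        z = h @ w
        if i < len(weights) - 1:
            if cfg.batch_norm:
                z = (z - model_like.bn_mean[i]) / np.sqrt(model_like.bn_var[i] + _BN_EPS)
            h = _leaky(z, cfg.leaky_slope)
        else:
            h = z
    return h


def _objective_eval(model_like, x: np.ndarray, c: np.ndarray, lam: float) -> float:
    out = _forward_eval(model_like, x)
    reg = 0.5 * lam * sum(float(np.sum(w**2)) for w in model_like.weights)
    return float(np.mean(np.sum((out - c) ** 2, axis=1))) + reg


def _train_step(model: DeepSVDDModel, batch: np.ndarray, velocity, lr: float) -> None:
    """One SGD step on a mini-batch: forward with batch BN stats, backprop."""
    cfg = model.config
    weights = model.weights
    n_layers = len(weights)
    m = batch.shape[0]
    lam = cfg.weight_decay

    acts = [batch]  # inputs to each linear layer
    caches = []  # per layer: (z_hat, inv_std) for BN backprop, or None
    h = batch
    for i, w in enumerate(weights):
        z = h @ w
        if i < n_layers - 1:
            if cfg.batch_norm:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                z_hat = (z - mu) * inv_std
                model.bn_mean[i] = (1 - _BN_MOMENTUM) * model.bn_mean[i] + _BN_MOMENTUM * mu
                model.bn_var[i] = (1 - _BN_MOMENTUM) * model.bn_var[i] + _BN_MOMENTUM * var
                caches.append((z_hat, inv_std))
                h = _leaky(z_hat, cfg.leaky_slope)
            else:
                caches.append((z, None))
                h = _leaky(z, cfg.leaky_slope)
        else:
            caches.append((z, None))
            h = z
        acts.append(h)

    delta = 2.0 * (acts[-1] - model.center) / m  # d(mean distance)/d(output)
    grads: list[np.ndarray] = [None] * n_layers
    for i in range(n_layers - 1, -1, -1):
        grads[i] = acts[i].T @ delta + lam * weights[i]
        if i > 0:
            delta = delta @ weights[i].T
            z_prev, inv_std = caches[i - 1]
            delta = np.where(z_prev > 0, delta, cfg.leaky_slope * delta)
            if inv_std is not None:  # through the batch normalization
                z_hat = z_prev
                delta = (
                    inv_std
                    / m
                    * (m * delta - delta.sum(axis=0) - z_hat * np.sum(delta * z_hat, axis=0))
                )
    for w, v, g in zip(weights, velocity, grads):
        v *= cfg.momentum
        v -= lr * g
        w += v


def fit_deep_svdd(features: np.ndarray, config: DeepSVDDConfig | None = None) -> DeepSVDDModel:
    """Train deep SVDD on normal feature vectors of shape (N₀, p)."""
    cfg = config or DeepSVDDConfig()
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("features must be (N0, p) with N0 >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    n, p = x.shape

    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    xs = (x - mean) / std if cfg.standardize else x.copy()

    rng = np.random.default_rng(cfg.seed)
    if cfg.identity:
        weights = [np.eye(p)]
        epochs = 0
    else:
        widths = (p, *cfg.hidden)
        # He-style scaling for the leaky-rectifier layers
        weights = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        epochs = cfg.epochs

    model = DeepSVDDModel(
        config=cfg,
        weights=weights,
        bn_mean=[np.zeros(w.shape[1]) for w in weights[:-1]],
        bn_var=[np.ones(w.shape[1]) for w in weights[:-1]],
        center=np.zeros(weights[-1].shape[1]),
        feat_mean=mean,
        feat_std=std,
        n_train=n,
    )

    # initialize the running BN statistics from one pass over the training set
    if cfg.batch_norm and len(weights) > 1:
        h = xs
        for i, w in enumerate(weights[:-1]):
            z = h @ w
            model.bn_mean[i] = z.mean(axis=0)
            model.bn_var[i] = z.var(axis=0)
            z = (z - model.bn_mean[i]) / np.sqrt(model.bn_var[i] + _BN_EPS)
            h = _leaky(z, cfg.leaky_slope)

    c = _forward_eval(model, xs).mean(axis=0)
    if cfg.center_floor > 0:
        small = np.abs(c) < cfg.center_floor
        c[small] = np.where(c[small] >= 0, cfg.center_floor, -cfg.center_floor)
    model.center = c

    lam = cfg.weight_decay
    history = [_objective_eval(model, xs, c, lam)]
    velocity = [np.zeros_like(w) for w in weights]
    lr = cfg.learning_rate
    for epoch in range(epochs):
        if epoch == cfg.lr_decay_at:
            lr *= 0.1
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = xs[order[start : start + cfg.batch_size]]
            if batch.shape[0] < 2 and cfg.batch_norm:
                continue  # a singleton batch has no usable batch statistics
            _train_step(model, batch, velocity, lr)
        history.append(_objective_eval(model, xs, c, lam))

    model.objective_history = np.asarray(history)
    train_scores = np.sum((_forward_eval(model, xs) - c) ** 2, axis=1)
    model.threshold = float(np.quantile(train_scores, cfg.quantile))
    return model


def deep_svdd_scores(model: DeepSVDDModel, features: np.ndarray) -> np.ndarray:
    """Squared latent distance to the center for a batch of feature vectors."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.feat_mean.size:
        raise ValueError(f"feature length {x.shape[1]} != model input {model.feat_mean.size}")
    if model.config.standardize:
        x = (x - model.feat_mean) / model.feat_std
    out = _forward_eval(model, x)
    return np.sum((out - model.center) ** 2, axis=1)


def score_deep_svdd(model: DeepSVDDModel, feature: np.ndarray) -> AnomalyScore:
    score = float(deep_svdd_scores(model, feature)[0])
    return AnomalyScore(score=score, threshold=model.threshold)


def save_deep_svdd(model: DeepSVDDModel, path: str | Path) -> None:
    cfg = model.config
    np.savez(
        path,
        format_version=2,
        n_layers=len(model.weights),
        center=model.center,
        feat_mean=model.feat_mean,
        feat_std=model.feat_std,
        threshold=model.threshold,
        objective_history=model.objective_history,
        n_train=model.n_train,
        cfg_hidden=np.asarray(cfg.hidden),
        cfg_scalars=np.asarray(
            [cfg.leaky_slope, cfg.epochs, cfg.batch_size, cfg.learning_rate,
             cfg.lr_decay_at, cfg.momentum, cfg.weight_decay, cfg.center_floor,
             float(cfg.standardize), cfg.quantile, cfg.seed, float(cfg.identity),
             float(cfg.batch_norm)]
        ),
        **{f"w_{i}": w for i, w in enumerate(model.weights)},
        **{f"bn_mean_{i}": m for i, m in enumerate(model.bn_mean)},
        **{f"bn_var_{i}": v for i, v in enumerate(model.bn_var)},
    )


def load_deep_svdd(path: str | Path) -> DeepSVDDModel:
    with np.load(path) as z:
        s = z["cfg_scalars"]
        cfg = DeepSVDDConfig(
            hidden=tuple(int(h) for h in z["cfg_hidden"]),
            leaky_slope=float(s[0]), epochs=int(s[1]), batch_size=int(s[2]),
            learning_rate=float(s[3]), lr_decay_at=int(s[4]), momentum=float(s[5]),
            weight_decay=float(s[6]), center_floor=float(s[7]),
            standardize=bool(s[8]), quantile=float(s[9]), seed=int(s[10]),
            identity=bool(s[11]), batch_norm=bool(s[12]),
        )
        n_layers = int(z["n_layers"])
        return DeepSVDDModel(
            config=cfg,
            weights=[z[f"w_{i}"] for i in range(n_layers)],
            bn_mean=[z[f"bn_mean_{i}"] for i in range(n_layers - 1)],
            bn_var=[z[f"bn_var_{i}"] for i in range(n_layers - 1)],
            center=z["center"],
            feat_mean=z["feat_mean"],
            feat_std=z["feat_std"],
            threshold=float(z["threshold"]),
            objective_history=z["objective_history"],
            n_train=int(z["n_train"]),
        )


# ---------------------------------------------------------------------------
# Classic kernel SVDD


@dataclass
class ClassicSVDDModel:
    alphas: np.ndarray  # dual coefficients, one per training sample
    gamma: float  # box bound (volume / slack trade-off)
    sigma: float  # Gaussian kernel bandwidth
    radius_sq: float
    train_features: np.ndarray
    offset: float  # Σ α_i α_j K(i, j), cached for distance evaluation
    threshold: float = 0.0  # = radius_sq; kept explicit for the score API


def _gaussian_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum(a**2, axis=1)[:, None] + np.sum(b**2, axis=1)[None, :] - 2.0 * a @ b.T
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma**2))


def median_heuristic(features: np.ndarray) -> float:
    """Median pairwise distance; a standard default Gaussian bandwidth."""
    d = pdist(np.asarray(features, dtype=float))
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def fit_classic_svdd(
    features: np.ndarray,
    gamma: float = 1.0,
    sigma: float | None = None,
) -> ClassicSVDDModel:
    """Solve the SVDD dual on normal features of shape (N₀, p).

    ``gamma`` must exceed 1/N₀ or the simplex/box constraints are infeasible.
    ``sigma`` defaults to the median pairwise training distance.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("features must be (N0, p)")
    n = x.shape[0]
    if gamma <= 1.0 / n:
        raise ValueError(f"gamma must exceed 1/N0 = {1.0 / n:.4g} for feasibility")
    if sigma is None:
        sigma = median_heuristic(x)
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    kmat = _gaussian_kernel(x, x, sigma)
    diag = np.diag(kmat).copy()

    def neg_dual(a: np.ndarray) -> float:
        return float(a @ kmat @ a - diag @ a)

    def neg_dual_grad(a: np.ndarray) -> np.ndarray:
        return 2.0 * kmat @ a - diag

    res = minimize(
        neg_dual,
        np.full(n, 1.0 / n),
        jac=neg_dual_grad,
        bounds=[(0.0, min(gamma, 1.0))] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(n)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    alphas = np.clip(res.x, 0.0, gamma)
    alphas /= alphas.sum()
    offset = float(alphas @ kmat @ alphas)

    dist_sq = diag - 2.0 * kmat @ alphas + offset
    eps = 1e-8
    interior = (alphas > eps) & (alphas < gamma - eps)
    if interior.any():
        # boundary support vectors share one distance at the exact optimum;
        # take their max so solver round-off never pushes one "outside"
        radius_sq = float(np.max(dist_sq[interior]))
    else:
        radius_sq = float(np.max(dist_sq[alphas > eps]))
    radius_sq = max(radius_sq, 0.0)
    return ClassicSVDDModel(
        alphas=alphas,
        gamma=float(gamma),
        sigma=float(sigma),
        radius_sq=radius_sq,
        train_features=x,
        offset=offset,
        threshold=radius_sq,
    )


def classic_svdd_scores(model: ClassicSVDDModel, features: np.ndarray) -> np.ndarray:
    """Squared kernel-space distance to the hypersphere center."""
    z = np.atleast_2d(np.asarray(features, dtype=float))
    if z.shape[1] != model.train_features.shape[1]:
        raise ValueError("feature length mismatch")
    kzz = np.ones(z.shape[0])  # Gaussian kernel: K(z, z) = 1
    kzx = _gaussian_kernel(z, model.train_features, model.sigma)
    return np.maximum(kzz - 2.0 * kzx @ model.alphas + model.offset, 0.0)


def score_classic_svdd(model: ClassicSVDDModel, feature: np.ndarray) -> AnomalyScore:
    score = float(classic_svdd_scores(model, feature)[0])
    return AnomalyScore(score=score, threshold=model.radius_sq)
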