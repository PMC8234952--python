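"""Hotelling T² control chart for personalized cycle-to-cycle monitoring.

Phase I estimates the in-control mean ϑ̄₀ and covariance S₀ from normal
feature vectors; the monitoring statistic for a new cycle is the squared
Mahalanobis distance

    T² = (ϑ − ϑ̄₀)ᵀ S₀⁻¹ (ϑ − ϑ̄₀).

The upper control limit is the empirical (1−α)·100th percentile of the
Phase-I T² values (linear-interpolation quantile); a Phase-II cycle whose T²
exceeds the UCL is flagged out of control.  Near-singular covariance is
stabilized with a small ridge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["T2Chart", "MonitoringResult", "calibrate", "monitor"]

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e10


@dataclass
class T2Chart:
    mean: np.ndarray  # ϑ̄₀, length p
    cov: np.ndarray  # S₀, (p, p)
    cov_inv: np.ndarray
    alpha: float
    ucl: float
    n_phase1: int
    ridge: float  # ε actually added to the diagonal (0 if none)

    @property
    def p(self) -> int:
        return self.mean.size


@dataclass
class MonitoringResult:
    t2: np.ndarray  # statistic per monitored cycle, arrival order
    out_of_control: np.ndarray  # boolean flags, t2 > ucl
    ucl: float

    @property
    def alarm_fraction(self) -> float:
        return float(self.out_of_control.mean())

    @property
    def alarm_indices(self) -> np.ndarray:
        return np.nonzero(self.out_of_control)[0]

    @property
    def run_lengths(self) -> np.ndarray:
        """Gaps between successive alarms (first entry: cycles to first alarm + 1)."""
        idx = self.alarm_indices
        if idx.size == 0:
            return np.zeros(0, dtype=int)
        return np.diff(np.concatenate([[-1], idx]))


def _t2_stats(x: np.ndarray, mean: np.ndarray, cov_inv: np.ndarray) -> np.ndarray:
    d = x - mean
    return np.einsum("ij,jk,ik->i", d, cov_inv, d)


def calibrate(phase1_features: np.ndarray, alpha: float = 0.05) -> T2Chart:
    """Build a T² chart from Phase-I (in-control) feature vectors (N₀, p)."""
    x = np.asarray(phase1_features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= p:
        raise ValueError(f"Phase I needs more samples than features (N0={n}, p={p})")

    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
    ridge = 0.0
    variances = np.diag(cov)
    if np.any(variances == 0):
        warnings.warn("zero-variance feature in Phase I; applying ridge", stacklevel=2)
    if np.any(variances == 0) or np.linalg.cond(cov) > _COND_LIMIT:
        ridge = 1e-8 * float(np.trace(cov)) / p
        if ridge == 0.0:
            ridge = 1e-12
        cov = cov + ridge * np.eye(p)
        logger.info("covariance ill-conditioned; ridge %.3e applied", ridge)
    cov_inv = np.linalg.inv(cov)

    t2_phase1 = _t2_stats(x, mean, cov_inv)
    ucl = float(np.quantile(t2_phase1, 1.0 - alpha))
    return T2Chart(
        mean=mean, cov=cov, cov_inv=cov_inv, alpha=float(alpha), ucl=ucl,
        n_phase1=n, ridge=ridge,
    )


def monitor(chart: T2Chart, features: np.ndarray) -> MonitoringResult:
    """Score a stream of Phase-II feature vectors against the frozen chart.

    The statistic is identical whether cycles are scored one at a time or in
    batch; results are emitted in arrival order.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != chart.p:
        raise ValueError(f"feature length {x.shape[1]} != chart dimension {chart.p}")
    t2 = _t2_stats(x, chart.mean, chart.cov_inv)
    return MonitoringResult(t2=t2, out_of_control=t2 > chart.ucl, ucl=chart.ucl)


def self_clean(
    phase1_features: np.ndarray, alpha: float = 0.05, trim_fraction: float = 0.01
) -> T2Chart:
    """Calibrate, drop the top ``trim_fraction`` T² cycles once, recalibrate.

    A light guard for unannotated Phase-I data that may contain a few abnormal
    cycles; annotated data should be filtered by its labels instead.
    """
    x = np.asarray(phase1_features, dtype=float)
    first = calibrate(x, alpha=alpha)
    t2 = _t2_stats(x if x.ndim == 2 else x[:, None], first.mean, first.cov_inv)
    cutoff = np.quantile(t2, 1.0 - trim_fraction)
    return calibrate(x[t2 <= cutoff], alpha=alpha)
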