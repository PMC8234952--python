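"""Gramian Angular Difference Field imaging of ECG cycles.

A [0,1]-rescaled series x̃ is mapped to polar angles φ = arccos(x̃) and the
difference field G[i, j] = sin(φ_i − φ_j) is computed in closed matrix form,

    G = sqrt(1 − x̃²) x̃ᵀ − x̃ sqrt(1 − x̃²)ᵀ,

an antisymmetric, zero-diagonal image of pairwise temporal correlation.
Piecewise aggregate approximation (PAA) block-averages the cycle down to the
image size first; the per-lead images are stacked into an (M′, M′, C) tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ECGCycle

__all__ = [
    "DegenerateSignalError",
    "RescaledSignal",
    "polar_angles",
    "rescale",
    "paa",
    "gadf",
    "build_tensor",
]


class DegenerateSignalError(ValueError):
    """Raised when a constant signal makes min-max rescaling undefined."""


@dataclass(frozen=True)
class RescaledSignal:
    """A series mapped to [0, 1], keeping the original range for reference."""

    values: np.ndarray
    original_min: float
    original_max: float


def rescale(x: np.ndarray) -> RescaledSignal:
    """Min-max rescale to [0, 1]; a constant input has no defined rescaling."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D sequence of length >= 2")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateSignalError("constant signal: max equals min, rescaling undefined")
    return RescaledSignal((x - lo) / (hi - lo), lo, hi)


def paa(x: np.ndarray, target_len: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``target_len`` segment means.

    Segment ``k`` spans indices ``[floor(k*M/M'), floor((k+1)*M/M'))`` so the
    blocks are near-equal in size; ``target_len == M`` returns the input
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    if not 1 <= target_len <= m:
        raise ValueError(f"target_len must be in [1, {m}], got {target_len}")
    if target_len == m:
        return x.copy()
    bounds = (np.arange(target_len + 1) * m) // target_len
    return np.array([x[bounds[k] : bounds[k + 1]].mean() for k in range(target_len)])


def polar_angles(rs: RescaledSignal) -> np.ndarray:
    """φ = arccos(x̃) in [0, π]; values clipped to absorb float overshoot."""
    return np.arccos(np.clip(rs.values, 0.0, 1.0))


def gadf(rs: RescaledSignal) -> np.ndarray:
    """Gramian Angular Difference Field of a rescaled signal.

    Computed by the closed matrix form; equals sin(φ_i − φ_j) elementwise to
    machine precision.  The exact zero diagonal is enforced explicitly.
    """
    x = np.clip(np.asarray(rs.values, dtype=float), 0.0, 1.0)
    s = np.sqrt(1.0 - x**2)
    g = np.outer(s, x) - np.outer(x, s)
    np.fill_diagonal(g, 0.0)
    return g


def build_tensor(cycle: ECGCycle, image_size: int = 32) -> np.ndarray:
    """rescale → PAA → GADF per lead, stacked to an (M′, M′, C) tensor.

    Raises :class:`DegenerateSignalError` naming the first constant lead.
    """
    if image_size > cycle.length:
        raise ValueError(
            f"image_size {image_size} exceeds cycle length {cycle.length}"
        )
    slices = []
    for name, lead in zip(cycle.leads, cycle.samples):
        try:
            rs = rescale(lead)
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(f"lead {name!r}: {exc}") from exc
        reduced = RescaledSignal(paa(rs.values, image_size), rs.original_min, rs.original_max)
        slices.append(gadf(reduced))
    return np.stack(slices, axis=2)
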