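"""Hermite-function representation of the QRS complex.

A 200 ms window around each annotated beat is projected onto the first
N orthonormal Hermite functions

    φ_n(t; σ) = (σ 2^n n! √π)^(-1/2) · H_n(t/σ) · exp(−t²/(2σ²)),

where H_n is the physicists' Hermite polynomial and σ scales the width
of the Gaussian envelope to the width of the QRS.  Because the φ_n are
(near-)orthonormal on the sampling grid, N coefficients plus σ give a
compact, ordered description of beat morphology: φ0 is a Gaussian bump,
higher orders add oscillations.  N = 16 is the conventional choice for
QRS complexes; σ is selected per beat by scanning a grid of candidate
widths and keeping the least-squares best fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import eval_hermite, gammaln

__all__ = [
    "HermiteFit",
    "default_sigma_grid",
    "extract_beat_window",
    "hermite_basis",
    "fit_hermite",
]

DEFAULT_N = 16
DEFAULT_WINDOW = 0.2  # seconds; covers the QRS, excludes P and T waves


@dataclass
class HermiteFit:
    """Least-squares Hermite description of one beat window on one lead."""

    coefficients: np.ndarray  # c_0 .. c_{N-1}
    sigma: float              # envelope width, seconds
    sse: float                # residual sum of squares

    @property
    def vector(self) -> np.ndarray:
        """The (N+1)-vector (c_0, …, c_{N-1}, σ) used as clustering features."""
        return np.append(self.coefficients, self.sigma)


def default_sigma_grid() -> np.ndarray:
    """Candidate σ values: 2–40 ms in 1 ms steps (physiological QRS widths)."""
    return np.arange(0.002, 0.0401, 0.001)


def extract_beat_window(
    signal: np.ndarray,
    fs: float,
    beat_time: float,
    width: float = DEFAULT_WINDOW,
    *,
    subtract_baseline: bool = True,
) -> np.ndarray:
    """Excerpt of ``width`` seconds centred on a beat annotation.

    The window has ``round(width·fs)`` samples; parts that overrun the
    record edges are zero-padded so every beat yields the same length.
    The window mean (local baseline) is subtracted by default.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if fs <= 0:
        raise ValueError("sampling frequency must be positive")
    if not 0 <= beat_time <= len(signal) / fs:
        raise ValueError(f"beat at {beat_time:.3f}s lies outside the record")
    length = int(np.round(width * fs))
    centre = int(np.round(beat_time * fs))
    start = centre - length // 2
    window = np.zeros(length)
    lo, hi = max(start, 0), min(start + length, len(signal))
    if hi > lo:
        window[lo - start:hi - start] = signal[lo:hi]
    if subtract_baseline:
        window -= window.mean()
    return window


@lru_cache(maxsize=512)
def _cached_basis(N: int, n_samples: int, fs: float, sigma: float):
    t = (np.arange(n_samples) - n_samples // 2) / fs
    B = _raw_basis(N, sigma, t)
    return B, np.linalg.pinv(B)


def _raw_basis(N: int, sigma: float, t: np.ndarray) -> np.ndarray:
    x = t / sigma
    env = np.exp(-(x**2) / 2.0)
    cols = []
    for n in range(N):
        lognorm = 0.5 * (np.log(sigma) + n * np.log(2.0) + gammaln(n + 1)
                         + 0.5 * np.log(np.pi))
        phi = eval_hermite(n, x) * env * np.exp(-lognorm)
        norm = np.linalg.norm(phi)
        if norm == 0:
            raise ValueError(f"Hermite function {n} vanished on the grid (sigma={sigma})")
        cols.append(phi / norm)  # renormalized so discrete projection ≡ inner product
    return np.column_stack(cols)


def hermite_basis(N: int, sigma: float, t: np.ndarray) -> np.ndarray:
    """Sampled Hermite-function basis: one column per order 0..N−1.

    Each column is renormalized to unit discrete norm so that, for σ
    small relative to the grid extent, the Gram matrix BᵀB is the
    identity and least squares reduces to inner products.
    """
    if N < 1:
        raise ValueError("need at least one Hermite function")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    if len(t) > 1:
        dt = np.median(np.diff(t))
        if sigma < 3 * dt:
            warnings.warn(
                f"sigma={sigma:.4g}s spans fewer than 3 samples; "
                "the sampled envelope may alias", stacklevel=2,
            )
    return _raw_basis(N, sigma, t)


def fit_hermite(
    window: np.ndarray,
    fs: float,
    N: int = DEFAULT_N,
    sigma_grid: np.ndarray | None = None,
) -> HermiteFit:
    """Best Hermite representation of one beat window over a σ grid.

    For each candidate σ the coefficients are the least-squares
    projection of the window on the sampled basis; the σ with the
    smallest reconstruction error wins (ties go to the smaller σ).
    """
    window = np.asarray(window, dtype=float).ravel()
    grid = default_sigma_grid() if sigma_grid is None else np.asarray(sigma_grid, float)
    if grid.size == 0:
        raise ValueError("sigma grid must not be empty")
    best: HermiteFit | None = None
    for sigma in grid:
        B, pinvB = _cached_basis(N, len(window), float(fs), float(sigma))
        coeffs = pinvB @ window
        resid = window - B @ coeffs
        sse = float(resid @ resid)
        if best is None or sse < best.sse:
            best = HermiteFit(coeffs, float(sigma), sse)
    return best
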