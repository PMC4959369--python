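"""Orthonormal dyadic discrete wavelet transform with periodic extension.

Implements the analysis/synthesis filter banks directly (no external wavelet
dependency).  Daubechies ``db{p}`` filters are derived numerically by spectral
factorization; ``db1`` is the Haar wavelet.  The transform is the orthogonal
periodized DWT: for even-length input the analysis matrix rows are the
low/high-pass filters circularly shifted by two, so the transform is exactly
orthonormal and the adjoint is the inverse.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.special import comb

__all__ = [
    "daubechies_filter",
    "quadrature_mirror",
    "dwt_step",
    "idwt_step",
    "wavedec",
    "waverec",
    "WaveletError",
]


class WaveletError(ValueError):
    """Invalid wavelet name or signal/level combination."""


@functools.lru_cache(maxsize=None)
def daubechies_filter(p: int) -> np.ndarray:
    """Return the length-``2p`` orthonormal Daubechies scaling filter.

    The filter has ``p`` vanishing moments and is the extremal-phase
    (minimum-phase) solution of the spectral factorization of

        |m0(w)|^2 = cos^{2p}(w/2) * P(sin^2(w/2)),

    with ``P`` the standard Bezout polynomial.  Coefficients sum to sqrt(2).
    """
    if p < 1:
        raise WaveletError(f"number of vanishing moments must be >= 1, got {p}")
    if p == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # Bezout polynomial P(y) = sum_k C(p-1+k, k) y^k, roots in y.
    coeffs = np.array([comb(p - 1 + k, k, exact=True) for k in range(p)], dtype=float)
    yroots = np.roots(coeffs[::-1])
    # Map each y-root to the z-plane via y = (2 - z - 1/z)/4, keep |z| < 1.
    zroots = []
    for y in yroots:
        r = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        zroots.append(r[np.argmin(np.abs(r))])
    # h(z) ~ (1+z)^p * prod (z - z_j); real up to rounding since complex
    # y-roots come in conjugate pairs.
    h = np.poly(np.concatenate([-np.ones(p), np.asarray(zroots)])).real
    h *= np.sqrt(2.0) / h.sum()
    # Extremal-phase convention: energy concentrated at the front.
    n = np.arange(h.size)
    if (n * h**2).sum() > (h.size - 1) / 2.0:
        h = h[::-1]
    return h


def quadrature_mirror(h: np.ndarray) -> np.ndarray:
    """High-pass filter ``g[n] = (-1)^n h[m-1-n]`` paired with scaling filter ``h``."""
    h = np.asarray(h, dtype=float)
    signs = np.where(np.arange(h.size) % 2 == 0, 1.0, -1.0)
    return signs * h[::-1]


def filters_for(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a wavelet name ('haar', 'db1'..'dbN') to (low, high) filters."""
    name = name.lower().strip()
    if name == "haar":
        name = "db1"
    if not name.startswith("db"):
        raise WaveletError(f"unknown wavelet family: {name!r} (supported: haar, dbN)")
    try:
        p = int(name[2:])
    except ValueError as exc:
        raise WaveletError(f"unknown wavelet name: {name!r}") from exc
    h = daubechies_filter(p)
    return h, quadrature_mirror(h)


def dwt_step(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step: (approximation, detail), each half length."""
    x = np.asarray(x, dtype=float)
    if x.size % 2 != 0:
        raise WaveletError(f"signal length {x.size} is odd; periodized DWT needs even length")
    half = x.size // 2
    idx = (2 * np.arange(half)[:, None] + np.arange(h.size)[None, :]) % x.size
    windows = x[idx]
    return windows @ h, windows @ g


def idwt_step(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dwt_step` (exact for orthonormal filter pairs)."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.size != d.size:
        raise WaveletError("approximation/detail length mismatch")
    n = 2 * a.size
    idx = ((2 * np.arange(a.size)[:, None] + np.arange(h.size)[None, :]) % n).ravel()
    x = np.zeros(n)
    np.add.at(x, idx, (np.outer(a, h) + np.outer(d, g)).ravel())
    return x


def wavedec(x: np.ndarray, levels: int, wavelet: str = "db4") -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Multilevel decomposition keeping BOTH bands at every level.

    Returns ``(approx, detail)`` where ``approx[l-1]`` / ``detail[l-1]`` are the
    level-``l`` approximation and detail coefficients (the approximation at
    level ``l`` is the cascade intermediate fed to level ``l+1``).  Each level
    halves the coefficient count.
    """
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise WaveletError(f"levels must be >= 1, got {levels}")
    if x.size % (2**levels) != 0 or x.size < 2**levels:
        raise WaveletError(
            f"signal length {x.size} does not support {levels} dyadic levels"
        )
    h, g = filters_for(wavelet)
    approx: list[np.ndarray] = []
    detail: list[np.ndarray] = []
    current = x
    for _ in range(levels):
        current, d = dwt_step(current, h, g)
        approx.append(current)
        detail.append(d)
    return approx, detail


def waverec(approx_last: np.ndarray, details: list[np.ndarray], wavelet: str = "db4") -> np.ndarray:
    """Reconstruct from the deepest approximation and all detail bands."""
    h, g = filters_for(wavelet)
    current = np.asarray(approx_last, dtype=float)
    for d in reversed(details):
        current = idwt_step(current, d, h, g)
    return current
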