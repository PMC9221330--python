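"""Minimal orthogonal (Daubechies-4) wavelet transform and denoiser.

Periodized analysis/synthesis: the analysis operator rows are the even
shifts of the decomposition filters, so synthesis is its exact transpose and
the round trip is lossless for any even-length input.
"""
from __future__ import annotations

import numpy as np

__all__ = ["wavedec", "waverec", "denoise"]

# Daubechies-4 decomposition low-pass filter (8 taps)
_DB4_LO = np.array(
    [
        -0.010597401784997278,
        0.032883011666982945,
        0.030841381835986965,
        -0.18703481171888114,
        -0.02798376941698385,
        0.6308807679295904,
        0.7148465705525415,
        0.23037781330885523,
    ]
)
# quadrature mirror: g[k] = (-1)^k h[L-1-k]
_DB4_HI = ((-1.0) ** np.arange(_DB4_LO.size)) * _DB4_LO[::-1]
_L = _DB4_LO.size


def _analysis(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(_L)[None, :]) % n
    xs = x[idx]
    return xs @ _DB4_LO, xs @ _DB4_HI


def _synthesis(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = 2 * a.size
    out = np.zeros(n)
    base = 2 * np.arange(a.size)
    for k in range(_L):
        pos = (base + k) % n
        np.add.at(out, pos, _DB4_LO[k] * a + _DB4_HI[k] * d)
    return out


def wavedec(x: np.ndarray, level: int) -> list[np.ndarray]:
    """Multi-level decomposition: ``[a_L, d_L, d_{L-1}, ..., d_1]``.

    The input is padded (edge replication) to a multiple of ``2**level``;
    :func:`waverec` with the returned original length undoes the padding.
    """
    x = np.asarray(x, dtype=float)
    a = x
    coeffs: list[np.ndarray] = []
    for _ in range(level):
        if a.size < _L:
            break
        if a.size % 2:
            a = np.concatenate([a, a[-1:]])
        a, d = _analysis(a)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray], length: int) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        # any odd-length padding added during decomposition is sliced off by
        # truncating the approximation to the detail band's size
        a = _synthesis(a[: d.size], d)
    return a[:length]


def denoise(x: np.ndarray, level: int) -> np.ndarray:
    """Soft-threshold denoising with the universal threshold.

    Noise scale is the median absolute deviation of the finest detail band
    divided by 0.6745; threshold is ``sigma * sqrt(2 ln N)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * _L or level < 1:
        return x.copy()
    coeffs = wavedec(x, level)
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(x.size))
    out = [coeffs[0]]
    for d in coeffs[1:]:
        out.append(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))
    return waverec(out, x.size)
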