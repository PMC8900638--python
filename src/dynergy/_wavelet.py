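"""Orthogonal Daubechies-4 ("db4", 8-tap) DWT with periodization.

Single-level analysis/synthesis plus a multilevel wavedec/waverec pair.
Periodization keeps the transform square and orthogonal, so waverec is the
exact inverse of wavedec (verified by tests).  Odd-length inputs are padded
by repeating the final sample.
"""

from __future__ import annotations

import numpy as np

# Daubechies 4-vanishing-moment decomposition low-pass filter.
DB4_DEC_LO = np.array([
    -0.010597401784997278,
    0.032883011666982945,
    0.030841381835986965,
    -0.18703481171888114,
    -0.02798376941698385,
    0.6308807679295904,
    0.7148465705525415,
    0.23037781330885523,
])
# quadrature mirror: hi[k] = (-1)^k lo[L-1-k]
DB4_DEC_HI = np.array([
    (-1.0) ** k * DB4_DEC_LO[len(DB4_DEC_LO) - 1 - k]
    for k in range(len(DB4_DEC_LO))
])

_L = len(DB4_DEC_LO)


def _even(x: np.ndarray) -> np.ndarray:
    if len(x) % 2:
        return np.concatenate([x, x[-1:]])
    return x


def dwt(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level; returns (approximation, detail), each length N/2."""
    x = _even(np.asarray(x, dtype=float))
    n = len(x)
    k = np.arange(n // 2)[:, None]
    taps = np.arange(_L)[None, :]
    idx = (2 * k + 1 - taps) % n
    gathered = x[idx]
    return gathered @ DB4_DEC_LO, gathered @ DB4_DEC_HI


def idwt(ca: np.ndarray, cd: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dwt` (adjoint of the orthogonal analysis operator)."""
    ca = np.asarray(ca, dtype=float)
    cd = np.asarray(cd, dtype=float)
    if len(ca) != len(cd):
        raise ValueError("approximation/detail length mismatch")
    n = 2 * len(ca)
    x = np.zeros(n)
    k = np.arange(len(ca))[:, None]
    taps = np.arange(_L)[None, :]
    idx = (2 * k + 1 - taps) % n
    np.add.at(x, idx, ca[:, None] * DB4_DEC_LO[None, :])
    np.add.at(x, idx, cd[:, None] * DB4_DEC_HI[None, :])
    return x


def wavedec(x: np.ndarray, levels: int = 6) -> list[np.ndarray]:
    """Multilevel decomposition: ``[A_levels, D_levels, ..., D_1]``."""
    coeffs: list[np.ndarray] = []
    approx = np.asarray(x, dtype=float)
    for _ in range(levels):
        approx, detail = dwt(approx)
        coeffs.append(detail)
    coeffs.append(approx)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    approx = coeffs[0]
    for detail in coeffs[1:]:
        if len(approx) != len(detail):  # odd-length padding at analysis time
            approx = approx[: len(detail)]
        approx = idwt(approx, detail)
    return approx
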