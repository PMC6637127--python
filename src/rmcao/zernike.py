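"""Zernike circle polynomials, Noll single-index convention.

Noll ordering maps j = 1, 2, 3, 4, ... to (n, m) = (0,0), (1,1), (1,-1),
(2,0), ... with the sign of m fixed by the parity rule; normalization is
Noll's, i.e. sqrt(n+1) for m = 0 and sqrt(2(n+1)) otherwise, so that each
mode has unit RMS over the unit disk.  Defocus is j = 4: sqrt(3)(2 rho^2 - 1).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["noll_to_nm", "zernike", "zernike_sum"]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Radial degree n and azimuthal frequency m for Noll index j >= 1."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    while (n + 1) * (n + 2) // 2 < j:
        n += 1
    base = n * (n + 1) // 2  # largest index of degree n-1
    r = j - base  # 1-based rank within degree n
    ms = sorted(range(-n, n + 1, 2), key=abs)
    m_abs = abs(ms[r - 1])
    if m_abs == 0:
        return n, 0
    # Noll: even j -> m >= 0, odd j -> m < 0
    return n, m_abs if j % 2 == 0 else -m_abs


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m_abs) // 2 - s)
                * math.factorial((n - m_abs) // 2 - s)
            )
        )
        out += c * rho ** (n - 2 * s)
    return out


def zernike(j: int, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Noll-normalized Zernike mode j on polar coordinates (rho, phi)."""
    n, m = noll_to_nm(j)
    R = _radial(n, abs(m), np.asarray(rho, dtype=float))
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
    if m == 0:
        ang = 1.0
    elif m > 0:
        ang = np.cos(m * phi)
    else:
        ang = np.sin(-m * phi)
    return norm * R * ang


def zernike_sum(coeffs: dict[int, float] | list[float], rho, phi) -> np.ndarray:
    """Linear combination of Noll modes.

    ``coeffs`` is either a mapping {noll_index: radians} or a sequence whose
    element i is the coefficient of Noll index i+1.
    """
    if not isinstance(coeffs, dict):
        coeffs = {i + 1: c for i, c in enumerate(coeffs)}
    out = np.zeros(np.broadcast(np.asarray(rho), np.asarray(phi)).shape)
    for j, c in coeffs.items():
        if c != 0.0:
            out = out + c * zernike(int(j), rho, phi)
    return out
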