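"""Time-gated reflection matrix: container, basis transforms and metrology.

The matrix E(output mode; input mode) holds the complex backscattered field
for every plane-wave illumination at a fixed optical gating delay tau0.  Rows
index output modes, columns input modes.  Either axis lives in the position
basis (one mode per pixel, row-major flattening of the centered grid) or in
the wavevector basis (output: one mode per in-pupil frequency node; input:
one mode per illumination wavevector).  Basis transforms are orthonormal
(unitary on the pupil support), so total energy is preserved and round trips
are identities for band-limited data.

The confocal image is the squared modulus of the matrix diagonal
E(r_o = r_i; r_i): detection position equal to illumination position, i.e.
the time-gated confocal microscope image.  PSFs are read off a single column:
the intensity map across r_o at a selected illumination position r_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .grid import GridSpec, fft2c, ifft2c

__all__ = [
    "ReflectionMatrix",
    "PSFEstimate",
    "to_wavevector_basis",
    "to_position_basis",
    "confocal_image",
    "point_spread_function",
    "strehl_enhancement",
    "BasisError",
    "MetrologyError",
]

POSITION = "position"
WAVEVECTOR = "wavevector"


class BasisError(ValueError):
    """Operation applied to a matrix in the wrong basis."""


class MetrologyError(RuntimeError):
    """PSF metrology failed (e.g. peakless column)."""


@dataclass(frozen=True)
class ReflectionMatrix:
    """Complex matrix (rows = output modes, columns = input modes) + metadata.

    ``k_in``: integer bin offsets (n_in, 2) of the illumination wavevectors
    when the input axis is in the wavevector basis (kept as provenance when in
    position basis).  ``k_out``: integer bin offsets (n_nodes, 2) of the
    retained output pupil nodes when the output axis is in the wavevector
    basis, None otherwise.
    """

    data: np.ndarray
    grid: GridSpec
    basis_out: str
    basis_in: str
    k_in: np.ndarray | None = None
    k_out: np.ndarray | None = None
    tau0: float = 0.0

    def __post_init__(self) -> None:
        n2 = self.grid.n**2
        rows, cols = self.data.shape
        if self.basis_out == POSITION and rows != n2:
            raise ValueError(f"position-basis output axis needs {n2} rows, got {rows}")
        if self.basis_out == WAVEVECTOR:
            if self.k_out is None or rows != len(self.k_out):
                raise ValueError("wavevector-basis output axis needs matching k_out")
        if self.basis_in == WAVEVECTOR:
            if self.k_in is None or cols != len(self.k_in):
                raise ValueError("wavevector-basis input axis needs matching k_in")
        if self.basis_in == POSITION and cols != n2:
            raise ValueError(f"position-basis input axis needs {n2} columns, got {cols}")

    @property
    def n_in(self) -> int:
        return self.data.shape[1]

    def total_power(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))

    # convenience wrappers over the module-level operations
    def to_wavevector_basis(self, axis: str = "both") -> "ReflectionMatrix":
        return to_wavevector_basis(self, axis)

    def to_position_basis(self, axis: str = "both") -> "ReflectionMatrix":
        return to_position_basis(self, axis)

    def confocal(self) -> np.ndarray:
        """Confocal intensity image |E(r, r)|^2, from any basis."""
        return np.abs(self.diagonal_field()) ** 2

    def diagonal_field(self) -> np.ndarray:
        """Complex confocal diagonal E(r_o = r; r_i = r) as an (n, n) map.

        Computed without materializing the full position/position matrix when
        the input axis is in the wavevector basis.
        """
        n = self.grid.n
        m = self if self.basis_out == POSITION else to_position_basis(self, "out")
        if m.basis_in == POSITION:
            return np.diagonal(m.data).reshape(n, n)
        d = np.zeros((n, n), dtype=complex)
        for j in range(m.n_in):
            kj = m.grid.bins_to_k(m.k_in[j])
            d += m.data[:, j].reshape(n, n) * m.grid.ramp(kj)
        return d / n


# ---------------------------------------------------------------------------
# basis transforms
# ---------------------------------------------------------------------------

def _output_to_wavevector(m: ReflectionMatrix) -> ReflectionMatrix:
    n = m.grid.n
    c = n // 2
    nodes = np.array(m.grid.pupil_nodes, dtype=int)
    out = np.empty((len(nodes), m.data.shape[1]), dtype=complex)
    iy, ix = c + nodes[:, 1], c + nodes[:, 0]
    for j in range(m.data.shape[1]):
        out[:, j] = fft2c(m.data[:, j].reshape(n, n))[iy, ix]
    return replace(m, data=out, basis_out=WAVEVECTOR, k_out=nodes)


def _output_to_position(m: ReflectionMatrix) -> ReflectionMatrix:
    n = m.grid.n
    c = n // 2
    iy, ix = c + m.k_out[:, 1], c + m.k_out[:, 0]
    out = np.empty((n * n, m.data.shape[1]), dtype=complex)
    buf = np.zeros((n, n), dtype=complex)
    for j in range(m.data.shape[1]):
        buf[:] = 0.0
        buf[iy, ix] = m.data[:, j]
        out[:, j] = ifft2c(buf).ravel()
    return replace(m, data=out, basis_out=POSITION, k_out=None)


def _input_synthesis_operator(m: ReflectionMatrix) -> np.ndarray:
    """Unitary-frame synthesis W (n^2, n_in): W[r, j] = exp(+i k_j.r)/n."""
    n = m.grid.n
    W = np.empty((n * n, len(m.k_in)), dtype=complex)
    for j, b in enumerate(m.k_in):
        W[:, j] = m.grid.ramp(m.grid.bins_to_k(b)).ravel()
    return W / n


def _input_to_position(m: ReflectionMatrix) -> ReflectionMatrix:
    # E(., r_i) = sum_j E(., k_j) exp(+i k_j . r_i) / n ; unsampled pupil
    # nodes are implicitly zero-filled, giving a square matrix.
    W = _input_synthesis_operator(m)
    return replace(m, data=m.data @ W.T, basis_in=POSITION)


def _input_to_wavevector(m: ReflectionMatrix, nodes: np.ndarray) -> ReflectionMatrix:
    tmp = replace(m, basis_in=WAVEVECTOR, k_in=np.array(nodes, dtype=int),
                  data=np.empty((m.data.shape[0], len(nodes)), dtype=complex))
    W = _input_synthesis_operator(tmp)
    return replace(tmp, data=m.data @ W.conj())


def to_wavevector_basis(m: ReflectionMatrix, axis: str = "both") -> ReflectionMatrix:
    """Orthonormal transform of the selected axis to the wavevector basis.

    The output axis is restricted to the in-pupil frequency nodes (lossless
    for pupil-band-limited data); a position-basis input axis is projected on
    the full set of in-pupil nodes.
    """
    if axis not in ("in", "out", "both"):
        raise ValueError(f"axis must be 'in', 'out' or 'both', got {axis!r}")
    if axis in ("out", "both"):
        if m.basis_out == WAVEVECTOR:
            if axis == "out":
                warnings.warn("output axis already in wavevector basis; no-op")
        else:
            m = _output_to_wavevector(m)
    if axis in ("in", "both"):
        if m.basis_in == WAVEVECTOR:
            if axis == "in":
                warnings.warn("input axis already in wavevector basis; no-op")
        else:
            m = _input_to_wavevector(m, m.grid.pupil_nodes)
    return m


def to_position_basis(m: ReflectionMatrix, axis: str = "both") -> ReflectionMatrix:
    """Inverse of :func:`to_wavevector_basis` (orthonormal)."""
    if axis not in ("in", "out", "both"):
        raise ValueError(f"axis must be 'in', 'out' or 'both', got {axis!r}")
    if axis in ("out", "both"):
        if m.basis_out == POSITION:
            if axis == "out":
                warnings.warn("output axis already in position basis; no-op")
        else:
            m = _output_to_position(m)
    if axis in ("in", "both"):
        if m.basis_in == POSITION:
            if axis == "in":
                warnings.warn("input axis already in position basis; no-op")
        else:
            m = _input_to_position(m)
    return m


# ---------------------------------------------------------------------------
# imaging & metrology
# ---------------------------------------------------------------------------

def confocal_image(m: ReflectionMatrix) -> np.ndarray:
    """|E(r_o = r; r_i = r)|^2 from a position/position matrix."""
    if m.basis_out != POSITION or m.basis_in != POSITION:
        raise BasisError("confocal_image requires both axes in the position basis")
    n = m.grid.n
    return np.abs(np.diagonal(m.data).reshape(n, n)) ** 2


@dataclass(frozen=True)
class PSFEstimate:
    """Point-spread-function metrology at one illumination position."""

    intensity: np.ndarray  # (n, n) over r_o
    peak: float
    peak_position: tuple[float, float]  # (x, y) in um, sub-pixel
    fwhm: float  # um, along the stated axis
    axis: str = "x"
    r_i: tuple[float, float] = (0.0, 0.0)


def _column_intensity(m: ReflectionMatrix, r_i: tuple[float, float]) -> np.ndarray:
    """Intensity map over r_o for the column nearest to position r_i."""
    n, c = m.grid.n, m.grid.n // 2
    ix = int(round(r_i[0] / m.grid.pitch)) + c
    iy = int(round(r_i[1] / m.grid.pitch)) + c
    if not (0 <= ix < n and 0 <= iy < n):
        raise ValueError(f"r_i {r_i} outside the field of view")
    if m.basis_in == POSITION:
        col = m.data[:, iy * n + ix]
    else:
        r = np.array([(ix - c) * m.grid.pitch, (iy - c) * m.grid.pitch])
        phases = np.exp(1j * (m.grid.bins_to_k(m.k_in) @ r)) / n
        col = m.data @ phases
    return np.abs(col.reshape(n, n)) ** 2


def point_spread_function(
    m: ReflectionMatrix,
    r_i: tuple[float, float] = (0.0, 0.0),
    *,
    axis: str = "x",
    upsample: int = 10,
) -> PSFEstimate:
    """Extract the PSF at illumination position r_i with sub-pixel metrology.

    The intensity profile through the sub-pixel peak is resampled with a cubic
    spline at ``upsample``-fold finer pitch; the FWHM is the distance between
    the half-maximum crossings, reported in micrometres.
    """
    if m.basis_out != POSITION:
        raise BasisError("point_spread_function requires the output axis in position basis")
    if axis not in ("x", "y", "radial"):
        raise ValueError("axis must be 'x', 'y' or 'radial'")
    intensity = _column_intensity(m, r_i)
    if intensity.max() <= 0 or np.ptp(intensity) < 1e-12 * intensity.max():
        raise MetrologyError("flat (peakless) column; no PSF to measure")
    x = m.grid.x
    spl = RectBivariateSpline(x, x, intensity, kx=3, ky=3)  # (y, x) ordering
    iy0, ix0 = np.unravel_index(np.argmax(intensity), intensity.shape)
    # refine peak on an upsampled neighbourhood
    h = 2 * m.grid.pitch
    fine = max(4 * upsample, 40)
    gx = np.linspace(x[ix0] - h, x[ix0] + h, fine)
    gy = np.linspace(x[iy0] - h, x[iy0] + h, fine)
    patch = spl(gy, gx)
    py, px = np.unravel_index(np.argmax(patch), patch.shape)
    x_pk, y_pk = gx[px], gy[py]
    peak = float(patch[py, px])
    if peak <= 0:
        raise MetrologyError("non-positive peak intensity")

    def profile(ts: np.ndarray) -> np.ndarray:
        if axis == "x":
            return spl(np.full_like(ts, y_pk), x_pk + ts, grid=False)
        if axis == "y":
            return spl(y_pk + ts, np.full_like(ts, x_pk), grid=False)
        angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        vals = [
            spl(y_pk + np.outer(ts, np.sin(a)).ravel(),
                x_pk + np.outer(ts, np.cos(a)).ravel(), grid=False)
            for a in angles
        ]
        return np.mean(vals, axis=0)

    half_span = m.grid.extent / 2
    ts = np.arange(0.0, half_span, m.grid.pitch / upsample)
    fwhm = 0.0
    for sgn in (+1, -1):
        p = profile(sgn * ts)
        below = np.nonzero(p < peak / 2)[0]
        if len(below) == 0:
            raise MetrologyError("profile never falls below half maximum")
        i = below[0]
        # linear interpolation of the crossing between samples i-1 and i
        p0, p1 = p[i - 1], p[i]
        frac = (p0 - peak / 2) / (p0 - p1) if p0 != p1 else 0.0
        fwhm += ts[i - 1] + frac * (ts[i] - ts[i - 1])
    return PSFEstimate(
        intensity=intensity,
        peak=peak,
        peak_position=(float(x_pk), float(y_pk)),
        fwhm=float(fwhm),
        axis=axis,
        r_i=(float(r_i[0]), float(r_i[1])),
    )


def strehl_enhancement(before: PSFEstimate, after: PSFEstimate) -> float:
    """Ratio of PSF peak intensities after / before aberration correction."""
    if before.peak == 0:
        raise ValueError("before.peak is zero; Strehl enhancement undefined")
    return after.peak / before.peak
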