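"""Sampling grids and Fourier conventions shared by every module.

All 2-D arrays in this package live on a square, even-sized pixel grid whose
spatial origin sits at index ``n // 2`` along each axis.  The conjugate
wavevector grid is the discrete Fourier grid of that position grid, likewise
centered, with spacing ``dk = 2*pi / (n * pitch)``.  A single pair of centered,
orthonormal FFT helpers (:func:`fft2c` / :func:`ifft2c`) implements the
position <-> wavevector transform so that energy bookkeeping needs no tracked
prefactors anywhere downstream.

The forward kernel is ``exp(-i k.r)``; the inverse therefore carries
``exp(+i k.r)``.  Wavevectors are expressed either physically (rad/um) or as
integer bin offsets from the grid center; conversions go through
:attr:`GridSpec.dk`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["GridSpec", "fft2c", "ifft2c"]


def fft2c(a: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D DFT (position -> wavevector, kernel exp(-ik.r))."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a), norm="ortho"))


def ifft2c(a: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D inverse DFT (wavevector -> position)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a), norm="ortho"))


class ConfigurationError(ValueError):
    """Raised when parameters violate a documented precondition."""


@dataclass(frozen=True)
class GridSpec:
    """Acquisition geometry: pixel grid, wavelength and objective aperture.

    Parameters
    ----------
    n : int
        Pixels per side (even).
    pitch : float
        Sample-plane pixel pitch in micrometres.  Must satisfy the Nyquist
        bound for the double-pass intensity PSF, ``pitch <= lambda / (4 NA)``.
    wavelength : float
        Center wavelength in micrometres.
    na : float
        Numerical aperture of the objective, in (0, 1].
    n_medium : float
        Refractive index of the immersion/specimen medium (used by the
        angular-spectrum propagator).
    """

    n: int
    pitch: float
    wavelength: float
    na: float
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if self.n <= 0 or self.n % 2:
            raise ConfigurationError(f"n must be a positive even integer, got {self.n}")
        if not (0.0 < self.na <= 1.0):
            raise ConfigurationError(f"NA must lie in (0, 1], got {self.na}")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ConfigurationError("pitch and wavelength must be positive")
        nyq = self.wavelength / (4.0 * self.na)
        if self.pitch > nyq * (1.0 + 1e-12):
            raise ConfigurationError(
                f"pitch {self.pitch} um exceeds the double-pass Nyquist bound "
                f"lambda/(4 NA) = {nyq:.4g} um"
            )

    # -- derived scalars ---------------------------------------------------
    @property
    def k0(self) -> float:
        """Free-space wavenumber 2*pi/lambda (rad/um)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def dk(self) -> float:
        """Wavevector bin spacing 2*pi/(n*pitch) (rad/um)."""
        return 2.0 * np.pi / (self.n * self.pitch)

    @property
    def pupil_radius(self) -> float:
        """Pupil radius k0*NA (rad/um)."""
        return self.k0 * self.na

    @property
    def pupil_radius_bins(self) -> float:
        return self.pupil_radius / self.dk

    @property
    def k_nyquist(self) -> float:
        """Largest representable wavevector component pi/pitch (rad/um)."""
        return np.pi / self.pitch

    @property
    def extent(self) -> float:
        """Physical field width n*pitch (um)."""
        return self.n * self.pitch

    # -- coordinate arrays -------------------------------------------------
    @cached_property
    def x(self) -> np.ndarray:
        """Centered 1-D position coordinates (um), origin at index n//2."""
        return (np.arange(self.n) - self.n // 2) * self.pitch

    @cached_property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of position coordinates, indexing='xy'."""
        X, Y = np.meshgrid(self.x, self.x, indexing="xy")
        return X, Y

    @cached_property
    def k_bins(self) -> np.ndarray:
        """Centered 1-D integer wavevector bins, origin at index n//2."""
        return np.arange(self.n) - self.n // 2

    @cached_property
    def k_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (KX, KY) of physical wavevectors (rad/um)."""
        k = self.k_bins * self.dk
        KX, KY = np.meshgrid(k, k, indexing="xy")
        return KX, KY

    @cached_property
    def pupil_mask(self) -> np.ndarray:
        """Boolean map of frequency nodes with |k| <= k0*NA."""
        KX, KY = self.k_xy
        m = KX**2 + KY**2 <= self.pupil_radius**2 * (1.0 + 1e-12)
        m.setflags(write=False)
        return m

    @cached_property
    def pupil_nodes(self) -> np.ndarray:
        """Integer bin offsets (bx, by) of in-pupil nodes, ascending |k|.

        Deterministic ordering: primary key |k|^2, then by, then bx.
        Shape (n_nodes, 2).
        """
        yy, xx = np.nonzero(self.pupil_mask)
        bx = xx - self.n // 2
        by = yy - self.n // 2
        order = np.lexsort((bx, by, bx**2 + by**2))
        nodes = np.column_stack([bx[order], by[order]])
        nodes.setflags(write=False)
        return nodes

    # -- helpers -----------------------------------------------------------
    def bins_to_k(self, bins: np.ndarray) -> np.ndarray:
        return np.asarray(bins, dtype=float) * self.dk

    def k_to_bins(self, k: np.ndarray, *, snap: bool = True) -> np.ndarray:
        b = np.asarray(k, dtype=float) / self.dk
        return np.rint(b).astype(int) if snap else b

    def in_pupil(self, k: np.ndarray) -> np.ndarray:
        """Whether physical wavevector(s) (..., 2) lie inside the pupil."""
        k = np.asarray(k, dtype=float)
        return np.hypot(k[..., 0], k[..., 1]) <= self.pupil_radius * (1 + 1e-12)

    def plane_wave(self, k: np.ndarray) -> np.ndarray:
        """Incident plane wave exp(-i k.r) on the position grid."""
        X, Y = self.xy
        return np.exp(-1j * (k[0] * X + k[1] * Y))

    def ramp(self, k: np.ndarray) -> np.ndarray:
        """Phase ramp exp(+i k.r) on the position grid."""
        X, Y = self.xy
        return np.exp(1j * (k[0] * X + k[1] * Y))
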