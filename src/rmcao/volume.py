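"""Numerical refocusing and volumetric stack assembly.

Between recorded depths the complex field is propagated with the exact
(non-paraxial) scalar angular-spectrum kernel

    E(z + dz) = IFFT[ FFT[E(z)] * exp(i dz sqrt((n k0)^2 - |k|^2)) ],

evanescent components set to zero.  The kernel is unitary on the propagating
band, so refocusing conserves band energy and composes additively in dz.
The coherence gate of the acquisition limits how far a single recorded slice
can be meaningfully refocused; the default validity half-range is 7.5 um
(half of a 15 um gate), beyond which a warning is issued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, fft2c, ifft2c
from .matrix import POSITION
from .simulate import ComplexFieldMap

__all__ = [
    "VolumeStack",
    "angular_spectrum_propagate",
    "assemble_volume",
    "max_intensity_projection",
    "PROPAGATION_VALIDITY_UM",
]

PROPAGATION_VALIDITY_UM = 7.5


def angular_spectrum_propagate(
    fmap: ComplexFieldMap, dz: float, *, validity: float = PROPAGATION_VALIDITY_UM
) -> ComplexFieldMap:
    """Propagate a position-basis field by a signed axial distance dz (um)."""
    if fmap.basis != POSITION:
        raise ValueError("angular_spectrum_propagate requires a position-basis field")
    if abs(dz) > validity:
        warnings.warn(
            f"|dz| = {abs(dz):.2f} um exceeds the coherence-gate validity "
            f"half-range ({validity} um); refocused amplitude is unreliable",
            stacklevel=2,
        )
    if dz == 0.0:
        return fmap
    grid = fmap.grid
    KX, KY = grid.k_xy
    nk0 = grid.n_medium * grid.k0
    kz_sq = nk0**2 - KX**2 - KY**2
    propagating = kz_sq > 0
    kernel = np.where(
        propagating, np.exp(1j * dz * np.sqrt(np.maximum(kz_sq, 0.0))), 0.0
    )
    out = ifft2c(fft2c(fmap.field) * kernel)
    return ComplexFieldMap(
        field=out, grid=grid, basis=POSITION, k_in=fmap.k_in, tau0=fmap.tau0
    )


@dataclass(frozen=True)
class VolumeStack:
    """Ordered intensity slices on a uniform fine z grid."""

    z: np.ndarray  # strictly increasing depths (um)
    slices: np.ndarray  # (n_z, n, n) intensity
    grid: GridSpec

    def __post_init__(self) -> None:
        if len(self.z) != len(self.slices):
            raise ValueError("z and slices length mismatch")
        if len(self.z) > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("depths must be strictly increasing")


def assemble_volume(
    slices: list[tuple[float, ComplexFieldMap]], fine_step: float
) -> VolumeStack:
    """Fill the gaps between recorded depths by numerical propagation.

    ``slices`` holds (depth, complex field) pairs at coarse depths whose
    spacing must be an integer multiple of ``fine_step``; each intermediate
    depth is synthesized by propagating from the nearer recorded slice (ties
    go to the shallower one) and stored as intensity.
    """
    if not slices:
        raise ValueError("need at least one recorded slice")
    zs = np.array([z for z, _ in slices], dtype=float)
    if len(zs) > 1 and not np.all(np.diff(zs) > 0):
        raise ValueError("input depths must be strictly increasing")
    if fine_step <= 0:
        raise ValueError("fine_step must be positive")
    grid = slices[0][1].grid
    if len(slices) == 1:
        z0, f0 = slices[0]
        return VolumeStack(
            z=np.array([z0]), slices=np.abs(f0.field[None]) ** 2, grid=grid
        )
    steps = np.diff(zs) / fine_step
    if not np.allclose(steps, np.rint(steps), atol=1e-6):
        raise ValueError("coarse spacing must be an integer multiple of fine_step")
    z_out: list[float] = []
    imgs: list[np.ndarray] = []
    for i, (z0, f0) in enumerate(slices):
        z_out.append(z0)
        imgs.append(np.abs(f0.field) ** 2)
        if i + 1 == len(slices):
            break
        z1, f1 = slices[i + 1]
        n_fill = int(round((z1 - z0) / fine_step)) - 1
        for m in range(1, n_fill + 1):
            z = z0 + m * fine_step
            if z - z0 <= z1 - z:
                f = angular_spectrum_propagate(f0, z - z0)
            else:
                f = angular_spectrum_propagate(f1, z - z1)
            z_out.append(z)
            imgs.append(np.abs(f.field) ** 2)
    return VolumeStack(z=np.array(z_out), slices=np.array(imgs), grid=grid)


def max_intensity_projection(
    stack: VolumeStack, z_range: tuple[float, float] | None = None
) -> np.ndarray:
    """Pixelwise maximum over the slices with z inside ``z_range`` (inclusive)."""
    if z_range is None:
        sel = np.ones(len(stack.z), dtype=bool)
    else:
        zmin, zmax = z_range
        sel = (stack.z >= zmin) & (stack.z <= zmax)
    if not np.any(sel):
        raise ValueError(f"z_range {z_range} does not intersect the stack")
    return stack.slices[sel].max(axis=0)
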