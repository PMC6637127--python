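"""Forward model: time-gated reflection fields, matrices and interferograms.

The single-scattering model illuminates the specimen with an aberrated plane
wave ``exp(-i k_i . r) * exp(i theta_in(k_i))``, multiplies by the complex
reflectivity O(r), and propagates the backscattered wave through the output
pupil (binary NA mask times ``exp(i theta_out(k))``) to the image plane.
Temporal gating is implicit: the simulated matrix is the already-gated field
at the target delay tau0, and within-gate multiple scattering is emulated as
additive circular-Gaussian speckle, band-limited to the output pupil and
independent across illuminations (the worst case for single-scattering
accumulation, since it never adds coherently on the confocal diagonal).

Raw acquisition can additionally be emulated as rotating-reference off-axis
interferograms: the reference wave co-scans with the illumination, carrying
transverse wavevector ``k_i + k_DG`` where k_DG is set by the diffraction
grating, and the camera records ``|E_S + E_R|^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .grid import ConfigurationError, GridSpec, fft2c, ifft2c
from .matrix import POSITION, WAVEVECTOR, ReflectionMatrix
from .scene import IlluminationSet, PupilPhase, SpecimenMap

__all__ = [
    "ComplexFieldMap",
    "InterferogramConfig",
    "Interferogram",
    "NoiseSpec",
    "simulate_reflection_field",
    "assemble_matrix",
    "synthesize_interferogram",
]


@dataclass(frozen=True)
class ComplexFieldMap:
    """Complex field on a grid with a basis tag and acquisition metadata."""

    field: np.ndarray
    grid: GridSpec
    basis: str = POSITION  # 'position' (r_o) or 'wavevector' (k_o)
    k_in: np.ndarray | None = None  # associated illumination wavevector (rad/um)
    tau0: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.field)
        if f.shape != (self.grid.n, self.grid.n):
            raise ValueError("field shape does not match grid")
        if not np.all(np.isfinite(f)):
            raise ValueError("field contains non-finite values")
        if self.basis not in (POSITION, WAVEVECTOR):
            raise ValueError(f"unknown basis {self.basis!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiple-scattering emulation: noise-to-signal power ratio gamma."""

    gamma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")


@dataclass(frozen=True)
class InterferogramConfig:
    """Off-axis acquisition: grating carrier, reference amplitude, camera noise.

    ``k_dg`` is the grating carrier wavevector (rad/um, sample-plane
    referred); the sideband-separation invariant |k_DG| > 2 k0 NA must hold.
    """

    k_dg: tuple[float, float]
    e_r0: float = 1.0
    camera_noise_var: float = 0.0

    def validate(self, grid: GridSpec) -> None:
        kdg = float(np.hypot(*self.k_dg))
        if kdg <= 2.0 * grid.pupil_radius:
            raise ConfigurationError(
                f"|k_DG| = {kdg:.4g} must exceed 2 k0 NA = "
                f"{2 * grid.pupil_radius:.4g} for sideband separation"
            )
        if self.e_r0 <= 0:
            raise ConfigurationError("reference amplitude e_r0 must be positive")
        if self.camera_noise_var < 0:
            raise ConfigurationError("camera noise variance must be >= 0")
        # the full modulus-squared spectrum must fit on the discrete grid
        if kdg + 2.0 * grid.pupil_radius > grid.k_nyquist:
            raise ConfigurationError(
                f"carrier band |k_DG| + 2 k0 NA = {kdg + 2 * grid.pupil_radius:.4g} "
                f"exceeds the grid Nyquist wavevector {grid.k_nyquist:.4g}; "
                "use a finer pixel pitch"
            )


@dataclass(frozen=True)
class Interferogram:
    """Real camera frame carrying the off-axis carrier k_i + k_DG."""

    data: np.ndarray
    grid: GridSpec
    k_in: np.ndarray | None = None  # ground-truth k_i, simulator provenance
    tau0: float = 0.0


def _pupil_transfer(phase_out: PupilPhase) -> np.ndarray:
    return phase_out.pupil_function()


def simulate_reflection_field(
    specimen: SpecimenMap,
    phase_in: PupilPhase,
    phase_out: PupilPhase,
    k_i: np.ndarray,
    grid: GridSpec | None = None,
) -> ComplexFieldMap:
    """Backscattered field E_S(r_o; k_i, tau0) for one plane-wave illumination.

    Linear in the specimen reflectivity and band-limited to the output pupil.
    The input aberration enters as the single phase exp(i theta_in(k_i)) of
    the illuminating plane wave (pure pupil model).
    """
    grid = grid or specimen.grid
    for obj in (specimen, phase_in, phase_out):
        if obj.grid != grid:
            raise ValueError("all inputs must share one GridSpec")
    k_i = np.asarray(k_i, dtype=float)
    if not grid.in_pupil(k_i):
        raise ValueError(f"illumination wavevector {k_i} outside the pupil")
    c = grid.n // 2
    b = grid.k_to_bins(k_i)
    theta_i = phase_in.phase[c + b[1], c + b[0]]
    incident = grid.plane_wave(k_i) * np.exp(1j * theta_i)
    spec = fft2c(specimen.reflectivity * incident)
    out = ifft2c(spec * _pupil_transfer(phase_out))
    return ComplexFieldMap(field=out, grid=grid, k_in=k_i, tau0=0.0)


def assemble_matrix(
    specimen: SpecimenMap,
    phase_in: PupilPhase,
    phase_out: PupilPhase,
    illum: IlluminationSet,
    grid: GridSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
    tau0: float = 0.0,
) -> ReflectionMatrix:
    """Assemble the time-gated reflection matrix for one illumination scan.

    Output basis: position; input basis: wavevector (one column per k_i).
    With gamma > 0, each column receives an independent pupil-band-limited
    circular-Gaussian speckle field; the block is scaled so that total noise
    power / total signal power equals gamma exactly.
    """
    grid = grid or specimen.grid
    if illum.n_in < 1:
        raise ValueError("empty illumination set")
    n = grid.n
    cols = np.empty((n * n, illum.n_in), dtype=complex)
    ks = illum.k
    for j in range(illum.n_in):
        cols[:, j] = simulate_reflection_field(
            specimen, phase_in, phase_out, ks[j], grid
        ).field.ravel()
    if noise.gamma > 0:
        rng = np.random.default_rng(noise.seed)
        mask = grid.pupil_mask
        noise_block = np.empty_like(cols)
        for j in range(illum.n_in):
            w = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
            noise_block[:, j] = ifft2c(fft2c(w) * mask).ravel()
        sig = np.sum(np.abs(cols) ** 2)
        npow = np.sum(np.abs(noise_block) ** 2)
        noise_block *= np.sqrt(noise.gamma * sig / npow)
        cols = cols + noise_block
    return ReflectionMatrix(
        data=cols,
        grid=grid,
        basis_out=POSITION,
        basis_in=WAVEVECTOR,
        k_in=np.array(illum.bins, dtype=int),
        tau0=tau0,
    )


def synthesize_interferogram(
    field: ComplexFieldMap,
    k_i: np.ndarray,
    cfg: InterferogramConfig,
    seed: int = 0,
) -> Interferogram:
    """Camera frame I = |E_S + E_R0 exp(-i (k_i + k_DG).r)|^2 (+ camera noise).

    Noise-free frames are real and nonnegative and contain exactly the DC,
    carrier and conjugate terms of the modulus-squared expansion.
    """
    grid = field.grid
    cfg.validate(grid)
    k_i = np.asarray(k_i, dtype=float)
    kr = k_i + np.asarray(cfg.k_dg, dtype=float)
    ref = cfg.e_r0 * grid.plane_wave(kr)
    frame = np.abs(field.field + ref) ** 2
    if cfg.camera_noise_var > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(
            0.0, np.sqrt(cfg.camera_noise_var), size=frame.shape
        )
    return Interferogram(data=frame, grid=grid, k_in=k_i, tau0=field.tau0)
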