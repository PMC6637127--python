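"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import rmcao as r

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid() -> r.GridSpec:
    """32 px grid, ~49 pupil nodes: cheap enough for exhaustive oracles."""
    return r.GridSpec(n=32, pitch=0.08, wavelength=0.515, na=0.8)


@pytest.fixture(scope="session")
def std_grid() -> r.GridSpec:
    """The matched-simulation geometry: 64 px, 80 nm pitch, 515 nm, NA 0.8."""
    return r.GridSpec(n=64, pitch=0.08, wavelength=0.515, na=0.8)


@pytest.fixture(scope="session")
def demod_grid() -> r.GridSpec:
    """Finer pitch so carrier |k_DG| = 5 k0 NA plus sidebands fit under Nyquist."""
    return r.GridSpec(n=64, pitch=0.04, wavelength=0.515, na=0.8)


@pytest.fixture(scope="session")
def full_pupil_illum(std_grid) -> r.IlluminationSet:
    return r.sample_illumination_angles(len(std_grid.pupil_nodes), std_grid, "grid")


def brute_force_psf(grid: r.GridSpec, r0=(0.0, 0.0), phase_out=None) -> np.ndarray:
    """Coherent PSF by direct summation of the diffraction integral.

    h(r) = (1/n^2) sum_{k in pupil} exp(i phase_out(k)) exp(i k.(r - r0)),
    evaluated with explicit loops over pupil nodes -- the independent oracle
    for the FFT-based forward model.
    """
    n, c = grid.n, grid.n // 2
    X, Y = grid.xy
    out = np.zeros((n, n), dtype=complex)
    for bx, by in grid.pupil_nodes:
        k = np.array([bx, by]) * grid.dk
        ph = 0.0 if phase_out is None else phase_out[c + by, c + bx]
        out += np.exp(1j * (ph + k[0] * (X - r0[0]) + k[1] * (Y - r0[1])))
    return out / n**2


def on_grid_k(grid: r.GridSpec, rng: np.random.Generator) -> np.ndarray:
    """A random in-pupil wavevector on the frequency grid."""
    nodes = grid.pupil_nodes
    bx, by = nodes[rng.integers(len(nodes))]
    return np.array([bx, by]) * grid.dk


def standard_fixture(
    grid: r.GridSpec,
    preset: str = "speckle_object",
    rms: float = 1.5,
    gamma: float = 0.0,
    seed: int = 0,
    corr_length: float = 0.25,
):
    """Specimen + screens + full-pupil matrix with ground truth retained."""
    illum = r.sample_illumination_angles(len(grid.pupil_nodes), grid, "grid")
    specimen = r.make_specimen(preset, grid, seed=seed)
    pin = r.make_aberration(grid, rms=rms, corr_length=corr_length, seed=seed + 1, role="input")
    pout = r.make_aberration(grid, rms=rms, corr_length=corr_length, seed=seed + 2, role="output")
    m = r.assemble_matrix(
        specimen, pin, pout, illum, noise=r.NoiseSpec(gamma=gamma, seed=seed + 3)
    )
    return m, specimen, pin, pout, illum
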