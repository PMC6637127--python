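"""Synthetic specimens, pupil aberration screens and illumination sets.

Everything here is a pure function of (parameters, seed), so downstream
stages can be tested against retained ground truth without any external data.
Scene presets emulate the structures met in label-free reflectance imaging of
neural tissue: isolated point reflectors, point grids, filament bundles
(myelinated-axon-like fibres, whose lipid sheaths reflect more strongly than
the surround) and fully developed speckle objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .grid import ConfigurationError, GridSpec
from .zernike import zernike_sum

__all__ = [
    "SpecimenMap",
    "PupilPhase",
    "IlluminationSet",
    "make_specimen",
    "make_aberration",
    "sample_illumination_angles",
    "SCENE_PRESETS",
]

SCENE_PRESETS = ("single_point", "point_grid", "filaments", "speckle_object")


@dataclass(frozen=True)
class SpecimenMap:
    """Complex reflectivity O(r) on a position grid, max |O| <= 1."""

    reflectivity: np.ndarray
    grid: GridSpec
    descriptor: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectivity)
        if r.shape != (self.grid.n, self.grid.n):
            raise ValueError("reflectivity shape does not match grid")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectivity contains non-finite values")


@dataclass(frozen=True)
class PupilPhase:
    """Phase map theta(k) in radians on the wavevector grid, zero outside the pupil.

    ``role`` tags the map as an applied aberration ('input' / 'output') or as a
    recovered correction ('correction').
    """

    phase: np.ndarray
    grid: GridSpec
    role: str = "input"

    def __post_init__(self) -> None:
        p = np.asarray(self.phase)
        if p.shape != (self.grid.n, self.grid.n):
            raise ValueError("phase shape does not match grid")
        if np.any(p[~self.grid.pupil_mask] != 0.0):
            raise ValueError("phase must vanish outside the pupil support")

    @property
    def wrapped(self) -> np.ndarray:
        """Phase wrapped to (-pi, pi] for display."""
        w = np.angle(np.exp(1j * self.phase))  # (-pi, pi]
        w[~self.grid.pupil_mask] = 0.0
        return w

    def at_nodes(self, nodes: np.ndarray) -> np.ndarray:
        """Phase values at integer bin offsets (n_nodes, 2) = (bx, by)."""
        c = self.grid.n // 2
        return self.phase[c + nodes[:, 1], c + nodes[:, 0]]

    def pupil_function(self) -> np.ndarray:
        """Complex pupil exp(i theta) masked to the support."""
        return np.where(self.grid.pupil_mask, np.exp(1j * self.phase), 0.0)


@dataclass(frozen=True)
class IlluminationSet:
    """Transverse illumination wavevectors k^i, all inside the pupil.

    ``bins`` holds integer frequency-bin offsets (n_in, 2) = (bx, by); the
    physical wavevectors are ``bins * grid.dk``.
    """

    bins: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        b = np.asarray(self.bins)
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 1:
            raise ValueError("bins must have shape (n_in >= 2D, 2) with n_in >= 1")
        if len(np.unique(b, axis=0)) != len(b):
            raise ValueError("duplicate illumination wavevectors")
        if not np.all(self.grid.in_pupil(self.k)):
            raise ValueError("illumination wavevector outside the pupil")

    @property
    def n_in(self) -> int:
        return len(self.bins)

    @property
    def k(self) -> np.ndarray:
        """Physical wavevectors (n_in, 2) in rad/um."""
        return np.asarray(self.bins, dtype=float) * self.grid.dk


# ---------------------------------------------------------------------------
# specimens
# ---------------------------------------------------------------------------

def make_specimen(preset: str, grid: GridSpec, seed: int = 0) -> SpecimenMap:
    """Generate a complex reflectivity map for one of the shipped presets.

    Deterministic in (preset, grid, seed).  Point presets record their
    ground-truth point pixel locations in ``descriptor['points']`` as (ix, iy)
    index pairs.
    """
    if preset not in SCENE_PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {SCENE_PRESETS}"
        )
    rng = np.random.default_rng(seed)
    n, c = grid.n, grid.n // 2
    desc: dict[str, Any] = {"preset": preset, "seed": seed}
    r = np.zeros((n, n), dtype=complex)

    if preset == "single_point":
        r[c, c] = 1.0
        desc["points"] = [(c, c)]
    elif preset == "point_grid":
        step = max(n // 8, 4)
        idx = np.arange(step // 2, n, step)
        pts = [(ix, iy) for iy in idx for ix in idx]
        for ix, iy in pts:
            r[iy, ix] = 1.0
        desc["points"] = pts
        desc["n_points"] = len(pts)
    elif preset == "filaments":
        amp = np.zeros((n, n))
        n_fib = max(3, n // 32)
        for _ in range(n_fib):
            # smooth random walk across the field
            x = rng.uniform(0, n)
            y = rng.uniform(0, n)
            ang = rng.uniform(0, 2 * np.pi)
            a = rng.uniform(0.5, 1.0)
            for _ in range(3 * n):
                ix, iy = int(round(x)) % n, int(round(y)) % n
                amp[iy, ix] = max(amp[iy, ix], a)
                ang += rng.normal(0.0, 0.12)
                x += np.cos(ang)
                y += np.sin(ang)
        amp = ndimage.gaussian_filter(amp, 0.8, mode="wrap")
        phase = ndimage.gaussian_filter(rng.standard_normal((n, n)), 4.0, mode="wrap")
        phase *= 0.5 / max(np.abs(phase).max(), 1e-12)
        r = amp * np.exp(1j * 2 * np.pi * phase)
        desc["n_filaments"] = n_fib
    else:  # speckle_object
        r = (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))) / np.sqrt(2)

    m = np.abs(r).max()
    if m > 0:
        r = r / max(m, 1.0)  # enforce max |O| <= 1 without boosting weak scenes
    if np.abs(r).max() > 1.0:
        r = r / np.abs(r).max()
    return SpecimenMap(reflectivity=r, grid=grid, descriptor=desc)


# ---------------------------------------------------------------------------
# aberration screens
# ---------------------------------------------------------------------------

def make_aberration(
    grid: GridSpec,
    *,
    zernike: dict[int, float] | list[float] | None = None,
    rms: float | None = None,
    corr_length: float = 0.25,
    seed: int = 0,
    role: str = "input",
) -> PupilPhase:
    """Build a pupil phase screen from Zernike coefficients or random-screen parameters.

    Parameters
    ----------
    zernike : mapping or sequence, optional
        Noll-indexed coefficients in radians (RMS normalization).  Mutually
        exclusive with ``rms``.
    rms : float, optional
        Target RMS phase (radians) of a random high-order screen: white
        Gaussian noise on the pupil grid, low-pass filtered by a Gaussian
        kernel of width ``corr_length`` (as a fraction of the pupil radius),
        then piston-removed and rescaled to the requested RMS over the support.
    corr_length : float
        Correlation length of the random screen as a fraction of the pupil
        radius k0*NA.  Values >= 1 degenerate toward a single smooth mode.
    """
    if (zernike is None) == (rms is None):
        raise ConfigurationError("specify exactly one of 'zernike' or 'rms'")
    mask = grid.pupil_mask
    if zernike is not None:
        KX, KY = grid.k_xy
        rho = np.hypot(KX, KY) / grid.pupil_radius
        phi = np.arctan2(KY, KX)
        p = zernike_sum(zernike, rho, phi)
        p = np.where(mask, p, 0.0)
        return PupilPhase(phase=p, grid=grid, role=role)

    if rms < 0:
        raise ConfigurationError(f"rms must be >= 0, got {rms}")
    if corr_length <= 0:
        raise ConfigurationError(f"corr_length must be > 0, got {corr_length}")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((grid.n, grid.n))
    sigma_bins = corr_length * grid.pupil_radius_bins
    p = ndimage.gaussian_filter(w, sigma_bins, mode="wrap")
    p = np.where(mask, p, 0.0)
    p[mask] -= p[mask].mean()  # piston removal
    s = np.sqrt(np.mean(p[mask] ** 2))
    if rms > 0 and s > 0:
        p[mask] *= rms / s
    elif rms == 0:
        p[:] = 0.0
    return PupilPhase(phase=p, grid=grid, role=role)


# ---------------------------------------------------------------------------
# illumination sampling
# ---------------------------------------------------------------------------

def _fermat_spiral_bins(n_target: int, grid: GridSpec) -> np.ndarray:
    """First n_target distinct pupil-grid nodes along a Fermat spiral."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    R = grid.pupil_radius_bins
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    m_total = 1
    # oversample the spiral until enough distinct on-grid nodes are collected
    while len(out) < n_target and m_total < 10000 * n_target:
        m_total *= 2
        seen.clear()
        out.clear()
        idx = np.arange(m_total) + 0.5
        rad = R * np.sqrt(idx / m_total)
        th = golden * np.arange(m_total)
        bx = np.rint(rad * np.cos(th)).astype(int)
        by = np.rint(rad * np.sin(th)).astype(int)
        ok = bx**2 + by**2 <= grid.pupil_radius_bins**2 * (1 + 1e-12)
        for x, y in zip(bx[ok], by[ok]):
            if (x, y) not in seen:
                seen.add((x, y))
                out.append((x, y))
                if len(out) == n_target:
                    break
    return np.array(out[:n_target], dtype=int)


def sample_illumination_angles(
    n_target: int, grid: GridSpec, pattern: str = "spiral"
) -> IlluminationSet:
    """Sample n_target illumination wavevectors covering the pupil uniformly.

    Both patterns return frequency-grid nodes (integer bins): 'spiral' walks a
    Fermat spiral snapped to the grid (uniform disk coverage at any count);
    'grid' returns a regular sublattice of the in-pupil nodes.  ``n_target``
    equal to the number of in-pupil nodes returns the full pupil.
    """
    if n_target < 1:
        raise ConfigurationError(f"n_target must be >= 1, got {n_target}")
    if pattern not in ("spiral", "grid"):
        raise ConfigurationError(f"unknown pattern {pattern!r}")
    capacity = len(grid.pupil_nodes)
    if n_target > capacity:
        raise ConfigurationError(
            f"n_target {n_target} exceeds the {capacity} resolvable pupil nodes "
            f"of this grid"
        )
    if n_target == 1:
        return IlluminationSet(bins=np.zeros((1, 2), dtype=int), grid=grid)
    if n_target == capacity:
        return IlluminationSet(bins=np.array(grid.pupil_nodes, dtype=int), grid=grid)

    if pattern == "spiral":
        bins = _fermat_spiral_bins(n_target, grid)
    else:
        # coarsest sublattice still holding n_target nodes, trimmed outermost-first
        nodes = np.array(grid.pupil_nodes, dtype=int)
        step = 1
        for t in range(int(np.sqrt(capacity / n_target)) + 1, 0, -1):
            sub = nodes[np.all(nodes % t == 0, axis=1)]
            if len(sub) >= n_target:
                step = t
                break
        sub = nodes[np.all(nodes % step == 0, axis=1)]
        bins = sub[:n_target]  # pupil_nodes are sorted ascending |k|
    return IlluminationSet(bins=bins, grid=grid)
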