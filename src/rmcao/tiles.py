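"""Tile-wise (isoplanatic-patch) aberration correction and stitching.

Sample-induced aberrations vary across the field of view; each aberration map
is only valid over an isoplanatic patch.  The field is therefore segmented
into tiles, the sub-matrix of each tile is corrected independently, and the
corrected tile images are blended back into a full-field image.  Tile cores
partition the field exactly; each core is expanded by an overlap margin
(window slid inward at the field edge so all tile grids stay square), and
corrected images are blended with linear feathering across the overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .correction import CLASSResults, run_class
from .grid import ConfigurationError, GridSpec
from .matrix import POSITION, ReflectionMatrix, confocal_image
from .scene import PupilPhase

__all__ = [
    "TileLayout",
    "Tile",
    "segment_field",
    "correct_and_stitch",
    "resample_pupil_phase",
]


@dataclass(frozen=True)
class TileLayout:
    """Tile counts and overlap fraction for field segmentation."""

    rows: int
    cols: int
    overlap: float = 0.25

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("tile counts must be >= 1")
        if not (0.0 <= self.overlap < 0.5):
            raise ConfigurationError("overlap fraction must lie in [0, 0.5)")

    def windows(self, n: int) -> list[dict]:
        """Per-tile index bookkeeping on an n x n field.

        Returns dicts with core slices (exact partition) and window slices
        (core +/- margin, slid inward at the edges; equal square size).
        """
        ys = np.linspace(0, n, self.rows + 1).astype(int)
        xs = np.linspace(0, n, self.cols + 1).astype(int)
        core_h = int(np.ceil(n / self.rows))
        core_w = int(np.ceil(n / self.cols))
        margin = int(round(self.overlap * max(core_h, core_w)))
        win = max(core_h, core_w) + 2 * margin
        win += win % 2  # keep tile grids even for the shared FFT conventions
        win = min(win, n)
        if win < 8:
            raise ConfigurationError(
                f"tile window {win} px smaller than 8 px: pupil sampling too coarse"
            )
        tiles = []
        for i in range(self.rows):
            for j in range(self.cols):
                cy0, cy1 = ys[i], ys[i + 1]
                cx0, cx1 = xs[j], xs[j + 1]
                wy0 = min(max(cy0 - margin, 0), n - win)
                wx0 = min(max(cx0 - margin, 0), n - win)
                tiles.append(
                    {
                        "index": (i, j),
                        "core": (slice(cy0, cy1), slice(cx0, cx1)),
                        "window": (slice(wy0, wy0 + win), slice(wx0, wx0 + win)),
                    }
                )
        return tiles


@dataclass(frozen=True)
class Tile:
    """A sub-matrix restricted to one tile window."""

    matrix: ReflectionMatrix  # position/position on the tile-local grid
    index: tuple[int, int]
    core: tuple[slice, slice]  # in full-field pixel coordinates
    window: tuple[slice, slice]


def _tile_grid(parent: GridSpec, win: int) -> GridSpec:
    return GridSpec(
        n=win,
        pitch=parent.pitch,
        wavelength=parent.wavelength,
        na=parent.na,
        n_medium=parent.n_medium,
    )


def segment_field(m: ReflectionMatrix, layout: TileLayout) -> list[Tile]:
    """Extract per-tile sub-matrices from a position/position matrix.

    Tile t holds exactly the rows and columns whose r_o and r_i fall inside
    t's window (core plus overlap margin); the union of cores reconstitutes
    the field.
    """
    if m.basis_out != POSITION or m.basis_in != POSITION:
        raise ValueError("segment_field requires a position/position matrix")
    n = m.grid.n
    tiles = []
    for w in layout.windows(n):
        wy, wx = w["window"]
        win = wy.stop - wy.start
        pix = (
            np.arange(wy.start, wy.stop)[:, None] * n
            + np.arange(wx.start, wx.stop)[None, :]
        ).ravel()
        sub = m.data[np.ix_(pix, pix)]
        tiles.append(
            Tile(
                matrix=ReflectionMatrix(
                    data=sub,
                    grid=_tile_grid(m.grid, win),
                    basis_out=POSITION,
                    basis_in=POSITION,
                    tau0=m.tau0,
                ),
                index=w["index"],
                core=w["core"],
                window=w["window"],
            )
        )
    return tiles


def _feather_weight(win: int, core: tuple[slice, slice], window: tuple[slice, slice]) -> np.ndarray:
    """Separable weight: 1 on the core, linear ramp to 0 at the window edge."""

    def ramp(c0, c1, w0, w1):
        t = np.zeros(w1 - w0)
        idx = np.arange(w0, w1)
        t[(idx >= c0) & (idx < c1)] = 1.0
        lm = c0 - w0
        if lm > 0:
            left = idx < c0
            t[left] = (idx[left] - w0 + 1) / (lm + 1)
        rm = w1 - c1
        if rm > 0:
            right = idx >= c1
            t[right] = (w1 - idx[right]) / (rm + 1)
        return t

    (cy, cx), (wy, wx) = core, window
    ty = ramp(cy.start, cy.stop, wy.start, wy.stop)
    tx = ramp(cx.start, cx.stop, wx.start, wx.stop)
    return ty[:, None] * tx[None, :]


def correct_and_stitch(
    tiles: list[Tile],
    tol: float = 1e-3,
    max_iter: int = 30,
    feather: bool = True,
) -> tuple[np.ndarray, list[CLASSResults | None], np.ndarray]:
    """Run the correction on every tile and blend the corrected images.

    Returns (full-field corrected intensity image, per-tile results in layout
    order, boolean failure mask in layout order).  A failing tile contributes
    its uncorrected confocal image and a None result instead of crashing.
    With ``feather=False`` only the (disjoint) cores are used, so stitching
    with zero correction reproduces the original confocal image bit-exactly.
    """
    if not tiles:
        raise ValueError("no tiles")
    n = max(t.window[0].stop for t in tiles)
    n = max(n, max(t.window[1].stop for t in tiles))
    acc = np.zeros((n, n))
    wacc = np.zeros((n, n))
    results: list[CLASSResults | None] = []
    failed = []
    for t in tiles:
        try:
            res = run_class(t.matrix, tol=tol, max_iter=max_iter)
            img = res.corrected_image()
            results.append(res)
            failed.append(False)
        except Exception:
            img = confocal_image(t.matrix)
            results.append(None)
            failed.append(True)
        wy, wx = t.window
        if feather:
            wgt = _feather_weight(wy.stop - wy.start, t.core, t.window)
            acc[wy, wx] += wgt * img
            wacc[wy, wx] += wgt
        else:
            cy, cx = t.core
            ly = slice(cy.start - wy.start, cy.stop - wy.start)
            lx = slice(cx.start - wx.start, cx.stop - wx.start)
            acc[cy, cx] = img[ly, lx]
            wacc[cy, cx] = 1.0
    out = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), 0.0)
    return out, results, np.array(failed, dtype=bool)


def resample_pupil_phase(phase: PupilPhase, target: GridSpec) -> PupilPhase:
    """Resample a pupil phase map onto another grid's pupil raster.

    Interpolates the complex pupil function on normalized pupil coordinates
    k / (k0 NA), so maps estimated on different tile grids become comparable.
    """
    src = phase.grid
    u = src.k_bins / src.pupil_radius_bins  # normalized pupil coordinate
    z = np.where(src.pupil_mask, np.exp(1j * phase.phase), 0.0)
    interp = RegularGridInterpolator(
        (u, u), z, bounds_error=False, fill_value=0.0, method="linear"
    )
    ut = target.k_bins / target.pupil_radius_bins
    UX, UY = np.meshgrid(ut, ut, indexing="xy")
    zt = interp(np.stack([UY.ravel(), UX.ravel()], axis=-1)).reshape(target.n, target.n)
    p = np.where(target.pupil_mask & (np.abs(zt) > 1e-9), np.angle(zt), 0.0)
    return PupilPhase(phase=p, grid=target, role=phase.role)
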