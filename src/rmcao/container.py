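"""HDF5 run container and TIFF export.

One HDF5 file per run holds every complex-valued payload losslessly:

    /meta/{wavelength,na,pitch,n,n_medium,tau0}    acquisition metadata
    /truth/{specimen,phase_in,phase_out}           simulator ground truth
    /frames/NNN                                    raw interferograms (real)
    /fields/NNN                                    lab-frame complex maps
    /matrix/{data,k_in,basis_in,basis_out}         reflection matrix
    /correction/{theta_in,theta_out,trace}         accumulated corrections

Every dataset written through :func:`write_dataset` carries provenance
attributes (stage, seed, config hash).  TIFF is used only for human-viewable
exports (32-bit float).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import h5py
import numpy as np
import tifffile

from .grid import GridSpec
from .matrix import ReflectionMatrix

__all__ = [
    "write_meta",
    "read_meta",
    "write_dataset",
    "write_matrix",
    "read_matrix",
    "write_frames",
    "read_frames",
    "export_tiff",
]


def write_dataset(
    h5: h5py.File | h5py.Group,
    name: str,
    data: np.ndarray,
    *,
    stage: str = "",
    seed: int | None = None,
    config_hash: str = "",
) -> h5py.Dataset:
    if name in h5:
        del h5[name]
    ds = h5.create_dataset(name, data=np.asarray(data))
    ds.attrs["stage"] = stage
    ds.attrs["config_hash"] = config_hash
    if seed is not None:
        ds.attrs["seed"] = seed
    return ds


def write_meta(h5: h5py.File, grid: GridSpec, tau0: float = 0.0, **extra: Any) -> None:
    g = h5.require_group("meta")
    g.attrs.update(
        wavelength=grid.wavelength,
        na=grid.na,
        pitch=grid.pitch,
        n=grid.n,
        n_medium=grid.n_medium,
        tau0=tau0,
        **extra,
    )


def read_meta(h5: h5py.File) -> tuple[GridSpec, float]:
    a = h5["meta"].attrs
    grid = GridSpec(
        n=int(a["n"]),
        pitch=float(a["pitch"]),
        wavelength=float(a["wavelength"]),
        na=float(a["na"]),
        n_medium=float(a.get("n_medium", 1.33)),
    )
    return grid, float(a.get("tau0", 0.0))


def write_matrix(h5: h5py.File, m: ReflectionMatrix, **prov: Any) -> None:
    write_dataset(h5, "matrix/data", m.data, **prov)
    if m.k_in is not None:
        write_dataset(h5, "matrix/k_in", m.k_in, **prov)
    if m.k_out is not None:
        write_dataset(h5, "matrix/k_out", m.k_out, **prov)
    h5["matrix"].attrs["basis_in"] = m.basis_in
    h5["matrix"].attrs["basis_out"] = m.basis_out
    write_meta(h5, m.grid, tau0=m.tau0)


def read_matrix(h5: h5py.File) -> ReflectionMatrix:
    grid, tau0 = read_meta(h5)
    g = h5["matrix"]
    return ReflectionMatrix(
        data=g["data"][...],
        grid=grid,
        basis_out=g.attrs["basis_out"],
        basis_in=g.attrs["basis_in"],
        k_in=g["k_in"][...] if "k_in" in g else None,
        k_out=g["k_out"][...] if "k_out" in g else None,
        tau0=tau0,
    )


def write_frames(
    h5: h5py.File, frames: list[np.ndarray], group: str = "frames", **prov: Any
) -> None:
    for i, f in enumerate(frames):
        write_dataset(h5, f"{group}/{i:03d}", f, **prov)


def read_frames(h5: h5py.File, group: str = "frames") -> list[np.ndarray]:
    g = h5[group]
    return [g[k][...] for k in sorted(g.keys())]


def export_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a real image or stack as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
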