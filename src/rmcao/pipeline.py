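"""End-to-end pipeline driver: simulate/ingest -> demodulate -> assemble ->
correct -> reconstruct, with one HDF5 container per run.

Each run directory receives the resolved config (YAML), a structured log with
per-stage timings, the HDF5 payload and TIFF exports of the human-viewable
images.  Runs are deterministic in (config, seed): all stage seeds are spawned
from the global seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from . import container
from .config import PipelineConfig
from .correction import CLASSResults, run_class
from .demod import hilbert_demodulate, to_lab_frame
from .grid import GridSpec
from .matrix import ReflectionMatrix, to_position_basis
from .scene import make_aberration, make_specimen, sample_illumination_angles
from .simulate import (
    ComplexFieldMap,
    InterferogramConfig,
    NoiseSpec,
    assemble_matrix,
    simulate_reflection_field,
    synthesize_interferogram,
)
from .tiles import TileLayout, correct_and_stitch, segment_field
from .volume import assemble_volume, max_intensity_projection

__all__ = ["run_pipeline", "PipelineResult"]

log = logging.getLogger("rmcao.pipeline")


@dataclass
class PipelineResult:
    run_dir: Path
    h5_path: Path
    corrected_image: np.ndarray
    uncorrected_image: np.ndarray
    results: list[CLASSResults | None]
    mip: np.ndarray | None


def _grid_from_config(cfg: PipelineConfig) -> GridSpec:
    g = cfg.grid
    return GridSpec(
        n=g.n,
        pitch=g.pitch_um,
        wavelength=g.wavelength_um,
        na=g.na,
        n_medium=g.n_medium,
    )


def _aberration(block, grid, seed, role):
    if block.kind == "none":
        return make_aberration(grid, rms=0.0, seed=seed, role=role)
    if block.kind == "zernike":
        return make_aberration(grid, zernike=block.zernike, role=role)
    return make_aberration(
        grid, rms=block.rms_rad, corr_length=block.corr_length, seed=seed, role=role
    )


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path | None = None) -> PipelineResult:
    """Execute the configured chain and write all artifacts to the run directory."""
    t_start = time.perf_counter()
    run_dir = Path(run_dir) if run_dir is not None else Path(cfg.out_dir) / f"run-{cfg.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(cfg.resolved_yaml())
    chash = cfg.config_hash()
    prov = dict(config_hash=chash, seed=cfg.seed)
    timings: dict[str, float] = {}

    grid = _grid_from_config(cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    h5_path = run_dir / "run.h5"
    with h5py.File(h5_path, "w") as h5:
        # --- scene -------------------------------------------------------
        t0 = time.perf_counter()
        specimen = make_specimen(cfg.scene.preset, grid, seed=seed_ints[0])
        phase_in = _aberration(cfg.aberration_in, grid, seed_ints[1], "input")
        phase_out = _aberration(cfg.aberration_out, grid, seed_ints[2], "output")
        illum = sample_illumination_angles(
            cfg.illumination.n_target, grid, cfg.illumination.pattern
        )
        container.write_dataset(h5, "truth/specimen", specimen.reflectivity, stage="scene", **prov)
        container.write_dataset(h5, "truth/phase_in", phase_in.phase, stage="scene", **prov)
        container.write_dataset(h5, "truth/phase_out", phase_out.phase, stage="scene", **prov)
        timings["scene"] = time.perf_counter() - t0

        # --- acquisition -------------------------------------------------
        t0 = time.perf_counter()
        noise = NoiseSpec(gamma=cfg.noise.gamma, seed=seed_ints[3])
        if cfg.interferogram is not None:
            # snap the carrier to a frequency-grid bin for exact demodulation
            kdg_x = round(cfg.interferogram.k_dg_over_kna * grid.pupil_radius / grid.dk) * grid.dk
            icfg = InterferogramConfig(
                k_dg=(kdg_x, 0.0),
                e_r0=cfg.interferogram.e_r0,
                camera_noise_var=cfg.interferogram.camera_noise_var,
            )
            cols = np.empty((grid.n**2, illum.n_in), dtype=complex)
            frames = []
            for j, k_i in enumerate(illum.k):
                fld = simulate_reflection_field(specimen, phase_in, phase_out, k_i, grid)
                frame = synthesize_interferogram(fld, k_i, icfg, seed=seed_ints[3] + j)
                frames.append(frame.data)
                e_gm = hilbert_demodulate(frame, np.asarray(icfg.k_dg))
                cols[:, j] = to_lab_frame(e_gm, k_i, icfg.e_r0).field.ravel()
            container.write_frames(h5, frames, stage="acquire", **prov)
            matrix = ReflectionMatrix(
                data=cols, grid=grid, basis_out="position", basis_in="wavevector",
                k_in=np.array(illum.bins, dtype=int),
            )
            # demodulation leaves the DC/conjugate terms behind; keep the matrix
            # as the lab-frame estimate of the single-scattering field
        else:
            matrix = assemble_matrix(specimen, phase_in, phase_out, illum, grid, noise)
        container.write_matrix(h5, matrix, stage="acquire", **prov)
        timings["acquire"] = time.perf_counter() - t0

        # --- correction --------------------------------------------------
        t0 = time.perf_counter()
        uncorrected = matrix.confocal()
        layout = TileLayout(cfg.correction.tile_rows, cfg.correction.tile_cols, cfg.correction.overlap)
        last_field: ComplexFieldMap
        if layout.rows == 1 and layout.cols == 1:
            res = run_class(matrix, tol=cfg.correction.tol, max_iter=cfg.correction.max_iter)
            corrected = res.corrected_image()
            results: list[CLASSResults | None] = [res]
            container.write_dataset(h5, "correction/theta_in", res.theta_in.phase, stage="correct", **prov)
            container.write_dataset(h5, "correction/theta_out", res.theta_out.phase, stage="correct", **prov)
            container.write_dataset(h5, "correction/trace", res.intensity_trace, stage="correct", **prov)
            log.info("correction trace: %s", res.intensity_trace.tolist())
            diag = res._state  # diagonal field for refocusing
            from .grid import ifft2c

            last_field = ComplexFieldMap(field=ifft2c(diag.D) / grid.n, grid=grid)
        else:
            pos = to_position_basis(matrix, "both")
            tls = segment_field(pos, layout)
            corrected, results, failmask = correct_and_stitch(
                tls, tol=cfg.correction.tol, max_iter=cfg.correction.max_iter
            )
            for t, r in zip(tls, results):
                if r is None:
                    continue
                i, j = t.index
                container.write_dataset(h5, f"correction/tiles/{i}_{j}/theta_in", r.theta_in.phase, stage="correct", **prov)
                container.write_dataset(h5, f"correction/tiles/{i}_{j}/theta_out", r.theta_out.phase, stage="correct", **prov)
                container.write_dataset(h5, f"correction/tiles/{i}_{j}/trace", r.intensity_trace, stage="correct", **prov)
            container.write_dataset(h5, "correction/failed", failmask, stage="correct", **prov)
            last_field = ComplexFieldMap(field=np.sqrt(corrected).astype(complex), grid=grid)
        container.write_dataset(h5, "correction/image", corrected, stage="correct", **prov)
        container.write_dataset(h5, "correction/uncorrected", uncorrected, stage="correct", **prov)
        timings["correct"] = time.perf_counter() - t0

        # --- volume ------------------------------------------------------
        mip = None
        if cfg.volume.enabled:
            t0 = time.perf_counter()
            v = cfg.volume
            zs = np.arange(v.z_min_um, v.z_max_um + 1e-9, v.fine_step_um)
            from .volume import angular_spectrum_propagate

            slices = [(float(z), angular_spectrum_propagate(last_field, float(z))) for z in zs]
            stack = assemble_volume(slices, v.fine_step_um)
            mip = max_intensity_projection(stack)
            container.write_dataset(h5, "volume/mip", mip, stage="volume", **prov)
            container.write_dataset(h5, "volume/z", stack.z, stage="volume", **prov)
            timings["volume"] = time.perf_counter() - t0

    container.export_tiff(run_dir / "confocal_uncorrected.tif", uncorrected)
    container.export_tiff(run_dir / "confocal_corrected.tif", corrected)
    if mip is not None:
        container.export_tiff(run_dir / "mip.tif", mip)
    timings["total"] = time.perf_counter() - t_start
    (run_dir / "log.json").write_text(
        json.dumps({"timings_s": timings, "config_hash": chash, "seed": cfg.seed}, indent=2)
    )
    log.info("pipeline finished in %.2f s -> %s", timings["total"], run_dir)
    return PipelineResult(
        run_dir=run_dir,
        h5_path=h5_path,
        corrected_image=corrected,
        uncorrected_image=uncorrected,
        results=results,
        mip=mip,
    )
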