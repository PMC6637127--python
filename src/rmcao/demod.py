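"""Off-axis interferogram demodulation and rotating-frame conversion.

A raw frame ``I = |E_S + E_R|^2`` with co-scanned reference
``E_R = E_R0 exp(-i (k_i + k_DG).r)`` carries the interference term

    E_GM(r) = E_S(r) (E_R0 exp(-i k_i.r))*   riding on the carrier exp(+i k_DG.r).

Demodulation (the 2-D Hilbert transform with respect to k_DG) windows the
frame spectrum in a disk about +k_DG and removes the carrier, yielding the
complex field in the rotating-reference frame; dividing out the conjugate
reference ramp converts to the laboratory frame.  The illumination wavevector
of each frame is calibrated from diffusive-sample frames, whose demodulated
spectrum is the pupil disk centered at +k_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, fft2c, ifft2c
from .matrix import POSITION
from .simulate import ComplexFieldMap, Interferogram

__all__ = [
    "CarrierEstimate",
    "DemodulationError",
    "CalibrationError",
    "hilbert_demodulate",
    "estimate_illumination_wavevector",
    "to_lab_frame",
]


class DemodulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CarrierEstimate:
    """Per-frame illumination wavevector estimate with a confidence figure."""

    k_hat: np.ndarray  # (2,) rad/um
    confidence: float  # peak-to-background ratio of the located spectral peak


def hilbert_demodulate(
    frame: Interferogram,
    k_dg: np.ndarray,
    band_radius: float | None = None,
) -> ComplexFieldMap:
    """Recover E_GM(r_o; k_i, tau0) from an off-axis frame.

    The frame spectrum is windowed by a hard disk of ``band_radius`` about
    +k_DG (default ``2 k0 NA``, wide enough for any in-pupil illumination)
    and the carrier is removed so k_DG maps to zero frequency.  No
    apodization: the pupil already band-limits the true signal, and a taper
    would bias the pupil edge where aberration estimates live.
    """
    grid = frame.grid
    k_dg = np.asarray(k_dg, dtype=float)
    if band_radius is None:
        band_radius = 2.0 * grid.pupil_radius
    kdg_mag = float(np.hypot(*k_dg))
    # the DC (autocorrelation) band has radius 2 k0 NA
    if band_radius + 2.0 * grid.pupil_radius > kdg_mag:
        raise DemodulationError(
            "sideband window overlaps the DC band: require "
            f"band_radius + 2 k0 NA <= |k_DG|, got {band_radius:.4g} + "
            f"{2 * grid.pupil_radius:.4g} > {kdg_mag:.4g}"
        )
    KX, KY = grid.k_xy
    window = (KX - k_dg[0]) ** 2 + (KY - k_dg[1]) ** 2 <= band_radius**2 * (1 + 1e-12)
    sideband = ifft2c(fft2c(frame.data) * window)
    e_gm = sideband * np.conj(grid.ramp(k_dg))  # shift carrier to zero frequency
    return ComplexFieldMap(
        field=e_gm, grid=grid, basis=POSITION, k_in=frame.k_in, tau0=frame.tau0
    )


def _quadratic_peak_refine(F: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-bin offset of a spectral peak from a 3x3 log-magnitude fit."""
    n0, n1 = F.shape

    def off(fm, f0, fp):
        den = fm - 2 * f0 + fp
        if den >= 0 or not np.isfinite(den):
            return 0.0
        return float(np.clip(0.5 * (fm - fp) / den, -0.5, 0.5))

    eps = 1e-300
    Fl = np.log(np.maximum(F, eps))
    dy = off(Fl[(iy - 1) % n0, ix], Fl[iy, ix], Fl[(iy + 1) % n0, ix])
    dx = off(Fl[iy, (ix - 1) % n1], Fl[iy, ix], Fl[iy, (ix + 1) % n1])
    return dx, dy


def estimate_illumination_wavevector(
    calib_frames: list[ComplexFieldMap],
    confidence_threshold: float = 3.0,
) -> list[CarrierEstimate]:
    """Estimate k_i for each demodulated diffusive-sample frame E_GM.

    The spectrum of a diffuse-sample E_GM is the pupil disk translated to
    +k_i.  When a single bin dominates the power (quasi-plane-wave frame) its
    location is refined directly by quadratic interpolation over 3x3 bins;
    otherwise the disk center is located by matched filtering the power
    spectrum with the pupil-disk indicator, refined the same way.
    """
    if not calib_frames:
        raise CalibrationError("need at least one calibration frame")
    grid = calib_frames[0].grid
    if any(f.grid != grid for f in calib_frames):
        raise CalibrationError("calibration frames must share one GridSpec")
    disk = np.fft.ifftshift(grid.pupil_mask).astype(float)
    disk_f = np.fft.fft2(disk)
    out: list[CarrierEstimate] = []
    c = grid.n // 2
    for f in calib_frames:
        P = np.abs(fft2c(f.field)) ** 2
        total = P.sum()
        if total == 0:
            raise CalibrationError("empty calibration frame")
        iy, ix = np.unravel_index(np.argmax(P), P.shape)
        if P[iy, ix] > 0.5 * total:
            # concentrated peak: refine on the raw spectrum
            dx, dy = _quadratic_peak_refine(P, iy, ix)
            conf = float(P[iy, ix] / max(np.median(P), 1e-300))
        else:
            # diffuse disk: circular cross-correlation with the pupil indicator
            C = np.fft.fftshift(
                np.real(np.fft.ifft2(np.fft.fft2(np.fft.ifftshift(P)) * np.conj(disk_f)))
            )
            iy, ix = np.unravel_index(np.argmax(C), C.shape)
            dx, dy = _quadratic_peak_refine(np.maximum(C, 0.0), iy, ix)
            conf = float(C[iy, ix] / max(np.median(C), 1e-300))
        if conf < confidence_threshold:
            raise CalibrationError(
                f"no spectral peak above confidence threshold ({conf:.2f} < "
                f"{confidence_threshold})"
            )
        k_hat = np.array([(ix - c + dx), (iy - c + dy)]) * grid.dk
        if not grid.in_pupil(k_hat):
            # clamp pathological refinements to the pupil edge direction
            k_hat *= grid.pupil_radius / np.hypot(*k_hat)
        out.append(CarrierEstimate(k_hat=k_hat, confidence=conf))
    return out


def to_lab_frame(
    e_gm: ComplexFieldMap, k_i: np.ndarray, e_r0: float = 1.0
) -> ComplexFieldMap:
    """Convert E_GM to the laboratory frame: E_S = E_GM exp(-i k_i.r) / E_R0."""
    if e_r0 <= 0:
        raise ValueError(f"reference amplitude must be positive, got {e_r0}")
    k_i = np.asarray(k_i, dtype=float)
    field = e_gm.field * np.conj(e_gm.grid.ramp(k_i)) / e_r0
    return ComplexFieldMap(
        field=field, grid=e_gm.grid, basis=POSITION, k_in=k_i, tau0=e_gm.tau0
    )
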