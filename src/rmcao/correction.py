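"""Single-scattering accumulation (CLASS) aberration correction.

The time-gated reflection matrix in the wavevector basis,
``E(k_o; k_i) = P(k_o) exp(i theta_o(k_o)) O~(k_o + k_i) exp(i theta_i(k_i))``,
couples every output mode k_o and input mode k_i through the object spectrum
O~ evaluated at q = k_o + k_i.  Shifting each input column by its own k_i
(and each output row by its k_o) aligns all single-scattered contributions on
the shared object spectrum, while multiple-scattering speckle stays
incoherent.  The correction therefore seeks phase-only maps theta(k_i),
theta(k_o) that maximize the total confocal (diagonal) intensity

    I_total = sum_r |E(r_o = r; r_i = r)|^2 = sum_q |D(q)|^2 / n^2,
    D(q)    = sum_{k_i} E(q - k_i; k_i).

The update for one mode is the exact single-coordinate maximizer: with
c_k the mode's contribution to the diagonal amplitude and S_k the sum of all
other contributions, the phase  theta = -arg <c_k, S_k>  maximizes
``sum |S_k + e^{i theta} c_k|^2``, so applying modes sequentially
(Gauss-Seidel, ascending |k|) never decreases the objective.  Iterating
input and output sweeps to convergence accumulates the sample-induced
aberrations ``theta(k) = sum_j theta^(j)(k)``; the recovered maps carry the
usual piston and tip/tilt (global image shift) gauge freedom.

The module follows a model/results idiom: :class:`CLASSModel` wraps a
reflection matrix, ``fit()`` returns :class:`CLASSResults` with the
accumulated pupils, the per-iteration intensity trace and the corrected
matrix; :func:`run_class` is the functional shorthand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import GridSpec, fft2c, ifft2c
from .matrix import (
    POSITION,
    WAVEVECTOR,
    ReflectionMatrix,
    to_position_basis,
    to_wavevector_basis,
)
from .scene import PupilPhase

__all__ = [
    "CLASSModel",
    "CLASSResults",
    "CorrectionError",
    "input_correction_step",
    "output_correction_step",
    "run_class",
    "pupil_cross_correlation",
    "compare_to_truth",
    "PhaseResidualReport",
]


class CorrectionError(RuntimeError):
    """Correction cannot proceed (no signal, non-finite intensities, ...)."""


# ---------------------------------------------------------------------------
# internal state: the k/k matrix in its diagonal-aligned representation
# ---------------------------------------------------------------------------

class _KKState:
    """k/k matrix stored as q-aligned column stack U[q, j] = E(q - k_j; k_j).

    ``U`` has shape (n, n, n_in) on the centered q grid (circular shifts);
    ``D = sum_j U[..., j]`` is the object-spectrum accumulation whose power
    equals n^2 times the total confocal intensity.

    Both axes are kept on the full frequency grid (lossless even for windowed
    tile sub-matrices, whose spectra leak beyond the pupil); the Gauss-Seidel
    sweeps update only the in-pupil modes, where aberrations live.
    """

    def __init__(self, m: ReflectionMatrix):
        grid = m.grid
        self.grid = grid
        self.tau0 = m.tau0
        n, c = grid.n, grid.n // 2
        n_cols = m.data.shape[1]

        # output axis -> full centered k_o grid per column
        if m.basis_out == POSITION:
            cols_k = np.empty((n, n, n_cols), dtype=complex)
            for j in range(n_cols):
                cols_k[:, :, j] = fft2c(m.data[:, j].reshape(n, n))
        else:
            cols_k = np.zeros((n, n, n_cols), dtype=complex)
            oy, ox = c + m.k_out[:, 1], c + m.k_out[:, 0]
            cols_k[oy, ox, :] = m.data

        # input axis -> wavevector modes
        if m.basis_in == POSITION:
            # unitary DFT over the input index; all n^2 modes retained
            X = cols_k.reshape(n * n, n, n)
            X = np.fft.ifftshift(X, axes=(1, 2))
            X = np.fft.fft2(X, axes=(1, 2), norm="ortho")
            X = np.fft.fftshift(X, axes=(1, 2))
            cols_k = X.reshape(n, n, n, n)  # (k_o grid, biy, bix)
            bb = grid.k_bins
            BX, BY = np.meshgrid(bb, bb, indexing="xy")
            self.k_in = np.column_stack([BX.ravel(), BY.ravel()]).astype(int)
            cols_k = cols_k.reshape(n, n, n * n)
        else:
            self.k_in = np.array(m.k_in, dtype=int)

        self.n_in = cols_k.shape[2]
        self.U = np.empty_like(cols_k)
        for j in range(self.n_in):
            self.U[:, :, j] = np.roll(
                cols_k[:, :, j], (self.k_in[j][1], self.k_in[j][0]), axis=(0, 1)
            )
        del cols_k
        self.D = self.U.sum(axis=2)

        # updated input modes: the in-pupil subset, ascending |k_i|
        in_pupil = grid.in_pupil(self.k_in * grid.dk)
        idx = np.nonzero(in_pupil)[0]
        r2 = self.k_in[idx, 0] ** 2 + self.k_in[idx, 1] ** 2
        self._in_order = idx[np.argsort(r2, kind="stable")]
        self.k_in_updated = self.k_in[self._in_order]

        # updated output rows: the in-pupil frequency nodes, ascending |k_o|
        self.k_out = np.array(grid.pupil_nodes, dtype=int)
        self.n_out = len(self.k_out)
        oy, ox = c + self.k_out[:, 1], c + self.k_out[:, 0]
        qy = (oy[:, None] + self.k_in[None, :, 1]) % n
        qx = (ox[:, None] + self.k_in[None, :, 0]) % n
        self._q_flat = qy * n + qx  # (n_out, n_in)
        self._cols = np.arange(self.n_in)

    def total_intensity(self) -> float:
        return float(np.sum(np.abs(self.D) ** 2)) / self.grid.n**2

    def input_sweep(self, theta: np.ndarray) -> None:
        """One Gauss-Seidel pass over in-pupil input modes, ascending |k_i|."""
        for t, j in enumerate(self._in_order):
            u = self.U[:, :, j]
            S = self.D - u
            g = np.vdot(S, u)  # sum_q u conj(S)
            if g == 0:
                continue
            dth = -np.angle(g)
            u *= np.exp(1j * dth)
            theta[t] += dth
            np.add(S, u, out=self.D)

    def output_sweep(self, theta: np.ndarray) -> None:
        """One Gauss-Seidel pass over in-pupil output modes, ascending |k_o|."""
        Df = self.D.ravel()
        Uf = self.U.reshape(-1, self.n_in)
        for i in range(self.n_out):
            q = self._q_flat[i]
            # row i of the k/k matrix lives at U[q_j, j] for each column j
            row = Uf[q, self._cols]
            S = Df[q] - row
            g = np.sum(row * np.conj(S))
            if g == 0:
                continue
            dth = -np.angle(g)
            row = row * np.exp(1j * dth)
            Uf[q, self._cols] = row
            Df[q] = S + row
            theta[i] += dth

    def to_matrix(self) -> ReflectionMatrix:
        """Materialize the corrected matrix in the wavevector/wavevector basis.

        Rows cover the full frequency grid (k_out lists all n^2 nodes)."""
        n = self.grid.n
        bb = self.grid.k_bins
        BX, BY = np.meshgrid(bb, bb, indexing="xy")
        k_out = np.column_stack([BX.ravel(), BY.ravel()]).astype(int)
        data = np.empty((n * n, self.n_in), dtype=complex)
        for j in range(self.n_in):
            buf = np.roll(
                self.U[:, :, j], (-self.k_in[j][1], -self.k_in[j][0]), axis=(0, 1)
            )
            data[:, j] = buf.ravel()
        return ReflectionMatrix(
            data=data,
            grid=self.grid,
            basis_out=WAVEVECTOR,
            basis_in=WAVEVECTOR,
            k_in=self.k_in,
            k_out=k_out,
            tau0=self.tau0,
        )


def _phase_map(grid: GridSpec, nodes: np.ndarray, values: np.ndarray) -> PupilPhase:
    """Embed per-node phases into a pupil-supported map, wrapped to (-pi, pi]."""
    c = grid.n // 2
    p = np.zeros((grid.n, grid.n))
    p[c + nodes[:, 1], c + nodes[:, 0]] = np.angle(np.exp(1j * values))
    p[~grid.pupil_mask] = 0.0
    return PupilPhase(phase=p, grid=grid, role="correction")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class CLASSResults:
    """Accumulated aberration estimates and diagnostics of a CLASS fit.

    ``theta_in`` / ``theta_out`` are the estimated sample-induced aberrations
    (the sum over iterations of the applied correction maps, negated: the
    correction that maximizes the confocal intensity is the conjugate of the
    aberration).  Both are defined up to piston and tip/tilt.
    """

    theta_in: PupilPhase
    theta_out: PupilPhase
    intensity_trace: np.ndarray  # length n_iterations + 1
    n_iterations: int
    converged: bool
    tol: float
    model: "CLASSModel" = field(repr=False)
    _state: _KKState = field(repr=False)
    _corrected: ReflectionMatrix | None = field(default=None, repr=False)

    @property
    def theta_in_nodes(self) -> np.ndarray:
        """Accumulated input estimate at the updated k_i nodes (radians)."""
        return self.theta_in.at_nodes(self._state.k_in_updated)

    @property
    def theta_out_nodes(self) -> np.ndarray:
        return self.theta_out.at_nodes(self._state.k_out)

    @property
    def corrected_matrix(self) -> ReflectionMatrix:
        """Corrected matrix in the position/position basis (cached)."""
        if self._corrected is None:
            self._corrected = to_position_basis(self._state.to_matrix(), "both")
        return self._corrected

    def corrected_matrix_kk(self) -> ReflectionMatrix:
        """Corrected matrix in the wavevector/wavevector basis (cheap)."""
        return self._state.to_matrix()

    def corrected_image(self) -> np.ndarray:
        """Aberration-corrected confocal intensity image |E(r, r)|^2."""
        # diagonal amplitude d(r) = (1/n^2) sum_q D(q) exp(i q.r) = ifft2c(D)/n
        return np.abs(ifft2c(self._state.D)) ** 2 / self._state.grid.n**2

    def enhancement(self) -> float:
        """Total-intensity gain of the correction, I_final / I_initial."""
        return float(self.intensity_trace[-1] / self.intensity_trace[0])

    def summary(self) -> str:
        g = self._state.grid
        rows = [
            "Single-scattering accumulation (CLASS) fit",
            "=" * 46,
            f"grid                 {g.n} x {g.n} px, pitch {g.pitch * 1e3:.0f} nm",
            f"wavelength / NA      {g.wavelength * 1e3:.0f} nm / {g.na}",
            f"input modes          {self._state.n_in}",
            f"output pupil nodes   {self._state.n_out}",
            f"iterations           {self.n_iterations} "
            f"({'converged' if self.converged else 'max_iter reached'}, tol {self.tol:g})",
            f"total intensity      {self.intensity_trace[0]:.6g} -> "
            f"{self.intensity_trace[-1]:.6g} (x{self.enhancement():.2f})",
            f"theta_in RMS         {np.sqrt(np.mean(self.theta_in_nodes**2)):.3f} rad (wrapped)",
            f"theta_out RMS        {np.sqrt(np.mean(self.theta_out_nodes**2)):.3f} rad (wrapped)",
        ]
        return "\n".join(rows)

    def plot_pupils(self, axes=None):
        """Show the accumulated input/output aberration maps (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(8, 4))
        for ax, ph, name in zip(axes, (self.theta_in, self.theta_out), ("input", "output")):
            im = ax.imshow(ph.wrapped, cmap="twilight", vmin=-np.pi, vmax=np.pi)
            ax.set_title(f"theta ({name})")
            ax.set_axis_off()
            plt.colorbar(im, ax=ax, label="rad")
        return axes


class CLASSModel:
    """Iterative two-sided pupil-phase correction of a reflection matrix.

    Parameters
    ----------
    matrix : ReflectionMatrix
        In any basis; converted internally to wavevector/wavevector.

    Examples
    --------
    >>> res = CLASSModel(matrix).fit(tol=1e-3, max_iter=30)
    >>> print(res.summary())
    """

    def __init__(self, matrix: ReflectionMatrix):
        if matrix.total_power() == 0:
            raise CorrectionError("zero matrix: no signal to correct")
        self.matrix = matrix

    def fit(self, tol: float = 1e-3, max_iter: int = 30) -> CLASSResults:
        """Alternate input/output sweeps until the total intensity converges.

        Stops when the relative change of the total diagonal intensity falls
        below ``tol`` or after ``max_iter`` iterations (one iteration = one
        input sweep + one output sweep).
        """
        if max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {max_iter}")
        if tol <= 0:
            raise ValueError(f"tol must be > 0, got {tol}")
        state = _KKState(self.matrix)
        th_in = np.zeros(len(state.k_in_updated))
        th_out = np.zeros(state.n_out)
        trace = [state.total_intensity()]
        converged = False
        for it in range(1, max_iter + 1):
            state.input_sweep(th_in)
            state.output_sweep(th_out)
            total = state.total_intensity()
            if not np.isfinite(total):
                raise CorrectionError(f"non-finite total intensity at iteration {it}")
            trace.append(total)
            if abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
                converged = True
                break
        self._fix_gauge(state, th_in, th_out)
        return CLASSResults(
            theta_in=_phase_map(state.grid, state.k_in_updated, -th_in),
            theta_out=_phase_map(state.grid, state.k_out, -th_out),
            intensity_trace=np.array(trace),
            n_iterations=len(trace) - 1,
            converged=converged,
            tol=tol,
            model=self,
            _state=state,
        )

    @staticmethod
    def _fix_gauge(state: _KKState, th_in: np.ndarray, th_out: np.ndarray) -> None:
        """Remove the piston and common-tilt gauge from the accumulated maps.

        A common linear phase on both pupils only shifts the corrected image
        (D(q) picks up a pure ramp); the solver's random walk along this flat
        direction is removed so fits are comparable across runs and tiles.
        The compensating ramp is applied to the state, leaving the objective
        untouched.  The accumulated sums are unwrapped by construction, so an
        ordinary least-squares plane fit is well defined.
        """

        def plane(nodes: np.ndarray, th: np.ndarray) -> np.ndarray:
            A = np.column_stack([np.ones(len(nodes)), nodes[:, 0], nodes[:, 1]])
            coef, *_ = np.linalg.lstsq(A.astype(float), th, rcond=None)
            return coef

        c_in = plane(state.k_in_updated, th_in)
        c_out = plane(state.k_out, th_out)
        a = (c_in[1:] + c_out[1:]) / 2.0  # common tilt, rad per bin
        th_in -= c_in[0] + state.k_in_updated @ a
        th_out -= c_out[0] + state.k_out @ a
        bb = state.grid.k_bins
        BX, BY = np.meshgrid(bb, bb, indexing="xy")
        ramp = np.exp(-1j * (c_in[0] + c_out[0] + a[0] * BX + a[1] * BY))
        state.U *= ramp[:, :, None]
        state.D *= ramp

# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def input_correction_step(m: ReflectionMatrix) -> tuple[PupilPhase, ReflectionMatrix]:
    """One Gauss-Seidel sweep of per-column phases theta_i(k_i).

    Requires both axes in the wavevector basis; returns the applied map and
    the updated matrix.
    """
    if m.basis_out != WAVEVECTOR or m.basis_in != WAVEVECTOR:
        raise ValueError("input_correction_step requires a wavevector/wavevector matrix")
    if m.total_power() == 0:
        raise CorrectionError("zero matrix: no signal to correct")
    state = _KKState(m)
    th = np.zeros(len(state.k_in_updated))
    state.input_sweep(th)
    return _phase_map(state.grid, state.k_in_updated, th), state.to_matrix()


def output_correction_step(m: ReflectionMatrix) -> tuple[PupilPhase, ReflectionMatrix]:
    """One Gauss-Seidel sweep of per-row phases theta_o(k_o) (mirror of input)."""
    if m.basis_out != WAVEVECTOR or m.basis_in != WAVEVECTOR:
        raise ValueError("output_correction_step requires a wavevector/wavevector matrix")
    if m.total_power() == 0:
        raise CorrectionError("zero matrix: no signal to correct")
    state = _KKState(m)
    th = np.zeros(state.n_out)
    state.output_sweep(th)
    return _phase_map(state.grid, state.k_out, th), state.to_matrix()


def run_class(
    m: ReflectionMatrix, tol: float = 1e-3, max_iter: int = 30
) -> CLASSResults:
    """Fit the two-sided correction; results carry the corrected matrix."""
    return CLASSModel(m).fit(tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# pupil comparison utilities
# ---------------------------------------------------------------------------

def pupil_cross_correlation(
    a: PupilPhase, b: PupilPhase, nodes: np.ndarray | None = None
) -> float:
    """Normalized cross-correlation of complex pupil functions, in [0, 1].

    |<exp(ia), exp(ib)>| / (||exp(ia)|| ||exp(ib)||) over the common support;
    invariant under piston.  ``nodes`` restricts the support to sampled bins.
    """
    if a.grid.n != b.grid.n or a.grid.pupil_radius_bins != b.grid.pupil_radius_bins:
        raise ValueError("pupil supports do not match")
    if nodes is None:
        pa = a.phase[a.grid.pupil_mask]
        pb = b.phase[b.grid.pupil_mask]
    else:
        pa, pb = a.at_nodes(nodes), b.at_nodes(nodes)
    za, zb = np.exp(1j * pa), np.exp(1j * pb)
    return float(np.abs(np.vdot(za, zb)) / (np.linalg.norm(za) * np.linalg.norm(zb)))


@dataclass(frozen=True)
class PhaseResidualReport:
    """Residual between a recovered and a true pupil phase, gauge removed."""

    correlation: float  # circular correlation after piston/tilt removal
    residual_rms: float  # rad
    residual_max: float  # rad
    tilt_bins: tuple[float, float]  # removed tilt, image-shift in pixels
    piston: float  # removed piston, rad


def _remove_piston_tilt(delta: np.ndarray, nodes: np.ndarray, n: int):
    """Remove piston + linear tilt from wrapped phase differences at nodes.

    The integer-pixel part of the image-shift tilt is found from the spectral
    peak of the phasor field exp(i delta) embedded on the k grid; the
    fractional part and the piston then follow from iterated least squares on
    the re-wrapped principal value.
    """
    c = n // 2
    z = np.zeros((n, n), dtype=complex)
    z[c + nodes[:, 1], c + nodes[:, 0]] = np.exp(1j * delta)
    # exp(i (a + 2 pi (mx bx + my by) / n)) transforms to a peak at (mx, my)
    F = np.abs(fft2c(z))
    my, mx = np.unravel_index(np.argmax(F), F.shape)
    shift = np.array([mx - c, my - c], dtype=float)
    A = np.column_stack([np.ones(len(nodes)), nodes[:, 0], nodes[:, 1]]).astype(float)
    coef = np.array([0.0, 2 * np.pi * shift[0] / n, 2 * np.pi * shift[1] / n])
    d = np.angle(np.exp(1j * (delta - A @ coef)))
    for _ in range(6):
        upd, *_ = np.linalg.lstsq(A, d, rcond=None)
        coef = coef + upd
        d = np.angle(np.exp(1j * (delta - A @ coef)))
    return d, coef


def compare_to_truth(
    recovered: PupilPhase, truth: PupilPhase, nodes: np.ndarray | None = None
) -> PhaseResidualReport:
    """Residual report after removing the piston and tip/tilt gauge.

    Both arguments are aberration maps of the same sign convention (e.g. a
    :class:`CLASSResults` estimate against the applied ground-truth screen);
    the residual is ``recovered - truth`` modulo piston and linear tilt, the
    declared image-shift ambiguity of two-sided phase correction.
    """
    if recovered.grid.n != truth.grid.n:
        raise ValueError("grids do not match")
    if nodes is None:
        nodes = np.array(recovered.grid.pupil_nodes, dtype=int)
    delta = recovered.at_nodes(nodes) - truth.at_nodes(nodes)
    d, coef = _remove_piston_tilt(
        np.angle(np.exp(1j * delta)), nodes, recovered.grid.n
    )
    n = recovered.grid.n
    return PhaseResidualReport(
        correlation=float(np.abs(np.mean(np.exp(1j * d)))),
        residual_rms=float(np.sqrt(np.mean(d**2))),
        residual_max=float(np.max(np.abs(d))),
        tilt_bins=(coef[1] * n / (2 * np.pi), coef[2] * n / (2 * np.pi)),
        piston=float(np.angle(np.exp(1j * coef[0]))),
    )
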