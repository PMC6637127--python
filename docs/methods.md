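# Methods

## The imaging model

All computation happens on a square, even-sized pixel grid of pitch p
(micrometre units throughout), with the conjugate wavevector grid spaced
dk = 2π/(n·p) and the pupil defined as the disk |k| ≤ k₀·NA, k₀ = 2π/λ.
Position ↔ wavevector transforms are centered, orthonormal FFTs with kernel
exp(−i k·r), so every transform is unitary and energy bookkeeping needs no
prefactors.  The grid must satisfy p ≤ λ/(4 NA), the Nyquist bound for the
double-pass intensity point-spread function.

A single acquisition illuminates the specimen with the plane wave
exp(−i k_i·r); the single-scattering (time-gated) return is

    E(r_o; k_i) = IFFT[ P(k) e^{iθ_o(k)} FFT[ O(r) e^{−i k_i·r} e^{iθ_i(k_i)} ] ],

with O the complex reflectivity, P the binary pupil, and θ_i, θ_o the
input/output pupil phase screens.  In the wavevector basis this is

    E(k_o; k_i) = P(k_o) e^{iθ_o(k_o)} Õ(k_o + k_i) e^{iθ_i(k_i)} :

every matrix element observes the object spectrum at q = k_o + k_i, which is
what makes two-sided phase retrieval from the matrix possible.  Temporal
gating is modelled implicitly — the matrix is the already-gated field at the
chosen delay — and within-gate multiple scattering is emulated as additive
circular-Gaussian speckle, band-limited to the output pupil, independent
across illuminations (the least favourable case: it never accumulates
coherently), and scaled so total noise power / total signal power = γ.

Raw acquisition can be emulated as rotating-reference off-axis
interferograms I = |E_S + E_R0·exp(−i(k_i+k_DG)·r)|².  Demodulation windows
the frame spectrum with a hard disk about the grating carrier +k_DG (no
apodization — the pupil already band-limits the signal, and a taper would
bias the pupil edge where aberrations are estimated), removes the carrier,
and divides out the conjugate reference ramp.  The window only separates
cleanly when band_radius + 2k₀NA ≤ |k_DG| (the DC autocorrelation band has
radius 2k₀NA); the simulator default is |k_DG| = 5k₀NA with
band_radius = 2k₀NA, which also accommodates any in-pupil illumination tilt.
Frame-wise illumination wavevectors are calibrated from diffusive-sample
frames: the demodulated power spectrum is the pupil disk translated to +k_i,
located by matched filtering with the pupil indicator and refined to sub-bin
precision by quadratic interpolation over 3×3 bins (a concentrated
quasi-plane-wave spectrum is refined directly).

## The correction

The aberration estimate maximizes the total confocal (diagonal) intensity
I = Σ_r |E(r_o=r; r_i=r)|² over phase-only maps applied per input column and
per output row.  Writing D(q) = Σ_{k_i} E(q−k_i; k_i) (the aligned object-
spectrum accumulation), I = Σ_q |D(q)|²/n².  For one mode with contribution
c and complementary sum S, the exact single-coordinate maximizer of
Σ|S + e^{iθ}c|² is θ = −arg⟨c, S⟩; modes are updated sequentially
(Gauss–Seidel) in ascending |k|, so each update cannot decrease the
objective and the intensity trace is non-decreasing by construction.  The
complementary sum excludes the mode being updated; including it adds a
constant positive bias that damps updates toward no-ops at small mode
counts.  Input and output sweeps alternate until the relative intensity
change falls below tol (default 1e-3, max_iter 30; typical fits converge in
3–8 iterations).  Accumulated maps are reported as the sample-induced
aberration estimate (the negated total applied correction), wrapped to
(−π, π].

Convergence behaviour worth knowing: on separable (single-point) fixtures
the update contracts geometrically — roughly one decade of residual per
iteration after the first — reaching machine precision at convergence but
not in any fixed small number of sweeps.

**Gauge.**  A piston on either pupil and a *common* tilt on both pupils leave
the objective exactly invariant (the common tilt multiplies D(q) by a pure
ramp, i.e. shifts the image).  The solver random-walks along this flat
direction, so `fit()` gauge-fixes afterwards: it removes each map's piston
and the common tilt by least squares on the (unwrapped, accumulated) maps
and applies the compensating spectral ramp to the corrected state — the
objective and trace are untouched.  The differential input/output tilt is
identifiable and kept.  Relative to ground truth an overall image shift
equal to the true screens' common tilt remains: it is not observable from
the matrix alone.  `compare_to_truth` therefore removes piston and tilt
(integer-pixel part located via the spectral peak of the wrapped-difference
phasor field, fractional part by iterated re-wrapped least squares) before
reporting circular correlation and residual RMS.

**Internal representation.**  The correction engine keeps both matrix axes on
the full frequency grid and updates only the in-pupil modes.  For the
full-field matrix this equals the pupil-restricted representation (the data
are band-limited); for windowed tile sub-matrices it is essential — spectral
leakage of the window carries ~30% of the diagonal energy on 24 px tiles,
and discarding it would corrupt the stitched image.  A corollary: on
windowed tiles the ascent legitimately re-phases leakage even for an
aberration-free input (intensity gain ≈ 0.5%, image change a few per cent),
so tiled results agree with unsegmented ones only to the leakage level,
while the 1×1 (unwindowed) case is an exact fixed point.

## Tiling, metrology, refocusing

Position-dependent aberrations are handled by segmenting the field into
m×m tile cores (an exact partition), expanding each core by an overlap
margin (default 25%, windows slid inward at the field edge so all tile grids
stay square), correcting each tile independently, and blending corrected
tile images with separable linear feathering normalized by the weight sum.
With feathering disabled the disjoint cores reassemble the uncorrected
confocal image bit-exactly.  Per-tile aberration maps live on tile-local
pupil rasters and are compared after resampling the complex pupil function
on normalized coordinates k/(k₀NA).  Tile-wise estimation presumes the
screen is smooth at the tile pupil's resolution; with 32 px tiles that means
correlation lengths ≳ 0.5 pupil radii.

PSFs are read off a single matrix column: the intensity over r_o at a chosen
illumination position r_i, peak-located and profiled with a bicubic spline
at ≥10× sub-pixel resolution; the FWHM is the distance between half-maximum
crossings, along the horizontal axis by default (the vertical and a radial
average are options).  Strehl enhancement is the after/before ratio of PSF
peaks.  For an unaberrated full-pupil fixture the column profile is the
coherent output PSF |h|², FWHM ≈ 0.51 λ/NA (330 nm at 515 nm / NA 0.8).

Refocusing multiplies the field spectrum by the exact non-paraxial
angular-spectrum kernel exp(i dz √((n_m k₀)² − |k|²)), evanescent modes
zeroed, with medium index n_m = 1.33 by default (NA 0.8 is far outside the
paraxial regime).  The kernel is unitary on the propagating band and
composes additively in dz.  Refocus validity is limited by the coherence
gate to ±7.5 μm (half a 15 μm gate); beyond that a warning is raised.
Volume assembly fills 5 μm-spaced recorded slices at 0.5 μm steps by
propagating from the nearer recorded slice (ties to the shallower one);
correction runs only at recorded planes.

## Synthetic scenes and their limits

Specimen presets: a centre delta, a regular point grid, filament bundles
(smooth random walks with Gaussian cross-section and slowly varying phase,
emulating the high-reflectivity lipid sheaths of myelinated axons), and
fully developed complex-Gaussian speckle; reflectivities are normalized to
max |O| ≤ 1 and all generators are pure functions of (parameters, seed).
Random screens are white Gaussian noise on the pupil grid smoothed by a
Gaussian kernel of width corr_length × pupil radius (default 0.25), piston-
removed and rescaled exactly to the requested RMS; Zernike screens use the
Noll index and normalization.  Illumination sets snap a Fermat spiral (or a
regular sublattice) to frequency-grid nodes, deduplicated — the basis
transforms and the accumulation use integer-bin spectrum shifts, mirroring
how measured illumination angles are discretized onto the camera grid.  At
the reference geometry (64 px, 80 nm pitch, 515 nm, NA 0.8) the pupil holds
exactly 193 nodes, so "pupil-filling" means N_in = 193.

What the generator does **not** emulate: depth-dependent and spectrally
varying aberrations, gate-shape effects and dispersion, vectorial/
polarization pupils at high NA, detector shot noise statistics (camera
noise is plain additive Gaussian), specimen motion, and multiple scattering
that is partially correlated across angles.  Passing tests therefore
demonstrate the correctness and self-consistency of the algorithms under
the stated scalar, static, angle-uncorrelated-noise model — not performance
on any particular tissue.

## Numerical choices and degenerate inputs

- Frequency-space conventions are shared package-wide (centered grids,
  orthonormal FFTs); illumination and carrier wavevectors used by the
  pipeline are snapped to grid bins so round trips are exact to machine
  precision; off-grid carriers degrade gracefully, bounded by windowing
  sidelobes, and are covered by tests.
- Gauss–Seidel order is ascending |k| with a stable sort — deterministic
  across runs; a zero inner product leaves a mode untouched; an all-zero
  matrix raises a correction error ("no signal") rather than dividing by
  zero; non-finite intensities name the failing iteration.
- Convergence default tol = 1e-3 with max_iter = 30 brackets the typical
  3–8 iterations with margin.
- Tile windows must be ≥ 8 px (coarser windows under-sample the pupil);
  anisotropic layouts (e.g. 1×2) produce square windows sized by the larger
  core dimension and are not recommended — split both axes comparably.
- Problem sizes in the shipped tests and the acceptance script (32–64 px
  grids, 45–193 illumination modes, ≤ 5 Monte-Carlo seeds) were chosen as
  the smallest scales at which the pupil is meaningfully sampled and
  speckle statistics are stable; the whole suite runs in about a minute.

## Known limitations

- Phase-only correction: no amplitude (apodization) estimation.
- Tiles are corrected independently; no joint estimation or smoothness
  prior across tiles, and no automatic isoplanatic-patch-size selection.
- The recovered maps are defined up to piston and common tilt; absolute
  image registration against an external reference is out of scope.
- The interferogram path assumes a spatially uniform reference amplitude
  (a measured reference map can be divided out upstream).
- Single-depth correction: refocused planes reuse the recorded-plane
  correction rather than re-running the fit after propagation.
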