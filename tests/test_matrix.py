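"""Reflection-matrix basis transforms, confocal imaging and PSF metrology."""

import numpy as np
import pytest

import rmcao as r
from rmcao.matrix import BasisError, MetrologyError

from .conftest import brute_force_psf, standard_fixture


@pytest.fixture(scope="module")
def point_matrix(small_grid):
    m, *_ = standard_fixture(small_grid, preset="single_point", rms=0.0)
    return m


class TestBasisTransforms:
    def test_round_trip_is_identity(self, small_grid):
        m, *_ = standard_fixture(small_grid, preset="speckle_object", rms=1.0, seed=2)
        kk = r.to_wavevector_basis(m, "both")
        back = r.to_position_basis(kk, "both")
        # input axis comes back on the full pupil-node set; compare columns
        kk2 = r.to_wavevector_basis(back, "both")
        idx = {tuple(b): i for i, b in enumerate(kk2.k_in)}
        cols = [idx[tuple(b)] for b in kk.k_in]
        err = np.linalg.norm(kk2.data[:, cols] - kk.data) / np.linalg.norm(kk.data)
        assert err < 1e-12

    def test_output_round_trip_identity_and_parseval(self, small_grid):
        m, *_ = standard_fixture(small_grid, preset="filaments", rms=0.8, seed=3)
        kk = r.to_wavevector_basis(m, "out")
        back = r.to_position_basis(kk, "out")
        assert np.linalg.norm(back.data - m.data) / np.linalg.norm(m.data) < 1e-12
        assert kk.total_power() == pytest.approx(m.total_power(), rel=1e-12)

    def test_delta_column_transforms_to_plane_wave(self, small_grid):
        # single column = delta at r0 -> k-basis column is exp(-i k.r0)/n
        g = small_grid
        n, c = g.n, g.n // 2
        col = np.zeros((n * n, 1), dtype=complex)
        iy, ix = c + 3, c - 5
        col[iy * n + ix, 0] = 1.0
        m = r.ReflectionMatrix(
            data=col, grid=g, basis_out="position", basis_in="wavevector",
            k_in=np.zeros((1, 2), dtype=int),
        )
        kk = r.to_wavevector_basis(m, "out")
        r0 = np.array([(ix - c) * g.pitch, (iy - c) * g.pitch])
        for i, (bx, by) in enumerate(kk.k_out):
            k = np.array([bx, by]) * g.dk
            expected = np.exp(-1j * k @ r0) / n  # orthonormal DFT scaling
            assert kk.data[i, 0] == pytest.approx(expected, abs=1e-12)

    def test_single_point_position_matrix_is_rank_one(self, small_grid):
        m, *_ = standard_fixture(small_grid, preset="single_point", rms=1.0, seed=4)
        pos = r.to_position_basis(m, "in")
        s = np.linalg.svd(pos.data, compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_mirror_kk_matrix_gives_diagonal_dominant_position_matrix(self, small_grid):
        # a mirror couples k_o = -k_i (object spectrum is a delta); its
        # position-basis matrix has discrete-sinc rows peaked on the diagonal
        g = small_grid
        nodes = np.array(g.pupil_nodes, dtype=int)
        idx = {tuple(b): i for i, b in enumerate(nodes)}
        data = np.zeros((len(nodes), len(nodes)), dtype=complex)
        for j, (bx, by) in enumerate(nodes):
            data[idx[(-bx, -by)], j] = 1.0
        m = r.ReflectionMatrix(
            data=data, grid=g, basis_out="wavevector", basis_in="wavevector",
            k_in=nodes, k_out=nodes,
        )
        pos = r.to_position_basis(m, "both")
        mags = np.abs(pos.data)
        d = np.diagonal(mags)
        off = mags - np.diag(d)
        assert d.min() > off.max()

    def test_noop_transform_warns(self, small_grid):
        m, *_ = standard_fixture(small_grid, preset="single_point", rms=0.0)
        with pytest.warns(UserWarning):
            r.to_position_basis(m, "out")


class TestConfocalImage:
    def test_unit_diagonal_gives_uniform_ones(self, small_grid):
        g = small_grid
        m = r.ReflectionMatrix(
            data=np.eye(g.n**2, dtype=complex), grid=g,
            basis_out="position", basis_in="position",
        )
        assert np.array_equal(r.confocal_image(m), np.ones((g.n, g.n)))

    def test_zero_diagonal_gives_zero_image(self, small_grid):
        g = small_grid
        data = np.ones((g.n**2, g.n**2), dtype=complex) - np.eye(g.n**2)
        m = r.ReflectionMatrix(
            data=data, grid=g, basis_out="position", basis_in="position"
        )
        assert np.all(r.confocal_image(m) == 0.0)

    def test_point_fixture_matches_double_pass_oracle(self, small_grid, point_matrix):
        # diagonal image of the unaberrated point: both passes contribute one
        # coherent PSF factor, d(r) = n h(r)^2 for full-pupil illumination
        g = small_grid
        pos = r.to_position_basis(point_matrix, "in")
        img = r.confocal_image(pos)
        h = brute_force_psf(g)
        oracle = np.abs(h * h) ** 2 * g.n**2
        assert np.allclose(img, oracle, atol=1e-10 * oracle.max())

    def test_basis_mismatch_rejected(self, small_grid, point_matrix):
        with pytest.raises(BasisError):
            r.confocal_image(point_matrix)  # input axis still in k basis

    def test_diagonal_field_agrees_with_materialized_diagonal(self, small_grid):
        m, *_ = standard_fixture(small_grid, preset="speckle_object", rms=1.2, seed=5)
        fast = m.diagonal_field()
        pos = r.to_position_basis(m, "in")
        slow = np.diagonal(pos.data).reshape(small_grid.n, small_grid.n)
        assert np.allclose(fast, slow, atol=1e-12)


class TestPSF:
    def test_gaussian_column_fwhm_closed_form(self, std_grid):
        g = std_grid
        sigma = 0.3  # um
        X, Y = g.xy
        amp = np.exp(-(X**2 + Y**2) / (4 * sigma**2))  # intensity sigma = 0.3
        col = amp.ravel()[:, None].astype(complex)
        m = r.ReflectionMatrix(
            data=col, grid=g, basis_out="position", basis_in="wavevector",
            k_in=np.zeros((1, 2), dtype=int),
        )
        psf = r.point_spread_function(m, (0.0, 0.0))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert psf.fwhm == pytest.approx(expected, rel=0.01)

    def test_unaberrated_point_fwhm_matches_diffraction_oracle(self, std_grid):
        # the column at r_i = point position profiles the output-pass coherent
        # PSF: intensity |h(r_o)|^2, FWHM ~ 0.51 lambda / NA
        m, *_ = standard_fixture(std_grid, preset="single_point", rms=0.0)
        pos = r.to_position_basis(m, "in")
        psf = r.point_spread_function(pos, (0.0, 0.0))
        h = brute_force_psf(std_grid)
        prof = np.abs(h[std_grid.n // 2, :]) ** 2
        x = std_grid.x
        fine = np.linspace(-1.0, 1.0, 4001)
        p = np.interp(fine, x, prof)
        above = fine[p >= p.max() / 2]
        fwhm_oracle = above.max() - above.min()
        assert abs(psf.fwhm - fwhm_oracle) / fwhm_oracle < 0.05
        airy = 0.514 * std_grid.wavelength / std_grid.na
        assert abs(psf.fwhm - airy) / airy < 0.1

    def test_defocus_broadens_the_psf(self, std_grid):
        sharp, *_ = standard_fixture(std_grid, preset="single_point", rms=0.0)
        g = std_grid
        illum = r.sample_illumination_angles(len(g.pupil_nodes), g, "grid")
        s = r.make_specimen("single_point", g, seed=0)
        flat = r.make_aberration(g, rms=0.0)
        defocus = r.make_aberration(g, zernike={4: 2.0})
        m_def = r.assemble_matrix(s, flat, defocus, illum)
        f0 = r.point_spread_function(r.to_position_basis(sharp, "in"), (0, 0))
        f1 = r.point_spread_function(r.to_position_basis(m_def, "in"), (0, 0))
        assert f1.fwhm > f0.fwhm

    def test_flat_column_raises_metrology_error(self, std_grid):
        g = std_grid
        col = np.ones((g.n**2, 1), dtype=complex)
        m = r.ReflectionMatrix(
            data=col, grid=g, basis_out="position", basis_in="wavevector",
            k_in=np.zeros((1, 2), dtype=int),
        )
        with pytest.raises(MetrologyError):
            r.point_spread_function(m, (0.0, 0.0))


class TestStrehl:
    def test_identical_psfs_give_unity(self, std_grid):
        m, *_ = standard_fixture(std_grid, preset="single_point", rms=0.0)
        psf = r.point_spread_function(r.to_position_basis(m, "in"), (0, 0))
        assert r.strehl_enhancement(psf, psf) == 1.0

    def test_correcting_known_screens_matches_pupil_integral(self, std_grid):
        # the on-axis intensity ratio between the ideal and the aberrated
        # point response equals the inverse double-pass Strehl computed from
        # the ground-truth pupil integrals |<e^{i phi}>|^2 -- exactly, since
        # E(0; 0) = const * <e^{i phi_in}> <e^{i phi_out}> for a center point
        g = std_grid
        c = g.n // 2
        illum = r.sample_illumination_angles(len(g.pupil_nodes), g, "grid")
        s = r.make_specimen("single_point", g, seed=0)
        pin = r.make_aberration(g, rms=1.0, seed=21)
        pout = r.make_aberration(g, rms=1.0, seed=22)
        flat = r.make_aberration(g, rms=0.0)
        m_ab = r.assemble_matrix(s, pin, pout, illum)
        m_id = r.assemble_matrix(s, flat, flat, illum)
        i_ab = r.matrix._column_intensity(m_ab, (0.0, 0.0))[c, c]
        i_id = r.matrix._column_intensity(m_id, (0.0, 0.0))[c, c]
        mask = g.pupil_mask
        strehl_out = np.abs(np.mean(np.exp(1j * pout.phase[mask]))) ** 2
        strehl_in = np.abs(np.mean(np.exp(1j * pin.phase[mask]))) ** 2
        assert i_id / i_ab == pytest.approx(1.0 / (strehl_in * strehl_out), rel=1e-6)

    def test_zero_before_peak_rejected(self, std_grid):
        m, *_ = standard_fixture(std_grid, preset="single_point", rms=0.0)
        psf = r.point_spread_function(r.to_position_basis(m, "in"), (0, 0))
        from dataclasses import replace

        with pytest.raises(ValueError):
            r.strehl_enhancement(replace(psf, peak=0.0), psf)
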