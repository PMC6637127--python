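"""Forward model: reflection fields, matrix assembly, interferogram synthesis."""

import numpy as np
import pytest

import rmcao as r
from rmcao.grid import ConfigurationError

from .conftest import brute_force_psf, on_grid_k


@pytest.fixture(scope="module")
def flat(small_grid):
    return r.make_aberration(small_grid, rms=0.0)


class TestReflectionField:
    def test_zero_specimen_gives_zero_field(self, small_grid, flat):
        s = r.SpecimenMap(reflectivity=np.zeros((32, 32), complex), grid=small_grid)
        f = r.simulate_reflection_field(s, flat, flat, np.zeros(2), small_grid)
        assert np.all(f.field == 0)

    def test_point_field_matches_diffraction_integral(self, small_grid, flat):
        # unaberrated point at center, normal incidence: field = coherent PSF
        s = r.make_specimen("single_point", small_grid, seed=0)
        f = r.simulate_reflection_field(s, flat, flat, np.zeros(2), small_grid)
        oracle = brute_force_psf(small_grid)
        assert np.linalg.norm(f.field - oracle) / np.linalg.norm(oracle) < 1e-10

    def test_offset_point_aberrated_output_matches_oracle(self, small_grid, flat):
        g = small_grid
        refl = np.zeros((32, 32), complex)
        refl[16 + 3, 16 - 2] = 1.0  # r0 = (-2, +3) pixels
        s = r.SpecimenMap(reflectivity=refl, grid=g)
        pout = r.make_aberration(g, rms=1.0, seed=5, role="output")
        f = r.simulate_reflection_field(s, flat, pout, np.zeros(2), g)
        r0 = (-2 * g.pitch, 3 * g.pitch)
        oracle = brute_force_psf(g, r0=r0, phase_out=pout.phase)
        assert np.linalg.norm(f.field - oracle) / np.linalg.norm(oracle) < 1e-10

    def test_oblique_illumination_phases_the_point_response(self, small_grid, flat):
        # point at r0, k_i != 0: same pattern times exp(-i k_i.r0)
        g = small_grid
        refl = np.zeros((32, 32), complex)
        refl[16 + 2, 16 + 4] = 1.0
        s = r.SpecimenMap(reflectivity=refl, grid=g)
        k_i = on_grid_k(g, np.random.default_rng(1))
        f0 = r.simulate_reflection_field(s, flat, flat, np.zeros(2), g)
        f1 = r.simulate_reflection_field(s, flat, flat, k_i, g)
        r0 = np.array([4 * g.pitch, 2 * g.pitch])
        assert np.allclose(f1.field, f0.field * np.exp(-1j * k_i @ r0), atol=1e-12)

    def test_linear_in_reflectivity(self, small_grid, flat):
        g = small_grid
        rng = np.random.default_rng(2)
        a = r.SpecimenMap(reflectivity=(rng.standard_normal((32, 32)) * 0.3).astype(complex), grid=g)
        b = r.SpecimenMap(reflectivity=(rng.standard_normal((32, 32)) * 0.3).astype(complex), grid=g)
        ab = r.SpecimenMap(reflectivity=a.reflectivity + b.reflectivity, grid=g)
        k = on_grid_k(g, rng)
        fa = r.simulate_reflection_field(a, flat, flat, k, g).field
        fb = r.simulate_reflection_field(b, flat, flat, k, g).field
        fab = r.simulate_reflection_field(ab, flat, flat, k, g).field
        assert np.allclose(fab, fa + fb, atol=1e-12)

    def test_band_limited_to_output_pupil(self, small_grid, flat):
        g = small_grid
        s = r.make_specimen("speckle_object", g, seed=4)
        f = r.simulate_reflection_field(s, flat, flat, np.zeros(2), g)
        spec = r.fft2c(f.field)
        assert np.all(np.abs(spec[~g.pupil_mask]) < 1e-12)

    def test_out_of_pupil_illumination_rejected(self, small_grid, flat):
        s = r.make_specimen("single_point", small_grid, seed=0)
        k_bad = np.array([small_grid.pupil_radius * 1.5, 0.0])
        with pytest.raises(ValueError):
            r.simulate_reflection_field(s, flat, flat, k_bad, small_grid)


class TestAssembleMatrix:
    def test_noise_free_columns_match_single_fields(self, small_grid, flat):
        g = small_grid
        s = r.make_specimen("speckle_object", g, seed=1)
        illum = r.sample_illumination_angles(20, g, "spiral")
        m = r.assemble_matrix(s, flat, flat, illum)
        for j, k in enumerate(illum.k):
            f = r.simulate_reflection_field(s, flat, flat, k, g)
            assert np.array_equal(m.data[:, j], f.field.ravel())

    def test_injected_noise_power_ratio(self, small_grid, flat):
        g = small_grid
        s = r.make_specimen("speckle_object", g, seed=1)
        illum = r.sample_illumination_angles(30, g, "spiral")
        clean = r.assemble_matrix(s, flat, flat, illum)
        noisy = r.assemble_matrix(s, flat, flat, illum, noise=r.NoiseSpec(gamma=1.0, seed=7))
        ratio = np.sum(np.abs(noisy.data - clean.data) ** 2) / clean.total_power()
        assert 0.9 <= ratio <= 1.1

    def test_noise_band_limited_and_seed_deterministic(self, small_grid, flat):
        g = small_grid
        s = r.make_specimen("single_point", g, seed=0)
        illum = r.sample_illumination_angles(10, g, "spiral")
        kwargs = dict(noise=r.NoiseSpec(gamma=0.5, seed=3))
        m1 = r.assemble_matrix(s, flat, flat, illum, **kwargs)
        m2 = r.assemble_matrix(s, flat, flat, illum, **kwargs)
        assert np.array_equal(m1.data, m2.data)
        spec = r.fft2c(m1.data[:, 4].reshape(g.n, g.n))
        assert np.all(np.abs(spec[~g.pupil_mask]) < 1e-12)

    def test_column_energy_parseval(self, small_grid, flat):
        # total signal power of a column equals its pupil-space Parseval sum
        g = small_grid
        s = r.make_specimen("filaments", g, seed=2)
        illum = r.sample_illumination_angles(10, g, "spiral")
        m = r.assemble_matrix(s, flat, flat, illum)
        kk = r.to_wavevector_basis(m, "out")
        for j in range(illum.n_in):
            assert np.sum(np.abs(m.data[:, j]) ** 2) == pytest.approx(
                np.sum(np.abs(kk.data[:, j]) ** 2), rel=1e-12
            )

    def test_double_pass_reciprocity_single_point(self, small_grid):
        # same screen on both passes, on-grid center point: the k/k matrix is
        # symmetric under exchange of the illumination and detection modes
        g = small_grid
        s = r.make_specimen("single_point", g, seed=0)
        screen = r.make_aberration(g, rms=1.0, seed=9)
        illum = r.sample_illumination_angles(len(g.pupil_nodes), g, "grid")
        m = r.assemble_matrix(s, screen, screen, illum)
        kk = r.to_wavevector_basis(m, "out")
        assert np.array_equal(kk.k_out, illum.bins)  # shared mode ordering
        A = kk.data
        assert np.allclose(A, A.T, atol=1e-12 * np.abs(A).max())


class TestInterferogram:
    def kdg(self, g):
        b = int(np.ceil(5 * g.pupil_radius / g.dk))
        return np.array([b * g.dk, 0.0])

    def test_zero_field_gives_flat_frame(self, demod_grid):
        g = demod_grid
        cfg = r.InterferogramConfig(k_dg=tuple(self.kdg(g)), e_r0=1.7)
        f = r.ComplexFieldMap(field=np.zeros((g.n, g.n), complex), grid=g)
        frame = r.synthesize_interferogram(f, np.zeros(2), cfg)
        assert np.allclose(frame.data, 1.7**2, atol=1e-12)

    def test_zero_reference_gives_plain_intensity(self, demod_grid):
        # E_R0 = 0 is rejected by the config (no carrier); emulate via the
        # modulus-squared identity instead: I - |E_R|^2 - cross terms = |E_S|^2
        g = demod_grid
        s = r.make_specimen("speckle_object", g, seed=3)
        flat = r.make_aberration(g, rms=0.0)
        fld = r.simulate_reflection_field(s, flat, flat, np.zeros(2), g)
        cfg = r.InterferogramConfig(k_dg=tuple(self.kdg(g)), e_r0=1.0)
        frame = r.synthesize_interferogram(fld, np.zeros(2), cfg)
        ref = g.plane_wave(self.kdg(g))
        direct = np.abs(fld.field + ref) ** 2
        assert np.allclose(frame.data, direct, atol=1e-12)

    def test_plane_wave_fringe_contrast(self, demod_grid):
        # sample field = plane wave of amplitude a at k_i: fringes at k_DG
        # with contrast 2 a E_R0 / (a^2 + E_R0^2), checked pixelwise
        g = demod_grid
        a, er0 = 0.6, 1.2
        k_i = np.zeros(2)
        fld = r.ComplexFieldMap(field=a * np.ones((g.n, g.n), complex), grid=g)
        cfg = r.InterferogramConfig(k_dg=tuple(self.kdg(g)), e_r0=er0)
        frame = r.synthesize_interferogram(fld, k_i, cfg)
        X, _ = g.xy
        expected = a**2 + er0**2 + 2 * a * er0 * np.cos(self.kdg(g)[0] * X)
        assert np.allclose(frame.data, expected, atol=1e-10)
        contrast = (frame.data.max() - frame.data.min()) / (
            frame.data.max() + frame.data.min()
        )
        assert contrast == pytest.approx(2 * a * er0 / (a**2 + er0**2), rel=1e-6)

    def test_spectrum_occupies_exactly_the_three_bands(self, demod_grid):
        g = demod_grid
        s = r.make_specimen("speckle_object", g, seed=5)
        flat = r.make_aberration(g, rms=0.0)
        rng = np.random.default_rng(0)
        k_i = on_grid_k(g, rng)
        fld = r.simulate_reflection_field(s, flat, flat, k_i, g)
        cfg = r.InterferogramConfig(k_dg=tuple(self.kdg(g)), e_r0=1.0)
        frame = r.synthesize_interferogram(fld, k_i, cfg)
        spec = r.fft2c(frame.data)
        KX, KY = g.k_xy
        kc = k_i + self.kdg(g)
        allowed = (
            (np.hypot(KX, KY) <= 2 * g.pupil_radius * (1 + 1e-9))
            | (np.hypot(KX - kc[0], KY - kc[1]) <= g.pupil_radius * (1 + 1e-9))
            | (np.hypot(KX + kc[0], KY + kc[1]) <= g.pupil_radius * (1 + 1e-9))
        )
        outside = np.abs(spec[~allowed])
        assert outside.max() < 1e-10 * np.abs(spec).max()

    def test_sideband_separation_invariant_enforced(self, demod_grid):
        g = demod_grid
        with pytest.raises(ConfigurationError):
            r.InterferogramConfig(k_dg=(1.5 * g.pupil_radius, 0.0)).validate(g)
        # a 120 lp/mm grating carrier referred to sample coordinates through a
        # 120x magnification (0.12 lp/um * 120 -> 90.5 rad/um) passes the
        # separation inequality on a sufficiently fine grid
        fine = r.GridSpec(n=32, pitch=0.025, wavelength=0.515, na=0.8)
        k_dg_sample = 2 * np.pi * 0.12 * 120
        cfg = r.InterferogramConfig(k_dg=(k_dg_sample, 0.0))
        cfg.validate(fine)  # no exception: separation inequality holds
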