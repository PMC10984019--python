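"""Generators: stiffness fields, shear waves, multi-TE scans, outlines."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from lungmech import synthetic as syn
from lungmech.density import fit_t2star


def _spec(**kw):
    base = dict(grid_shape=(1, 64, 64), pixel_spacing=3.125e-3,
                slice_spacing=0.01, base_modulus=3000.0)
    base.update(kw)
    return syn.StiffnessFieldSpec(**base)


class TestStiffnessField:
    def test_zero_cv_is_constant(self):
        f = syn.generate_stiffness_field(_spec(heterogeneity_cv=0.0))
        assert np.allclose(f.values, 3000.0)

    def test_sample_cv_matches_target(self):
        # 10^4 pixels, short correlation so the moment estimate is stable
        f = syn.generate_stiffness_field(_spec(
            grid_shape=(1, 100, 100), heterogeneity_cv=0.3,
            correlation_length=0.004, pixel_spacing=1.5625e-3, seed=1))
        cv = f.values.std() / f.values.mean()
        assert abs(cv - 0.3) < 0.05

    def test_inclusion_contrast_and_labels(self):
        inc = syn.Inclusion(center=(0.01, 0.0, 0.0), radius=0.02,
                            modulus=9000.0)
        f = syn.generate_stiffness_field(_spec(
            grid_shape=(1, 128, 128), heterogeneity_cv=0.3,
            inclusion=inc, seed=2))
        med_in = np.median(f.values[f.roi_labels == 1])
        med_out = np.median(f.values[f.roi_labels == 0])
        assert med_in >= 2.0 * med_out

    def test_seeded_determinism(self):
        a = syn.generate_stiffness_field(_spec(heterogeneity_cv=0.3, seed=9))
        b = syn.generate_stiffness_field(_spec(heterogeneity_cv=0.3, seed=9))
        assert np.array_equal(a.values, b.values)

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            _spec(base_modulus=-1.0)


class TestWavefield:
    def test_plane_wave_wavelength(self):
        # G = 1000 Pa, rho = 1000 kg/m^3, f = 50 Hz -> lambda = 0.02 m;
        # fine pixels so the discrete-dispersion correction is negligible
        dx = 0.78125e-3
        f = syn.generate_stiffness_field(_spec(
            grid_shape=(1, 256, 256), pixel_spacing=dx,
            base_modulus=1000.0))
        wave = syn.synthesize_wavefield(f, 50.0, 1000.0)
        u = wave.complex_displacement[0]
        phase = np.unwrap(np.angle(u[128]))
        k = -np.gradient(phase) / dx
        lam = 2 * np.pi / np.mean(k[10:-10])
        assert abs(lam - 0.02) / 0.02 < 0.01

    def test_noiseless_single_direction_constant_amplitude(self):
        f = syn.generate_stiffness_field(_spec(base_modulus=2000.0))
        wave = syn.synthesize_wavefield(f, 50.0, 1000.0)
        amp = np.abs(wave.complex_displacement)
        assert amp.std() / amp.mean() < 1e-4

    def test_four_offset_sampling_roundtrip(self):
        f = syn.generate_stiffness_field(_spec(heterogeneity_cv=0.2, seed=3))
        wave = syn.synthesize_wavefield(f, 50.0, 800.0, snr_db=25, seed=4)
        samples = syn.sample_phase_offsets(wave, 4)
        n = 4
        w = np.exp(-2j * np.pi * np.arange(n) / n)
        rec = (2.0 / n) * np.tensordot(w, samples, axes=(0, 0))
        assert np.allclose(rec, wave.complex_displacement, atol=1e-18)

    def test_zero_density_rejected(self):
        f = syn.generate_stiffness_field(_spec())
        with pytest.raises(ValueError):
            syn.synthesize_wavefield(f, 50.0, 0.0)

    def test_non_compass_direction_rejected(self):
        f = syn.generate_stiffness_field(_spec())
        with pytest.raises(ValueError):
            syn.synthesize_wavefield(f, 50.0, 1000.0, directions=((0, 0),))


class TestDensityScan:
    def test_exponential_decay_value(self):
        # I0 = 100, T2* = 2 ms, TE = 2 ms -> 100/e
        scan = syn.synthesize_density_scan(np.full((12, 12), 100.0), 2.0,
                                           [1.0, 2.0], 50.0)
        lung = ~scan.phantom_roi
        assert np.allclose(scan.magnitude_images[1][lung],
                           100.0 * np.exp(-1.0), rtol=1e-12)

    def test_zero_te_gives_i0(self):
        scan = syn.synthesize_density_scan(np.full((12, 12), 73.0), 1.5,
                                           [0.0, 1.0], 50.0)
        assert np.allclose(scan.magnitude_images[0][~scan.phantom_roi], 73.0)

    def test_noiseless_roundtrip_through_fit(self):
        scan = syn.synthesize_density_scan(np.full((16, 16), 100.0), 2.0,
                                           [1.07, 1.5, 2.0, 2.5], 120.0)
        fit = fit_t2star(scan)
        lung = ~scan.phantom_roi
        assert np.nanmax(np.abs(fit.I0_map[lung] - 100.0) / 100.0) < 1e-6
        assert np.nanmax(np.abs(fit.T2star_map[lung] - 2.0) / 2.0) < 1e-6

    def test_empty_echo_list_rejected(self):
        with pytest.raises(ValueError):
            syn.synthesize_density_scan(np.ones((4, 4)), 2.0, [], 10.0)


class TestOutlines:
    def test_circular_offset(self):
        stack = syn.generate_lung_outlines(n_slices=5, base_radius=0.05,
                                           inner_offset=0.005,
                                           irregularity=0.0, taper=0.0)
        r_out = np.linalg.norm(stack.outlines[0], axis=1)
        r_in = np.linalg.norm(stack.inner_outlines[0], axis=1)
        assert np.allclose(r_out, 0.05)
        assert np.allclose(r_in, 0.045)

    def test_z_range(self):
        stack = syn.generate_lung_outlines(n_slices=5, slice_spacing=0.01)
        assert np.isclose(stack.z[-1] - stack.z[0], 0.04)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_inner_contained_in_outer(self, seed):
        stack = syn.generate_lung_outlines(seed=seed)
        for outer, inner in zip(stack.outlines, stack.inner_outlines):
            po, pi = Polygon(outer), Polygon(inner)
            assert po.is_valid and pi.is_valid
            assert po.contains(pi)

    def test_excessive_offset_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_lung_outlines(base_radius=0.05, inner_offset=0.05)
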