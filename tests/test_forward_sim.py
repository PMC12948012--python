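import math

import numpy as np
import pytest
from scipy import stats

from speckleflow.forward import (
    ModulatorPattern,
    PatternStack,
    apply_sample,
    generate_checkerboard,
    generate_coded_mask,
    make_trajectory,
    phase_to_displacement,
    propagate_fresnel,
    render_reference_stack,
    subpixel_shift,
)
from speckleflow.optics import OpticsConfig
from speckleflow.phantoms import SamplePhantom


def uniform_phantom(shape, t=1.0, d=0.0, phase=None):
    return SamplePhantom(
        phase=np.zeros(shape) if phase is None else phase,
        transmission=np.full(shape, t, dtype=float),
        darkfield=np.full(shape, d, dtype=float),
        pixel_size_um=0.65,
    )


class TestModulators:
    def test_zero_fill_fraction_is_empty_modulator(self):
        p = generate_coded_mask(fill_fraction=0.0, shape=(64, 64), seed=0)
        assert np.allclose(p.transmission, 1.0)

    def test_mask_cell_size_and_determinism(self):
        # 5 um pitch at 0.65 um pixels: ~7.69 px cells, supersampled raster
        a = generate_coded_mask(5.0, 0.65, (128, 128), seed=4)
        b = generate_coded_mask(5.0, 0.65, (128, 128), seed=4)
        assert np.array_equal(a.transmission, b.transmission)
        # count cell transitions along a row: cell side must be 7-8 px
        phase = np.angle(a.transmission[0])
        edges = np.abs(np.diff(phase)) > 0.1
        runs = np.diff(np.nonzero(edges)[0])
        assert 6 <= np.median(runs[runs > 3]) <= 9

    def test_modulated_cell_fraction_matches_fill_fraction(self):
        # binomial count over ~10^4 cells
        frac = 0.37
        pitch, pixel = 5.0, 0.65
        n_cells = 110  # per side
        shape = (int(n_cells * pitch / pixel),) * 2
        p = generate_coded_mask(pitch, pixel, shape, fill_fraction=frac, seed=8)
        # sample cell centres
        centres = ((np.arange(n_cells) + 0.5) * pitch / pixel).astype(int)
        vals = np.angle(p.transmission)[np.ix_(centres, centres)]
        measured = (np.abs(vals) > 0.5).mean()
        assert abs(measured - frac) < 0.02

    def test_checkerboard_alternates_at_two_pixel_period(self):
        p = generate_checkerboard(period_um=2 * 0.65, pixel_size_um=0.65,
                                  shape=(16, 16), phase_shift_rad=1.0, supersample=1)
        ph = np.angle(p.transmission)
        assert np.allclose(ph[0, ::2], ph[0, 0])
        assert np.allclose(ph[0, 1::2], ph[0, 1])
        assert not np.isclose(ph[0, 0], ph[0, 1])

    def test_checkerboard_periodicity(self):
        period_px = 8
        p = generate_checkerboard(period_um=period_px * 0.65, pixel_size_um=0.65,
                                  shape=(64, 64), supersample=1)
        t = p.transmission
        assert np.allclose(t[:, : 64 - period_px], t[:, period_px:])

    def test_checkerboard_mean_amplitude_is_midpoint(self):
        period_px = 8
        p = generate_checkerboard(period_um=period_px * 0.65, pixel_size_um=0.65,
                                  shape=(64, 64), amplitudes=(0.6, 1.0), supersample=1)
        assert abs(np.abs(p.transmission).mean() - 0.8) < 1e-9


class TestFresnel:
    def test_zero_distance_returns_input_intensity(self):
        rng = np.random.default_rng(0)
        u = rng.random((32, 32)) * np.exp(1j * rng.random((32, 32)))
        optics = OpticsConfig(energy_keV=14.0, distance_m=0.0)
        assert np.array_equal(propagate_fresnel(u, optics), np.abs(u) ** 2)

    def test_pure_phase_mask_conserves_energy(self, optics):
        p = generate_coded_mask(shape=(128, 128), amplitude=1.0, seed=1)
        out = propagate_fresnel(p, optics)
        assert abs(out.sum() - np.abs(p.transmission ** 2).sum()) < 1e-9 * out.sum()

    def test_plane_wave_is_propagation_invariant(self, optics):
        u = np.ones((128, 128), dtype=complex)
        out = propagate_fresnel(u, optics)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_aliasing_bound_violation_raises(self):
        optics = OpticsConfig(energy_keV=14.0, distance_m=50.0, pixel_size_um=0.65)
        with pytest.raises(ValueError, match="distance_m"):
            propagate_fresnel(np.ones((64, 64), dtype=complex), optics)


class TestSubpixelShift:
    def test_zero_shift_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        assert np.allclose(subpixel_shift(img, 0.0, 0.0), img, atol=1e-12)

    def test_integer_shift_equals_roll(self):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        out = subpixel_shift(img, 3.0, -2.0)
        assert np.allclose(out, np.roll(img, (-2, 3), axis=(0, 1)), atol=1e-10)

    def test_fractional_shift_composes_to_identity(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        img = gaussian_filter(rng.random((32, 32)), 1.5, mode="wrap")
        out = subpixel_shift(subpixel_shift(img, 0.3, 0.0), -0.3, 0.0)
        assert np.allclose(out, img, atol=1e-9)


class TestTrajectory:
    def test_single_position_near_origin(self):
        t = make_trajectory("diagonal", 1, 3.0, seed=0)
        assert len(t) == 1
        assert np.abs(t.offsets_um).max() <= 1.5

    def test_diagonal_without_jitter_is_arithmetic(self):
        t = make_trajectory("diagonal", 4, 3.0, jitter=0.0, seed=0)
        assert np.allclose(t.offsets_um, [[0, 0], [3, 3], [6, 6], [9, 9]])

    def test_default_jitter_is_uniform_half_step(self):
        step = 3.0
        t = make_trajectory("diagonal", 10_000, step, seed=11)
        resid = t.offsets_um - np.arange(10_000)[:, None] * step
        assert resid.min() >= -0.5 * step and resid.max() <= 0.5 * step
        # uniformity by KS test at alpha = 0.01
        pvalue = stats.kstest(resid.ravel() / step, stats.uniform(-0.5, 1.0).cdf).pvalue
        assert pvalue > 0.01

    def test_grid_requires_square_n(self):
        with pytest.raises(ValueError, match="square"):
            make_trajectory("xy-grid", 10, 3.0)

    def test_grid_steps_follow_gaussian_spec(self):
        t = make_trajectory("xy-grid", 10_000, 3.0, jitter=0.3, seed=4)
        xs = np.unique(np.round(t.offsets_um[:, 0], 9))
        steps = np.diff(np.sort(xs))
        assert abs(steps.mean() - 3.0) < 0.05
        assert abs(steps.std() - 0.3) < 0.05


class TestRenderReference:
    def test_single_zero_offset_frame_is_propagated_pattern(self, optics):
        p = generate_coded_mask(shape=(128, 128), seed=6)
        traj = make_trajectory("diagonal", 1, 0.0, jitter=0.0, seed=0)
        stack = render_reference_stack(p, traj, optics, (64, 64))
        expected = propagate_fresnel(p, optics)[32:96, 32:96]
        assert np.allclose(stack.frames[0], expected, atol=1e-12)

    def test_translate_then_propagate_commutes(self, optics):
        p = generate_coded_mask(shape=(128, 128), seed=7)
        dx_px = 4.3 / 0.65
        shifted_first = propagate_fresnel(subpixel_shift(p.transmission, dx_px, 0.0), optics)
        shifted_after = subpixel_shift(propagate_fresnel(p.transmission, optics, return_field=True), dx_px, 0.0)
        assert np.allclose(shifted_first, np.abs(shifted_after) ** 2, atol=1e-8)

    def test_deterministic_with_noise_off(self, optics, small_reference):
        p = generate_coded_mask(shape=(160, 160), seed=21)
        traj = make_trajectory("diagonal", 6, 3.0, seed=21)
        again = render_reference_stack(p, traj, optics, (64, 64), seed=21)
        assert np.array_equal(again.frames, small_reference.frames)

    def test_margin_violation_raises(self, optics):
        p = generate_coded_mask(shape=(72, 72), seed=0)
        traj = make_trajectory("diagonal", 20, 3.0, seed=0)
        with pytest.raises(ValueError, match="excursion"):
            render_reference_stack(p, traj, optics, (64, 64))


class TestPhaseToDisplacement:
    def test_constant_phase_no_displacement(self, optics):
        d = phase_to_displacement(uniform_phantom((32, 32)), optics)
        assert d.max_abs() == 0.0

    def test_linear_ramp_gives_uniform_displacement(self, optics):
        a = 0.05  # rad per px
        phase = a * np.arange(64)[None, :] * np.ones((64, 1))
        d = phase_to_displacement(uniform_phantom((64, 64), phase=phase), optics)
        expected = optics.distance_m * optics.wavelength_m / (
            2 * math.pi * optics.pixel_size_m**2) * a
        assert np.allclose(d.dx, expected, rtol=1e-6)
        assert np.allclose(d.dy, 0.0, atol=1e-12)

    def test_linearity_in_phase(self, optics):
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter
        phase = gaussian_filter(rng.standard_normal((64, 64)), 5)
        d1 = phase_to_displacement(uniform_phantom((64, 64), phase=phase), optics)
        d2 = phase_to_displacement(uniform_phantom((64, 64), phase=2 * phase), optics)
        assert np.allclose(d2.dx, 2 * d1.dx)
        assert np.allclose(d2.dy, 2 * d1.dy)


class TestApplySample:
    def test_vacuum_phantom_bit_identical(self, optics, small_reference):
        vac = uniform_phantom((64, 64))
        out = apply_sample(small_reference, vac, optics)
        assert np.array_equal(out.frames, small_reference.frames)

    def test_full_darkfield_removes_speckle_contrast(self, optics, small_reference):
        from scipy.ndimage import gaussian_filter

        ph = uniform_phantom((64, 64), t=0.8, d=1.0)
        out = apply_sample(small_reference, ph, optics, avg_sigma_px=10.0)
        expected = 0.8 * gaussian_filter(small_reference.frames[0], 10.0, mode="nearest")
        assert np.allclose(out.frames[0], expected, atol=1e-12)

    def test_uniform_transmission_scales_mean(self, optics, small_reference):
        ph = uniform_phantom((64, 64), t=0.9, d=0.0)
        out = apply_sample(small_reference, ph, optics)
        for i in range(out.n):
            ratio = out.frames[i].mean() / small_reference.frames[i].mean()
            assert abs(ratio - 0.9) < 1e-3

    def test_photometry_with_darkfield_off(self, optics, small_reference):
        ph = uniform_phantom((64, 64), t=0.7, d=0.0)
        out = apply_sample(small_reference, ph, optics)
        for i in range(out.n):
            expected = (0.7 * small_reference.frames[i]).sum()
            assert abs(out.frames[i].sum() - expected) < 1e-6 * expected

    def test_speckle_contrast_monotone_in_darkfield(self, optics, small_reference):
        stds = []
        for d in (0.0, 0.5, 1.0):
            out = apply_sample(small_reference, uniform_phantom((64, 64), d=d), optics)
            stds.append(out.frames[0].std())
        assert stds[0] > stds[1] > stds[2]

    def test_displacement_exceeding_margin_raises(self, optics, small_reference):
        phase = 5000.0 * np.arange(64)[None, :] * np.ones((64, 1))
        ph = uniform_phantom((64, 64), phase=phase)
        with pytest.raises(ValueError, match="displacement"):
            apply_sample(small_reference, ph, optics)

    def test_ground_truth_attached(self, optics, small_reference):
        ph = uniform_phantom((64, 64), t=0.9, d=0.1)
        out = apply_sample(small_reference, ph, optics)
        gt = out.ground_truth
        assert set(gt) == {"transmission", "darkfield", "dx", "dy", "phase"}
        assert np.array_equal(gt["transmission"], ph.transmission)


def test_poisson_noise_variance_matches_mean(optics):
    # shot-noise contract: per-pixel variance ~ mean/P at photon count P
    pattern = generate_coded_mask(shape=(128, 128), seed=3)
    for photons in (1e2, 1e4):
        noisy_optics = OpticsConfig(energy_keV=14.0, distance_m=0.5,
                                    pixel_size_um=0.65, photon_count=photons)
        traj = make_trajectory("diagonal", 1, 0.0, jitter=0.0, seed=0)
        reps = np.stack([
            render_reference_stack(pattern, traj, noisy_optics, (32, 32), seed=s).frames[0]
            for s in range(200)
        ])
        mean = reps.mean(axis=0)
        var = reps.var(axis=0)
        ratio = var.mean() / (mean.mean() / photons)
        assert 0.85 < ratio < 1.15
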