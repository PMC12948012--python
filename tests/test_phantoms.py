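import math

import numpy as np
import pytest

from speckleflow.phantoms import (
    PhantomConfig,
    generate_bezier_outline,
    generate_smooth_field,
    make_lens_phantom,
    make_phantom,
    read_phantom,
    write_phantom,
)


class TestBezierOutline:
    def test_triangle_control_points_give_filled_convex_region(self):
        cfg = PhantomConfig(shape=(64, 64), n_bezier_control=3, seed=0)
        mask = generate_bezier_outline(cfg)
        assert mask.any()
        # convex-ish: the filled region contains the centroid of its pixels
        ys, xs = np.nonzero(mask)
        assert mask[int(ys.mean()), int(xs.mean())]

    def test_deterministic_under_fixed_seed(self):
        cfg = PhantomConfig(shape=(64, 64), seed=123)
        assert np.array_equal(generate_bezier_outline(cfg), generate_bezier_outline(cfg))

    def test_mask_inside_frame_with_positive_area_100_seeds(self):
        for seed in range(100):
            cfg = PhantomConfig(shape=(48, 48), n_bezier_control=6, seed=seed)
            mask = generate_bezier_outline(cfg)
            assert 0 < mask.sum() < mask.size
            assert not mask[0, :].any() and not mask[-1, :].any()
            assert not mask[:, 0].any() and not mask[:, -1].any()

    def test_too_few_control_points_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(n_bezier_control=2)


class TestSmoothField:
    def test_zero_peak_is_identically_zero(self):
        assert not generate_smooth_field((32, 32), 4.0, 0.0, 1).any()

    def test_unfiltered_noise_has_exact_peak_to_peak(self):
        f = generate_smooth_field((64, 64), 0.0, 2.5, 7)
        assert abs((f.max() - f.min()) - 2.5) < 1e-12
        assert abs(f.mean()) < 1e-12

    def test_gaussian_filter_attenuates_beyond_half_sigma_frequency(self):
        sigma = 8.0
        f = generate_smooth_field((256, 256), sigma, 1.0, 3)
        spec = np.abs(np.fft.rfft(f, axis=1)).mean(axis=0)
        freqs = np.fft.rfftfreq(256)
        dc = spec[0]
        high = spec[freqs > 1.0 / (2.0 * sigma)]
        assert high.max() < dc / 100.0

    def test_constant_field_cannot_satisfy_amplitude(self):
        with pytest.raises(ValueError):
            generate_smooth_field((8, 8), 1e4, 1.0, 0)


class TestMakePhantom:
    def test_zero_ranges_give_vacuum(self):
        cfg = PhantomConfig(
            shape=(48, 48),
            phase_peak_range=(0.0, 0.0),
            T_deviation_range=(0.0, 0.0),
            D_deviation_range=(0.0, 0.0),
            seed=5,
        )
        p = make_phantom(cfg)
        assert not p.phase.any()
        assert np.array_equal(p.transmission, np.ones((48, 48)))
        assert not p.darkfield.any()

    def test_default_ranges_follow_training_recipe(self):
        cfg = PhantomConfig()
        assert cfg.phase_peak_range == (0.0, 10.0 * math.pi)
        assert cfg.T_deviation_range == (0.02, 0.2)
        assert cfg.D_deviation_range == (0.02, 0.2)

    def test_invariants_hold_over_1000_seeds(self):
        # full invariant scan: maps share shape, T in (0,1], D in [0,1],
        # finite phase, exact vacuum outside the support
        for seed in range(1000):
            cfg = PhantomConfig(
                shape=(48, 48), smoothing_sigma_range=(2.0, 8.0),
                n_bezier_control=6, seed=seed,
            )
            p = make_phantom(cfg)  # SamplePhantom.__post_init__ validates
            outside = ~generate_bezier_outline(cfg)
            assert (p.phase[outside] == 0.0).all()
            assert (p.transmission[outside] == 1.0).all()
            assert (p.darkfield[outside] == 0.0).all()

    def test_support_consistency_exact(self):
        cfg = PhantomConfig(shape=(64, 64), seed=9, smoothing_sigma_range=(3, 6))
        p = make_phantom(cfg)
        mask = generate_bezier_outline(cfg)
        assert (p.phase[~mask] == 0.0).all()
        assert (p.transmission[~mask] == 1.0).all()
        assert (p.darkfield[~mask] == 0.0).all()

    def test_deterministic(self):
        cfg = PhantomConfig(shape=(48, 48), seed=77)
        a, b = make_phantom(cfg), make_phantom(cfg)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.transmission, b.transmission)
        assert np.array_equal(a.darkfield, b.darkfield)

    def test_bandlimit_beyond_cutoff(self):
        sigma = 5.0
        cfg = PhantomConfig(
            shape=(128, 128), smoothing_sigma_range=(sigma, sigma),
            edge_sigma=5.0, seed=3,
        )
        p = make_phantom(cfg)
        f = np.fft.fftshift(np.abs(np.fft.fft2(p.phase)) ** 2)
        h = 128
        yy, xx = np.mgrid[0:h, 0:h]
        r = np.hypot(yy - h / 2, xx - h / 2)
        freqs = r / h
        dc = f.max()
        cutoff = 1.0 / (2.0 * sigma)
        assert f[freqs > cutoff].max() < 0.01 * dc


class TestLensPhantom:
    def test_zero_decrement_gives_flat_phase(self):
        p = make_lens_phantom(200.0, 0.0, 8.86e-11, (64, 64), 0.65)
        assert not p.phase.any()

    def test_phase_gradient_linear_in_radius(self):
        # parabolic phase: d(phi)/dx along the central row is linear in the
        # offset from the axis; compare finite differences with closed form
        shape = (129, 129)
        p_um = 0.65
        lam = 8.86e-11
        delta = 1.8e-6
        radius = 200.0
        p = make_lens_phantom(radius, delta, lam, shape, p_um, edge_sigma_px=0.0)
        row = p.phase[64]
        grad = np.gradient(row)  # rad per px
        ks = np.arange(-20, 21)
        expected = -(2 * math.pi / lam) * delta * 2 * ks * (p_um * 1e-6) ** 2 / (radius * 1e-6)
        measured = grad[64 + ks]
        assert np.allclose(measured, expected, rtol=1e-6, atol=1e-12)

    def test_darkfield_zero_and_aperture_guard(self):
        p = make_lens_phantom(200.0, 1.8e-6, 8.86e-11, (64, 64), 0.65)
        assert not p.darkfield.any()
        with pytest.raises(ValueError):
            make_lens_phantom(200.0, 1.8e-6, 8.86e-11, (64, 64), 0.65,
                              aperture_radius_um=100.0)


def test_phantom_tiff_roundtrip(tmp_path):
    p = make_phantom(PhantomConfig(shape=(48, 48), seed=2))
    path = tmp_path / "phantom.tiff"
    write_phantom(p, path)
    q = read_phantom(path)
    assert np.allclose(q.phase, p.phase, atol=1e-6)
    assert np.allclose(q.transmission, p.transmission, atol=1e-6)
    assert q.meta["seed"] == 2
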