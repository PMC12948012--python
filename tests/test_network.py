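import numpy as np
import pytest

from speckleflow.nn import autodiff as ad
from speckleflow.nn.autodiff import Tensor
from speckleflow.nn.layers import Conv2d, UpsampleLearnable
from speckleflow.nn.model import (
    MultiContrastNet,
    NetworkConfig,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    scale_stack,
)


@pytest.fixture(scope="module")
def desk_net():
    return MultiContrastNet(NetworkConfig.desk(seed=1))


@pytest.fixture(scope="module")
def random_pair():
    rng = np.random.default_rng(0)
    ref = (rng.random((2, 5, 64, 64)) + 0.5).astype(np.float32)
    sam = (rng.random((2, 5, 64, 64)) + 0.5).astype(np.float32)
    return ref, sam


class TestScaleStack:
    def test_exact_count_is_identity(self):
        frames = np.random.default_rng(0).random((20, 8, 8))
        assert np.array_equal(scale_stack(frames, 20), frames)

    def test_excess_frames_truncated_to_first_n(self):
        frames = np.random.default_rng(1).random((100, 4, 4))
        assert np.array_equal(scale_stack(frames, 20), frames[:20])

    def test_nearest_doubles_each_frame_in_order(self):
        frames = np.arange(10, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        out = scale_stack(frames, 20, "nearest")
        assert np.array_equal(out[:, 0, 0], np.repeat(np.arange(10.0), 2))

    @pytest.mark.parametrize("method", ["nearest", "linear", "bilinear", "spline"])
    def test_all_methods_produce_finite_stacks(self, method):
        frames = np.random.default_rng(2).random((3, 8, 8))
        out = scale_stack(frames, 5, method)
        assert out.shape == (5, 8, 8)
        assert np.isfinite(out).all()


class TestFeaturePyramid:
    def test_full_scale_pyramid_shapes(self):
        # 512x512x20 input: level 1 features 256x256x32, deepest 16x16x196
        net = MultiContrastNet(NetworkConfig.full_scale(seed=0))
        rng = np.random.default_rng(0)
        stack = (rng.random((1, 20, 512, 512)) + 0.5).astype(np.float32)
        net.eval()
        feats = net.extract_features(Tensor(stack))
        assert feats[0].data.shape == (1, 32, 256, 256)
        assert feats[-1].data.shape == (1, 196, 16, 16)

    def test_desk_pyramid_follows_dyadic_schedule(self, desk_net, random_pair):
        desk_net.eval()
        feats = desk_net.extract_features(Tensor(random_pair[0]))
        shapes = [f.data.shape[2] for f in feats]
        assert shapes == [32, 16, 8]

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig.desk(input_size=60)


class TestWarping:
    def test_zero_flow_is_identity(self):
        rng = np.random.default_rng(3)
        feat = Tensor(rng.random((1, 4, 8, 8)).astype(np.float32))
        out = ad.warp_bilinear(feat, np.zeros((1, 2, 8, 8), np.float32))
        assert np.allclose(out.data, feat.data, atol=1e-7)

    def test_integer_flow_moves_hot_pixel(self):
        feat = np.zeros((1, 1, 8, 8), np.float32)
        feat[0, 0, 4, 4] = 1.0
        flow = np.zeros((1, 2, 8, 8), np.float32)
        flow[0, 0] = 1.0  # sample at x+1: hot pixel appears one column left
        out = ad.warp_bilinear(Tensor(feat), flow)
        assert out.data[0, 0, 4, 3] == 1.0
        assert out.data[0, 0, 4, 4] == 0.0

    def test_warp_and_inverse_warp_compose_to_identity_on_smooth_fields(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(4)
        feat = gaussian_filter(rng.random((16, 16)), 3.0)[None, None].astype(np.float32)
        flow = np.full((1, 2, 16, 16), 0.4, np.float32)
        fwd = ad.warp_bilinear(Tensor(feat), flow)
        back = ad.warp_bilinear(fwd, -flow)
        inner = np.s_[:, :, 3:-3, 3:-3]
        assert np.abs(back.data[inner] - feat[inner]).max() < 1e-2


class TestCostVolume:
    def test_channel_count_for_window_three(self):
        rng = np.random.default_rng(5)
        a = Tensor(rng.random((1, 4, 8, 8)).astype(np.float32))
        b = Tensor(rng.random((1, 4, 8, 8)).astype(np.float32))
        assert ad.cost_volume(a, b, 3).data.shape[1] == 49

    def test_one_hot_features_peak_at_zero_offset(self):
        feat = np.zeros((1, 2, 9, 9), np.float32)
        feat[0, :, 4, 4] = 1.0
        cv = ad.cost_volume(Tensor(feat), Tensor(feat), 1).data[0, :, 4, 4]
        assert cv.argmax() == 4  # centre of the 3x3 offset grid

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.random((1, 4, 8, 8)).astype(np.float32)
        b = rng.random((1, 4, 8, 8)).astype(np.float32)
        n_w = 2
        got = ad.cost_volume(Tensor(a), Tensor(b), n_w).data[0]
        side = 2 * n_w + 1
        expected = np.zeros((side * side, 8, 8), np.float32)
        for k, (dy, dx) in enumerate(
            (dy, dx) for dy in range(-n_w, n_w + 1) for dx in range(-n_w, n_w + 1)
        ):
            for y in range(8):
                for x in range(8):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < 8 and 0 <= xx < 8:
                        expected[k, y, x] = (b[0, :, y, x] * a[0, :, yy, xx]).mean()
        assert np.allclose(got, expected, atol=1e-6)


class TestLearnableUpsampling:
    def test_identity_kernel_reduces_to_nearest_neighbour(self):
        rng = np.random.default_rng(7)
        up = UpsampleLearnable(3, rng)
        up.conv.set_identity()
        x = rng.random((1, 3, 4, 4)).astype(np.float32)
        out = up(Tensor(x)).data
        assert np.allclose(out, x.repeat(2, axis=2).repeat(2, axis=3), atol=1e-7)

    def test_output_is_twice_the_input_size(self):
        rng = np.random.default_rng(8)
        up = UpsampleLearnable(2, rng)
        out = up(Tensor(rng.random((1, 2, 5, 7)).astype(np.float32)))
        assert out.data.shape == (1, 2, 10, 14)

    def test_flow_value_rescaling_with_identity_kernel(self):
        rng = np.random.default_rng(9)
        up = UpsampleLearnable(2, rng)
        up.conv.set_identity()
        flow = np.zeros((1, 2, 4, 4), np.float32)
        flow[0, 0] = 1.0
        out = up(Tensor(flow)).scale(2.0).data
        assert np.allclose(out[0, 0], 2.0, atol=1e-7)
        assert np.allclose(out[0, 1], 0.0, atol=1e-7)


class TestForward:
    def test_untrained_forward_is_reproducible(self, desk_net, random_pair):
        r1 = desk_net.forward(random_pair[0][0], random_pair[1][0])
        r2 = desk_net.forward(random_pair[0][0], random_pair[1][0])
        assert np.array_equal(r1.dx, r2.dx)
        assert np.array_equal(r1.transmission, r2.transmission)

    def test_output_shapes_at_full_resolution(self, desk_net, random_pair):
        res = desk_net.forward(random_pair[0][0], random_pair[1][0])
        for m in (res.dx, res.dy, res.transmission, res.darkfield):
            assert m.shape == (64, 64)
        assert (res.transmission >= 0).all()
        assert ((res.darkfield >= 0) & (res.darkfield <= 1)).all()

    def test_wrong_frame_count_rejected(self, desk_net):
        bad = np.ones((1, 7, 64, 64), np.float32)
        with pytest.raises(ValueError, match="n_net"):
            desk_net.forward_tensors(bad, bad)

    def test_translation_consistency_of_flow_maps(self, desk_net, random_pair):
        # rolling both stacks by the same offset rolls the flow map
        ref, sam = random_pair
        res0 = desk_net.forward(ref[0], sam[0])
        ref_r = np.roll(ref[0], (8, 8), axis=(1, 2))
        sam_r = np.roll(sam[0], (8, 8), axis=(1, 2))
        res1 = desk_net.forward(ref_r, sam_r)
        inner = np.s_[16:-16, 16:-16]
        diff = np.abs(np.roll(res0.dx, (8, 8), axis=(0, 1)) - res1.dx)[inner]
        assert np.median(diff) < 0.1


class TestParameterCount:
    def test_single_conv_parameter_count(self):
        conv = Conv2d(1, 1, 3)
        assert conv.weight.data.size + conv.bias.data.size == 10

    def test_counts_add_over_submodules(self, desk_net):
        total = count_parameters(desk_net)
        parts = sum(count_parameters(m) for m in
                    [*desk_net.encoder_levels, *desk_net.phase_nets,
                     *desk_net.flow_upsamplers, desk_net.t_net, desk_net.d_net,
                     desk_net.phase_refiner, desk_net.t_refiner, desk_net.d_refiner])
        assert total == parts

    def test_full_scale_count_in_sanity_band(self):
        net = MultiContrastNet(NetworkConfig.full_scale(seed=0))
        n = count_parameters(net)
        assert 1e6 < n < 1e7


def test_checkpoint_roundtrip(tmp_path, desk_net, random_pair):
    path = tmp_path / "model.npz"
    save_checkpoint(desk_net, path, extra={"note": "test"})
    loaded, extra = load_checkpoint(path)
    assert extra["note"] == "test"
    r0 = desk_net.forward(random_pair[0][0], random_pair[1][0])
    r1 = loaded.forward(random_pair[0][0], random_pair[1][0])
    assert np.array_equal(r0.dx, r1.dx)
    assert np.array_equal(r0.darkfield, r1.darkfield)
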