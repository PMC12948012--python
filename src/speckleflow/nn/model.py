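"""Multi-resolution cost-volume network for scanning multi-contrast retrieval.

The network mirrors the classical tracking pipeline with learnable parts:
a shared convolutional encoder turns the reference and sample scan stacks
into feature pyramids; at each pyramid level the reference features are
warped by the upsampled flow from the coarser level (zero at the
coarsest), a local correlation cost volume is built over a (2 n_w + 1)^2
offset window, and a per-level estimator (PhaseNet) predicts the pattern
displacement at that level.  Transmission (TNet) and dark-field (DNet)
estimators consume scan-axis mean/std statistics of the warped reference
and sample stacks plus the final flow; refiner networks apply residual
corrections at full resolution.  Flow values are expressed in the pixel
units of their own level; the learnable x2 upsampler rescales them by 2
per level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from speckleflow.forward import PatternStack
from speckleflow.nn import autodiff as ad
from speckleflow.nn.autodiff import Tensor
from speckleflow.nn.layers import (
    Conv2d,
    Module,
    Sequential,
    UpsampleLearnable,
    conv_block,
)

__all__ = [
    "NetworkConfig",
    "MultiContrastNet",
    "MultiContrastResult",
    "scale_stack",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    The full-scale configuration uses 20 scan channels, 5 pyramid levels
    with a level-1 width of 32 growing to 196 at the deepest volume, and a
    cost-volume half-window of 3 (49 correlation channels).  The ``desk``
    preset is a reduced configuration for CPU-scale experiments.
    """

    n_net: int = 20
    levels: int = 5
    cost_window: int = 3
    channels: tuple[int, ...] = (32, 48, 64, 96, 196)
    input_size: int = 512
    scaling_method: str = "nearest"
    estimator_width: int = 64
    estimator_blocks: int = 4
    td_width: int = 32
    td_blocks: int = 3
    refiner_width: int = 32
    refiner_blocks: int = 3
    normalize_cost: bool = True
    cost_peak_prior: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != self.levels:
            raise ValueError("channels must list one width per level")
        if self.cost_window < 1:
            raise ValueError("cost_window must be >= 1")
        if self.input_size % (2**self.levels) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^levels={2**self.levels}"
            )
        if self.scaling_method not in ("nearest", "linear", "bilinear", "spline"):
            raise ValueError(f"unknown scaling_method {self.scaling_method!r}")

    @classmethod
    def full_scale(cls, **overrides) -> "NetworkConfig":
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "NetworkConfig":
        defaults = dict(
            n_net=5,
            levels=3,
            cost_window=3,
            channels=(12, 16, 24),
            input_size=64,
            estimator_width=24,
            estimator_blocks=2,
            td_width=16,
            td_blocks=2,
            refiner_width=12,
            refiner_blocks=2,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass
class MultiContrastResult:
    """Full-resolution multi-contrast maps recovered by the network."""

    dx: np.ndarray
    dy: np.ndarray
    transmission: np.ndarray
    darkfield: np.ndarray
    level_flows: dict | None = None
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transmission = np.maximum(self.transmission, 0.0)
        self.darkfield = np.clip(self.darkfield, 0.0, 1.0)


def scale_stack(stack, n_net: int, method: str = "nearest"):
    """Adjust a scan stack to exactly ``n_net`` frames.

    With N >= n_net the first n_net raw frames are taken unchanged (the scan
    step is usually below the speckle size, so truncation preserves the
    effective step while sub-sampling would not).  With N < n_net the stack
    is interpolated along the scan axis: 'nearest' repeats frames in order,
    'linear' interpolates on the frame-index grid, 'bilinear' resizes the
    stack with the image-style half-pixel grid convention, 'spline' uses a
    cubic interpolant.
    """
    frames = stack.frames if isinstance(stack, PatternStack) else np.asarray(stack)
    n = frames.shape[0]
    if n >= n_net:
        out = frames[:n_net].copy()
    elif method == "nearest":
        idx = (np.arange(n_net) * n) // n_net
        out = frames[idx].copy()
    elif method == "linear":
        t = np.linspace(0.0, n - 1, n_net)
        i0 = np.floor(t).astype(int)
        i1 = np.minimum(i0 + 1, n - 1)
        frac = (t - i0)[:, None, None]
        out = frames[i0] * (1.0 - frac) + frames[i1] * frac
    elif method == "bilinear":
        from skimage.transform import resize

        out = resize(
            frames, (n_net,) + frames.shape[1:], order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    elif method == "spline":
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(np.arange(n), frames, axis=0)
        out = spline(np.linspace(0.0, n - 1, n_net))
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return out


def _cost_peak_estimate(cv: np.ndarray, n_w: int) -> np.ndarray:
    """Closed-form sub-pixel peak of a cost volume: argmax + 3-point parabola.

    Returns [B, 2, h, w] (dx, dy) in that level's pixels.  Computed outside
    the autodiff graph; it acts as a correlation-peak prior that the flow
    estimator refines.
    """
    b, c, h, w = cv.shape
    side = 2 * n_w + 1
    vol = cv.reshape(b, side, side, h, w)  # [B, v(dy), u(dx), h, w]
    flat = vol.reshape(b, side * side, h, w)
    best = flat.argmax(axis=1)
    iu = best % side
    iv = best // side
    bi = np.arange(b)[:, None, None]
    yy, xx = np.mgrid[0:h, 0:w]
    iu_c = np.clip(iu, 1, side - 2)
    iv_c = np.clip(iv, 1, side - 2)

    def parabola(cm, c0, cp):
        den = cm - 2.0 * c0 + cp
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = 0.5 * (cm - cp) / den
        return np.clip(np.where(np.abs(den) > 1e-12, frac, 0.0), -0.5, 0.5)

    du = parabola(vol[bi, iv, iu_c - 1, yy, xx], vol[bi, iv, iu_c, yy, xx],
                  vol[bi, iv, iu_c + 1, yy, xx])
    dv = parabola(vol[bi, iv_c - 1, iu, yy, xx], vol[bi, iv_c, iu, yy, xx],
                  vol[bi, iv_c + 1, iu, yy, xx])
    dx = (iu - n_w) + du
    dy = (iv - n_w) + dv
    return np.stack([dx, dy], axis=1).astype(np.float32)


def _pool_map(x: np.ndarray, level: int) -> np.ndarray:
    """Average-pool [B,C,H,W] by 2^level without value rescaling."""
    f = 2**level
    b, c, h, w = x.shape
    return x.reshape(b, c, h // f, f, w // f, f).mean(axis=(3, 5)).astype(np.float32)


def _downsample_prior(prior: np.ndarray, level: int) -> np.ndarray:
    """Average-pool a full-resolution flow [B,2,H,W] to pyramid ``level`` and
    rescale into that level's pixel units."""
    return _pool_map(prior, level) / (2**level)


def _estimator(cin: int, width: int, blocks: int, cout: int,
               rng: np.random.Generator) -> Sequential:
    """Decoder-style head: stride-1 conv blocks then a 1x1 output conv."""
    layers: list[Module] = [conv_block(cin, width, 1, rng)]
    for _ in range(blocks - 1):
        layers.append(conv_block(width, width, 1, rng))
    layers.append(Conv2d(width, cout, kernel=1, pad=0, rng=rng))
    return Sequential(*layers)


class MultiContrastNet(Module):
    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        L = config.levels
        nw = config.cost_window
        cv_ch = (2 * nw + 1) ** 2

        # shared encoder: per level a stride-2 block then a stride-1 block
        self.encoder_levels = []
        cin = config.n_net
        for l in range(L):
            self.encoder_levels.append(
                Sequential(conv_block(cin, ch[l], 2, rng), conv_block(ch[l], ch[l], 1, rng))
            )
            cin = ch[l]

        # per-level flow estimators: cost volume + sample features + upsampled
        # flow (+ the correlation-peak prior and its confidence when enabled)
        est_in = cv_ch + 2 + (3 if config.cost_peak_prior else 0)
        self.phase_nets = [
            _estimator(est_in + ch[l], config.estimator_width,
                       config.estimator_blocks, 2, rng)
            for l in range(L)
        ]
        if config.cost_peak_prior:
            # start exactly at the classical peak estimate
            for net in self.phase_nets:
                net.layers[-1].weight.data[:] = 0.0
                net.layers[-1].bias.data[:] = 0.0
        # learnable x2 upsamplers for the flow: between levels and to full res;
        # identity (delta-kernel) start so initial flows pass through unchanged
        self.flow_upsamplers = [UpsampleLearnable(2, rng) for _ in range(L)]
        for up in self.flow_upsamplers:
            up.conv.set_identity()

        head_in = 6 + (1 if config.cost_peak_prior else 0)
        self.t_net = _estimator(head_in, config.td_width, config.td_blocks, 1, rng)
        self.d_net = _estimator(head_in, config.td_width, config.td_blocks, 1, rng)
        # vacuum initialization: T starts at 1, D at 0
        self.t_net.layers[-1].bias.data[:] = 1.0
        self.phase_refiner = _estimator(head_in, config.refiner_width,
                                        config.refiner_blocks, 2, rng)
        self.t_refiner = _estimator(5, config.refiner_width, config.refiner_blocks, 1, rng)
        self.d_refiner = _estimator(5, config.refiner_width, config.refiner_blocks, 1, rng)
        # zero-initialized residual outputs: refiners start as identity
        for refiner in (self.phase_refiner, self.t_refiner, self.d_refiner):
            refiner.layers[-1].weight.data[:] = 0.0
            refiner.layers[-1].bias.data[:] = 0.0

    # -- pieces ------------------------------------------------------------

    def extract_features(self, stack: Tensor) -> list[Tensor]:
        """Feature pyramid, finest (level 1) first."""
        feats = []
        x = stack
        for enc in self.encoder_levels:
            x = enc(x)
            feats.append(x)
        return feats

    def _check_input(self, arr: np.ndarray) -> None:
        if arr.ndim != 4:
            raise ValueError("expect [batch, n_net, H, W]")
        if arr.shape[1] != self.config.n_net:
            raise ValueError(
                f"stack has {arr.shape[1]} frames, expected n_net={self.config.n_net}; "
                "run scale_stack first"
            )
        if arr.shape[2] % (2**self.config.levels) or arr.shape[3] % (2**self.config.levels):
            raise ValueError("spatial size must be divisible by 2^levels")

    def forward_tensors(
        self,
        reference: np.ndarray,
        sample: np.ndarray,
        finest_level: int = 1,
        include_td: bool = True,
        include_refiners: bool = True,
    ) -> dict:
        """Run the pyramid; returns tensors for training.

        ``finest_level`` > 1 stops the coarse-to-fine loop early (used by the
        staged training schedule); T/D heads and refiners then stay off.
        """
        self._check_input(reference)
        self._check_input(sample)
        cfg = self.config
        # flux normalization: both stacks share the reference global mean so
        # that transmission stays physical
        norm = reference.mean(axis=(1, 2, 3), keepdims=True)
        ref = (reference / norm).astype(np.float32)
        sam = (sample / norm).astype(np.float32)
        f_r = self.extract_features(Tensor(ref))
        f_s = self.extract_features(Tensor(sam))
        if cfg.cost_peak_prior:
            prior_full, conf_full = self._classical_prior(ref, sam)
        else:
            prior_full = conf_full = None

        level_flows: dict[int, Tensor] = {}
        flow = None
        for l in range(cfg.levels, finest_level - 1, -1):
            fl_r, fl_s = f_r[l - 1], f_s[l - 1]
            b, _, hl, wl = fl_r.data.shape
            if flow is None:
                flow_prev = Tensor(np.zeros((b, 2, hl, wl), dtype=np.float32))
            else:
                flow_prev = self.flow_upsamplers[l - 1](flow).scale(2.0)
            warped_r = ad.warp_bilinear(fl_r, flow_prev.data)
            if cfg.normalize_cost:
                # exact local zero-normalized correlation: the channel-mean
                # product is only a correlation for zero-biased features
                warped_r = ad.channel_znorm(warped_r)
                fl_s_c = ad.channel_znorm(fl_s)
            else:
                fl_s_c = fl_s
            cv = ad.cost_volume(warped_r, fl_s_c, cfg.cost_window)
            if cfg.normalize_cost:
                # channel mean of unit vectors: rescale to the ZNCC in [-1, 1]
                cv = cv.scale(float(fl_r.data.shape[1]))
            if prior_full is not None:
                # classical peak readout pooled to this level's pixel units
                prior = Tensor(_downsample_prior(prior_full, l))
                conf = Tensor(_pool_map(conf_full, l))
                inp = ad.concat_channels([cv, fl_s, flow_prev, prior, conf])
                flow = self.phase_nets[l - 1](inp) + prior
            else:
                inp = ad.concat_channels([cv, fl_s, flow_prev])
                flow = self.phase_nets[l - 1](inp)
            level_flows[l] = flow

        out = {"level_flows": level_flows}
        if finest_level > 1:
            return out

        flow_full = self.flow_upsamplers[0](flow).scale(2.0)
        stats = self._stack_statistics(ref, sam, flow_full.data)
        stats_t = Tensor(stats)
        head_parts = [stats_t, flow_full]
        if conf_full is not None:
            head_parts.append(Tensor(conf_full.astype(np.float32)))
        head_in = ad.concat_channels(head_parts)
        if include_td:
            t_map = self.t_net(head_in)
            d_map = self.d_net(head_in)
        else:
            t_map = d_map = None
        if include_refiners:
            flow_full = flow_full + self.phase_refiner(head_in)
            if include_td:
                t_map = t_map + self.t_refiner(ad.concat_channels([t_map, stats_t]))
                d_map = d_map + self.d_refiner(ad.concat_channels([d_map, stats_t]))
        out.update(flow_full=flow_full, t_map=t_map, d_map=d_map)
        return out

    def _classical_prior(
        self, ref: np.ndarray, sam: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Full-resolution correlation-peak flow prior from the raw stacks.

        Zero-normalizes the scan vectors, builds a raw-intensity cost volume
        over a doubled search window, reads off the sub-pixel peak
        (argmax + parabola, median-filtered 3x3) and applies a short
        Gauss-Newton refinement.  Returns the flow prior [B,2,H,W] and the
        peak-correlation confidence map [B,1,H,W].  This embeds the
        classical vector-tracking readout as the starting point that the
        learned estimators refine.
        """
        from scipy import ndimage

        from speckleflow.xsvt import _gradient_refine

        def znorm(x):
            c = x - x.mean(axis=1, keepdims=True)
            return c / (np.sqrt((c**2).sum(axis=1, keepdims=True)) + 1e-6)

        nw = 2 * self.config.cost_window
        cv = ad.cost_volume(
            Tensor(znorm(ref)), Tensor(znorm(sam)), nw
        ).data * ref.shape[1]
        peak = _cost_peak_estimate(cv, nw)
        conf = cv.max(axis=1, keepdims=True)
        peak = ndimage.median_filter(peak, size=(1, 1, 3, 3))
        refined = np.empty_like(peak)
        for b in range(len(peak)):
            dx, dy = _gradient_refine(
                ref[b].astype(np.float64), sam[b].astype(np.float64),
                peak[b, 0], peak[b, 1], iterations=2, order=3,
            )
            refined[b, 0], refined[b, 1] = dx, dy
        return refined, conf

    @staticmethod
    def _stack_statistics(ref: np.ndarray, sam: np.ndarray, flow: np.ndarray) -> np.ndarray:
        """Scan-axis mean/std of the warped reference and the sample stacks."""
        warped = ad.warp_bilinear(Tensor(ref), flow).data
        return np.stack(
            [
                warped.mean(axis=1),
                warped.std(axis=1),
                sam.mean(axis=1),
                sam.std(axis=1),
            ],
            axis=1,
        ).astype(np.float32)

    def forward(
        self,
        reference,
        sample,
        include_refiners: bool = True,
    ) -> MultiContrastResult:
        """Inference on one stack pair (or a batch) in eval mode."""
        was_training = self.training
        self.eval()
        try:
            ref = np.asarray(
                reference.frames if isinstance(reference, PatternStack) else reference
            )
            sam = np.asarray(sample.frames if isinstance(sample, PatternStack) else sample)
            squeeze = ref.ndim == 3
            if squeeze:
                ref = ref[None]
                sam = sam[None]
            out = self.forward_tensors(ref, sam, include_refiners=include_refiners)
            flow = out["flow_full"].data
            t_map = out["t_map"].data
            d_map = out["d_map"].data
            idx = 0 if squeeze else slice(None)
            return MultiContrastResult(
                dx=flow[idx, 0] if squeeze else flow[:, 0],
                dy=flow[idx, 1] if squeeze else flow[:, 1],
                transmission=t_map[idx, 0] if squeeze else t_map[:, 0],
                darkfield=d_map[idx, 0] if squeeze else d_map[:, 0],
                level_flows={l: f.data for l, f in out["level_flows"].items()},
            )
        finally:
            self.train(was_training)

    __call__ = forward


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: MultiContrastNet, path: str | Path, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights, running stats and embedded config."""
    path = Path(path)
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    arrays = model.state_arrays()
    with open(path, "wb") as fh:
        np.savez_compressed(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[MultiContrastNet, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    model = MultiContrastNet(NetworkConfig.from_dict(meta["config"]))
    model.load_state_arrays(arrays)
    return model, meta.get("extra", {})
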