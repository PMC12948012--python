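"""Dataset assembly, loss, staged training schedule and evaluation studies.

Training follows the coarse-to-fine schedule: the flow estimators are
first trained at the coarse pyramid levels only, progressing level by
level, with the refiner sub-networks joining in a final stage at full
resolution.  The loss is

    L = |dx - dx_gt| + |dy - dy_gt| + beta1 |T - T_gt| + beta2 |D - D_gt|

with mean-absolute-error norms, flow terms evaluated at every active
pyramid level against average-pooled (and value-rescaled) ground truth,
and beta1 = beta2 = 10.

Two scale presets exist: ``full`` mirrors the full-scale study conditions
(10000 scenes of 512 px, 20 scans, stage epochs 200/500/800 then 1500,
Adam 1e-4, batch sizes 128/72/64/64) and ``desk`` is a small configuration
(64 px scenes, 5 scans, ~300 phantoms) that trains in minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from speckleflow.forward import (
    PatternStack,
    apply_sample,
    generate_coded_mask,
    make_trajectory,
    render_reference_stack,
)
from speckleflow.integration import displacement_to_refraction, refraction_to_phase
from speckleflow.nn import autodiff as ad
from speckleflow.nn.autodiff import Tensor
from speckleflow.nn.layers import Adam
from speckleflow.nn.model import MultiContrastNet, scale_stack
from speckleflow.optics import OpticsConfig
from speckleflow.phantoms import PhantomConfig, make_phantom
from speckleflow.xsvt import TrackingConfig, fill_invalid, xsvt_track

__all__ = [
    "TrainConfig",
    "SimulationPreset",
    "build_dataset",
    "Dataset",
    "loss_tensor",
    "train_staged",
    "validation_metrics",
    "evaluate_scan_numbers",
    "compare_scaling_methods",
    "zncc",
]


# -- dataset ---------------------------------------------------------------


@dataclass
class SimulationPreset:
    """Scene-generation conditions for one dataset scale."""

    scene_px: int = 64
    n_frames: int = 5
    pattern_px: int = 128
    step_um: float = 3.0
    pixel_size_um: float = 0.65
    energy_keV: float = 14.0
    distance_m: float = 0.5
    mask_pitch_um: float = 5.0
    phase_peak_range: tuple[float, float] = (1.0, 2.5)
    T_deviation_range: tuple[float, float] = (0.02, 0.2)
    D_deviation_range: tuple[float, float] = (0.02, 0.2)
    smoothing_sigma_range: tuple[float, float] = (3.0, 7.0)
    n_bezier_control: int = 6
    # one resolution scale governs interior structure and the support edge,
    # keeping the displacement field bandlimited everywhere
    edge_sigma: float = 5.0
    photon_count: float | None = None

    @classmethod
    def desk(cls, **overrides) -> "SimulationPreset":
        return cls(**overrides)

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationPreset":
        defaults = dict(
            scene_px=512,
            n_frames=20,
            pattern_px=768,
            phase_peak_range=(0.0, 10.0 * math.pi),
            smoothing_sigma_range=(1.0, 31.0),
            n_bezier_control=8,
            edge_sigma=2.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def optics(self) -> OpticsConfig:
        return OpticsConfig(
            energy_keV=self.energy_keV,
            distance_m=self.distance_m,
            pixel_size_um=self.pixel_size_um,
            photon_count=self.photon_count,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_bundle(preset: SimulationPreset, seed: int, n_frames: int | None = None):
    """One (reference, sample) scene pair with attached ground truth."""
    rng = np.random.default_rng(seed)
    s_mask, s_traj, s_phantom = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    optics = preset.optics()
    shape = (preset.scene_px, preset.scene_px)
    trajectory = make_trajectory(
        "diagonal", n_frames or preset.n_frames, preset.step_um, seed=s_traj
    )
    # the modulator must cover the detector plus the full scan excursion
    excursion_px = int(np.ceil(np.abs(trajectory.offsets_um).max() / preset.pixel_size_um))
    pattern_px = max(preset.pattern_px, preset.scene_px + 2 * excursion_px + 16)
    pattern = generate_coded_mask(
        pitch_um=preset.mask_pitch_um,
        pixel_size_um=preset.pixel_size_um,
        shape=(pattern_px, pattern_px),
        seed=s_mask,
    )
    reference = render_reference_stack(pattern, trajectory, optics, shape, seed=seed)
    phantom_cfg = PhantomConfig(
        shape=shape,
        phase_peak_range=preset.phase_peak_range,
        T_deviation_range=preset.T_deviation_range,
        D_deviation_range=preset.D_deviation_range,
        smoothing_sigma_range=preset.smoothing_sigma_range,
        n_bezier_control=preset.n_bezier_control,
        edge_sigma=preset.edge_sigma,
        seed=s_phantom,
    )
    phantom = make_phantom(phantom_cfg)
    sample = apply_sample(
        reference, phantom, optics, seed=seed + 1,
        max_displacement_px=0.35 * preset.scene_px,
    )
    return reference, sample


@dataclass
class Dataset:
    """In-memory collection of (reference, sample, truth) bundles."""

    references: np.ndarray  # [n, N, H, W] float32
    samples: np.ndarray
    truth_dx: np.ndarray  # [n, H, W]
    truth_dy: np.ndarray
    truth_t: np.ndarray
    truth_d: np.ndarray
    seeds: np.ndarray
    split: float = 0.8
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.references)

    @property
    def train_indices(self) -> np.ndarray:
        return np.arange(int(round(self.split * len(self))))

    @property
    def val_indices(self) -> np.ndarray:
        return np.arange(int(round(self.split * len(self))), len(self))

    def save_h5(self, path) -> None:
        import h5py, json

        with h5py.File(path, "w") as fh:
            for name in ("references", "samples", "truth_dx", "truth_dy",
                         "truth_t", "truth_d", "seeds"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs["split"] = self.split
            fh.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load_h5(cls, path) -> "Dataset":
        import h5py, json

        with h5py.File(path, "r") as fh:
            kwargs = {
                name: fh[name][...]
                for name in ("references", "samples", "truth_dx", "truth_dy",
                             "truth_t", "truth_d", "seeds")
            }
            return cls(**kwargs, split=float(fh.attrs["split"]),
                       meta=json.loads(fh.attrs["meta"]))


def build_dataset(
    n_samples: int,
    preset: SimulationPreset | None = None,
    seed: int = 0,
    split: float = 0.8,
) -> Dataset:
    """Seeded, reproducible dataset; train/validation split by index."""
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    preset = preset or SimulationPreset.desk()
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_samples)
    refs, sams, dxs, dys, ts, ds = [], [], [], [], [], []
    for s in seeds:
        reference, sample = simulate_bundle(preset, int(s))
        gt = sample.ground_truth
        refs.append(reference.frames.astype(np.float32))
        sams.append(sample.frames.astype(np.float32))
        dxs.append(gt["dx"].astype(np.float32))
        dys.append(gt["dy"].astype(np.float32))
        ts.append(gt["transmission"].astype(np.float32))
        ds.append(gt["darkfield"].astype(np.float32))
    return Dataset(
        references=np.stack(refs),
        samples=np.stack(sams),
        truth_dx=np.stack(dxs),
        truth_dy=np.stack(dys),
        truth_t=np.stack(ts),
        truth_d=np.stack(ds),
        seeds=seeds,
        split=split,
        meta={"preset": preset.to_dict(), "seed": seed},
    )


# -- loss ------------------------------------------------------------------


def _downsample_flow(flow_px: np.ndarray, level: int) -> np.ndarray:
    """Average-pool a full-resolution flow [B,2,H,W] to pyramid level ``level``
    and rescale the values into that level's pixel units."""
    f = 2**level
    b, c, h, w = flow_px.shape
    pooled = flow_px.reshape(b, c, h // f, f, w // f, f).mean(axis=(3, 5))
    return (pooled / f).astype(np.float32)


def loss_tensor(
    out: dict,
    truth: dict,
    beta1: float = 10.0,
    beta2: float = 10.0,
) -> Tensor:
    """Multi-contrast training loss on the tensors returned by the network."""
    flow_gt = truth["flow"]  # [B, 2, H, W] full-res px
    total: Tensor | None = None

    def acc(t: Tensor | None, term: Tensor) -> Tensor:
        return term if t is None else t + term

    for level, flow_l in out["level_flows"].items():
        gt_l = _downsample_flow(flow_gt, level)
        # rescale each level's MAE into full-resolution pixel units so the
        # flow terms carry comparable weight at every level
        total = acc(total, ad.mean_abs_error(flow_l, gt_l).scale(float(2**level)))
    if out.get("flow_full") is not None:
        total = acc(total, ad.mean_abs_error(out["flow_full"], flow_gt))
    if out.get("t_map") is not None:
        total = acc(total, ad.mean_abs_error(out["t_map"], truth["t"]).scale(beta1))
    if out.get("d_map") is not None:
        total = acc(total, ad.mean_abs_error(out["d_map"], truth["d"]).scale(beta2))
    return total


# -- staged training -------------------------------------------------------


@dataclass
class TrainConfig:
    """Staged-training schedule.

    ``stage_epochs[i]`` trains with the coarse-to-fine loop stopped at
    ``finest_levels[i]`` and no refiners; the final stage runs the full
    network (refiners included) for ``final_epochs``.
    """

    stage_epochs: tuple[int, ...] = (2, 2, 4)
    final_epochs: int = 6
    batch_size: int = 8
    lr: float = 1e-3
    beta1: float = 10.0
    beta2: float = 10.0
    seed: int = 0
    freeze_earlier: bool = False  # exposed; default keeps all levels trainable

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        return cls(**overrides)

    @classmethod
    def full_scale(cls, **overrides) -> "TrainConfig":
        defaults = dict(
            stage_epochs=(200, 500, 800),
            final_epochs=1500,
            batch_size=64,
            lr=1e-4,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainResult:
    history: list[dict]
    val_metrics: dict
    aborted: bool = False


def _batches(indices: np.ndarray, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(indices)
    for i in range(0, len(order), batch_size):
        yield order[i : i + batch_size]


def train_staged(
    model: MultiContrastNet,
    dataset: Dataset,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Coarse-to-fine staged training with Adam; deterministic under seed.

    A NaN loss aborts the run and restores the last epoch-end state.
    """
    config = config or TrainConfig()
    levels = model.config.levels
    n_stages = len(config.stage_epochs)
    # stage i stops the pyramid at this level (coarse first, then finer)
    finest_levels = [max(1, levels - i) for i in range(n_stages)]
    stages = [
        {"finest": fl, "epochs": ep, "refiners": False}
        for fl, ep in zip(finest_levels, config.stage_epochs)
    ] + [{"finest": 1, "epochs": config.final_epochs, "refiners": True}]

    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    train_idx = dataset.train_indices
    snapshot = {k: v.copy() for k, v in model.state_arrays().items()}
    aborted = False

    model.train(True)
    for stage_no, stage in enumerate(stages):
        optimizer = Adam(model.parameters(), lr=config.lr)
        include_td = stage["finest"] == 1
        for epoch in range(stage["epochs"]):
            epoch_loss = 0.0
            n_batches = 0
            for idx in _batches(train_idx, config.batch_size, rng):
                ref = dataset.references[idx]
                sam = dataset.samples[idx]
                truth = {
                    "flow": np.stack(
                        [dataset.truth_dx[idx], dataset.truth_dy[idx]], axis=1
                    ),
                    "t": dataset.truth_t[idx][:, None],
                    "d": dataset.truth_d[idx][:, None],
                }
                model.zero_grad()
                out = model.forward_tensors(
                    ref, sam,
                    finest_level=stage["finest"],
                    include_td=include_td,
                    include_refiners=stage["refiners"],
                )
                loss = loss_tensor(out, truth, config.beta1, config.beta2)
                value = float(np.asarray(loss.data).ravel()[0])
                if not np.isfinite(value):
                    model.load_state_arrays(snapshot)
                    aborted = True
                    break
                loss.backward()
                optimizer.step()
                epoch_loss += value
                n_batches += 1
            if aborted:
                break
            history.append(
                {"stage": stage_no, "epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
            )
            if verbose:
                print(f"stage {stage_no} epoch {epoch}: loss {history[-1]['loss']:.4f}")
            snapshot = {k: v.copy() for k, v in model.state_arrays().items()}
        if aborted:
            break
    if not aborted:
        _calibrate_batchnorm(model, dataset, config, rng)
    model.eval()
    metrics = validation_metrics(model, dataset)
    return TrainResult(history=history, val_metrics=metrics, aborted=aborted)


def _calibrate_batchnorm(
    model: MultiContrastNet,
    dataset: Dataset,
    config: TrainConfig,
    rng: np.random.Generator,
) -> None:
    """Recompute batch-norm running statistics exactly under the final weights.

    The staged schedule leaves the momentum-based running estimates lagging
    behind the trained weights; one statistics-only pass over the training
    set with cumulative averaging (momentum 1/k at step k) replaces them
    with the exact mean of the per-batch statistics.
    """
    from speckleflow.nn.layers import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    model.train(True)
    for step, idx in enumerate(_batches(dataset.train_indices, config.batch_size, rng)):
        for bn in bns:
            bn.momentum = 1.0 / (step + 1)
        model.forward_tensors(
            dataset.references[idx], dataset.samples[idx],
            include_td=True, include_refiners=True,
        )
    for bn, m in zip(bns, saved):
        bn.momentum = m


def validation_metrics(
    model: MultiContrastNet, dataset: Dataset, batch_size: int = 16
) -> dict:
    """Held-out flow RMSE (px) and T/D mean absolute errors."""
    idx = dataset.val_indices
    sq_err = 0.0
    n_px = 0
    t_err = 0.0
    d_err = 0.0
    model.eval()
    for i in range(0, len(idx), batch_size):
        sel = idx[i : i + batch_size]
        out = model.forward_tensors(
            dataset.references[sel], dataset.samples[sel],
            include_td=True, include_refiners=True,
        )
        flow = out["flow_full"].data
        gt = np.stack([dataset.truth_dx[sel], dataset.truth_dy[sel]], axis=1)
        sq_err += float(((flow - gt) ** 2).sum())
        n_px += flow.size
        t_err += float(np.abs(out["t_map"].data[:, 0] - dataset.truth_t[sel]).sum())
        d_err += float(np.abs(out["d_map"].data[:, 0] - dataset.truth_d[sel]).sum())
    n_maps = n_px // 2
    return {
        "flow_rmse_px": math.sqrt(sq_err / n_px),
        "t_mae": t_err / n_maps,
        "d_mae": d_err / n_maps,
    }


# -- evaluation studies ----------------------------------------------------


def zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two maps (similarity metric)."""
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / den) if den > 0 else 0.0


def _net_phase(model, ref_frames, sam_frames, optics) -> np.ndarray:
    cfg = model.config
    ref_s = scale_stack(ref_frames, cfg.n_net, cfg.scaling_method)
    sam_s = scale_stack(sam_frames, cfg.n_net, cfg.scaling_method)
    res = model.forward(ref_s, sam_s)
    from speckleflow.forward import DisplacementField

    ax, ay = displacement_to_refraction(
        DisplacementField(res.dx.astype(np.float64), res.dy.astype(np.float64)), optics
    )
    return refraction_to_phase(ax, ay, optics)


def _xsvt_phase(ref_frames, sam_frames, optics, tracking) -> np.ndarray:
    disp, _ = xsvt_track(ref_frames, sam_frames, tracking)
    disp = fill_invalid(disp)
    ax, ay = displacement_to_refraction(disp, optics)
    return refraction_to_phase(ax, ay, optics)


def evaluate_scan_numbers(
    model: MultiContrastNet,
    reference: PatternStack,
    sample: PatternStack,
    optics: OpticsConfig,
    scan_numbers: tuple[int, ...] = (20, 10, 5, 3, 2),
    tracking: TrackingConfig | None = None,
) -> list[dict]:
    """Scan-number study on one scene: phase similarity vs the largest-N
    reconstruction, for the network and for XSVT side by side."""
    tracking = tracking or TrackingConfig(search_window=4, min_valid_correlation=0.2)
    n_ref = max(scan_numbers)
    ref_phase_net = _net_phase(model, reference.frames[:n_ref], sample.frames[:n_ref], optics)
    ref_phase_xsvt = _xsvt_phase(
        reference.frames[:n_ref], sample.frames[:n_ref], optics, tracking
    )
    rows = []
    for n in scan_numbers:
        phase_net = _net_phase(model, reference.frames[:n], sample.frames[:n], optics)
        phase_xsvt = _xsvt_phase(reference.frames[:n], sample.frames[:n], optics, tracking)
        gt = sample.ground_truth
        row = {
            "n": n,
            "net_similarity": zncc(phase_net, ref_phase_net),
            "xsvt_similarity": zncc(phase_xsvt, ref_phase_xsvt),
        }
        if gt is not None:
            row["net_phase_zncc_gt"] = zncc(phase_net, gt["phase"])
            row["xsvt_phase_zncc_gt"] = zncc(phase_xsvt, gt["phase"])
        rows.append(row)
    return rows


def compare_scaling_methods(
    model: MultiContrastNet,
    reference: PatternStack,
    sample: PatternStack,
    optics: OpticsConfig,
    n_reduced: int,
    methods: tuple[str, ...] = ("nearest", "linear", "bilinear", "spline"),
) -> dict:
    """Data-scaling study: relative mean-square error of T, D and phase for
    each interpolation method against the full-N reconstruction."""
    cfg = model.config

    def run(ref_frames, sam_frames, method):
        ref_s = scale_stack(ref_frames, cfg.n_net, method)
        sam_s = scale_stack(sam_frames, cfg.n_net, method)
        res = model.forward(ref_s, sam_s)
        from speckleflow.forward import DisplacementField

        ax, ay = displacement_to_refraction(
            DisplacementField(res.dx.astype(np.float64), res.dy.astype(np.float64)),
            optics,
        )
        phase = refraction_to_phase(ax, ay, optics)
        return res.transmission, res.darkfield, phase

    t_ref, d_ref, p_ref = run(reference.frames, sample.frames, cfg.scaling_method)

    def rel_mse(a, b):
        return float(((a - b) ** 2).mean() / ((b**2).mean() + 1e-30))

    table = {}
    for method in methods:
        t, d, p = run(reference.frames[:n_reduced], sample.frames[:n_reduced], method)
        table[method] = {
            "transmission": rel_mse(t, t_ref),
            "darkfield": rel_mse(d, d_ref),
            "phase": rel_mse(p, p_ref),
        }
    return table
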