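"""Physics forward model: modulators, Fresnel propagation and sample modulation.

The simulator renders a *reference* stack (modulator scanned across N
positions, no sample) by translating the modulator's complex transmission
and propagating it to the detector with the angular-spectrum transfer
function, then applies a phantom to produce the *sample* stack via the
scanning-mode multi-contrast model

    I_s(x, y, i) = T(x, y) * [ (1 - D) * I_r(x + dx, y + dy, i)
                               + D * Ibar_r(x + dx, y + dy, i) ],

where Ibar_r is the locally averaged reference, T the transmission, D the
dark-field damping of the pattern contrast (D = 0: full speckle contrast,
D = 1: contrast fully washed out) and (dx, dy) the pattern displacement
induced by the sample's refraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from speckleflow.optics import OpticsConfig

__all__ = [
    "ModulatorPattern",
    "ScanTrajectory",
    "PatternStack",
    "DisplacementField",
    "generate_coded_mask",
    "generate_checkerboard",
    "propagate_fresnel",
    "subpixel_shift",
    "make_trajectory",
    "render_reference_stack",
    "phase_to_displacement",
    "apply_sample",
]


@dataclass
class ModulatorPattern:
    """Complex transmission map of the modulator at its own plane."""

    transmission: np.ndarray  # complex, [H, W]
    pixel_size_um: float
    pitch_um: float
    kind: str = "coded-mask"

    def __post_init__(self) -> None:
        amp = np.abs(self.transmission)
        if amp.max() > 1.0 + 1e-9:
            raise ValueError("modulator amplitude must be <= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission.shape


@dataclass
class ScanTrajectory:
    """Ordered modulator offsets in micrometres, one per frame."""

    offsets_um: np.ndarray  # [N, 2] as (x, y)
    kind: str = "diagonal"
    step_um: float = 3.0

    def __post_init__(self) -> None:
        self.offsets_um = np.asarray(self.offsets_um, dtype=np.float64).reshape(-1, 2)
        if len(self.offsets_um) < 1:
            raise ValueError("trajectory must contain at least one position")
        if not np.all(np.isfinite(self.offsets_um)):
            raise ValueError("trajectory offsets must be finite")

    def __len__(self) -> int:
        return len(self.offsets_um)

    def to_dict(self) -> dict:
        return {
            "offsets_um": self.offsets_um.tolist(),
            "kind": self.kind,
            "step_um": self.step_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanTrajectory":
        return cls(
            offsets_um=np.asarray(d["offsets_um"]),
            kind=d.get("kind", "diagonal"),
            step_um=d.get("step_um", 3.0),
        )


@dataclass
class PatternStack:
    """N x H x W intensity frames plus the trajectory that produced them."""

    frames: np.ndarray
    trajectory: ScanTrajectory
    role: str = "reference"  # or "sample"
    ground_truth: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be N x H x W")
        if len(self.frames) != len(self.trajectory):
            raise ValueError("frame count does not match trajectory length")
        if self.frames.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DisplacementField:
    """Per-pixel pattern shifts in detector pixels."""

    dx: np.ndarray
    dy: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx/dy shapes differ")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("displacements must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape

    def max_abs(self) -> float:
        return float(max(np.abs(self.dx).max(), np.abs(self.dy).max()))


def _rasterize_cells(
    cell_values: np.ndarray, cell_size_um: float, pixel_size_um: float,
    shape: tuple[int, int], supersample: int = 4,
) -> np.ndarray:
    """Average a cell-wise complex map onto the pixel grid with supersampling.

    Cells generally do not align with pixels (e.g. 5 um pitch at 0.65 um
    pixels is ~7.69 px per cell); each pixel value is the area-weighted
    complex average over ``supersample^2`` sub-samples.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=complex)
    k = supersample
    # sub-pixel sample coordinates in um (pixel centre convention)
    sub = (np.arange(k) + 0.5) / k
    for iy in range(k):
        for ix in range(k):
            ys = (np.arange(h) + sub[iy]) * pixel_size_um
            xs = (np.arange(w) + sub[ix]) * pixel_size_um
            cy = np.minimum((ys / cell_size_um).astype(int), cell_values.shape[0] - 1)
            cx = np.minimum((xs / cell_size_um).astype(int), cell_values.shape[1] - 1)
            out += cell_values[np.ix_(cy, cx)]
    return out / (k * k)


def generate_coded_mask(
    pitch_um: float = 5.0,
    pixel_size_um: float = 0.65,
    shape: tuple[int, int] = (768, 768),
    phase_shift_rad: float = 1.0,
    amplitude: float = 0.95,
    fill_fraction: float = 0.5,
    seed: int = 0,
    supersample: int = 4,
) -> ModulatorPattern:
    """Random binary coded mask: cells of side ``pitch_um`` are either open
    (transmission 1) or modulated (``amplitude * exp(i * phase_shift)``).

    The default models a lithographed phase mask on a thin membrane: mostly
    phase modulation with weak absorption.
    """
    if pitch_um < pixel_size_um:
        raise ValueError("pitch must be >= pixel size")
    h, w = shape
    n_cy = int(math.ceil(h * pixel_size_um / pitch_um)) + 1
    n_cx = int(math.ceil(w * pixel_size_um / pitch_um)) + 1
    rng = np.random.default_rng(seed)
    modulated = rng.random((n_cy, n_cx)) < fill_fraction
    cell_values = np.where(modulated, amplitude * np.exp(1j * phase_shift_rad), 1.0 + 0j)
    tx = _rasterize_cells(cell_values, pitch_um, pixel_size_um, shape, supersample)
    # supersampled averaging of unit-modulus cells can exceed 1 only by rounding
    amp = np.abs(tx)
    np.clip(amp, None, 1.0, out=amp)
    tx = amp * np.exp(1j * np.angle(tx))
    return ModulatorPattern(tx, pixel_size_um, pitch_um, kind="coded-mask")


def generate_checkerboard(
    period_um: float = 20.0,
    pixel_size_um: float = 0.65,
    shape: tuple[int, int] = (768, 768),
    phase_shift_rad: float = math.pi / 2,
    amplitudes: tuple[float, float] = (1.0, 1.0),
    supersample: int = 4,
) -> ModulatorPattern:
    """Checkerboard phase grating of the stated period (two cells per period)."""
    if period_um < 2 * pixel_size_um:
        raise ValueError("period must cover at least two pixels")
    h, w = shape
    cell_um = period_um / 2.0
    n_cy = int(math.ceil(h * pixel_size_um / cell_um)) + 1
    n_cx = int(math.ceil(w * pixel_size_um / cell_um)) + 1
    iy, ix = np.mgrid[0:n_cy, 0:n_cx]
    odd = (iy + ix) % 2 == 1
    a0, a1 = amplitudes
    cell_values = np.where(odd, a1 * np.exp(1j * phase_shift_rad), a0 + 0j)
    tx = _rasterize_cells(cell_values, cell_um, pixel_size_um, shape, supersample)
    amp = np.abs(tx)
    np.clip(amp, None, 1.0, out=amp)
    tx = amp * np.exp(1j * np.angle(tx))
    return ModulatorPattern(tx, pixel_size_um, period_um, kind="checkerboard")


def _check_sampling(shape: tuple[int, int], optics: OpticsConfig) -> None:
    # angular-spectrum validity: the quadratic phase of the transfer function
    # must be sampled below Nyquist, i.e. d <= N p^2 / lambda per axis.
    p = optics.pixel_size_m
    for n_axis, name in zip(shape, ("rows", "cols")):
        d_max = n_axis * p * p / optics.wavelength_m
        if optics.distance_m > d_max:
            raise ValueError(
                f"aliasing bound violated along {name}: distance_m="
                f"{optics.distance_m} exceeds N*p^2/lambda = {d_max:.4g} "
                f"(N={n_axis}, pixel_size_um={optics.pixel_size_um})"
            )


def propagate_fresnel(
    pattern: ModulatorPattern | np.ndarray,
    optics: OpticsConfig,
    return_field: bool = False,
) -> np.ndarray:
    """Near-field propagation by the angular-spectrum (Fresnel) transfer function.

    Returns |U(d)|^2 on the same grid.  The transfer function
    H = exp(-i pi lambda d (fx^2 + fy^2)) is unitary, so total intensity is
    conserved for pure-phase modulators; d = 0 returns |U(0)|^2 exactly.
    """
    u0 = pattern.transmission if isinstance(pattern, ModulatorPattern) else pattern
    u0 = np.asarray(u0, dtype=complex)
    if optics.distance_m == 0.0:
        field_d = u0
    else:
        _check_sampling(u0.shape, optics)
        h, w = u0.shape
        p = optics.pixel_size_m
        fy = np.fft.fftfreq(h, d=p)[:, None]
        fx = np.fft.fftfreq(w, d=p)[None, :]
        transfer = np.exp(
            -1j * math.pi * optics.wavelength_m * optics.distance_m * (fx**2 + fy**2)
        )
        field_d = np.fft.ifft2(np.fft.fft2(u0) * transfer)
    if return_field:
        return field_d
    return np.abs(field_d) ** 2


def subpixel_shift(image: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Fourier-domain sub-pixel shift with periodic boundary semantics.

    Image content moves by (+dx, +dy) pixels: ``out(y, x) = in(y - dy, x - dx)``.
    Real input returns real output.
    """
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("shifts must be finite")
    if dx == 0.0 and dy == 0.0:
        return image.copy()
    h, w = image.shape
    ry = np.exp(-2j * math.pi * np.fft.fftfreq(h) * dy)
    rx = np.exp(-2j * math.pi * np.fft.fftfreq(w) * dx)
    if np.isrealobj(image):
        # keep the output exactly real: the Nyquist bin of a real signal
        # must receive a real factor (cosine of the shift phase)
        if h % 2 == 0:
            ry[h // 2] = ry[h // 2].real
        if w % 2 == 0:
            rx[w // 2] = rx[w // 2].real
        ramp = ry[:, None] * rx[None, :]
        return np.fft.ifft2(np.fft.fft2(image) * ramp).real
    ramp = ry[:, None] * rx[None, :]
    return np.fft.ifft2(np.fft.fft2(image) * ramp)


def make_trajectory(
    kind: str = "diagonal",
    n: int = 20,
    step_um: float = 3.0,
    jitter: float | None = None,
    seed: int = 0,
) -> ScanTrajectory:
    """Scan trajectory with jittered steps.

    diagonal: position i = i * step * (1, 1) plus a uniform jitter of
    +-``jitter`` um per axis (default 0.5 * step).  xy-grid: sqrt(N) x sqrt(N)
    grid built from cumulative Gaussian steps with mean ``step`` and standard
    deviation ``jitter`` um (default 0.1 * step).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "diagonal":
        half = 0.5 * step_um if jitter is None else jitter
        base = np.arange(n)[:, None] * step_um * np.ones((1, 2))
        offs = base + rng.uniform(-half, half, size=(n, 2))
    elif kind == "xy-grid":
        side = int(round(math.sqrt(n)))
        if side * side != n:
            raise ValueError(f"xy-grid requires a square N, got {n}")
        sigma = 0.1 * step_um if jitter is None else jitter
        steps_x = rng.normal(step_um, sigma, size=side)
        steps_y = rng.normal(step_um, sigma, size=side)
        xs = np.concatenate([[0.0], np.cumsum(steps_x[:-1])])
        ys = np.concatenate([[0.0], np.cumsum(steps_y[:-1])])
        offs = np.array([(x, y) for y in ys for x in xs])
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    return ScanTrajectory(offsets_um=offs, kind=kind, step_um=step_um)


def render_reference_stack(
    pattern: ModulatorPattern,
    trajectory: ScanTrajectory,
    optics: OpticsConfig,
    detector_shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> PatternStack:
    """Reference stack: translate the modulator per scan position, propagate,
    crop the central detector region, optionally add Poisson noise.

    The pattern array must exceed the detector by the maximum scan excursion
    plus a guard margin so that periodic wrap-around from the Fourier shift
    never reaches the cropped region.
    """
    if detector_shape is None:
        detector_shape = pattern.shape
    ph, pw = pattern.shape
    dh, dw = detector_shape
    off_px = trajectory.offsets_um / pattern.pixel_size_um
    max_exc = float(np.abs(off_px).max()) if len(off_px) else 0.0
    margin_y = (ph - dh) / 2.0
    margin_x = (pw - dw) / 2.0
    if margin_y < max_exc or margin_x < max_exc:
        raise ValueError(
            f"pattern margin ({margin_y:.1f}, {margin_x:.1f}) px does not cover the "
            f"scan excursion {max_exc:.1f} px; enlarge the pattern"
        )
    y0 = (ph - dh) // 2
    x0 = (pw - dw) // 2
    rng = np.random.default_rng(seed)
    frames = np.empty((len(trajectory), dh, dw))
    for i, (ox, oy) in enumerate(off_px):
        # the Fourier shift may overshoot the [0, 1] amplitude range slightly
        # (Gibbs ringing at binary cell edges); propagate the raw field
        shifted = subpixel_shift(pattern.transmission, ox, oy)
        intensity = propagate_fresnel(shifted, optics)
        frame = intensity[y0 : y0 + dh, x0 : x0 + dw]
        if optics.photon_count is not None:
            frame = rng.poisson(np.maximum(frame, 0.0) * optics.photon_count) / float(
                optics.photon_count
            )
        frames[i] = frame
    return PatternStack(
        frames=frames,
        trajectory=trajectory,
        role="reference",
        meta={
            "pitch_um": pattern.pitch_um,
            "pixel_size_um": pattern.pixel_size_um,
            "modulator": pattern.kind,
            "optics": optics.to_dict(),
        },
    )


def phase_to_displacement(
    phantom_or_phase, optics: OpticsConfig, periodic: bool = False
) -> DisplacementField:
    """Pattern displacement induced by the sample's phase gradient.

    alpha = (lambda / 2 pi) * grad(phi) and delta[px] = d * alpha / p, i.e.
    delta = d * lambda / (2 pi p^2) * dphi/dpx with central differences on
    the pixel grid (one-sided at the borders, or wrapped when ``periodic``).
    """
    phase = getattr(phantom_or_phase, "phase", phantom_or_phase)
    if periodic:
        gx = 0.5 * (np.roll(phase, -1, axis=1) - np.roll(phase, 1, axis=1))
        gy = 0.5 * (np.roll(phase, -1, axis=0) - np.roll(phase, 1, axis=0))
    else:
        gy, gx = np.gradient(phase)  # rad per px along rows (y) and cols (x)
    c = optics.displacement_per_gradient
    return DisplacementField(dx=c * gx, dy=c * gy)


def apply_sample(
    reference: PatternStack,
    phantom,
    optics: OpticsConfig,
    avg_sigma_px: float | None = None,
    max_displacement_px: float | None = None,
    seed: int = 0,
    interpolation_order: int = 3,
) -> PatternStack:
    """Modulate the reference stack by a phantom, with exact ground truth.

    Each frame is resampled at (x + dx, y + dy) with the displacement field
    derived from the phantom phase, then blended between the full-contrast
    frame and its local average according to the dark-field map and scaled
    by the transmission.  A vacuum phantom (T = 1, D = 0, phi = 0) returns a
    bit-identical copy of the reference frames.
    """
    if phantom.phase.shape != reference.shape:
        raise ValueError("phantom and reference stack are on different grids")
    disp = phase_to_displacement(phantom, optics)
    h, w = reference.shape
    bound = max_displacement_px if max_displacement_px is not None else 0.25 * min(h, w)
    if disp.max_abs() > bound:
        raise ValueError(
            f"max displacement {disp.max_abs():.2f} px exceeds the allowed margin "
            f"{bound:.2f} px"
        )
    if avg_sigma_px is None:
        pitch = reference.meta.get("pitch_um")
        pixel = reference.meta.get("pixel_size_um")
        avg_sigma_px = 2.0 * pitch / pixel if pitch and pixel else 15.0

    t_map = phantom.transmission
    d_map = phantom.darkfield
    uniform_shift = disp.max_abs() == 0.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + disp.dy, xx + disp.dx])

    frames = np.empty_like(reference.frames)
    rng = np.random.default_rng(seed)
    for i, frame in enumerate(reference.frames):
        local_avg = ndimage.gaussian_filter(frame, avg_sigma_px, mode="nearest")
        if uniform_shift:
            warped, warped_avg = frame, local_avg
        else:
            warped = ndimage.map_coordinates(
                frame, coords, order=interpolation_order, mode="reflect"
            )
            warped_avg = ndimage.map_coordinates(
                local_avg, coords, order=interpolation_order, mode="reflect"
            )
        # algebraically identical to Ibar + (1-D)(I - Ibar); this form is
        # bit-exact for the vacuum case (T=1, D=0)
        out = t_map * ((1.0 - d_map) * warped + d_map * warped_avg)
        if not uniform_shift:
            # cubic resampling can overshoot slightly below zero at sharp
            # speckle edges; intensities are physical
            np.maximum(out, 0.0, out=out)
        if optics.photon_count is not None:
            out = rng.poisson(np.maximum(out, 0.0) * optics.photon_count) / float(
                optics.photon_count
            )
        frames[i] = out

    return PatternStack(
        frames=frames,
        trajectory=reference.trajectory,
        role="sample",
        ground_truth={
            "transmission": t_map.copy(),
            "darkfield": d_map.copy(),
            "dx": disp.dx.copy(),
            "dy": disp.dy.copy(),
            "phase": phantom.phase.copy(),
        },
        meta=dict(reference.meta, avg_sigma_px=avg_sigma_px),
    )
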