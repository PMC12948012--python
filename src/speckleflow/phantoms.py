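"""Synthetic test samples with known phase, transmission and dark-field maps.

Random phantoms follow the training-sample recipe used throughout the
package: a closed Bezier outline with random structure, filled with
Gaussian-smoothed noise fields whose peak amplitudes are drawn from
configured ranges, so that every map is bandlimited below the detector
resolution.  An analytic parabolic-lens phantom (the standard compound
refractive lens, CRL) provides a quantitative oracle: its phase is
phi(r) = -(2 pi / lambda) * delta * r^2 / R for apex radius R and
refractive decrement delta.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "SamplePhantom",
    "generate_bezier_outline",
    "generate_smooth_field",
    "make_phantom",
    "make_lens_phantom",
    "write_phantom",
    "read_phantom",
]


@dataclass
class SamplePhantom:
    """Ground-truth sample maps on the detector grid.

    ``phase`` is in radians, ``transmission`` in (0, 1] and ``darkfield``
    (small-angle scattering strength) in [0, 1]; all three share one shape.
    """

    phase: np.ndarray
    transmission: np.ndarray
    darkfield: np.ndarray
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.phase.shape == self.transmission.shape == self.darkfield.shape):
            raise ValueError("phase/transmission/darkfield shapes differ")
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    def validate(self) -> None:
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase contains non-finite values")
        if np.any(self.transmission <= 0) or np.any(self.transmission > 1):
            raise ValueError("transmission must lie in (0, 1]")
        if np.any(self.darkfield < 0) or np.any(self.darkfield > 1):
            raise ValueError("darkfield must lie in [0, 1]")


@dataclass
class PhantomConfig:
    """Recipe for one random phantom.

    Peak ranges are *deviation* ranges: the per-phantom peak phase is drawn
    from ``phase_peak_range`` (rad), the transmission dip from
    ``T_deviation_range`` (so T spans [1 - dev, 1]) and the dark-field
    amplitude from ``D_deviation_range``.  With
    ``literal_transmission=True`` the transmission range is instead read
    literally, i.e. T inside the support spans ``T_deviation_range`` itself
    (strongly absorbing samples).
    """

    shape: tuple[int, int] = (512, 512)
    phase_peak_range: tuple[float, float] = (0.0, 10.0 * math.pi)
    T_deviation_range: tuple[float, float] = (0.02, 0.2)
    D_deviation_range: tuple[float, float] = (0.02, 0.2)
    smoothing_sigma_range: tuple[float, float] = (1.0, 31.0)
    n_bezier_control: int = 8
    edge_sigma: float = 2.0
    literal_transmission: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bezier_control < 3:
            raise ValueError("n_bezier_control must be >= 3")
        if min(self.shape) < 32:
            raise ValueError("shape must be at least 32x32")
        for name, (lo, hi), dom in (
            ("phase_peak_range", self.phase_peak_range, (0.0, math.inf)),
            ("T_deviation_range", self.T_deviation_range, (0.0, 1.0)),
            ("D_deviation_range", self.D_deviation_range, (0.0, 1.0)),
            ("smoothing_sigma_range", self.smoothing_sigma_range, (0.0, math.inf)),
        ):
            if not (dom[0] <= lo <= hi <= dom[1]):
                raise ValueError(f"{name}=({lo}, {hi}) is not a valid sub-interval")

    def to_dict(self) -> dict:
        return asdict(self)


def _closed_bezier_samples(points: np.ndarray, samples_per_segment: int = 48) -> np.ndarray:
    """Smooth closed curve through quadratic Bezier segments.

    Each segment runs from the midpoint of (P[i-1], P[i]) to the midpoint of
    (P[i], P[i+1]) with P[i] as the control point, which yields a C1 closed
    curve for any control polygon.
    """
    n = len(points)
    t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)[:, None]
    segs = []
    for i in range(n):
        p_prev = points[i - 1]
        p_ctrl = points[i]
        p_next = points[(i + 1) % n]
        a = 0.5 * (p_prev + p_ctrl)
        b = 0.5 * (p_ctrl + p_next)
        seg = (1 - t) ** 2 * a + 2 * (1 - t) * t * p_ctrl + t**2 * b
        segs.append(seg)
    return np.concatenate(segs, axis=0)


def generate_bezier_outline(config: PhantomConfig, max_retries: int = 20) -> np.ndarray:
    """Closed, filled random outline strictly inside the frame.

    Control points are placed at sorted random angles around the frame
    centre with random radii; the filled region of the smooth closed Bezier
    curve through them is returned as a boolean mask.  Deterministic under
    ``config.seed``.
    """
    from skimage.draw import polygon as draw_polygon

    h, w = config.shape
    rng = np.random.default_rng(config.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_max = 0.42 * min(h, w)
    for _ in range(max_retries):
        n = config.n_bezier_control
        angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, n))
        radii = rng.uniform(0.35 * r_max, r_max, n)
        pts = np.stack(
            [cy + radii * np.sin(angles), cx + radii * np.cos(angles)], axis=1
        )
        curve = _closed_bezier_samples(pts)
        rr, cc = draw_polygon(curve[:, 0], curve[:, 1], shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        area = mask.sum()
        touches_border = (
            mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
        )
        if 0 < area < h * w and not touches_border:
            return mask
    raise RuntimeError(
        f"could not draw a valid outline in {max_retries} attempts (seed={config.seed})"
    )


def generate_smooth_field(
    shape: tuple[int, int], sigma: float, peak: float, seed: int
) -> np.ndarray:
    """Gaussian-filtered white noise with exact peak-to-peak amplitude.

    Returns a zero-mean map whose max - min equals ``peak``; ``sigma`` is
    the Gaussian smoothing length in pixels (0 means unfiltered noise).
    Filtering uses periodic boundaries so the spectral content is exactly
    the Gaussian transfer function.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if peak < 0:
        raise ValueError("peak must be >= 0")
    if peak == 0.0:
        return np.zeros(shape, dtype=np.float64)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    noise -= noise.mean()
    ptp = noise.max() - noise.min()
    # the raw noise is standard normal (ptp of order 5-10); anything this
    # small means the filter has flattened the field to numerical noise
    if ptp < 1e-6:
        raise ValueError(
            f"sigma={sigma} leaves the field numerically constant; "
            f"cannot realize peak-to-peak {peak}"
        )
    return noise * (peak / ptp)


def _support_window(mask: np.ndarray, edge_sigma: float) -> np.ndarray:
    """Smooth apodization of the binary support, exactly zero outside it.

    Built from the Euclidean distance to the support boundary,
    w = 1 - exp(-d^2 / (2 sigma^2)), so the window rises smoothly over
    ~3 sigma inside the outline while staying identically zero outside;
    the filled maps remain bandlimited without breaking the exact
    vacuum-outside-support contract.
    """
    if edge_sigma <= 0:
        return mask.astype(np.float64)
    dist = ndimage.distance_transform_edt(mask)
    win = 1.0 - np.exp(-0.5 * (dist / edge_sigma) ** 2)
    m = win.max()
    return win / m if m > 0 else mask.astype(np.float64)


def make_phantom(config: PhantomConfig) -> SamplePhantom:
    """Random phantom: outline filled with smooth phase/T/D distributions.

    Outside the support the maps are exactly (phase, T, D) = (0, 1, 0);
    inside, each map is a smooth noise field whose peak is drawn uniformly
    from the configured range.
    """
    rng = np.random.default_rng(config.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]
    mask = generate_bezier_outline(config)
    window = _support_window(mask, config.edge_sigma)

    sigma = rng.uniform(*config.smoothing_sigma_range)
    phase_peak = rng.uniform(*config.phase_peak_range)
    t_dev = rng.uniform(*config.T_deviation_range)
    d_dev = rng.uniform(*config.D_deviation_range)

    def positive_field(peak: float, seed: int) -> np.ndarray:
        if peak == 0.0:
            return np.zeros(config.shape)
        f = generate_smooth_field(config.shape, sigma, peak, seed)
        return f - f.min()  # span [0, peak]

    phase = positive_field(phase_peak, sub[0]) * window
    if config.literal_transmission:
        lo, hi = config.T_deviation_range
        t_in = lo + positive_field(hi - lo, sub[1])  # values in [lo, hi]
        transmission = 1.0 + (t_in - 1.0) * window
    else:
        transmission = 1.0 - positive_field(t_dev, sub[1]) * window
    darkfield = positive_field(d_dev, sub[2]) * window
    # guard against rounding at the upper clip boundaries
    np.clip(darkfield, 0.0, 1.0, out=darkfield)
    transmission = np.minimum(transmission, 1.0)

    return SamplePhantom(
        phase=phase,
        transmission=transmission,
        darkfield=darkfield,
        pixel_size_um=1.0,
        meta={
            "seed": config.seed,
            "config": config.to_dict(),
            "sigma": sigma,
            "phase_peak": phase_peak,
            "T_deviation": t_dev,
            "D_deviation": d_dev,
        },
    )


def make_lens_phantom(
    apex_radius_um: float,
    delta: float,
    wavelength_m: float,
    shape: tuple[int, int],
    pixel_size_um: float,
    aperture_radius_um: float | None = None,
    absorption_mu_per_m: float = 0.0,
    edge_sigma_px: float = 2.0,
) -> SamplePhantom:
    """Parabolic refractive lens phantom (single CRL element).

    Phase is the analytic parabola phi(r) = -(2 pi / lambda) * delta * r^2 / R
    inside the aperture, flat outside; transmission follows the parabolic
    material thickness t(r) = r^2 / R with attenuation coefficient
    ``absorption_mu_per_m``; dark-field is identically zero.  The aperture
    edge is smoothed by ``edge_sigma_px`` to keep the maps bandlimited.
    """
    if apex_radius_um <= 0:
        raise ValueError("apex_radius_um must be positive")
    h, w = shape
    if aperture_radius_um is None:
        aperture_radius_um = 0.42 * min(h, w) * pixel_size_um
    if 2 * aperture_radius_um >= min(h, w) * pixel_size_um:
        raise ValueError(
            f"lens aperture (diameter {2 * aperture_radius_um:.1f} um) exceeds the "
            f"frame ({min(h, w) * pixel_size_um:.1f} um)"
        )
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2_um2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * pixel_size_um**2
    r2_clamped = np.minimum(r2_um2, aperture_radius_um**2)
    if edge_sigma_px > 0:
        r2_clamped = ndimage.gaussian_filter(r2_clamped, edge_sigma_px)
    # material thickness in metres (parabolic profile t = r^2 / R)
    thickness_m = r2_clamped * 1e-12 / (apex_radius_um * 1e-6)
    phase = -(2.0 * math.pi / wavelength_m) * delta * thickness_m
    transmission = np.exp(-absorption_mu_per_m * thickness_m)
    return SamplePhantom(
        phase=phase,
        transmission=transmission,
        darkfield=np.zeros(shape),
        pixel_size_um=pixel_size_um,
        meta={
            "kind": "parabolic_lens",
            "apex_radius_um": apex_radius_um,
            "delta": delta,
            "wavelength_m": wavelength_m,
            "aperture_radius_um": aperture_radius_um,
            "absorption_mu_per_m": absorption_mu_per_m,
        },
    )


def write_phantom(phantom: SamplePhantom, path: str | Path) -> None:
    """3-page float32 TIFF (phase, transmission, darkfield) + JSON sidecar."""
    import tifffile

    path = Path(path)
    pages = np.stack(
        [phantom.phase, phantom.transmission, phantom.darkfield]
    ).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pages": ["phase_rad", "transmission", "darkfield"],
        "pixel_size_um": phantom.pixel_size_um,
        "meta": phantom.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_phantom(path: str | Path) -> SamplePhantom:
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path).astype(np.float64)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SamplePhantom(
        phase=pages[0],
        transmission=pages[1],
        darkfield=pages[2],
        pixel_size_um=sidecar["pixel_size_um"],
        meta=sidecar.get("meta", {}),
    )
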