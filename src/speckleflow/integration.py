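"""Refraction-angle conversion and Frankot-Chellappa phase integration.

The two displacement maps are converted to refraction angles
(alpha = delta * p / d, small-angle) and then to per-pixel phase gradients
(g = (2 pi / lambda) * alpha * p), which are integrated into a single
scalar phase surface by the Fourier-domain least-squares projection of
Frankot and Chellappa.  The phase is defined up to an additive constant;
the zero-frequency component is set to zero so the output has exactly zero
mean.  Mirror (even) padding by one full image per side is the default
boundary treatment for non-periodic fields.
"""

from __future__ import annotations

import math

import numpy as np

from speckleflow.forward import DisplacementField
from speckleflow.optics import OpticsConfig

__all__ = ["displacement_to_refraction", "frankot_chellappa", "refraction_to_phase"]


def displacement_to_refraction(
    disp: DisplacementField, optics: OpticsConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Refraction angles (alpha_x, alpha_y) in radians from pixel displacements."""
    scale = optics.pixel_size_m / optics.distance_m
    return disp.dx * scale, disp.dy * scale


def _mirror_extend(gx: np.ndarray, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Even extension of the underlying surface: gx odd in x / even in y, gy vice versa."""
    gx_e = np.block([[gx, -gx[:, ::-1]], [gx[::-1, :], -gx[::-1, ::-1]]])
    gy_e = np.block([[gy, gy[:, ::-1]], [-gy[::-1, :], -gy[::-1, ::-1]]])
    return gx_e, gy_e


def frankot_chellappa(
    gx: np.ndarray, gy: np.ndarray, padding: str = "mirror",
    kernel: str = "central",
) -> np.ndarray:
    """Least-squares integrable surface from a two-component gradient field.

    ``gx``/``gy`` are phase gradients in rad/px along columns (x) and rows
    (y).  ``padding='mirror'`` (default) integrates the even extension and
    crops back, suppressing periodic-boundary artifacts; ``padding='none'``
    assumes the field is periodic.  ``kernel='central'`` (default) uses the
    transfer function of the central-difference operator, i sin(k), so that
    integration exactly inverts the gradient convention used elsewhere in
    the package; ``kernel='spectral'`` uses the classical continuous i k
    form.  The output mean is exactly zero.
    """
    if gx.shape != gy.shape:
        raise ValueError("gx/gy shapes differ")
    if padding not in ("mirror", "none"):
        raise ValueError("padding must be 'mirror' or 'none'")
    if kernel not in ("central", "spectral"):
        raise ValueError("kernel must be 'central' or 'spectral'")
    h, w = gx.shape
    if padding == "mirror":
        gx_w, gy_w = _mirror_extend(gx, gy)
    else:
        gx_w, gy_w = gx, gy
    hh, ww = gx_w.shape
    kx = 2.0 * math.pi * np.fft.fftfreq(ww)[None, :]
    ky = 2.0 * math.pi * np.fft.fftfreq(hh)[:, None]
    if kernel == "central":
        kx = np.sin(kx)
        ky = np.sin(ky)
    gx_f = np.fft.fft2(gx_w)
    gy_f = np.fft.fft2(gy_w)
    k2 = kx**2 + ky**2
    null = k2 < 1e-24  # DC and, for the central kernel, pure Nyquist modes
    k2[null] = 1.0
    phi_f = (-1j) * (kx * gx_f + ky * gy_f) / k2
    phi_f[null] = 0.0
    phi = np.fft.ifft2(phi_f).real
    phi = phi[:h, :w]
    return phi - phi.mean()


def refraction_to_phase(
    alpha_x: np.ndarray,
    alpha_y: np.ndarray,
    optics: OpticsConfig,
    padding: str = "mirror",
    kernel: str = "central",
) -> np.ndarray:
    """Integrated phase (rad, zero mean) from the two refraction-angle maps.

    Scales the angles to per-pixel phase gradients
    g = (2 pi / lambda) * alpha * p and applies :func:`frankot_chellappa`.
    """
    scale = 2.0 * math.pi / optics.wavelength_m * optics.pixel_size_m
    return frankot_chellappa(
        alpha_x * scale, alpha_y * scale, padding=padding, kernel=kernel
    )
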