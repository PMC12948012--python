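"""Beam/geometry configuration shared by every pipeline stage.

All unit conversions between wavelength, energy, detector pixels and
refraction angles go through :class:`OpticsConfig`; no other module is
allowed to own a lambda/d/p constant.  Coordinate convention (single
source of truth): images are indexed ``[row, col]`` = ``[y, x]`` with the
origin at the top-left; ``x`` increases rightward along columns and ``y``
downward along rows.  A positive pattern displacement ``(dx, dy)`` means
the modulation pattern seen *with* the sample samples the reference at
``(x + dx, y + dy)``.
"""

from __future__ import annotations

from dataclasses import dataclass

# hc in keV * m; lambda[m] = HC_KEV_M / E[keV]
HC_KEV_M = 1.2398e-9


@dataclass
class OpticsConfig:
    """Monochromatic beam, propagation distance and detector sampling.

    Parameters
    ----------
    energy_keV :
        Photon energy.  Mutually consistent with ``wavelength_m``; give
        either (or both, in which case they must agree to 1e-6 relative).
    wavelength_m :
        X-ray wavelength in metres.
    distance_m :
        Sample-to-detector propagation distance ``d`` in metres.
    pixel_size_um :
        Effective detector pixel size ``p`` in micrometres.
    photon_count :
        Expected photons per pixel for shot noise; ``None`` disables noise.
    """

    energy_keV: float | None = None
    wavelength_m: float | None = None
    distance_m: float = 0.5
    pixel_size_um: float = 0.65
    photon_count: float | None = None

    def __post_init__(self) -> None:
        if self.energy_keV is None and self.wavelength_m is None:
            raise ValueError("give energy_keV or wavelength_m")
        if self.energy_keV is None:
            self.energy_keV = HC_KEV_M / self.wavelength_m
        elif self.wavelength_m is None:
            self.wavelength_m = HC_KEV_M / self.energy_keV
        else:
            implied = HC_KEV_M / self.energy_keV
            if abs(implied - self.wavelength_m) > 1e-6 * implied:
                raise ValueError(
                    f"wavelength {self.wavelength_m} inconsistent with "
                    f"energy {self.energy_keV} keV (implies {implied})"
                )
        for name in ("energy_keV", "wavelength_m", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.distance_m < 0:
            raise ValueError("distance_m must be >= 0")
        if self.photon_count is not None and self.photon_count <= 0:
            raise ValueError("photon_count must be positive or None")

    @property
    def pixel_size_m(self) -> float:
        return self.pixel_size_um * 1e-6

    @property
    def displacement_per_gradient(self) -> float:
        """Pattern displacement in detector px per unit phase gradient (rad/px).

        delta[px] = d * alpha / p with alpha = (lambda / 2pi) * dphi/dx and
        the spatial derivative taken per metre, so for a per-pixel phase
        gradient g [rad/px]:  delta = d * lambda / (2 pi p^2) * g.
        """
        import math

        p = self.pixel_size_m
        return self.distance_m * self.wavelength_m / (2.0 * math.pi * p * p)

    def to_dict(self) -> dict:
        return {
            "energy_keV": self.energy_keV,
            "wavelength_m": self.wavelength_m,
            "distance_m": self.distance_m,
            "pixel_size_um": self.pixel_size_um,
            "photon_count": self.photon_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        return cls(**{k: d.get(k) for k in (
            "energy_keV", "wavelength_m", "distance_m", "pixel_size_um", "photon_count")})
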