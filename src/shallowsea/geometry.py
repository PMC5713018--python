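"""Sun/view geometry above and below the air-water interface.

Sub-surface direction cosines are obtained by Snell refraction with a
water refractive index of 1.34; refraction steepens rays, so the
sub-surface cosines are never smaller than their in-air counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from .errors import ValidationError

WATER_REFRACTIVE_INDEX = 1.34


@dataclass(frozen=True)
class Geometry:
    """Solar/view zenith angles (deg), relative azimuth (deg), Earth-Sun distance (AU)."""

    sun_zenith_deg: float = 30.0
    view_zenith_deg: float = 10.0
    rel_azimuth_deg: float = 90.0
    earth_sun_au: float = 1.0

    def __post_init__(self):
        if not (0 <= self.sun_zenith_deg < 90 and 0 <= self.view_zenith_deg < 90):
            raise ValidationError("zenith angles must lie in [0, 90) deg")
        if not (0.95 <= self.earth_sun_au <= 1.06):
            raise ValidationError("Earth-Sun distance must lie in [0.95, 1.06] AU")

    @property
    def mu_s(self) -> float:
        return math.cos(math.radians(self.sun_zenith_deg))

    @property
    def mu_v(self) -> float:
        return math.cos(math.radians(self.view_zenith_deg))

    @staticmethod
    def _subsurface_cos(theta_deg: float) -> float:
        sin_w = math.sin(math.radians(theta_deg)) / WATER_REFRACTIVE_INDEX
        return math.sqrt(1.0 - sin_w * sin_w)

    @property
    def mu_s_sw(self) -> float:
        """Sub-surface solar direction cosine (Snell-refracted)."""
        return self._subsurface_cos(self.sun_zenith_deg)

    @property
    def mu_v_sw(self) -> float:
        """Sub-surface view direction cosine (Snell-refracted)."""
        return self._subsurface_cos(self.view_zenith_deg)
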