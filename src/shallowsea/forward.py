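"""Shallow-water remote-sensing reflectance forward model.

The sub-surface spectrum mixes an optically-deep water term with a
bottom term attenuated along the two-way path (Beer–Lambert):

    rrs(λ) = rrs∞(λ) · (1 − e^{−(1/μs_sw + Duc/μv_sw)·kd·z})
           + (ρ_alb(λ)/π) · e^{−(1/μs_sw + Dub/μv_sw)·kd·z}

``Duc`` and ``Dub`` are upward diffusion factors for the water-column and
bottom streams.  The spectrum is optionally transferred through the
air–water interface (``Rrs = 0.5·rrs/(1 − 1.5·rrs)``) and reduced to the
sensor's optical bands by response-weighted integration — the quantity the
per-pixel inversion fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BandSet
from .benthos import EndmemberLibrary, mix_albedo
from .errors import ValidationError
from .geometry import Geometry
from .water import (WaterColumn, absorption, backscatter, deep_water_rrs,
                    diffuse_attenuation, gordon_u, default_tables,
                    LAMBDA0_ADG_NM, LAMBDA0_BBP_NM)

__all__ = ["PixelParams", "DiffusionFactors", "ForwardModel", "rrs_shallow",
           "diffusion_factors", "to_above_surface", "from_above_surface",
           "simulate_bands"]

# Default semi-analytical diffusion-factor constants (water column / bottom).
DUC_COEFFS = (1.03, 2.4)
DUB_COEFFS = (1.04, 5.4)


@dataclass(frozen=True)
class DiffusionFactors:
    Duc: np.ndarray
    Dub: np.ndarray


@dataclass
class PixelParams:
    """Everything the forward model needs for one pixel."""

    wc: WaterColumn
    z: float
    ab: np.ndarray
    geom: Geometry

    def __post_init__(self):
        if self.z < 0:
            raise ValidationError("depth must be non-negative")
        self.ab = np.asarray(self.ab, float)


def diffusion_factors(u: np.ndarray,
                      duc_coeffs=DUC_COEFFS, dub_coeffs=DUB_COEFFS) -> DiffusionFactors:
    """Upward diffusion factors Duc, Dub as functions of the Gordon parameter."""
    u = np.asarray(u, float)
    duc = duc_coeffs[0] * np.sqrt(1.0 + duc_coeffs[1] * u)
    dub = dub_coeffs[0] * np.sqrt(1.0 + dub_coeffs[1] * u)
    return DiffusionFactors(duc, dub)


def to_above_surface(rrs: np.ndarray) -> np.ndarray:
    """Sub-surface rrs → above-surface Rrs, ``0.5·rrs/(1 − 1.5·rrs)``."""
    rrs = np.asarray(rrs, float)
    if np.any(rrs >= 2.0 / 3.0):
        raise ValidationError("rrs >= 2/3 sr-1 is non-physical")
    return 0.5 * rrs / (1.0 - 1.5 * rrs)


def from_above_surface(Rrs: np.ndarray) -> np.ndarray:
    """Inverse interface transfer, ``rrs = Rrs/(0.5 + 1.5·Rrs)``."""
    Rrs = np.asarray(Rrs, float)
    return Rrs / (0.5 + 1.5 * Rrs)


def rrs_shallow(p: PixelParams, grid_nm: np.ndarray, lib: EndmemberLibrary,
                angle_mode: str = "divide") -> np.ndarray:
    """Sub-surface shallow-water rrs(λ) for a single pixel (sr⁻¹)."""
    albedo = mix_albedo(p.ab, lib.on_grid(np.asarray(grid_nm, float)))
    return rrs_shallow_albedo(p.wc, p.z, albedo, p.geom, grid_nm,
                              angle_mode=angle_mode)


def rrs_shallow_albedo(wc: WaterColumn, z, albedo: np.ndarray, geom: Geometry,
                       grid_nm: np.ndarray, angle_mode: str = "divide") -> np.ndarray:
    """Sub-surface rrs(λ) given an explicit bottom albedo spectrum."""
    a = absorption(wc, grid_nm)
    bb = backscatter(wc, grid_nm)
    u = gordon_u(a, bb)
    rrs_inf = deep_water_rrs(u, geom, angle_mode=angle_mode)
    kd = diffuse_attenuation(a, bb, geom)
    df = diffusion_factors(u)
    inv_mu_s = 1.0 / geom.mu_s_sw
    inv_mu_v = 1.0 / geom.mu_v_sw
    att_c = np.exp(-(inv_mu_s + df.Duc * inv_mu_v) * kd * z)
    att_b = np.exp(-(inv_mu_s + df.Dub * inv_mu_v) * kd * z)
    return rrs_inf * (1.0 - att_c) + (np.asarray(albedo, float) / np.pi) * att_b


class ForwardModel:
    """Precompiled forward operator for one scene geometry and band set.

    Precomputes the wavelength tables, endmember matrix and band response
    weights once, then evaluates band-integrated Rrs for arrays of pixel
    parameters — the hot path of both scene synthesis and inversion.
    """

    def __init__(self, bands: BandSet, lib: EndmemberLibrary, geom: Geometry,
                 grid_nm: np.ndarray | None = None, Sg: float = 0.015, Y: float = 1.0,
                 angle_mode: str = "divide", interface_transfer: bool = True,
                 tables=None):
        from .water import default_grid
        self.grid_nm = np.asarray(grid_nm if grid_nm is not None else default_grid(), float)
        self.bands = bands
        self.lib = lib.on_grid(self.grid_nm)
        self.geom = geom
        self.Sg = Sg
        self.Y = Y
        self.angle_mode = angle_mode
        self.interface_transfer = interface_transfer
        t = tables or default_tables()
        g = self.grid_nm
        self._aw = t.aw(g)
        self._bbw = t.bbw(g)
        self._a0 = t.a0(g)
        self._a1 = t.a1(g)
        self._adg_shape = np.exp(-Sg * (g - LAMBDA0_ADG_NM))
        self._bbp_shape = (LAMBDA0_BBP_NM / g) ** Y
        self._W = bands.response_matrix(g)          # (nbands, ngrid)
        self._E = self.lib.matrix                   # (ngrid, nem)
        if angle_mode == "divide":
            self._angle_factor = ((1.0 + 0.1098 / geom.mu_s_sw)
                                  * (1.0 + 0.4021 / geom.mu_v_sw))
        else:
            self._angle_factor = ((1.0 + 0.1098 * geom.mu_s_sw)
                                  * (1.0 + 0.4021 * geom.mu_v_sw))
        self._inv_mu_s = 1.0 / geom.mu_s_sw
        self._inv_mu_v = 1.0 / geom.mu_v_sw

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def rrs_spectrum(self, G, P, X, z, ab) -> np.ndarray:
        """Vectorised sub-surface rrs: scalar or (npix,) params → (..., ngrid)."""
        G = np.asarray(G, float)[..., None]
        P = np.asarray(P, float)[..., None]
        X = np.asarray(X, float)[..., None]
        z = np.asarray(z, float)[..., None]
        ab = np.asarray(ab, float)
        aph = np.where(P > 0, (self._a0 + self._a1 * np.log(np.where(P > 0, P, 1.0))) * P, 0.0)
        a = self._aw + aph + G * self._adg_shape
        bb = self._bbw + X * self._bbp_shape
        u = bb / (a + bb)
        rrs_inf = (0.0512 * u * (1.0 + 4.6659 * u - 7.8387 * u ** 2 + 5.4571 * u ** 3)
                   * self._angle_factor)
        kd = (a + bb) * self._inv_mu_s
        duc = DUC_COEFFS[0] * np.sqrt(1.0 + DUC_COEFFS[1] * u)
        dub = DUB_COEFFS[0] * np.sqrt(1.0 + DUB_COEFFS[1] * u)
        att_c = np.exp(-(self._inv_mu_s + duc * self._inv_mu_v) * kd * z)
        att_b = np.exp(-(self._inv_mu_s + dub * self._inv_mu_v) * kd * z)
        albedo = ab @ self._E.T
        return rrs_inf * (1.0 - att_c) + (albedo / np.pi) * att_b

    def simulate(self, G, P, X, z, ab) -> np.ndarray:
        """Band-integrated (above-surface, by default) Rrs: (..., nbands)."""
        rrs = self.rrs_spectrum(G, P, X, z, ab)
        if self.interface_transfer:
            rrs = to_above_surface(rrs)
        return rrs @ self._W.T

    def simulate_jac(self, G, P, X, z, f1, f2):
        """Band Rrs and its exact Jacobian wrt (G, P, X, z, f1, f2).

        Scalar parameters only; (f1, f2) are the stick-breaking simplex
        fractions.  Returns ``(bands (nb,), jac (nb, 6))``.  Used as the
        analytic derivative in the per-pixel fit; agreement with finite
        differences is covered by tests.
        """
        Pe = max(P, 1e-300)
        aph = (self._a0 + self._a1 * np.log(Pe)) * P
        a = self._aw + aph + G * self._adg_shape
        bb = self._bbw + X * self._bbp_shape
        s = a + bb
        u = bb / s
        du_da = -bb / s ** 2
        du_dbb = a / s ** 2
        k0 = 0.0512 * self._angle_factor
        rrs_inf = k0 * u * (1.0 + 4.6659 * u - 7.8387 * u ** 2 + 5.4571 * u ** 3)
        drinf_du = k0 * (1.0 + 2 * 4.6659 * u - 3 * 7.8387 * u ** 2
                         + 4 * 5.4571 * u ** 3)
        kd = s * self._inv_mu_s
        sq_c = np.sqrt(1.0 + DUC_COEFFS[1] * u)
        sq_b = np.sqrt(1.0 + DUB_COEFFS[1] * u)
        duc = DUC_COEFFS[0] * sq_c
        dub = DUB_COEFFS[0] * sq_b
        dduc_du = DUC_COEFFS[0] * DUC_COEFFS[1] * 0.5 / sq_c
        ddub_du = DUB_COEFFS[0] * DUB_COEFFS[1] * 0.5 / sq_b
        sig_c = self._inv_mu_s + duc * self._inv_mu_v
        sig_b = self._inv_mu_s + dub * self._inv_mu_v
        Ec = np.exp(-sig_c * kd * z)
        Eb = np.exp(-sig_b * kd * z)
        ab = np.array([f1, (1.0 - f1) * f2, (1.0 - f1) * (1.0 - f2)])
        albedo_pi = (self._E @ ab) / np.pi
        rrs = rrs_inf * (1.0 - Ec) + albedo_pi * Eb

        J = np.empty((6, self.grid_nm.size))
        da = (self._adg_shape,
              self._a0 + self._a1 * (np.log(Pe) + 1.0),
              0.0)
        dbb = (0.0, 0.0, self._bbp_shape)
        for i in range(3):
            du = du_da * da[i] + du_dbb * dbb[i]
            dkd = (da[i] + dbb[i]) * self._inv_mu_s
            dEc = -z * (sig_c * dkd + kd * self._inv_mu_v * dduc_du * du) * Ec
            dEb = -z * (sig_b * dkd + kd * self._inv_mu_v * ddub_du * du) * Eb
            J[i] = drinf_du * du * (1.0 - Ec) - rrs_inf * dEc + albedo_pi * dEb
        J[3] = rrs_inf * sig_c * kd * Ec - albedo_pi * sig_b * kd * Eb
        dab_f1 = np.array([1.0, -f2, -(1.0 - f2)])
        dab_f2 = np.array([0.0, 1.0 - f1, -(1.0 - f1)])
        J[4] = ((self._E @ dab_f1) / np.pi) * Eb
        J[5] = ((self._E @ dab_f2) / np.pi) * Eb

        if self.interface_transfer:
            denom = 1.0 - 1.5 * rrs
            J *= 0.5 / denom ** 2
            rrs = 0.5 * rrs / denom
        return rrs @ self._W.T, (J @ self._W.T).T


def simulate_bands(p: PixelParams, bands: BandSet, lib: EndmemberLibrary,
                   grid_nm: np.ndarray | None = None,
                   angle_mode: str = "divide",
                   interface_transfer: bool = True) -> np.ndarray:
    """Band-integrated Rrs for one pixel (convenience wrapper on ForwardModel)."""
    fm = ForwardModel(bands, lib, p.geom, grid_nm=grid_nm, Sg=p.wc.Sg, Y=p.wc.Y,
                      angle_mode=angle_mode, interface_transfer=interface_transfer,
                      tables=p.wc.tables)
    return fm.simulate(p.wc.G, p.wc.P, p.wc.X, p.z, p.ab)
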