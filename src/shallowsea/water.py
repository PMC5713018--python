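"""Inherent and apparent optical properties of the water column.

The water column is summarised by three retrievable scalars:

* ``G`` — coloured dissolved/detrital matter absorption at 440 nm (m⁻¹),
  decaying exponentially with wavelength at slope ``Sg``;
* ``P`` — phytoplankton absorption at 440 nm (m⁻¹), with the spectral
  shape ``aph(λ) = (a0(λ) + a1(λ) ln P) · P``;
* ``X`` — particulate backscatter at 400 nm (m⁻¹), with a power-law
  spectrum ``bbp(λ) = X · (400/λ)^Y``.

Pure-seawater absorption/backscatter and the phytoplankton shape
coefficients come from bundled tables, linearly interpolated onto the
working 5-nm grid.  Downstream, the Gordon parameter ``u = bb/(a+bb)``
drives the deep-water reflectance polynomial and ``kd = (a+bb)/μs_sw``
the diffuse attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .geometry import Geometry

__all__ = ["WaterColumn", "WaterTables", "absorption", "backscatter",
           "gordon_u", "deep_water_rrs", "diffuse_attenuation",
           "default_grid"]

LAMBDA0_ADG_NM = 440.0   # reference wavelength for dissolved-matter absorption
LAMBDA0_BBP_NM = 400.0   # reference wavelength for particulate backscatter


def default_grid(lo: float = 400.0, hi: float = 750.0) -> np.ndarray:
    """The working 5-nm wavelength grid (nm)."""
    return np.arange(lo, hi + 2.5, 5.0)


def _load_table(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("shallowsea.data") / name) as p:
        return pd.read_csv(p, sep="\t", comment="#")


class WaterTables:
    """Bundled pure-seawater and phytoplankton-shape coefficient tables."""

    def __init__(self, water_path=None, phyto_path=None):
        w = pd.read_csv(water_path, sep="\t", comment="#") if water_path \
            else _load_table("water_optics.tsv")
        p = pd.read_csv(phyto_path, sep="\t", comment="#") if phyto_path \
            else _load_table("phyto_shape.tsv")
        self._lam_w = w["lambda_nm"].to_numpy(float)
        self._aw = w["aw"].to_numpy(float)
        self._bbw = w["bbw"].to_numpy(float)
        self._lam_p = p["lambda_nm"].to_numpy(float)
        self._a0 = p["a0"].to_numpy(float)
        self._a1 = p["a1"].to_numpy(float)

    def _interp(self, grid, lam, val, what):
        grid = np.asarray(grid, float)
        if grid[0] < lam[0] - 1e-9 or grid[-1] > lam[-1] + 1e-9:
            raise CoverageError(
                f"{what} table covers [{lam[0]}, {lam[-1]}] nm, "
                f"requested [{grid[0]}, {grid[-1]}] nm")
        return np.interp(grid, lam, val)

    def aw(self, grid_nm):
        return self._interp(grid_nm, self._lam_w, self._aw, "pure-water absorption")

    def bbw(self, grid_nm):
        return self._interp(grid_nm, self._lam_w, self._bbw, "pure-water backscatter")

    def a0(self, grid_nm):
        return self._interp(grid_nm, self._lam_p, self._a0, "phytoplankton a0")

    def a1(self, grid_nm):
        return self._interp(grid_nm, self._lam_p, self._a1, "phytoplankton a1")


_DEFAULT_TABLES = None


def default_tables() -> WaterTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = WaterTables()
    return _DEFAULT_TABLES


@dataclass
class WaterColumn:
    """Retrievable water-column IOP magnitudes plus fixed spectral shapes."""

    G: float = 0.05       # dissolved-matter absorption at 440 nm, m-1
    P: float = 0.05       # phytoplankton absorption at 440 nm, m-1
    X: float = 0.01       # particulate backscatter at 400 nm, m-1
    Sg: float = 0.015     # dissolved-matter spectral slope, nm-1
    Y: float = 1.0        # particulate backscatter spectral exponent
    tables: WaterTables = field(default=None, repr=False)

    def __post_init__(self):
        if min(self.G, self.P, self.X) < 0:
            raise ValidationError("G, P, X must be non-negative")
        if not (0.01 <= self.Sg <= 0.03):
            raise ValidationError("Sg must lie in [0.01, 0.03] nm-1")
        if self.tables is None:
            self.tables = default_tables()


def absorption(wc: WaterColumn, grid_nm: np.ndarray) -> np.ndarray:
    """Total absorption a(λ) = aw + aph + adg (m⁻¹).

    ``P = 0`` short-circuits the phytoplankton term (the P·lnP → 0 limit).
    """
    grid_nm = np.asarray(grid_nm, float)
    aw = wc.tables.aw(grid_nm)
    if wc.P > 0:
        aph = (wc.tables.a0(grid_nm) + wc.tables.a1(grid_nm) * np.log(wc.P)) * wc.P
    else:
        aph = np.zeros_like(grid_nm)
    adg = wc.G * np.exp(-wc.Sg * (grid_nm - LAMBDA0_ADG_NM))
    a = aw + aph + adg
    if a.min() <= 0:
        i = int(np.argmin(a))
        raise ValidationError(
            f"non-positive absorption at {grid_nm[i]:.0f} nm (P={wc.P})")
    return a


def backscatter(wc: WaterColumn, grid_nm: np.ndarray) -> np.ndarray:
    """Total backscatter bb(λ) = bbw + X·(400/λ)^Y (m⁻¹)."""
    grid_nm = np.asarray(grid_nm, float)
    return wc.tables.bbw(grid_nm) + wc.X * (LAMBDA0_BBP_NM / grid_nm) ** wc.Y


def gordon_u(a: np.ndarray, bb: np.ndarray) -> np.ndarray:
    """Gordon parameter u = bb/(a+bb) ∈ [0, 1)."""
    a = np.asarray(a, float)
    bb = np.asarray(bb, float)
    denom = a + bb
    if np.any(denom <= 0):
        raise ValidationError("a + bb must be positive")
    return bb / denom


def deep_water_rrs(u: np.ndarray, geom: Geometry,
                   angle_mode: str = "divide") -> np.ndarray:
    """Optically-deep sub-surface remote-sensing reflectance rrs∞(u) (sr⁻¹).

    The base polynomial ``0.0512·u·(1 + 4.6659u − 7.8387u² + 5.4571u³)`` is
    scaled by sun/view factors.  ``angle_mode`` selects whether the 0.1098 and
    0.4021 coefficients divide (default, physically increasing toward grazing
    geometry) or multiply the sub-surface cosines.
    """
    u = np.asarray(u, float)
    poly = 0.0512 * u * (1.0 + 4.6659 * u - 7.8387 * u ** 2 + 5.4571 * u ** 3)
    if angle_mode == "divide":
        fs = 1.0 + 0.1098 / geom.mu_s_sw
        fv = 1.0 + 0.4021 / geom.mu_v_sw
    elif angle_mode == "multiply":
        fs = 1.0 + 0.1098 * geom.mu_s_sw
        fv = 1.0 + 0.4021 * geom.mu_v_sw
    else:
        raise ValidationError(f"unknown angle_mode {angle_mode!r}")
    return poly * fs * fv


def diffuse_attenuation(a: np.ndarray, bb: np.ndarray, geom: Geometry) -> np.ndarray:
    """Diffuse attenuation kd = (a + bb)/μs_sw (m⁻¹)."""
    if geom.mu_s_sw <= 0:
        raise ValidationError("sub-surface solar cosine must be positive")
    return (np.asarray(a, float) + np.asarray(bb, float)) / geom.mu_s_sw
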