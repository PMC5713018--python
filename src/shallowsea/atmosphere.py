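"""Algebraic surface-reflectance correctors and match-up evaluation.

Three correction forms are provided, each driven by externally supplied
per-band coefficients (typically produced offline by an atmospheric
radiative-transfer code, which is not part of this package):

* a generic Lambertian corrector: path radiance, two-way transmissivities,
  solar and diffuse irradiance;
* a FLAASH-shaped model ``L_TOA = A·ρ/(1−ρe·S) + B·ρe/(1−ρe·S) + Lo``
  with spherical-albedo coupling to the neighbourhood mean reflectance ρe;
* an ATCOR-shaped two-step model (Lambertian inversion, then an optional
  adjacency adjustment);
* a 6S-shaped TOA-reflectance equation separating gas transmissivity,
  atmospheric reflectivity, direct/diffuse transmittance and the
  surface–atmosphere multiple-scattering term.

Each inverter is the exact algebraic inverse of the corresponding forward
form.  Match-up quality against field spectra is summarised by RMSE and
BIAS over 3×3 pixel windows; a negative BIAS means the correction
overestimates the field measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .errors import ConfigurationError, ValidationError
from .geometry import Geometry

__all__ = ["AtmosTerms", "MatchUp", "correct_generic", "flaash_forward",
           "invert_flaash", "atcor_forward", "invert_atcor", "toa_6s",
           "invert_6s", "spatial_mean_reflectance", "rmse_bias",
           "load_coefficient_table"]

log = logging.getLogger(__name__)


def _col(x, ndim_extra):
    """Reshape a per-band vector for broadcasting over raster axes."""
    x = np.atleast_1d(np.asarray(x, float))
    return x.reshape(x.shape + (1,) * ndim_extra)


@dataclass
class AtmosTerms:
    """Per-band atmospheric coefficients for the three correction forms."""

    # generic Lambertian set
    La: np.ndarray = None        # path radiance
    tau_v: np.ndarray = None     # upward transmissivity, (0, 1]
    tau_s: np.ndarray = None     # downward transmissivity, (0, 1]
    E0: np.ndarray = None        # exo-atmospheric solar irradiance, > 0
    Ed: np.ndarray = None        # diffuse irradiance at the surface, >= 0
    # FLAASH-form set
    A: np.ndarray = None
    B: np.ndarray = None
    S: np.ndarray = None         # spherical albedo, [0, 1)
    Lo: np.ndarray = None
    # ATCOR-form set
    a0: np.ndarray = None
    a1: np.ndarray = None
    E_toa: np.ndarray = None
    # 6S-form set
    tg: np.ndarray = None        # gas transmissivity, (0, 1]
    rho_a: np.ndarray = None     # atmospheric reflectivity
    tau: np.ndarray = None       # aerosol optical depth, >= 0
    td_s: np.ndarray = None      # diffuse transmittance, sun path
    td_v: np.ndarray = None      # diffuse transmittance, view path
    S6: np.ndarray = None        # spherical albedo for the 6S form

    def __post_init__(self):
        for name in ("tau_v", "tau_s", "tg"):
            v = getattr(self, name)
            if v is not None and (np.min(v) <= 0 or np.max(v) > 1):
                raise ValidationError(f"{name} must lie in (0, 1]")
        for name in ("S", "S6"):
            v = getattr(self, name)
            if v is not None and (np.min(v) < 0 or np.max(v) >= 1):
                raise ValidationError(f"{name} must lie in [0, 1)")
        if self.tau is not None and np.min(self.tau) < 0:
            raise ValidationError("tau must be non-negative")
        for name in ("E0", "E_toa"):
            v = getattr(self, name)
            if v is not None and np.min(v) <= 0:
                raise ValidationError(f"{name} must be positive")


def load_coefficient_table(path, model: str, bands: list[str]) -> AtmosTerms:
    """Read a (model, band, symbol, value) columnar table into AtmosTerms."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    need = {"model", "band", "symbol", "value"}
    if not need <= set(df.columns):
        raise ConfigurationError(f"coefficient table needs columns {sorted(need)}")
    sub = df[df["model"] == model]
    kwargs = {}
    for symbol, grp in sub.groupby("symbol"):
        by_band = dict(zip(grp["band"], grp["value"]))
        try:
            kwargs[symbol] = np.array([by_band[b] for b in bands], float)
        except KeyError as e:
            raise ConfigurationError(
                f"model {model!r}, symbol {symbol!r}: missing band {e}")
    return AtmosTerms(**kwargs)


@dataclass
class MatchUp:
    """One field-spectrum match-up site on the image grid."""

    site: str
    row: int
    col: int
    in_situ: np.ndarray          # per-band surface reflectance
    half_window: int = 1         # 1 → 3×3 window

    def __post_init__(self):
        self.in_situ = np.asarray(self.in_situ, float)


def _report_out_of_range(rho: np.ndarray, what: str,
                         lo: float = -0.05, hi: float = 1.2):
    bad = np.count_nonzero((rho < lo) | (rho > hi))
    if bad:
        log.warning("%s: %d pixels outside [%g, %g] (not clipped)", what, bad, lo, hi)


def correct_generic(L: np.ndarray, terms: AtmosTerms, geom: Geometry) -> np.ndarray:
    """Radiance → Lambertian surface reflectance.

    ``ρ = (L − La)·d_ES²·π / (τv·(E0·cosθs·τs + Ed))``
    """
    for name in ("La", "tau_v", "tau_s", "E0", "Ed"):
        if getattr(terms, name) is None:
            raise ConfigurationError(f"generic correction needs term {name!r}")
    L = np.asarray(L, float)
    k = L.ndim - 1
    denom = _col(terms.tau_v, k) * (
        _col(terms.E0, k) * geom.mu_s * _col(terms.tau_s, k) + _col(terms.Ed, k))
    if np.any(denom == 0):
        raise ValidationError("zero denominator in generic correction")
    rho = (L - _col(terms.La, k)) * geom.earth_sun_au ** 2 * np.pi / denom
    _report_out_of_range(rho, "correct_generic")
    return rho


def generic_forward(rho: np.ndarray, terms: AtmosTerms, geom: Geometry) -> np.ndarray:
    """Forward form of the generic corrector (for round-trip testing)."""
    rho = np.asarray(rho, float)
    k = rho.ndim - 1
    denom = _col(terms.tau_v, k) * (
        _col(terms.E0, k) * geom.mu_s * _col(terms.tau_s, k) + _col(terms.Ed, k))
    return rho * denom / (np.pi * geom.earth_sun_au ** 2) + _col(terms.La, k)


def flaash_forward(rho_su: np.ndarray, rho_e: np.ndarray, terms: AtmosTerms) -> np.ndarray:
    """FLAASH-shaped TOA radiance from surface and neighbourhood reflectance."""
    rho_su = np.asarray(rho_su, float)
    k = rho_su.ndim - 1
    coupling = 1.0 - np.asarray(rho_e, float) * _col(terms.S, k)
    return (_col(terms.A, k) * rho_su + _col(terms.B, k) * np.asarray(rho_e, float)) \
        / coupling + _col(terms.Lo, k)


def invert_flaash(L_toa: np.ndarray, terms: AtmosTerms, rho_e: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`flaash_forward` for the surface reflectance."""
    if np.any(np.asarray(terms.A) <= 0):
        raise ValidationError("FLAASH gain A must be positive")
    L_toa = np.asarray(L_toa, float)
    rho_e = np.asarray(rho_e, float)
    k = L_toa.ndim - 1
    coupling = 1.0 - rho_e * _col(terms.S, k)
    if np.any(coupling <= 0):
        raise ValidationError("1 - rho_e*S must stay positive")
    rho = ((L_toa - _col(terms.Lo, k)) * coupling
           - _col(terms.B, k) * rho_e) / _col(terms.A, k)
    _report_out_of_range(rho, "invert_flaash")
    return rho


def atcor_forward(rho_su: np.ndarray, terms: AtmosTerms, geom: Geometry) -> np.ndarray:
    """ATCOR-shaped Lambertian TOA radiance (step-1 forward form)."""
    rho_su = np.asarray(rho_su, float)
    k = rho_su.ndim - 1
    return (_col(terms.a1, k) * rho_su + _col(terms.a0, k)) \
        * _col(terms.E_toa, k) * geom.mu_s / (np.pi * geom.earth_sun_au ** 2)


def invert_atcor(L_toa: np.ndarray, terms: AtmosTerms, geom: Geometry,
                 rho_e: np.ndarray | None = None, q: float = 0.0) -> np.ndarray:
    """ATCOR-shaped two-step inversion.

    Step 1 (Lambertian): ``ρ = (d²·π·L_TOA/(E_TOA·cosθs) − a0)/a1``.
    Step 2 (adjacency): ``ρ ← ρ + q·(ρ − ρe)`` with configurable strength
    ``q`` (default 0, i.e. off).
    """
    if np.any(np.asarray(terms.a1) == 0):
        raise ValidationError("ATCOR gain a1 must be non-zero")
    L_toa = np.asarray(L_toa, float)
    k = L_toa.ndim - 1
    rho = (geom.earth_sun_au ** 2 * np.pi * L_toa
           / (_col(terms.E_toa, k) * geom.mu_s) - _col(terms.a0, k)) / _col(terms.a1, k)
    if q != 0.0:
        if rho_e is None:
            raise ConfigurationError("adjacency step needs rho_e")
        rho = rho + q * (rho - np.asarray(rho_e, float))
    _report_out_of_range(rho, "invert_atcor")
    return rho


def toa_6s(rho_su: np.ndarray, rho_e: np.ndarray, terms: AtmosTerms,
           geom: Geometry) -> np.ndarray:
    """6S-shaped TOA reflectance.

    ``ρ_TOA = tg·{ρa + [e^{−τ/μs} + td(θs)]·[ρ_su·e^{−τ/μv} + ρe·td(θv)]/(1 − ρe·S)}``
    """
    rho_su = np.asarray(rho_su, float)
    rho_e = np.asarray(rho_e, float)
    k = rho_su.ndim - 1
    coupling = 1.0 - rho_e * _col(terms.S6, k)
    if np.any(coupling <= 0):
        raise ValidationError("1 - rho_e*S must stay positive")
    down = np.exp(-_col(terms.tau, k) / geom.mu_s) + _col(terms.td_s, k)
    inner = (rho_su * np.exp(-_col(terms.tau, k) / geom.mu_v)
             + rho_e * _col(terms.td_v, k)) / coupling
    return _col(terms.tg, k) * (_col(terms.rho_a, k) + down * inner)


def invert_6s(rho_toa: np.ndarray, rho_e: np.ndarray, terms: AtmosTerms,
              geom: Geometry) -> np.ndarray:
    """Exact algebraic inverse of :func:`toa_6s` for the surface reflectance."""
    if np.any(np.asarray(terms.tg) <= 0):
        raise ValidationError("gas transmissivity tg must be positive")
    rho_toa = np.asarray(rho_toa, float)
    rho_e = np.asarray(rho_e, float)
    k = rho_toa.ndim - 1
    coupling = 1.0 - rho_e * _col(terms.S6, k)
    down = np.exp(-_col(terms.tau, k) / geom.mu_s) + _col(terms.td_s, k)
    inner = (rho_toa / _col(terms.tg, k) - _col(terms.rho_a, k)) / down
    rho = (inner * coupling - rho_e * _col(terms.td_v, k)) \
        / np.exp(-_col(terms.tau, k) / geom.mu_v)
    _report_out_of_range(rho, "invert_6s")
    return rho


def spatial_mean_reflectance(raster: np.ndarray, radius: int = 10) -> np.ndarray:
    """Neighbourhood-mean reflectance ρe: box mean with edge replication.

    ``radius`` counts pixels each side of the centre; 0 is the identity.
    Works per band on (nbands, ny, nx) or on a single (ny, nx) plane.
    """
    if radius < 0:
        raise ValidationError("radius must be non-negative")
    raster = np.asarray(raster, float)
    if radius == 0:
        return raster.copy()
    size = 2 * radius + 1
    if raster.ndim == 2:
        return uniform_filter(raster, size=size, mode="nearest")
    return np.stack([uniform_filter(b, size=size, mode="nearest") for b in raster])


def window_mean(raster: np.ndarray, row: int, col: int, half: int = 1) -> np.ndarray:
    """Per-band mean over a (2·half+1)² window, which must fit the raster."""
    ny, nx = raster.shape[-2:]
    if not (half <= row < ny - half and half <= col < nx - half):
        raise ValidationError(f"window at ({row},{col}) not fully inside raster")
    return raster[..., row - half:row + half + 1, col - half:col + half + 1].mean(axis=(-2, -1))


def rmse_bias(matchups: list[MatchUp], corrected: np.ndarray) -> tuple[float, float]:
    """Match-up RMSE and BIAS pooled over sites and bands.

    The satellite value per site is the mean over its window; differences
    are ``ρ_in-situ − ρ_sat``, so a negative BIAS flags overestimation by
    the correction.
    """
    if not matchups:
        raise ValidationError("empty match-up set")
    diffs = []
    for m in matchups:
        sat = window_mean(corrected, m.row, m.col, m.half_window)
        diffs.append(m.in_situ - sat)
    d = np.concatenate([np.atleast_1d(x) for x in diffs])
    return float(np.sqrt(np.mean(d ** 2))), float(np.mean(d))
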