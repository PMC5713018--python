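"""Sensor band bookkeeping, radiometric calibration and spectral integration.

A :class:`BandSet` carries, for each multispectral band, the calibration
factor ``K`` (radiance per count per µm), the effective bandwidth ``Δλ``
(µm) and a peak-normalised spectral response curve sampled on a 5-nm
wavelength grid.  Digital counts are converted to band radiance as
``L = K · q / Δλ``, and fine-grid spectra are reduced to band values by a
response-weighted mean over the 5-nm grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError, ValidationError

__all__ = ["Band", "BandSet", "Spectrum", "calibrate_radiance", "band_integrate",
           "resample_field_spectrum", "default_bandset"]

GRID_STEP_NM = 5.0


@dataclass(frozen=True)
class Band:
    """One sensor band: nominal interval, calibration and response curve."""

    name: str
    center_nm: float
    min_nm: float
    max_nm: float
    K: float                      # radiance units per count per µm
    delta_lambda_um: float        # effective bandwidth, µm
    response_nm: np.ndarray = field(repr=False, default=None)
    response: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.K <= 0 or self.delta_lambda_um <= 0:
            raise ValidationError(
                f"band {self.name!r}: K and delta_lambda must be positive")
        if self.response_nm is None:
            nm = np.arange(self.min_nm, self.max_nm + GRID_STEP_NM / 2, GRID_STEP_NM)
            object.__setattr__(self, "response_nm", nm)
            object.__setattr__(self, "response", np.ones_like(nm))
        r = np.asarray(self.response, float)
        nm = np.asarray(self.response_nm, float)
        if np.any(np.diff(nm) <= 0):
            raise ValidationError(f"band {self.name!r}: response grid not increasing")
        if r.min() < 0 or r.max() > 1 or r.max() <= 0:
            raise ValidationError(
                f"band {self.name!r}: response must be in [0,1] with a positive peak")


class BandSet:
    """Ordered collection of bands (coastal-blue .. NIR2)."""

    def __init__(self, bands: list[Band]):
        if not bands:
            raise ValidationError("empty band set")
        self.bands = list(bands)

    def __len__(self):
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, key):
        if isinstance(key, str):
            for b in self.bands:
                if b.name == key:
                    return b
            raise KeyError(key)
        return self.bands[key]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def subset(self, n_or_names) -> "BandSet":
        """First ``n`` bands, or the named bands, as a new BandSet."""
        if isinstance(n_or_names, int):
            return BandSet(self.bands[: n_or_names])
        return BandSet([self[n] for n in n_or_names])

    @property
    def K(self) -> np.ndarray:
        return np.array([b.K for b in self.bands])

    @property
    def delta_lambda_um(self) -> np.ndarray:
        return np.array([b.delta_lambda_um for b in self.bands])

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([b.center_nm for b in self.bands])

    @classmethod
    def from_table(cls, path) -> "BandSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"band", "center_nm", "min_nm", "max_nm", "K", "delta_lambda_um"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"band table missing columns: {sorted(missing)}")
        return cls([
            Band(r.band, r.center_nm, r.min_nm, r.max_nm, r.K, r.delta_lambda_um)
            for r in df.itertuples()
        ])

    def response_matrix(self, grid_nm: np.ndarray) -> np.ndarray:
        """(nbands, ngrid) matrix of normalised response weights on ``grid_nm``.

        Row ``i`` dotted with a spectrum gives the band-``i`` response-weighted
        mean.  Raises :class:`CoverageError` if a band's support falls outside
        the grid.
        """
        grid_nm = np.asarray(grid_nm, float)
        W = np.zeros((len(self.bands), grid_nm.size))
        for i, b in enumerate(self.bands):
            if b.response_nm[0] < grid_nm[0] - 1e-9 or b.response_nm[-1] > grid_nm[-1] + 1e-9:
                raise CoverageError(
                    f"band {b.name!r} support [{b.response_nm[0]}, {b.response_nm[-1]}] nm "
                    f"outside spectrum grid [{grid_nm[0]}, {grid_nm[-1]}] nm")
            r = np.interp(grid_nm, b.response_nm, b.response, left=0.0, right=0.0)
            W[i] = r / r.sum()
        return W


@dataclass
class Spectrum:
    """A wavelength-indexed quantity (reflectance or Rrs), with a unit tag."""

    wavelength_nm: np.ndarray
    values: np.ndarray
    unit: str = "reflectance"   # "reflectance" (dimensionless) or "rrs" (sr-1)

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("spectrum grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectrum contains non-finite values")
        if self.unit == "reflectance" and (
                self.values.min() < -1e-9 or self.values.max() > 1.5):
            raise ValidationError("reflectance outside [0, 1.5]")


def default_bandset() -> BandSet:
    """The bundled WV-2-like 8-band set with boxcar responses."""
    with resources.as_file(resources.files("shallowsea.data") / "wv2_bands.tsv") as p:
        return BandSet.from_table(p)


def calibrate_radiance(counts: np.ndarray, bands: BandSet) -> np.ndarray:
    """Counts → band radiance, ``L = K · q / Δλ`` (per-µm radiance units).

    ``counts`` is (nbands, ny, nx) or (nbands, npix); geometry is preserved.
    """
    counts = np.asarray(counts)
    if counts.shape[0] != len(bands):
        raise ConfigurationError(
            f"raster has {counts.shape[0]} bands, band set has {len(bands)}")
    if counts.min() < 0:
        raise ValidationError("negative counts")
    shape = (len(bands),) + (1,) * (counts.ndim - 1)
    K = bands.K.reshape(shape)
    dl = bands.delta_lambda_um.reshape(shape)
    return K * counts.astype(np.float64) / dl


def band_integrate(spec: Spectrum | np.ndarray, bands: BandSet,
                   grid_nm: np.ndarray | None = None) -> np.ndarray:
    """Response-weighted mean of a spectrum over each band's 5-nm response.

    Accepts a :class:`Spectrum` or a bare array with ``grid_nm`` supplied;
    bare arrays may carry extra leading axes (…, ngrid) for vectorised use.
    """
    if isinstance(spec, Spectrum):
        grid_nm, values = spec.wavelength_nm, spec.values
    else:
        if grid_nm is None:
            raise ConfigurationError("grid_nm required with a bare array")
        values = np.asarray(spec, float)
    W = bands.response_matrix(np.asarray(grid_nm, float))
    return values @ W.T


def resample_field_spectrum(fine: Spectrum, bands: BandSet) -> np.ndarray:
    """Band values of a 1-nm field-spectroradiometer spectrum.

    The fine spectrum is block-averaged onto the sensor's 5-nm grid first
    (each 5-nm node takes the mean of the 1-nm samples within ±2.5 nm), then
    handed to :func:`band_integrate`.
    """
    lam = fine.wavelength_nm
    step = np.median(np.diff(lam))
    if abs(step - 1.0) > 1e-6:
        raise ValidationError(f"field spectrum must be on a 1-nm grid, got {step} nm")
    lo = np.ceil(lam[0] / GRID_STEP_NM) * GRID_STEP_NM
    hi = np.floor(lam[-1] / GRID_STEP_NM) * GRID_STEP_NM
    nodes = np.arange(lo, hi + GRID_STEP_NM / 2, GRID_STEP_NM)
    vals = np.empty_like(nodes)
    for i, c in enumerate(nodes):
        sel = (lam >= c - GRID_STEP_NM / 2) & (lam < c + GRID_STEP_NM / 2)
        vals[i] = fine.values[sel].mean()
    return band_integrate(Spectrum(nodes, vals, unit=fine.unit), bands)
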