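"""Sunglint removal using the NIR excess over a glint-free baseline.

Specular reflection on wave facets adds a spectrally flat-ish offset to
every band, fully visible in the NIR where the water-leaving signal is
small but — in shallow or turbid coastal water — not strictly zero.  The
correction therefore measures the NIR *excess* over an ambient baseline
informed by the water's radiative-transfer model (or, failing that, a low
percentile of the observed NIR), regresses each visible band against the
NIR over a glint-spanning sample region, and subtracts the per-band
scaled excess:

    band' = band − b_band · (NIR − baseline).

Applying the correction twice is a no-op to numerical precision, because
the first pass removes the NIR excess itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["GlintModel", "estimate_ambient_nir", "fit_glint_slopes", "apply_deglint"]

log = logging.getLogger(__name__)


@dataclass
class GlintModel:
    """Per-visible-band regression slopes against the NIR, plus the baseline."""

    slopes: np.ndarray           # one slope per visible band
    baseline: float              # ambient (glint-free) NIR reflectance
    nir_index: int               # index of the NIR band used
    n_samples: int = 0

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, float)
        if not np.all(np.isfinite(self.slopes)):
            raise ValidationError("non-finite glint slopes")
        if self.baseline < 0:
            raise ValidationError("NIR baseline must be non-negative")


def _polygon_mask(shape, polygon) -> np.ndarray:
    """Boolean mask from a (row0, row1, col0, col1) box or an existing mask."""
    if polygon is None:
        return np.ones(shape, bool)
    polygon = np.asarray(polygon)
    if polygon.dtype == bool:
        if polygon.shape != shape:
            raise ValidationError("polygon mask geometry mismatch")
        return polygon
    r0, r1, c0, c1 = (int(v) for v in polygon)
    m = np.zeros(shape, bool)
    m[r0:r1, c0:c1] = True
    return m


def estimate_ambient_nir(cube: np.ndarray, nir_index: int = 6,
                         polygon=None, percentile: float = 2.0,
                         modeled_nir: float | None = None) -> float:
    """Glint-free ambient NIR level.

    The baseline is the larger of the forward-modelled NIR water-leaving
    reflectance (when a water model is available) and a low percentile of
    the observed NIR over the sample region — so it never dips below what
    the water itself must contribute, and never goes negative.
    """
    mask = _polygon_mask(cube.shape[-2:], polygon)
    if not mask.any():
        raise ValidationError("empty glint-fit polygon")
    observed = float(np.percentile(cube[nir_index][mask], percentile))
    baseline = max(observed, modeled_nir or 0.0, 0.0)
    return baseline


def fit_glint_slopes(cube: np.ndarray, polygon=None, nir_index: int = 6,
                     visible: slice | list | None = None,
                     baseline: float | None = None,
                     percentile: float = 2.0,
                     modeled_nir: float | None = None,
                     min_pixels: int = 100) -> GlintModel:
    """Ordinary least-squares slope of each visible band against the NIR."""
    mask = _polygon_mask(cube.shape[-2:], polygon)
    if mask.sum() < min_pixels:
        raise ValidationError(
            f"glint polygon covers {int(mask.sum())} pixels, need >= {min_pixels}")
    vis = visible if visible is not None else list(range(min(6, cube.shape[0])))
    nir = cube[nir_index][mask]
    if np.var(nir) == 0:
        raise ValidationError("no glint signal: NIR variance is zero over polygon")
    nc = nir - nir.mean()
    denom = np.sum(nc * nc)
    slopes = np.array([np.sum((cube[b][mask] - cube[b][mask].mean()) * nc) / denom
                       for b in vis])
    if baseline is None:
        baseline = estimate_ambient_nir(cube, nir_index, polygon,
                                        percentile, modeled_nir)
    return GlintModel(slopes=slopes, baseline=baseline, nir_index=nir_index,
                      n_samples=int(mask.sum()))


def apply_deglint(cube: np.ndarray, gm: GlintModel,
                  visible: list | None = None,
                  keep_nir: bool = False) -> np.ndarray:
    """Subtract the per-band scaled NIR excess; floor at zero.

    The NIR band itself is replaced by the ambient baseline unless
    ``keep_nir`` is set.  Negative post-correction values are floored at
    zero and counted in the log.
    """
    cube = np.asarray(cube, float)
    vis = visible if visible is not None else list(range(len(gm.slopes)))
    if len(vis) != len(gm.slopes):
        raise ValidationError("glint model fitted on a different band set")
    excess = cube[gm.nir_index] - gm.baseline
    out = cube.copy()
    for slope, b in zip(gm.slopes, vis):
        out[b] = cube[b] - slope * excess
    negatives = int(np.count_nonzero(out[vis] < 0))
    if negatives:
        log.info("deglint floored %d negative values at 0", negatives)
        out[vis] = np.maximum(out[vis], 0.0)
    if not keep_nir:
        out[gm.nir_index] = gm.baseline
    return out
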