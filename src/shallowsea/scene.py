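"""Synthetic coastal scenes with full ground truth.

A scene emulates a 6–8-band high-resolution sensor over shallow seafloor:
a depth field (constant, shore-to-sea gradient, or smoothed random), water
IOP fields, a benthic cover that is either per-pixel random simplex
abundances or a Voronoi patch mosaic of named cover classes, optional
sunglint streaks, and multiplicative/additive noise.  The observation
cube is produced by exactly the same forward operator the inversion fits,
so recovery experiments measure the inversion, not a model mismatch.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .atmosphere import MatchUp
from .bands import BandSet, default_bandset
from .benthos import EndmemberLibrary, default_library
from .errors import ValidationError
from .forward import ForwardModel
from .geometry import Geometry

__all__ = ["CoverClass", "SceneConfig", "SceneTruth", "generate",
           "generate_matchups", "four_class_mosaic_config"]

NIR1_INDEX = 6
FULL_GRID_LO, FULL_GRID_HI = 400.0, 1050.0


@dataclass(frozen=True)
class CoverClass:
    """One benthic cover class: mean abundances, jitter, depth stratum."""

    name: str
    ab_mean: tuple
    ab_jitter: float = 0.05
    depth_range: tuple = (1.0, 10.0)


@dataclass
class SceneConfig:
    """Full specification of a synthetic scene."""

    shape: tuple = (64, 64)
    seed: int = 0
    # depth field: "constant" | "gradient" | "random", over depth_range (m)
    depth_kind: str = "gradient"
    depth_range: tuple = (0.5, 15.0)
    # IOP fields: "constant" pins each at the range midpoint; "random" draws
    # smoothed fields within the ranges (m-1)
    iop_kind: str = "random"
    g_range: tuple = (0.01, 0.3)
    p_range: tuple = (0.005, 0.2)
    x_range: tuple = (0.001, 0.05)
    # benthic cover: "random" per-pixel simplex, or "mosaic" of CoverClass patches
    cover_kind: str = "random"
    classes: tuple = ()
    patch_size: float = 12.0       # mean Voronoi patch diameter, pixels
    border_mix: float = 0.0        # abundance smoothing across patch borders (px)
    # glint streaks (in observation-reflectance units at the NIR reference band)
    glint_amplitude: float = 0.0
    glint_direction_deg: float = 30.0
    glint_period_px: float = 9.0
    glint_band_slopes: tuple = (1.02, 1.0, 0.97, 0.95, 0.93, 0.9, 1.0, 0.98)
    # noise
    noise_multiplicative: float = 0.0
    noise_additive: float = 0.0
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self):
        if self.depth_range[0] < 0 or self.depth_range[1] > 33.0:
            raise ValidationError("depth range outside inversion bounds [0, 33] m")
        for rng in (self.g_range, self.p_range, self.x_range):
            if rng[0] < 0 or rng[1] > 5.0:
                raise ValidationError("IOP range outside inversion bounds [0, 5] m-1")
        if self.cover_kind == "mosaic" and not self.classes:
            raise ValidationError("mosaic cover needs cover classes")


@dataclass
class SceneTruth:
    """Ground-truth rasters plus the observation cube derived from them."""

    config: SceneConfig
    bands: BandSet
    lib: EndmemberLibrary
    grid_nm: np.ndarray
    z: np.ndarray                 # (ny, nx) depth, m
    G: np.ndarray
    P: np.ndarray
    X: np.ndarray
    abundance: np.ndarray         # (n_endmembers, ny, nx)
    class_map: np.ndarray | None  # (ny, nx) int, mosaic scenes only
    rrs_bands: np.ndarray         # (nbands, ny, nx) glint- and noise-free Rrs
    glint: np.ndarray             # (ny, nx) NIR-referenced glint field
    observed: np.ndarray          # (nbands, ny, nx) final cube


def _smooth_field(rng, shape, lo, hi, sigma=6.0):
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


def _depth_field(cfg: SceneConfig, rng) -> np.ndarray:
    ny, nx = cfg.shape
    lo, hi = cfg.depth_range
    if cfg.depth_kind == "constant":
        return np.full(cfg.shape, 0.5 * (lo + hi))
    if cfg.depth_kind == "gradient":
        ramp = np.linspace(lo, hi, nx)
        wobble = _smooth_field(rng, cfg.shape, -0.03, 0.03) * (hi - lo)
        return np.clip(ramp[None, :] + wobble, lo, hi)
    if cfg.depth_kind == "random":
        return _smooth_field(rng, cfg.shape, lo, hi)
    raise ValidationError(f"unknown depth_kind {cfg.depth_kind!r}")


def _iop_fields(cfg: SceneConfig, rng):
    out = []
    for lo, hi in (cfg.g_range, cfg.p_range, cfg.x_range):
        if cfg.iop_kind == "constant":
            out.append(np.full(cfg.shape, 0.5 * (lo + hi)))
        else:
            out.append(_smooth_field(rng, cfg.shape, lo, hi, sigma=8.0))
    return out


def _voronoi_labels(cfg: SceneConfig, rng, n_classes: int) -> np.ndarray:
    ny, nx = cfg.shape
    n_seeds = max(n_classes, int(round(ny * nx / cfg.patch_size ** 2)))
    pts = rng.uniform([0, 0], [ny, nx], size=(n_seeds, 2))
    seed_class = np.concatenate([np.arange(n_classes),
                                 rng.integers(0, n_classes, n_seeds - n_classes)])
    rng.shuffle(seed_class)
    rows, cols = np.mgrid[0:ny, 0:nx]
    _, nearest = cKDTree(pts).query(np.column_stack([rows.ravel(), cols.ravel()]))
    return seed_class[nearest].reshape(ny, nx)


def _cover(cfg: SceneConfig, rng, n_em: int):
    ny, nx = cfg.shape
    if cfg.cover_kind == "random":
        ab = rng.dirichlet(np.ones(n_em), size=(ny, nx))   # (ny, nx, nem)
        return np.moveaxis(ab, -1, 0), None
    labels = _voronoi_labels(cfg, rng, len(cfg.classes))
    ab = np.zeros((n_em, ny, nx))
    for k, cls in enumerate(cfg.classes):
        mean = np.asarray(cls.ab_mean, float)
        if mean.size != n_em:
            raise ValidationError(f"class {cls.name!r}: expected {n_em} abundances")
        sel = labels == k
        jit = rng.normal(0.0, cls.ab_jitter, size=(n_em, int(sel.sum())))
        ab[:, sel] = mean[:, None] + jit
    if cfg.border_mix > 0:
        ab = np.stack([gaussian_filter(p, cfg.border_mix, mode="nearest") for p in ab])
    ab = np.clip(ab, 0.0, None)
    ab /= ab.sum(axis=0, keepdims=True)
    return ab, labels


def generate(cfg: SceneConfig, bands: BandSet | None = None,
             lib: EndmemberLibrary | None = None) -> SceneTruth:
    """Build truth rasters and the observation cube for one scene."""
    rng = np.random.default_rng(cfg.seed)
    bands = bands or default_bandset()
    lib = lib or default_library()
    ny, nx = cfg.shape

    z = _depth_field(cfg, rng)
    G, P, X = _iop_fields(cfg, rng)
    ab, class_map = _cover(cfg, rng, len(lib))
    if class_map is not None:
        # depth stratified by class, smoothed inside each stratum
        base = _smooth_field(rng, cfg.shape, 0.0, 1.0)
        z = np.empty(cfg.shape)
        for k, cls in enumerate(cfg.classes):
            lo, hi = cls.depth_range
            sel = class_map == k
            z[sel] = lo + (hi - lo) * base[sel]

    grid = np.arange(FULL_GRID_LO, FULL_GRID_HI + 2.5, 5.0)
    fm = ForwardModel(bands, lib, cfg.geometry, grid_nm=grid)
    flat_ab = np.moveaxis(ab, 0, -1).reshape(-1, len(lib))
    rrs = fm.simulate(G.ravel(), P.ravel(), X.ravel(), z.ravel(), flat_ab)
    rrs_bands = rrs.T.reshape(len(bands), ny, nx)

    glint = np.zeros(cfg.shape)
    observed = rrs_bands.copy()
    if cfg.glint_amplitude > 0:
        th = np.radians(cfg.glint_direction_deg)
        rows, cols = np.mgrid[0:ny, 0:nx]
        phase = 2 * np.pi * (rows * np.cos(th) + cols * np.sin(th)) / cfg.glint_period_px
        streaks = np.maximum(np.sin(phase) - 0.3, 0.0) / 0.7
        modulation = _smooth_field(rng, cfg.shape, 0.2, 1.0, sigma=4.0)
        glint = cfg.glint_amplitude * streaks * modulation
        slopes = np.asarray(cfg.glint_band_slopes, float)[: len(bands)]
        observed = observed + slopes[:, None, None] * glint[None]
    if cfg.noise_multiplicative > 0:
        observed = observed * (1.0 + cfg.noise_multiplicative
                               * rng.standard_normal(observed.shape))
    if cfg.noise_additive > 0:
        observed = observed + cfg.noise_additive * rng.standard_normal(observed.shape)
    observed = np.maximum(observed, 0.0)

    return SceneTruth(config=cfg, bands=bands, lib=lib, grid_nm=grid,
                      z=z, G=G, P=P, X=X, abundance=ab, class_map=class_map,
                      rrs_bands=rrs_bands, glint=glint, observed=observed)


def generate_matchups(truth: SceneTruth, n_sites: int = 14, seed: int = 0,
                      instrument_noise: float = 0.0) -> list[MatchUp]:
    """Sample pseudo field-spectrometer sites from a scene's glint-free truth."""
    ny, nx = truth.z.shape
    if n_sites > (ny - 2) * (nx - 2):
        raise ValidationError("more sites than interior pixels")
    rng = np.random.default_rng(seed)
    rows = rng.integers(1, ny - 1, n_sites)
    cols = rng.integers(1, nx - 1, n_sites)
    out = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        spec = truth.rrs_bands[:, r, c].copy()
        if instrument_noise > 0:
            spec = spec + instrument_noise * rng.standard_normal(spec.shape)
        out.append(MatchUp(site=f"S{i:02d}", row=int(r), col=int(c), in_situ=spec))
    return out


def four_class_mosaic_config(shape=(48, 48), seed: int = 0,
                             **overrides) -> SceneConfig:
    """A 4-class benthic mosaic (sand, algae/seagrass, rock outcrop,
    stones-blocks) with class-stratified depth, for end-to-end runs."""
    classes = (
        CoverClass("sand", (0.85, 0.05, 0.10), 0.03, (1.0, 4.0)),
        CoverClass("algae", (0.15, 0.70, 0.15), 0.03, (4.0, 8.0)),
        CoverClass("rock", (0.10, 0.15, 0.75), 0.03, (8.0, 12.0)),
        CoverClass("stones", (0.45, 0.05, 0.50), 0.03, (2.0, 6.0)),
    )
    kw = dict(shape=shape, seed=seed, cover_kind="mosaic", classes=classes,
              iop_kind="constant", g_range=(0.02, 0.08), p_range=(0.01, 0.05),
              x_range=(0.002, 0.01), patch_size=12.0)
    kw.update(overrides)
    return SceneConfig(**kw)
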