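"""Per-pixel inversion of the shallow-water forward model.

Seven unknowns — the water-column magnitudes (G, P, X), the depth z and
three benthic abundances constrained to the unit simplex — are retrieved
from the six optical bands by damped least squares on the relative
spectral misfit

    δRrs = n · Σ_b (Rrs_model(b) − Rrs_obs(b))² / Σ_b Rrs_obs(b),   n = 6.

The sum-to-one constraint removes one abundance: the simplex is
parameterised by stick-breaking fractions (f1, f2) ∈ [0,1]², a smooth
bijection, leaving a 6-parameter bound-constrained problem solved with
scipy's trust-region-reflective least squares.  Depth is initialised from
the blue/green log-ratio heuristic; because the misfit surface has
multiple regional minima, the worst-fitting pixels of a scene are re-run
from jittered depth starts and the best fit kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bands import BandSet
from .benthos import EndmemberLibrary
from .errors import ValidationError
from .forward import ForwardModel
from .geometry import Geometry

__all__ = ["RatioCoefficients", "InversionOptions", "PixelSolution",
           "cost", "init_depth", "calibrate_ratio", "invert_pixel",
           "invert_scene"]

log = logging.getLogger(__name__)

FLAG_OK = 0
FLAG_NONCONVERGED = 1
FLAG_Z_AT_MAX = 2
FLAG_RATIO_FALLBACK = 4
FLAG_NODATA = 255


def _z_plane(solutions: dict, ny: int, nx: int) -> np.ndarray:
    z = np.full((ny, nx), np.nan)
    for (i, j), s in solutions.items():
        z[i, j] = s.z
    return z


def cost(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Relative spectral misfit δRrs = n·Σ(m−o)²/Σo over the n bands."""
    o = np.asarray(observed, float)
    m = np.asarray(modeled, float)
    total = o.sum()
    if total <= 0:
        raise ValidationError("observed spectrum sums to zero")
    return float(o.size * np.sum((m - o) ** 2) / total)


@dataclass(frozen=True)
class RatioCoefficients:
    """Blue/green log-ratio depth heuristic: z ≈ m1·ln(n·blue)/ln(n·green) − m0."""

    m0: float = 20.0     # offset, m
    m1: float = 25.0     # gain, m
    n: float = 1000.0    # scaling constant keeping the logs positive

    def __post_init__(self):
        if self.m1 == 0:
            raise ValidationError("ratio gain m1 must be non-zero")


def init_depth(blue, green, rc: RatioCoefficients,
               z_max: float = 33.0, fallback: float = 2.0):
    """Heuristic depth initialisation from the blue and green bands.

    Vectorised; pixels where either log is out of domain fall back to
    ``fallback`` metres and are reported in the returned flag array.
    Result is clamped to [0.1, z_max].
    """
    blue = np.asarray(blue, float)
    green = np.asarray(green, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.log(rc.n * blue)
        den = np.log(rc.n * green)
        z0 = rc.m1 * num / den - rc.m0
    bad = ~np.isfinite(z0) | (rc.n * blue <= 1) | (rc.n * green <= 1)
    z0 = np.where(bad, fallback, z0)
    z0 = np.clip(z0, 0.1, z_max)
    return (float(z0), bool(bad)) if z0.ndim == 0 else (z0, bad)


def calibrate_ratio(blue, green, z_truth, n: float = 1000.0) -> RatioCoefficients:
    """Least-squares fit of (m0, m1) against known depths at sample points."""
    x = np.log(n * np.asarray(blue, float)) / np.log(n * np.asarray(green, float))
    A = np.column_stack([x, -np.ones_like(x)])
    (m1, m0), *_ = np.linalg.lstsq(A, np.asarray(z_truth, float), rcond=None)
    return RatioCoefficients(m0=float(m0), m1=float(m1), n=n)


@dataclass
class InversionOptions:
    """Bounds, initial values, tolerances and multi-start policy."""

    gpx_max: float = 5.0          # upper bound on G, P, X (m-1)
    z_max: float = 33.0           # maximum retrievable depth (m)
    init_G: float = 0.05
    init_P: float = 0.05
    init_X: float = 0.01
    ftol: float = 1e-8            # relative cost-change tolerance
    xtol: float = 1e-10           # step-norm tolerance
    max_iter: int = 200
    multistart: bool = True
    multistart_quantile: float = 0.95   # scene-cost quantile that triggers restarts
    z_jitter: tuple = (0.5, 2.0)        # depth multipliers for restarts
    ratio: RatioCoefficients = field(default_factory=RatioCoefficients)
    seed: int = 0                 # recorded in run metadata; jitter is deterministic


@dataclass
class PixelSolution:
    """Retrieved parameters and fit diagnostics for one pixel."""

    G: float
    P: float
    X: float
    z: float
    ab: np.ndarray
    cost: float
    n_iter: int
    converged: bool
    residuals: np.ndarray
    flag: int = FLAG_OK

    @property
    def params(self):
        return np.array([self.G, self.P, self.X, self.z, *self.ab])


def _stick_to_simplex(f1: float, f2: float) -> np.ndarray:
    return np.array([f1, (1.0 - f1) * f2, (1.0 - f1) * (1.0 - f2)])


def _simplex_to_stick(ab: np.ndarray) -> tuple[float, float]:
    a1 = float(np.clip(ab[0], 0.0, 1.0))
    rest = 1.0 - a1
    f2 = float(np.clip(ab[1] / rest, 0.0, 1.0)) if rest > 1e-12 else 0.5
    return a1, f2


def invert_pixel(observed: np.ndarray, fm: ForwardModel,
                 opts: InversionOptions | None = None,
                 z0: float | None = None,
                 ab0: np.ndarray | None = None) -> PixelSolution:
    """Fit one pixel's 6-band Rrs; never raises on non-convergence.

    ``fm`` is a precompiled :class:`ForwardModel` over the optical bands.
    """
    opts = opts or InversionOptions()
    obs = np.asarray(observed, float)
    if obs.shape != (fm.n_bands,):
        raise ValidationError(f"expected {fm.n_bands}-band observation")
    if not np.all(np.isfinite(obs)) or obs.min() < 0:
        raise ValidationError("observation must be finite and non-negative")
    obs_sum = obs.sum()
    if obs_sum <= 0:
        raise ValidationError("observed spectrum sums to zero")
    scale = np.sqrt(obs.size / obs_sum)

    if z0 is None:
        z0, _ = init_depth(obs[1], obs[2], opts.ratio, z_max=opts.z_max)
    f1, f2 = _simplex_to_stick(ab0) if ab0 is not None \
        else (1.0 / 3.0, 0.5)

    cache = {"x": None, "bands": None, "jac": None}

    def _eval(p):
        if cache["x"] is None or not np.array_equal(p, cache["x"]):
            bands_val, jac_val = fm.simulate_jac(*p)
            cache["x"] = p.copy()
            cache["bands"] = bands_val
            cache["jac"] = jac_val
        return cache["bands"], cache["jac"]

    def residuals(p):
        return (_eval(p)[0] - obs) * scale

    def jacobian(p):
        return _eval(p)[1] * scale

    x0 = np.array([opts.init_G, opts.init_P, opts.init_X,
                   float(np.clip(z0, 0.1, opts.z_max)), f1, f2])
    lo = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    hi = np.array([opts.gpx_max] * 3 + [opts.z_max, 1.0, 1.0])
    try:
        res = least_squares(residuals, x0, jac=jacobian, bounds=(lo, hi),
                            method="trf", ftol=opts.ftol, xtol=opts.xtol,
                            gtol=None, x_scale=[0.1, 0.1, 0.02, 5.0, 0.3, 0.3],
                            max_nfev=opts.max_iter * (x0.size + 1))
        ok = res.status > 0
    except Exception:  # pragma: no cover - defensive: flagged, never raised
        class _Fail:
            x = x0
            fun = residuals(x0)
            nfev = 0
        res, ok = _Fail(), False

    G, P, X, z, f1, f2 = res.x
    ab = _stick_to_simplex(f1, f2)
    final_cost = float(np.sum(np.asarray(res.fun) ** 2))
    flag = FLAG_OK if ok else FLAG_NONCONVERGED
    if z >= opts.z_max * 0.99:
        flag |= FLAG_Z_AT_MAX
    return PixelSolution(G=float(G), P=float(P), X=float(X), z=float(z),
                         ab=ab, cost=final_cost, n_iter=int(res.nfev),
                         converged=ok, residuals=np.asarray(res.fun) / scale,
                         flag=flag)


def invert_scene(cube: np.ndarray, geom: Geometry, lib: EndmemberLibrary,
                 bands: BandSet, opts: InversionOptions | None = None,
                 mask: np.ndarray | None = None,
                 fm: ForwardModel | None = None) -> dict[str, np.ndarray]:
    """Per-pixel inversion of a corrected 6-band Rrs raster.

    Returns rasters ``G, P, X, z``, per-class abundances, final cost and an
    8-bit flag plane (255 = masked / no data).  Deterministic for fixed
    inputs and options; the multi-start pass re-fits pixels whose first
    cost exceeds the scene's configured quantile.
    """
    opts = opts or InversionOptions()
    cube = np.asarray(cube, float)
    nb, ny, nx = cube.shape
    if fm is None:
        fm = ForwardModel(bands.subset(nb) if len(bands) != nb else bands, lib, geom)
    if mask is None:
        mask = np.ones((ny, nx), bool)
    elif mask.shape != (ny, nx):
        raise ValidationError("mask geometry does not match raster")

    out = {k: np.full((ny, nx), np.nan) for k in ("G", "P", "X", "z", "cost")}
    ab_out = np.full((len(lib), ny, nx), np.nan)
    flags = np.full((ny, nx), FLAG_NODATA, np.uint8)

    z0_map, z0_bad = init_depth(cube[1], cube[2], opts.ratio, z_max=opts.z_max)
    solutions = {}
    idx = np.argwhere(mask)
    for t, (i, j) in enumerate(idx):
        sol = invert_pixel(cube[:, i, j], fm, opts, z0=float(z0_map[i, j]))
        if z0_bad[i, j]:
            sol.flag |= FLAG_RATIO_FALLBACK
        solutions[i, j] = sol
        if t and t % 1000 == 0:
            log.info("inverted %d/%d pixels", t, len(idx))

    if opts.multistart and len(solutions) > 1:
        from scipy.ndimage import median_filter

        costs = np.array([s.cost for s in solutions.values()])
        # catch both relative outliers (the scene's worst quantile) and, on
        # near-noiseless data, anything far above the scene's typical misfit
        threshold = min(np.quantile(costs, opts.multistart_quantile),
                        10.0 * max(np.median(costs), 1e-30))
        z_first = _z_plane(solutions, ny, nx)
        z_med = median_filter(np.where(np.isfinite(z_first), z_first, 0.0),
                              size=3, mode="nearest")
        n_em = len(lib)
        corners = np.eye(n_em) * 0.9 + (0.1 / (n_em - 1)) * (1 - np.eye(n_em))
        for (i, j), sol in solutions.items():
            zr = z_med[i, j]
            spatial_outlier = abs(sol.z - zr) > max(1.0, 0.35 * max(zr, 0.1))
            if sol.cost <= threshold and not spatial_outlier:
                continue
            candidates = [sol]
            starts = [(float(np.clip(zr, 0.1, opts.z_max)), None)]
            starts += [(float(np.clip(zr, 0.1, opts.z_max)), corners[k])
                       for k in range(n_em)]
            starts += [(float(np.clip(sol.z * fac, 0.1, opts.z_max)), None)
                       for fac in opts.z_jitter]
            for z_start, ab_start in starts:
                candidates.append(invert_pixel(cube[:, i, j], fm, opts,
                                               z0=z_start, ab0=ab_start))
            # lowest misfit wins; exact ties (degenerate band-space fits)
            # break toward spatial depth consistency
            def score(s):
                return s.cost + 1e-10 * ((s.z - zr) / max(zr, 1.0)) ** 2
            solutions[i, j] = min(candidates, key=score)

    for (i, j), sol in solutions.items():
        out["G"][i, j], out["P"][i, j], out["X"][i, j] = sol.G, sol.P, sol.X
        out["z"][i, j], out["cost"][i, j] = sol.z, sol.cost
        ab_out[:, i, j] = sol.ab
        flags[i, j] = sol.flag
    out["abundance"] = ab_out
    out["flags"] = flags
    return out
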