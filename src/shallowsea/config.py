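"""Run configuration: YAML schema, validation and run-metadata sidecars."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from datetime import datetime, timezone

import yaml

from .errors import ConfigurationError
from .geometry import Geometry
from .scene import CoverClass, SceneConfig

__all__ = ["load_scene_config", "write_run_metadata"]

_SCENE_KEYS = {
    "shape", "seed", "depth_kind", "depth_range", "iop_kind", "g_range",
    "p_range", "x_range", "cover_kind", "classes", "patch_size", "border_mix",
    "glint_amplitude", "glint_direction_deg", "glint_period_px",
    "glint_band_slopes", "noise_multiplicative", "noise_additive", "geometry",
}
_GEOM_KEYS = {"sun_zenith_deg", "view_zenith_deg", "rel_azimuth_deg", "earth_sun_au"}
_CLASS_KEYS = {"name", "ab_mean", "ab_jitter", "depth_range"}


def load_scene_config(path) -> SceneConfig:
    """Parse a YAML scene description, rejecting unknown keys."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    unknown = set(raw) - _SCENE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "geometry" in kwargs:
        g = kwargs["geometry"]
        bad = set(g) - _GEOM_KEYS
        if bad:
            raise ConfigurationError(f"unknown geometry keys: {sorted(bad)}")
        kwargs["geometry"] = Geometry(**g)
    if "classes" in kwargs:
        classes = []
        for c in kwargs["classes"]:
            bad = set(c) - _CLASS_KEYS
            if bad:
                raise ConfigurationError(f"unknown class keys: {sorted(bad)}")
            c = dict(c)
            for k in ("ab_mean", "depth_range"):
                if k in c:
                    c[k] = tuple(c[k])
            classes.append(CoverClass(**c))
        kwargs["classes"] = tuple(classes)
    for k in ("shape", "depth_range", "g_range", "p_range", "x_range",
              "glint_band_slopes"):
        if k in kwargs:
            kwargs[k] = tuple(kwargs[k])
    return SceneConfig(**kwargs)


def write_run_metadata(path, command: str, options: dict, seed=None) -> None:
    """Echo every effective option into a JSON sidecar next to the outputs."""
    from . import __version__

    def _clean(v):
        if isinstance(v, (Geometry, SceneConfig, CoverClass)):
            return asdict(v)
        if isinstance(v, tuple):
            return list(v)
        return v

    meta = {
        "tool": "shallowsea",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": sys.version.split()[0],
        "seed": seed,
        "options": {k: _clean(v) for k, v in options.items()},
    }
    with open(path, "w") as f:
        json.dump(meta, f, indent=1, default=str)
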