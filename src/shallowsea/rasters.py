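"""Raster I/O: multiband TIFF (primary), ENVI flat-binary (read), geo sidecar.

Rasters are float arrays in (band, row, col) order, row 0 = north.
Georeferencing travels in a small JSON sidecar (``<raster>.geo.json``)
holding an affine transform and CRS string; writers copy it from their
input so every derived product stays registered.  No-data is IEEE NaN in
float rasters and 255 in flag rasters.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile

from .errors import ConfigurationError

__all__ = ["read_raster", "write_raster", "read_envi", "default_geo"]


def default_geo(shape) -> dict:
    """Identity georeferencing for synthetic scenes (1-px grid at origin)."""
    return {"transform": [1.0, 0.0, 0.0, 0.0, -1.0, 0.0], "crs": "synthetic",
            "shape": list(shape)}


def _sidecar(path) -> str:
    return str(path) + ".geo.json"


def write_raster(path, array: np.ndarray, geo: dict | None = None,
                 nodata=None) -> None:
    """Write a (nbands, ny, nx) float raster as multiband TIFF + geo sidecar."""
    array = np.asarray(array)
    if array.ndim == 2:
        array = array[None]
    tifffile.imwrite(path, array.astype(np.float32) if array.dtype.kind == "f"
                     else array, photometric="minisblack")
    geo = dict(geo) if geo else default_geo(array.shape[-2:])
    geo["shape"] = [int(s) for s in array.shape[-2:]]
    if nodata is not None:
        geo["nodata"] = nodata
    with open(_sidecar(path), "w") as f:
        json.dump(geo, f, indent=1)


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a multiband TIFF (or ENVI pair) → ((nbands, ny, nx), geo)."""
    path = str(path)
    if path.endswith(".hdr") or os.path.exists(path + ".hdr"):
        return read_envi(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    geo = default_geo(arr.shape[-2:])
    if os.path.exists(_sidecar(path)):
        with open(_sidecar(path)) as f:
            geo = json.load(f)
    return arr, geo


_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}


def read_envi(path) -> tuple[np.ndarray, dict]:
    """Read an ENVI header/flat-binary pair → ((nbands, ny, nx), geo)."""
    path = str(path)
    hdr_path = path if path.endswith(".hdr") else path + ".hdr"
    bin_path = path[:-4] if path.endswith(".hdr") else path
    fields = {}
    with open(hdr_path) as f:
        text = f.read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ConfigurationError(f"{hdr_path}: not an ENVI header")
    # key = value, with {...} blocks allowed to span lines
    body = text.split("\n", 1)[1]
    buf = ""
    for line in body.splitlines():
        buf += line.strip() + " "
        if buf.count("{") > buf.count("}"):
            continue
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip().lower()] = val.strip().strip("{}").strip()
        buf = ""
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields.get("bands", 1))
        dtype = _ENVI_DTYPES[int(fields["data type"])]
    except KeyError as e:
        raise ConfigurationError(f"{hdr_path}: missing ENVI field {e}")
    interleave = fields.get("interleave", "bsq").lower()
    order = ">" if fields.get("byte order", "0").strip() == "1" else "<"
    raw = np.fromfile(bin_path, dtype=np.dtype(dtype).newbyteorder(order))
    if raw.size != samples * lines * bands:
        raise ConfigurationError(f"{bin_path}: size does not match header")
    if interleave == "bsq":
        arr = raw.reshape(bands, lines, samples)
    elif interleave == "bil":
        arr = raw.reshape(lines, bands, samples).transpose(1, 0, 2)
    elif interleave == "bip":
        arr = raw.reshape(lines, samples, bands).transpose(2, 0, 1)
    else:
        raise ConfigurationError(f"unknown interleave {interleave!r}")
    geo = default_geo((lines, samples))
    geo["envi_map_info"] = fields.get("map info", "")
    return np.ascontiguousarray(arr), geo
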