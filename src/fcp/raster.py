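"""Raster containers and I/O.

All gridded layers live in an :class:`xarray.Dataset` on a single regular
WGS84 latitude/longitude grid (north-up, latitude descending).  Layers are
persisted one band per file as float32 GeoTIFFs carrying the minimal
georeferencing tags (ModelPixelScale / ModelTiepoint), written and read with
:mod:`tifffile`.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import tifffile
import xarray as xr
import yaml

# mean Earth radius, km
EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922


def make_grid(grid_height: int, grid_width: int,
              lat_range: tuple[float, float],
              lon_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates of a north-up grid (lat descending)."""
    lat0, lat1 = min(lat_range), max(lat_range)
    lon0, lon1 = min(lon_range), max(lon_range)
    dlat = (lat1 - lat0) / grid_height
    dlon = (lon1 - lon0) / grid_width
    lats = lat1 - dlat * (np.arange(grid_height) + 0.5)
    lons = lon0 + dlon * (np.arange(grid_width) + 0.5)
    return lats, lons


def new_stack(layers: dict[str, np.ndarray], lats: np.ndarray,
              lons: np.ndarray, attrs: dict | None = None) -> xr.Dataset:
    data = {k: (("lat", "lon"), np.asarray(v, dtype=float)) for k, v in layers.items()}
    return xr.Dataset(data, coords={"lat": lats, "lon": lons}, attrs=attrs or {})


def check_aligned(*datasets: xr.Dataset | xr.DataArray) -> None:
    """Raise if the layers are not on one common grid."""
    ref = datasets[0]
    for ds in datasets[1:]:
        if (ds.sizes.get("lat") != ref.sizes.get("lat")
                or ds.sizes.get("lon") != ref.sizes.get("lon")
                or not np.allclose(ds["lat"].values, ref["lat"].values)
                or not np.allclose(ds["lon"].values, ref["lon"].values)):
            raise ValueError("raster layers are not co-registered on one grid")


def pixel_area_ha(ds: xr.Dataset | xr.DataArray) -> xr.DataArray:
    """Per-pixel area in hectares: nominal cell area scaled by cos(latitude)."""
    lat = ds["lat"].values
    lon = ds["lon"].values
    dlat = float(np.abs(np.diff(lat)).mean()) if lat.size > 1 else 1.0
    dlon = float(np.abs(np.diff(lon)).mean()) if lon.size > 1 else 1.0
    cell_km2 = (dlat * KM_PER_DEGREE) * (dlon * KM_PER_DEGREE)
    area = cell_km2 * 100.0 * np.cos(np.deg2rad(lat))  # km^2 -> ha
    grid = np.repeat(area[:, None], lon.size, axis=1)
    return xr.DataArray(grid, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))


def _geotags(lats: np.ndarray, lons: np.ndarray) -> list[tuple]:
    dlat = float(np.abs(np.diff(lats)).mean()) if lats.size > 1 else 1.0
    dlon = float(np.abs(np.diff(lons)).mean()) if lons.size > 1 else 1.0
    north = float(lats.max()) + dlat / 2.0
    west = float(lons.min()) - dlon / 2.0
    scale = (dlon, dlat, 0.0)
    tiepoint = (0.0, 0.0, 0.0, west, north, 0.0)
    return [
        (_GEOTIFF_PIXELSCALE, "d", 3, scale, True),
        (_GEOTIFF_TIEPOINT, "d", 6, tiepoint, True),
    ]


def write_stack(ds: xr.Dataset, out_dir: str) -> None:
    """One float32 GeoTIFF per layer plus a YAML grid manifest."""
    os.makedirs(out_dir, exist_ok=True)
    lats, lons = ds["lat"].values, ds["lon"].values
    tags = _geotags(lats, lons)
    for name in ds.data_vars:
        arr = np.asarray(ds[name].values, dtype=np.float32)
        tifffile.imwrite(os.path.join(out_dir, f"{name}.tif"), arr, extratags=tags)
    meta = {
        "lat_range": [float(lats.min()), float(lats.max())],
        "lon_range": [float(lons.min()), float(lons.max())],
        "grid_height": int(lats.size),
        "grid_width": int(lons.size),
        "layers": sorted(ds.data_vars),
        "attrs": {k: v for k, v in ds.attrs.items()},
    }
    with open(os.path.join(out_dir, "stack.yml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stack(in_dir: str, layers: Iterable[str] | None = None) -> xr.Dataset:
    with open(os.path.join(in_dir, "stack.yml")) as fh:
        meta = yaml.safe_load(fh)
    names = list(layers) if layers is not None else meta["layers"]
    lats = np.linspace(meta["lat_range"][1], meta["lat_range"][0], meta["grid_height"])
    lons = np.linspace(meta["lon_range"][0], meta["lon_range"][1], meta["grid_width"])
    data = {}
    for name in names:
        arr = tifffile.imread(os.path.join(in_dir, f"{name}.tif"))
        data[name] = arr.astype(float)
    ds = new_stack(data, lats, lons, attrs=meta.get("attrs") or {})
    return ds
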