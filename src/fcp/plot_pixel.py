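"""Plot-to-pixel carbon scaling and the model training table.

A forest-inventory plot samples the forested part of a pixel, so plot carbon
density is rescaled to the pixel by
``C_pixel = C_plot / canopy_plot * canopy_pixel``.  Two conventions bound the
unknown within-plot canopy: the *upper* convention takes the maximum canopy
of the pixel (plots assumed to sit in the densest forest, hence the smallest
pixel carbon) and the *lower* convention takes the mean canopy of the
forested (>= 10% cover) part.  Pixels with no sub-pixel canopy detail use
the pixel canopy itself for both conventions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .raster import check_aligned

log = logging.getLogger(__name__)

FOREST_CANOPY_THRESHOLD = 0.10


def scale_plot_to_pixel(plot_density: float | np.ndarray,
                        canopy_plot: float | np.ndarray,
                        canopy_pixel: float | np.ndarray) -> np.ndarray:
    """``C_pixel = C_plot / canopy_plot * canopy_pixel`` (t C / ha)."""
    plot_density = np.asarray(plot_density, dtype=float)
    canopy_plot = np.asarray(canopy_plot, dtype=float)
    canopy_pixel = np.asarray(canopy_pixel, dtype=float)
    bad = (canopy_plot <= 0) & (plot_density > 0)
    if np.any(bad):
        raise ValueError("zero plot canopy with positive carbon is inconsistent")
    out = np.where(canopy_plot > 0, plot_density / np.where(canopy_plot > 0,
                                                            canopy_plot, 1.0)
                   * canopy_pixel, 0.0)
    return out


def canopy_conventions(subpixel_canopy: np.ndarray | None,
                       canopy_pixel: float) -> tuple[float, float]:
    """(upper, lower) within-plot canopy assumptions for one pixel.

    Upper = maximum sub-pixel canopy; lower = mean canopy of the forested
    (>= 10%) sub-pixel fraction.  Without sub-pixel detail both fall back to
    the pixel canopy.
    """
    if subpixel_canopy is None or len(np.atleast_1d(subpixel_canopy)) == 0:
        return canopy_pixel, canopy_pixel
    sub = np.asarray(subpixel_canopy, dtype=float)
    upper = float(sub.max())
    forested = sub[sub >= FOREST_CANOPY_THRESHOLD]
    lower = float(forested.mean()) if forested.size else canopy_pixel
    return upper, lower


def table_from_raster(carbon: xr.DataArray, stack: xr.Dataset,
                      canopy: xr.DataArray,
                      extra_layers: tuple[str, ...] = ("minimal_disturbance",),
                      ) -> pd.DataFrame:
    """Training table for raster-derived designs: every finite carbon pixel
    becomes one observation (columns as in :func:`build_training_table`,
    with the raster value in both carbon columns)."""
    check_aligned(carbon, stack, canopy)
    finite = np.isfinite(carbon.values)
    rows, cols = np.nonzero(finite)
    table = pd.DataFrame({
        "row": rows, "col": cols,
        "lat": stack["lat"].values[rows], "lon": stack["lon"].values[cols],
        "carbon_upper": carbon.values[rows, cols],
        "carbon_lower": carbon.values[rows, cols],
        "canopy_pixel": canopy.values[rows, cols],
    })
    cov_names = list(stack.attrs.get("env_layers", [])) \
        + list(stack.attrs.get("human_layers", []))
    for name in cov_names + list(extra_layers):
        table[name] = stack[name].values[rows, cols]
    return table.dropna().reset_index(drop=True)


def build_training_table(plots: pd.DataFrame, stack: xr.Dataset,
                         canopy: xr.DataArray,
                         extra_layers: tuple[str, ...] = ("minimal_disturbance",),
                         ) -> pd.DataFrame:
    """Join plot carbon with pixel covariates into a model-ready table.

    ``plots`` needs columns ``lat, lon, carbon_density, canopy_cover_plot``
    (canopy may be NaN -> pixel canopy used for both conventions).  Plots
    outside the raster extent are excluded with a warning; co-located plots
    are averaged per pixel; rows with any missing covariate are dropped.
    Output columns: ``row, col, lat, lon, carbon_upper, carbon_lower,
    canopy_pixel``, every covariate layer, and ``extra_layers``.
    """
    check_aligned(stack, canopy)
    lats = stack["lat"].values
    lons = stack["lon"].values
    dlat = float(np.abs(np.diff(lats)).mean())
    dlon = float(np.abs(np.diff(lons)).mean())

    lat_top = lats.max() + dlat / 2.0   # grid edges, not pixel centres
    lon_left = lons.min() - dlon / 2.0
    rows = np.floor((lat_top - plots["lat"].to_numpy()) / dlat).astype(int)
    cols = np.floor((plots["lon"].to_numpy() - lon_left) / dlon).astype(int)
    inside = ((rows >= 0) & (rows < lats.size)
              & (cols >= 0) & (cols < lons.size))
    if np.any(~inside):
        log.warning("excluded %d plots outside the raster extent",
                    int(np.sum(~inside)))
    df = plots.loc[inside].copy()
    rows, cols = rows[inside], cols[inside]

    canopy_pixel = canopy.values[rows, cols]
    cplot = df["canopy_cover_plot"].to_numpy(dtype=float)
    cplot = np.where(np.isfinite(cplot) & (cplot > 0), cplot, canopy_pixel)
    dens = df["carbon_density"].to_numpy(dtype=float)
    # without sub-pixel canopy detail the two conventions coincide at the
    # recorded plot canopy; the split is kept so richer canopy inputs plug in
    upper_assumption = np.maximum(cplot, canopy_pixel)
    lower_assumption = cplot
    zero = dens <= 0
    carbon_upper = np.where(zero | (upper_assumption <= 0), 0.0,
                            dens / np.where(upper_assumption > 0, upper_assumption, 1.0)
                            * canopy_pixel)
    carbon_lower = np.where(zero | (lower_assumption <= 0), 0.0,
                            dens / np.where(lower_assumption > 0, lower_assumption, 1.0)
                            * canopy_pixel)

    table = pd.DataFrame({
        "row": rows, "col": cols,
        "lat": lats[rows], "lon": lons[cols],
        "carbon_upper": carbon_upper, "carbon_lower": carbon_lower,
        "canopy_pixel": canopy_pixel,
    })
    cov_names = list(stack.attrs.get("env_layers", [])) \
        + list(stack.attrs.get("human_layers", []))
    for name in cov_names + list(extra_layers):
        table[name] = stack[name].values[rows, cols]

    # average plots sharing a pixel, then drop rows with missing covariates
    table = table.groupby(["row", "col"], as_index=False).mean()
    n0 = len(table)
    table = table.dropna()
    if n0 - len(table):
        log.info("dropped %d pixel rows with missing covariates", n0 - len(table))
    return table.reset_index(drop=True)
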