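"""Scaling living tree carbon to ecosystem carbon pools.

Dead wood and litter are a forest-class ratio of living tree carbon
(tropical 22% [15-33], temperate 33% [30-37], boreal 80% [68-94], dryland
21% [2-40]); soil carbon potential is consumed as a data layer with an
absolute-error layer, masked to pixels that would naturally support trees
(potential canopy cover >= 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .raster import check_aligned
from .synthetic_world import BIOMES

POTENTIAL_CANOPY_MIN = 0.10

DEFAULT_RATIOS = {
    "tropical": (0.22, 0.15, 0.33),
    "temperate": (0.33, 0.30, 0.37),
    "boreal": (0.80, 0.68, 0.94),
    "dryland": (0.21, 0.02, 0.40),
}


@dataclass
class PoolRatios:
    """Dead wood + litter to living tree carbon, per forest class."""

    ratios: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIOS))

    def __post_init__(self) -> None:
        for cls, (mean, low, high) in self.ratios.items():
            if not 0 < low <= mean <= high:
                raise ValueError(f"inconsistent ratio range for {cls!r}")

    def arrays(self, forest_class: np.ndarray) -> tuple[np.ndarray, ...]:
        """(mean, low, high) rasters looked up from integer class codes."""
        known = set(range(len(BIOMES)))
        codes = np.unique(forest_class[np.isfinite(forest_class)]).astype(int)
        if not set(codes) <= known:
            raise ValueError(f"unknown forest class codes {set(codes) - known}")
        shape = forest_class.shape
        mean = np.full(shape, np.nan)
        low = np.full(shape, np.nan)
        high = np.full(shape, np.nan)
        for code in codes:
            m, lo, hi = self.ratios[BIOMES[code]]
            sel = forest_class == code
            mean[sel], low[sel], high[sel] = m, lo, hi
        return mean, low, high


def dead_wood_litter(living: xr.DataArray, forest_class: xr.DataArray,
                     ratios: PoolRatios | None = None,
                     living_bounds: tuple[xr.DataArray, xr.DataArray] | None = None,
                     ) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray]:
    """Dead wood + litter carbon with endpoint-product bounds."""
    ratios = ratios or PoolRatios()
    check_aligned(living, forest_class)
    r_mean, r_low, r_high = ratios.arrays(forest_class.values)

    def wrap(v: np.ndarray) -> xr.DataArray:
        return xr.DataArray(v, coords=living.coords, dims=living.dims)

    mean = wrap(living.values * r_mean)
    l_lo, l_hi = living_bounds if living_bounds is not None else (living, living)
    corners = np.stack([l_lo.values * r_low, l_lo.values * r_high,
                        l_hi.values * r_low, l_hi.values * r_high])
    return mean, wrap(corners.min(axis=0)), wrap(corners.max(axis=0))


def soil_potential(soil_delta: xr.DataArray, soil_error: xr.DataArray,
                   potential_canopy: xr.DataArray,
                   ) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray]:
    """Soil carbon potential masked to potential canopy >= 10%.

    Bounds are delta +/- absolute error.
    """
    check_aligned(soil_delta, soil_error, potential_canopy)
    if float((soil_error < 0).sum()) > 0:
        raise ValueError("negative soil error layer")
    mask = potential_canopy.values >= POTENTIAL_CANOPY_MIN

    def wrap(v: np.ndarray) -> xr.DataArray:
        return xr.DataArray(np.where(mask, v, np.nan),
                            coords=soil_delta.coords, dims=soil_delta.dims)

    return (wrap(soil_delta.values),
            wrap(soil_delta.values - soil_error.values),
            wrap(soil_delta.values + soil_error.values))
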