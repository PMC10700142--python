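"""Deficit partitioning, land-cover allocation and the uncertainty budget.

The pixel carbon deficit (potential minus current, floored at zero) is split
into a *conservation* component (degradation of standing forest: recoverable
by letting existing forest mature) and a *restoration* component (carbon
attributable to lost canopy cover).  Carbon proportional to the canopy-cover
increase is attributed to restoration first; any excess above that
proportional baseline is distributed across the total potential canopy, i.e.
allocated cc_cur : (cc_pot - cc_cur) to conservation : restoration.  The two
components close the deficit exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

log = logging.getLogger(__name__)

from .carbon_model import total_stock
from .raster import check_aligned

UNCERTAINTY_SOURCES = ("model_type", "input_data", "aboveground_bootstrap",
                       "roots", "deadwood_litter", "soil")

LAND_COVER_CLASSES = ("urban", "cropland", "pasture", "rangeland")
FOREST_CANOPY_MIN = 0.10
PLANTATION_MIN_SHARE = 0.10


def partition_deficit(c_cur: np.ndarray, c_pot: np.ndarray,
                      cc_cur: np.ndarray, cc_pot: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Split the pixel deficit into (conservation, restoration) t C/ha.

    Rules per pixel (deficit d = c_pot - c_cur, when positive):

    * equal canopies: conservation = d, restoration = 0;
    * no current canopy: restoration = d, conservation = 0;
    * otherwise a canopy-proportional baseline ``c_cur * cc_pot / cc_cur``
      attributes its part of the deficit to restoration, and the excess E
      above the baseline is split cc_cur : (cc_pot - cc_cur); if potential
      falls short of the baseline, the shortfall shrinks the restoration
      term (floored at zero).

    Pixels with no deficit (c_pot <= c_cur) yield (0, 0).
    """
    c_cur = np.asarray(c_cur, dtype=float)
    c_pot = np.asarray(c_pot, dtype=float)
    cc_cur = np.asarray(np.broadcast_to(cc_cur, c_cur.shape), dtype=float)
    cc_pot = np.asarray(np.broadcast_to(cc_pot, c_cur.shape), dtype=float)
    over = cc_cur > cc_pot
    if np.any(over):
        log.info("clipped %d pixels with current canopy above potential",
                 int(np.sum(over)))
        cc_cur = np.minimum(cc_cur, cc_pot)

    deficit = c_pot - c_cur
    conservation = np.zeros_like(c_cur)
    restoration = np.zeros_like(c_cur)

    has_deficit = deficit > 0
    equal_cc = has_deficit & np.isclose(cc_cur, cc_pot)
    conservation[equal_cc] = deficit[equal_cc]

    no_cc = has_deficit & ~equal_cc & (cc_cur <= 0)
    restoration[no_cc] = deficit[no_cc]

    mixed = has_deficit & ~equal_cc & (cc_cur > 0)
    if np.any(mixed):
        r = cc_pot[mixed] / cc_cur[mixed]
        baseline = c_cur[mixed] * r
        excess = np.maximum(c_pot[mixed] - baseline, 0.0)
        cons = excess * cc_cur[mixed] / cc_pot[mixed]
        rest = (c_cur[mixed] * (r - 1.0)
                + excess * (cc_pot[mixed] - cc_cur[mixed]) / cc_pot[mixed])
        shortfall = np.maximum(baseline - c_pot[mixed], 0.0)
        rest = np.maximum(rest - shortfall, 0.0)
        conservation[mixed] = cons
        restoration[mixed] = rest
    return conservation, restoration


def allocate_land_cover(deficit: xr.DataArray,
                        cover_fractions: dict[str, xr.DataArray],
                        canopy_cur: xr.DataArray,
                        plantation: xr.DataArray | None = None,
                        excluded: tuple[str, ...] = ("water", "ice"),
                        ) -> pd.DataFrame:
    """Allocate pixel deficits to land-cover classes in proportion to cover.

    The residual pixel fraction not covered by any mapped class (nor water /
    ice) goes to ``low_human_pressure`` in non-forest pixels (< 10% canopy)
    and to ``forest`` in forest pixels.  Plantation deficit is tallied (as a
    memo row, subset of forest) where plantation cover exceeds 10% of the
    canopy area.  Returns a table of Gt C totals per class.
    """
    check_aligned(deficit, canopy_cur, *cover_fractions.values())
    attributable = {k: v for k, v in cover_fractions.items()
                    if k not in excluded}
    frac_sum = sum(v.values for v in cover_fractions.values())
    if np.nanmax(frac_sum) > 1 + 1e-6:
        raise ValueError("land-cover fractions sum above 1")

    d = np.nan_to_num(deficit.values, nan=0.0)
    forest = canopy_cur.values >= FOREST_CANOPY_MIN
    residual = np.clip(1.0 - frac_sum, 0.0, 1.0)

    def stock(weight: np.ndarray) -> float:
        return total_stock(xr.DataArray(d * weight, coords=deficit.coords,
                                        dims=deficit.dims))

    rows = {name: stock(layer.values) for name, layer in attributable.items()}
    rows["low_human_pressure"] = stock(residual * ~forest)
    rows["forest"] = stock(residual * forest)
    out = pd.DataFrame({"deficit_gt": rows})
    out.index.name = "land_cover"

    if plantation is not None:
        share = np.where(canopy_cur.values > 0,
                         plantation.values / np.maximum(canopy_cur.values, 1e-12),
                         0.0)
        sel = forest & (share > PLANTATION_MIN_SHARE)
        out.loc["plantation_memo"] = stock(residual * sel)
    return out


def uncertainty_budget(sources: dict[str, np.ndarray]) -> pd.DataFrame | xr.Dataset:
    """Per-pixel uncertainty budget across the six canonical sources.

    The total is the linear sum of the absolute uncertainties; shares divide
    each source by the total; the top source takes ties in the fixed source
    order.  All-zero pixels are masked (NaN shares).
    """
    missing = [s for s in UNCERTAINTY_SOURCES if s not in sources]
    if missing:
        raise ValueError(f"missing uncertainty sources: {missing}")
    stackd = np.stack([np.asarray(sources[s], dtype=float)
                       for s in UNCERTAINTY_SOURCES])
    if np.nanmin(stackd) < 0:
        raise ValueError("uncertainties must be non-negative")
    total = stackd.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(total > 0, stackd / total, np.nan)
    top = np.argmax(stackd, axis=0).astype(float)
    top[total <= 0] = np.nan
    flat_index = pd.Index(range(total.size), name="pixel")
    df = pd.DataFrame({"total": total.ravel()}, index=flat_index)
    for i, s in enumerate(UNCERTAINTY_SOURCES):
        df[f"share_{s}"] = shares[i].ravel()
    df["top_source"] = [UNCERTAINTY_SOURCES[int(t)] if np.isfinite(t) else None
                        for t in top.ravel()]
    return df
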