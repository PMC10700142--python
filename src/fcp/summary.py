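"""Ensemble accounting and budget reporting.

The arithmetic behind the headline numbers: averaging per-model totals of
potential living tree carbon, contrasting model-design groups, and deriving
the land-use / carbon-pool breakdown of the deficit between current and
potential ecosystem carbon from a budget table (rows = land-use types,
columns = living / dead wood + litter / soil carbon, in Gt C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_DESIGN_PREFIXES = ("GS1", "GS2", "SD1", "SD2")
TYPE1_PREFIXES = ("GS1", "SD1")
TYPE2_PREFIXES = ("GS2", "SD2")

LAND_USE_ROWS = ("urban", "cropland", "pasture", "rangeland",
                 "low_human_pressure", "existing_forest")
POOL_COLUMNS = ("living", "dead_litter", "soil")


@dataclass
class ModelTotals:
    """Per-model totals of potential living tree carbon (Gt C)."""

    potential: dict[str, float]
    existing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in self.potential.items():
            if not label.startswith(VALID_DESIGN_PREFIXES):
                raise ValueError(f"unknown design label {label!r}")
            if value < 0:
                raise ValueError("totals must be non-negative")

    def group(self, prefixes: tuple[str, ...]) -> list[float]:
        return [v for k, v in self.potential.items() if k.startswith(prefixes)]


def ensemble_mean(totals: ModelTotals) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean across member models, with the min-max model range."""
    values = list(totals.potential.values())
    if not values:
        raise ValueError("no model totals")
    return float(np.mean(values)), (float(min(values)), float(max(values)))


def design_contrast(totals: ModelTotals,
                    group_a: tuple[str, ...] = TYPE1_PREFIXES,
                    group_b: tuple[str, ...] = TYPE2_PREFIXES) -> float:
    """mean(group_b) - mean(group_a) in Gt C (default: type 2 minus type 1)."""
    a = totals.group(group_a)
    b = totals.group(group_b)
    if not a or not b:
        raise ValueError("both design groups must be non-empty")
    return float(np.mean(b) - np.mean(a))


def relative_difference(a: float, b: float) -> dict[str, float]:
    """|a-b| as a percentage of the larger, smaller and average value."""
    d = abs(a - b)
    return {"of_larger": 100 * d / max(a, b),
            "of_smaller": 100 * d / min(a, b),
            "of_average": 100 * d / ((a + b) / 2)}


def budget_report(budget: pd.DataFrame) -> dict:
    """Summary table and derived shares from a land-use x pool budget.

    ``budget`` must carry the rows urban, cropland, pasture, rangeland,
    low_human_pressure, existing_forest and the columns living, dead_litter,
    soil (Gt C means).  A budget table quoted from a published source may
    carry its own margins — a ``total`` column and/or a ``sum`` row — which,
    when present, are honoured instead of re-summing independently rounded
    cells.  Shares are computed from unrounded values; display rounding
    (integer Gt, integer percent) is left to the caller.
    """
    for row in LAND_USE_ROWS:
        if row not in budget.index:
            raise ValueError(f"missing land-use row {row!r}")
    for col in POOL_COLUMNS:
        if col not in budget.columns:
            raise ValueError(f"missing carbon-pool column {col!r}")
    b = budget.loc[list(LAND_USE_ROWS), list(POOL_COLUMNS)].astype(float)
    if "total" in budget.columns:
        row_totals = budget.loc[list(LAND_USE_ROWS), "total"].astype(float)
    else:
        row_totals = b.sum(axis=1)
    if "sum" in budget.index:
        pool_totals = budget.loc["sum", list(POOL_COLUMNS)].astype(float)
    else:
        pool_totals = b.sum(axis=0)
    total = float(pool_totals.sum())

    urban_crop_pasture = float(row_totals[["urban", "cropland", "pasture"]].sum())
    outside = total - urban_crop_pasture
    conservation = float(row_totals["existing_forest"])
    restoration = outside - conservation
    converted = total - conservation
    converted_rows = row_totals.drop("existing_forest")

    report = {
        "total_deficit_gt": total,
        "pool_totals_gt": pool_totals.to_dict(),
        "pool_shares_pct": (100 * pool_totals / total).to_dict(),
        "land_use_totals_gt": row_totals.to_dict(),
        "urban_cropland_pasture_gt": urban_crop_pasture,
        "outside_urban_cropland_pasture_gt": outside,
        "conservation_gt": conservation,
        "restoration_gt": restoration,
        "conservation_share_pct": 100 * conservation / outside if outside else np.nan,
        "restoration_share_pct": 100 * restoration / outside if outside else np.nan,
        "converted_lands_gt": converted,
        "converted_shares_pct": (100 * converted_rows / converted).to_dict()
        if converted else {},
    }
    if converted:
        shares = report["converted_shares_pct"]
        report["livestock_share_pct"] = shares["pasture"] + shares["rangeland"]
    return report


def format_report(report: dict) -> str:
    """Human-readable report; Gt rounded to integers, shares to percent."""
    lines = [
        f"Total carbon deficit:                {report['total_deficit_gt']:.1f} Gt C",
        f"  outside urban/cropland/pasture:    {report['outside_urban_cropland_pasture_gt']:.0f} Gt C",
        f"  conservation (existing forest):    {report['conservation_gt']:.0f} Gt C"
        f" ({report['conservation_share_pct']:.0f}%)",
        f"  restoration (removed canopy):      {report['restoration_gt']:.0f} Gt C"
        f" ({report['restoration_share_pct']:.0f}%)",
        f"  converted lands:                   {report['converted_lands_gt']:.0f} Gt C",
        f"  urban+cropland+pasture:            {report['urban_cropland_pasture_gt']:.0f} Gt C",
        "Converted-land shares:",
    ]
    for name, share in report["converted_shares_pct"].items():
        lines.append(f"  {name:<20s} {share:.0f}%")
    lines.append(f"  livestock (pasture+rangeland): {report['livestock_share_pct']:.0f}%")
    lines.append("Carbon-pool shares:")
    for name, share in report["pool_shares_pct"].items():
        lines.append(f"  {name:<20s} {share:.0f}%")
    return "\n".join(lines)
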