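"""Tree- and plot-level biomass and carbon.

Individual aboveground dry biomass W (kg) follows the log-log allometry
``ln W = beta0 + beta1 * ln DBH`` with biome-level coefficients obtained by
refitting pooled pseudo-data back-calculated from source equations.  Tropical
trees may instead use a wood-density power law ``W = a * (rho * DBH^2)**b``.
Plot carbon density (t C ha^-1) sums tree biomass, divides by plot area and
applies a biome wood-carbon fraction; outliers are screened with a
median +/- k*MAD rule on log(x+1)-transformed densities and a hard cap at
the maximum density ever recorded for forests (1,867 t C ha^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

MAX_FOREST_DENSITY = 1867.0  # t C / ha, densest forest on record

# DBH grid of the back-calculated pseudo dataset: 1-cm steps from 5 to 25,
# 5-cm steps to 100, 10-cm steps to 300; shared endpoints belong to the
# finer bin and are emitted once.
PSEUDO_DBH_GRID = np.concatenate([
    np.arange(5, 26, 1.0),
    np.arange(30, 101, 5.0),
    np.arange(110, 301, 10.0),
])

# default pantropical power-law coefficients, configurable
TROPICAL_COEFFS = (0.0673, 0.976)


@dataclass(frozen=True)
class AllometricEquation:
    """Log-log DBH allometry ``ln W = beta0 + beta1 ln DBH`` (W in kg)."""

    beta0: float
    beta1: float
    dbh_range: tuple[float, float] = (5.0, 300.0)
    biome: str = ""
    beta0_se: float = float("nan")
    beta1_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError("beta1 must be positive")


@dataclass(frozen=True)
class WoodParams:
    """Wood density (g cm^-3) and carbon fraction of dry biomass."""

    wood_density: float = 0.6
    carbon_fraction: float = 0.47

    def __post_init__(self) -> None:
        if not 0.2 <= self.wood_density <= 1.2:
            raise ValueError("wood_density outside plausible range")
        if not 0.40 <= self.carbon_fraction <= 0.55:
            raise ValueError("carbon_fraction outside plausible range")


@dataclass
class PlotCarbon:
    plot_id: int
    lat: float
    lon: float
    carbon_density: float      # t C / ha
    canopy_cover_plot: float
    n_trees: int
    year: float
    biome: str = ""


def predict_biomass(dbh: float | np.ndarray, eq: AllometricEquation) -> np.ndarray:
    """Aboveground dry biomass (kg) from DBH (cm)."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("DBH must be positive")
    return np.exp(eq.beta0 + eq.beta1 * np.log(dbh))


def predict_biomass_tropical(dbh: float | np.ndarray,
                             wood_density: float | np.ndarray | None,
                             coeffs: tuple[float, float] = TROPICAL_COEFFS,
                             fallback_density: float = 0.6) -> np.ndarray:
    """Pantropical wood-density power law ``W = a * (rho * DBH^2)**b``."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("DBH must be positive")
    a, b = coeffs
    rho = np.asarray(wood_density, dtype=float) if wood_density is not None \
        else np.full_like(dbh, np.nan)
    missing = ~np.isfinite(rho)
    if np.any(missing):
        log.info("wood density missing for %d trees; using biome-median %.2f",
                 int(np.sum(missing)), fallback_density)
        rho = np.where(missing, fallback_density, rho)
    return a * (rho * dbh ** 2) ** b


def generate_pseudo_data(eq: AllometricEquation) -> pd.DataFrame:
    """Back-calculated (DBH, biomass) pairs on the fixed 56-point DBH grid."""
    return pd.DataFrame({
        "dbh_cm": PSEUDO_DBH_GRID,
        "biomass_kg": predict_biomass(PSEUDO_DBH_GRID, eq),
    })


def fit_biome_equation(pseudo: pd.DataFrame, biome: str = "") -> AllometricEquation:
    """OLS of ln(biomass) on ln(DBH) over pooled pseudo-data."""
    if len(pseudo) == 0:
        raise ValueError("empty pseudo-data")
    dbh = pseudo["dbh_cm"].to_numpy(dtype=float)
    if np.unique(dbh).size < 2:
        raise ValueError("degenerate design: need at least 2 distinct DBH values")
    y = np.log(pseudo["biomass_kg"].to_numpy(dtype=float))
    X = sm.add_constant(np.log(dbh))
    res = sm.OLS(y, X).fit()
    return AllometricEquation(
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        dbh_range=(float(dbh.min()), float(dbh.max())), biome=biome,
        beta0_se=float(res.bse[0]), beta1_se=float(res.bse[1]))


def plot_carbon_density(trees: pd.DataFrame, plot_area_m2: float,
                        equations: dict[str, AllometricEquation],
                        wood: WoodParams, biome: str = "",
                        tropical_power_law: bool = False) -> PlotCarbon:
    """Plot carbon density from a tree table of one plot.

    Multi-year plots are averaged with equal weight per calendar year.  Rows
    with non-finite DBH (placeholder rows of empty plots) contribute nothing.
    """
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be positive")
    area_ha = plot_area_m2 / 1e4
    valid = trees[np.isfinite(trees["dbh_cm"])] if len(trees) else trees

    def one_year(sub: pd.DataFrame) -> float:
        if len(sub) == 0:
            return 0.0
        if tropical_power_law:
            w = predict_biomass_tropical(sub["dbh_cm"].to_numpy(),
                                         sub.get("wood_density"),
                                         fallback_density=wood.wood_density)
        else:
            w = predict_biomass(sub["dbh_cm"].to_numpy(), equations[biome])
        return float(w.sum()) / 1000.0 / area_ha * wood.carbon_fraction

    if len(valid):
        density = float(np.mean([one_year(g) for _, g in valid.groupby("year")]))
    else:
        density = 0.0
    first = trees.iloc[0] if len(trees) else None
    return PlotCarbon(
        plot_id=int(first["plot_id"]) if first is not None else -1,
        lat=float(first["lat"]) if first is not None else np.nan,
        lon=float(first["lon"]) if first is not None else np.nan,
        carbon_density=density,
        canopy_cover_plot=float(first["canopy_plot"]) if first is not None
        and "canopy_plot" in trees.columns else np.nan,
        n_trees=int(len(valid)),
        year=float(valid["year"].mean()) if len(valid)
        else (float(first["year"]) if first is not None else np.nan),
        biome=biome)


def mad_filter(values: np.ndarray, k: float = 2.5,
               transform: bool = True) -> np.ndarray:
    """Keep mask: |t - median(t)| <= k * MAD(t), t = ln(x+1) when transformed.

    MAD is the raw median absolute deviation (no consistency constant).  A
    zero MAD keeps only values equal to the median.
    """
    x = np.asarray(values, dtype=float)
    t = np.log1p(x) if transform else x
    med = np.median(t)
    mad = np.median(np.abs(t - med))
    return np.abs(t - med) <= k * mad


def apply_plot_filters(plots: pd.DataFrame, k: float = 2.5,
                       human_col: str = "human_index",
                       canopy_col: str = "canopy_pixel",
                       density_col: str = "carbon_density",
                       biome_col: str = "biome") -> pd.DataFrame:
    """Density cap plus per-biome MAD screen with the non-forest exception.

    Densities above the 1,867 t C ha^-1 cap are always removed.  MAD outliers
    are removed per biome, except low-side outliers in human-modified
    non-forest pixels (human index > 0.10 and canopy < 0.10), which are kept
    so that trees outside forests are not discarded.  Plots sharing a pixel
    should be averaged afterwards (see ``plot_pixel``).
    """
    df = plots.copy()
    n0 = len(df)
    df = df[df[density_col] <= MAX_FOREST_DENSITY]
    if n0 - len(df):
        log.info("removed %d plots above the %.0f t C/ha cap",
                 n0 - len(df), MAX_FOREST_DENSITY)

    keep = np.ones(len(df), dtype=bool)
    dens = df[density_col].to_numpy(dtype=float)
    for biome in df[biome_col].unique():
        idx = np.flatnonzero((df[biome_col] == biome).to_numpy())
        if idx.size == 0:
            continue
        mask = mad_filter(dens[idx], k=k, transform=True)
        t = np.log1p(dens[idx])
        low_side = t < np.median(t)
        exempt = ((df[human_col].to_numpy()[idx] > 0.10)
                  & (df[canopy_col].to_numpy()[idx] < 0.10))
        keep[idx] = mask | (~mask & low_side & exempt)
    out = df[keep]
    log.info("MAD filter removed %d of %d plots", len(df) - len(out), len(df))
    return out
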