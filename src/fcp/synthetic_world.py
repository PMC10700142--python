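"""Synthetic world generator.

Builds a self-contained landscape — environmental covariate rasters, eight
human-disturbance rasters, land-cover fractions, ancillary layers and a
tree-level inventory — around a known potential aboveground-carbon (AGC)
surface and a known degradation response.  The world provides ground truth
for every downstream stage: the potential surface depends on the environment
only, degradation multiplies it by ``(1 - H)**gamma`` where ``H`` is a fixed
mixture of the human layers, and inventory plots are calibrated so that plot
carbon density is an unbiased estimator of pixel current carbon.

Spatial autocorrelation is produced by Gaussian-filtering white noise
(``filter_sigma`` pixels, default 5), which is sufficient structure for the
spatial-subsampling and buffered cross-validation machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import make_grid, new_stack

BIOMES = ("boreal", "temperate", "dryland", "tropical")
BIOME_CODES = {name: i for i, name in enumerate(BIOMES)}

HUMAN_LAYERS = (
    "hum_cultivated", "hum_urban", "hum_cropland", "hum_grazing",
    "hum_pasture", "hum_rangeland", "hum_modification", "hum_infrastructure",
)
# mixture defining the scalar disturbance index H; the cumulative
# human-modification layer carries the largest weight
HUMAN_WEIGHTS = np.array([0.10, 0.10, 0.15, 0.10, 0.15, 0.10, 0.20, 0.10])

LAND_COVER_LAYERS = ("lc_urban", "lc_cropland", "lc_pasture", "lc_rangeland",
                     "lc_water", "lc_ice")

# reference log-log allometry (beta0, beta1) used to synthesize tree lists
REFERENCE_EQUATIONS = {
    "tropical": (-2.00, 2.45),
    "temperate": (-2.20, 2.45),
    "boreal": (-2.40, 2.40),
    "dryland": (-2.10, 2.35),
}
# biome wood carbon fractions; printed endpoints anchor tropical and temperate
CARBON_FRACTIONS = {"tropical": 0.456, "temperate": 0.501,
                    "boreal": 0.47, "dryland": 0.47}

# biome ceiling of the potential AGC surface, t C / ha
_BIOME_POTENTIAL = {"boreal": 70.0, "temperate": 120.0,
                    "dryland": 45.0, "tropical": 170.0}


@dataclass
class WorldConfig:
    """Parameters of the synthetic world."""

    grid_height: int = 128
    grid_width: int = 128
    lat_range: tuple[float, float] = (-32.0, 32.0)
    lon_range: tuple[float, float] = (0.0, 64.0)
    n_env: int = 40
    gamma_degradation: float = 1.0
    plot_density: float = 5.0       # plots per 100 pixels
    plot_area_m2: float = 250.0
    filter_sigma: float = 5.0
    dbh_min_cm: float = 5.0
    plot_noise_sigma: float = 0.15  # lognormal sd of plot biomass noise
    seed: int = 0
    year_range: tuple[int, int] = (1998, 2012)

    def __post_init__(self) -> None:
        if self.grid_height < 32 or self.grid_width < 32:
            raise ValueError("grid dimensions must be at least 32x32")
        if self.gamma_degradation < 0:
            raise ValueError("gamma_degradation must be >= 0")

    def biome_map(self) -> np.ndarray:
        """Four latitudinal bands, boreal poleward to tropical equatorward."""
        lats, _ = make_grid(self.grid_height, self.grid_width,
                            self.lat_range, self.lon_range)
        max_abs = max(abs(self.lat_range[0]), abs(self.lat_range[1]))
        frac = np.abs(lats) / max_abs
        code = np.full(lats.size, BIOME_CODES["tropical"])
        code[frac >= 0.25] = BIOME_CODES["dryland"]
        code[frac >= 0.50] = BIOME_CODES["temperate"]
        code[frac >= 0.75] = BIOME_CODES["boreal"]
        return np.repeat(code[:, None], self.grid_width, axis=1)


@dataclass
class GroundTruth:
    """Known truth of the synthetic world (rasters on the covariate grid)."""

    potential_agc: xr.DataArray
    degradation_multiplier: xr.DataArray
    current_agc: xr.DataArray
    potential_canopy: xr.DataArray
    current_canopy: xr.DataArray

    def as_dataset(self) -> xr.Dataset:
        return xr.Dataset({
            "potential_agc": self.potential_agc,
            "degradation_multiplier": self.degradation_multiplier,
            "current_agc": self.current_agc,
            "potential_canopy": self.potential_canopy,
            "current_canopy": self.current_canopy,
        })


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, standardized to zero mean / unit sd."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_covariates(config: WorldConfig) -> xr.Dataset:
    """Environmental, human-disturbance and ancillary rasters.

    Human layers are scaled to [0, 1] with zero meaning no human impact; the
    binary minimal-disturbance mask marks the least-pressured fifth of the
    landscape, where all human layers are forced to zero.
    """
    shape = (config.grid_height, config.grid_width)
    rng = np.random.default_rng(config.seed)
    lats, lons = make_grid(config.grid_height, config.grid_width,
                           config.lat_range, config.lon_range)
    sigma = config.filter_sigma

    layers: dict[str, np.ndarray] = {}
    env_names = []
    for i in range(config.n_env):
        name = f"env_{i:02d}"
        layers[name] = _smooth_field(rng, shape, sigma)
        env_names.append(name)

    # latent human-pressure field, independent of the environmental layers
    pressure = expit(1.5 * _smooth_field(rng, shape, sigma))
    minimal = pressure < np.quantile(pressure, 0.20)
    pressure = np.where(minimal, 0.0, pressure)
    for j, name in enumerate(HUMAN_LAYERS):
        weight = rng.uniform(0.55, 1.0)
        wiggle = 0.15 * _smooth_field(rng, shape, sigma)
        layer = np.clip(pressure * (weight + wiggle), 0.0, 1.0)
        layer[minimal] = 0.0
        layers[name] = layer
    layers["minimal_disturbance"] = minimal.astype(float)

    # land-cover fractions derived from the matching human layers
    layers["lc_urban"] = 0.10 * layers["hum_urban"]
    layers["lc_cropland"] = 0.45 * layers["hum_cropland"]
    layers["lc_pasture"] = 0.30 * layers["hum_pasture"]
    layers["lc_rangeland"] = 0.25 * layers["hum_rangeland"]
    water = _smooth_field(rng, shape, sigma)
    layers["lc_water"] = 0.5 * (water > np.quantile(water, 0.97))
    ice = np.zeros(shape)
    polar = np.abs(lats) > 0.95 * np.abs(lats).max()
    ice[polar, :] = 0.3
    layers["lc_ice"] = ice
    total = sum(layers[k] for k in LAND_COVER_LAYERS)
    scale = np.where(total > 0.98, 0.98 / np.maximum(total, 1e-12), 1.0)
    for k in LAND_COVER_LAYERS:
        layers[k] = layers[k] * scale
    plantation_field = _smooth_field(rng, shape, sigma)
    layers["lc_plantation"] = 0.3 * (
        plantation_field > np.quantile(plantation_field, 0.92))

    rmf = np.clip(0.18 + 0.08 * _smooth_field(rng, shape, sigma), 0.02, 0.6)
    layers["rmf"] = rmf
    layers["rmf_low"] = np.clip(rmf - 0.04, 0.01, 0.6)
    layers["rmf_high"] = np.clip(rmf + 0.04, 0.01, 0.6)

    soil = 30.0 * np.clip(_smooth_field(rng, shape, sigma) + 1.5, 0.0, None)
    layers["soil_potential"] = soil
    layers["soil_error"] = 0.25 * soil

    layers["biome_code"] = config.biome_map().astype(float)

    attrs = {"env_layers": list(env_names),
             "human_layers": list(HUMAN_LAYERS),
             "seed": config.seed}
    return new_stack(layers, lats, lons, attrs=attrs)


def disturbance_index(stack: xr.Dataset) -> xr.DataArray:
    """Scalar human-disturbance index H in [0, 1] (fixed layer mixture)."""
    h = sum(w * stack[name] for w, name in zip(HUMAN_WEIGHTS, HUMAN_LAYERS))
    return h / HUMAN_WEIGHTS.sum()


def generate_truth(stack: xr.Dataset, config: WorldConfig) -> GroundTruth:
    """Potential AGC from the environment only; degradation = (1 - H)**gamma."""
    biome = stack["biome_code"].values.astype(int)
    ceiling = np.vectorize(lambda c: _BIOME_POTENTIAL[BIOMES[c]])(biome)
    signal = expit(0.9 * stack["env_00"].values
                   + 0.6 * stack["env_01"].values
                   - 0.4 * stack["env_02"].values)
    potential = ceiling * (0.35 + 0.85 * signal)

    h = disturbance_index(stack).values
    multiplier = np.power(1.0 - h, config.gamma_degradation)
    current = potential * multiplier

    potential_canopy = np.clip((potential - 15.0) / 150.0, 0.0, 0.95)
    converted = np.clip(stack["lc_urban"].values + stack["lc_cropland"].values
                        + stack["lc_pasture"].values, 0.0, 0.95)
    current_canopy = potential_canopy * (1.0 - converted)

    coords = {"lat": stack["lat"].values, "lon": stack["lon"].values}

    def da(arr: np.ndarray) -> xr.DataArray:
        return xr.DataArray(arr, coords=coords, dims=("lat", "lon"))

    return GroundTruth(
        potential_agc=da(potential),
        degradation_multiplier=da(multiplier),
        current_agc=da(current),
        potential_canopy=da(potential_canopy),
        current_canopy=da(current_canopy),
    )


def _truncated_weibull(rng: np.random.Generator, n: int, shape_k: float,
                       scale: float, minimum: float) -> np.ndarray:
    """Inverse-CDF sampling of a Weibull left-truncated at ``minimum``."""
    u0 = 1.0 - np.exp(-((minimum / scale) ** shape_k))
    u = u0 + (1.0 - u0) * rng.random(n)
    return scale * (-np.log1p(-u)) ** (1.0 / shape_k)


_WEIBULL_SHAPE = 1.8
_WEIBULL_SCALE = 14.0


def _mean_tree_biomass(beta0: float, beta1: float, dbh_min: float) -> float:
    """Expected per-tree biomass under the truncated-Weibull DBH law."""
    from scipy import integrate, stats

    dist = stats.weibull_min(_WEIBULL_SHAPE, scale=_WEIBULL_SCALE)
    trunc_mass = dist.sf(dbh_min)

    def integrand(d: float) -> float:
        return np.exp(beta0 + beta1 * np.log(d)) * dist.pdf(d) / trunc_mass

    value, _ = integrate.quad(integrand, dbh_min, 400.0, limit=200)
    return float(value)


def sample_inventory(truth: GroundTruth, config: WorldConfig) -> pd.DataFrame:
    """Tree-level inventory calibrated to the pixel current-AGC surface.

    Plots land preferentially (not exclusively) in pixels with canopy; stem
    counts are scaled so that plot biomass under the world's reference
    allometry matches ``current_agc * canopy_plot / canopy_pixel`` up to
    multiplicative lognormal noise, making recomputed plot carbon an unbiased
    estimator of pixel current carbon.

    Returns a table with one row per tree:
    ``plot_id, lat, lon, year, area_m2, tree_id, dbh_cm, wood_density``.
    """
    canopy = truth.current_canopy.values
    if float(np.nanmax(canopy)) < 0.10:
        raise ValueError("no pixel has canopy cover >= 10%; cannot place plots")

    rng = np.random.default_rng([config.seed, 7919])
    h, w = canopy.shape
    lats = truth.current_canopy["lat"].values
    lons = truth.current_canopy["lon"].values
    dlat = float(np.abs(np.diff(lats)).mean())
    dlon = float(np.abs(np.diff(lons)).mean())

    n_plots = int(round(config.plot_density * h * w / 100.0))
    prob = (canopy + 0.05).ravel()
    prob = prob / prob.sum()
    cells = rng.choice(h * w, size=n_plots, replace=True, p=prob)

    biome_codes = config.biome_map()
    mean_biomass = {b: _mean_tree_biomass(*REFERENCE_EQUATIONS[b], config.dbh_min_cm)
                    for b in BIOMES}
    area_ha = config.plot_area_m2 / 1e4
    sigma = config.plot_noise_sigma
    current = truth.current_agc.values

    records: list[tuple] = []
    for plot_id, cell in enumerate(cells):
        r, c = divmod(int(cell), w)
        lat = lats[r] + dlat * rng.uniform(-0.45, 0.45)
        lon = lons[c] + dlon * rng.uniform(-0.45, 0.45)
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        biome = BIOMES[int(biome_codes[r, c])]
        cf = CARBON_FRACTIONS[biome]
        cpix = canopy[r, c]
        cplot = float(np.clip(cpix * rng.uniform(0.9, 1.1), 0.0, 1.0))
        if cpix <= 0 or cplot <= 0:
            records.append((plot_id, lat, lon, year, config.plot_area_m2,
                            -1, np.nan, np.nan))
            continue
        density = current[r, c] * cplot / cpix  # t C / ha at plot scale
        density *= float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
        target_kg = density * area_ha * 1000.0 / cf
        n_trees = int(round(target_kg / mean_biomass[biome]))
        if n_trees == 0:
            records.append((plot_id, lat, lon, year, config.plot_area_m2,
                            -1, np.nan, np.nan))
            continue
        dbhs = _truncated_weibull(rng, n_trees, _WEIBULL_SHAPE,
                                  _WEIBULL_SCALE, config.dbh_min_cm)
        wd = np.clip(rng.normal(0.6, 0.08, n_trees), 0.3, 0.9)
        for t in range(n_trees):
            records.append((plot_id, lat, lon, year, config.plot_area_m2,
                            t, float(dbhs[t]), float(wd[t])))

    return pd.DataFrame(records, columns=[
        "plot_id", "lat", "lon", "year", "area_m2",
        "tree_id", "dbh_cm", "wood_density"])


def generate_world(config: WorldConfig) -> tuple[xr.Dataset, GroundTruth, pd.DataFrame]:
    """Convenience wrapper: covariates, truth and inventory in one call."""
    stack = generate_covariates(config)
    truth = generate_truth(stack, config)
    trees = sample_inventory(truth, config)
    return stack, truth, trees
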