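"""Ensemble random-forest modelling of current and potential tree carbon.

Current pixel carbon is regressed on environmental covariates, the eight
human-disturbance covariates and canopy cover.  The counterfactual "no
human disturbance" prediction comes in two designs:

* type 1 (GS1/SD1): train on all observations, then predict with every
  human covariate set to zero;
* type 2 (GS2/SD2): train only on minimally disturbed observations with the
  human covariates excluded, then extrapolate everywhere.

In both designs the canopy covariate is replaced by potential canopy cover
at prediction time and predictions are masked to potential canopy >= 10%.
Each ensemble member is fitted on a spatially subsampled bootstrap (one
random observation per grid cell; 0.7 deg for GS1, 0.25 deg for GS2, 1.0 deg
for SD2, simple random sampling for SD1) with hyperparameters chosen by the
highest tenfold-CV R^2 over a configured grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .raster import check_aligned, pixel_area_ha

log = logging.getLogger(__name__)

DESIGNS = ("GS1", "GS2", "SD1", "SD2")
TYPE1_DESIGNS = ("GS1", "SD1")
TYPE2_DESIGNS = ("GS2", "SD2")

# per-design spatial subsample grids (degrees); SD1 draws simple random
# samples because raster-derived observations are evenly distributed
DEFAULT_GRID_DEG = {"GS1": 0.7, "GS2": 0.25, "SD1": None, "SD2": 1.0}

POTENTIAL_CANOPY_MIN = 0.10
MIN_TRAINING_ROWS = 50


def default_hyperparameter_grid() -> list[dict]:
    """12 candidate settings over trees / feature fraction / leaf size."""
    grid = []
    for n, mf, leaf in itertools.product((25, 50), (0.33, 0.6, 1.0), (2, 5)):
        grid.append({"n_estimators": n, "max_features": mf,
                     "min_samples_leaf": leaf})
    return grid


@dataclass
class ModelSpec:
    design: str = "GS1"
    n_bootstrap: int = 100
    subsample_grid_deg: float | None = None
    hyperparameter_grid: list[dict] = field(default_factory=default_hyperparameter_grid)
    n_cv_folds: int = 10
    sd_sample_target: int = 4500   # SD1 simple-random sample size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if self.subsample_grid_deg is None:
            self.subsample_grid_deg = DEFAULT_GRID_DEG[self.design]
        if self.subsample_grid_deg is not None and self.subsample_grid_deg <= 0:
            raise ValueError("subsample grid must be positive")

    @property
    def is_type1(self) -> bool:
        return self.design in TYPE1_DESIGNS


@dataclass
class FittedMember:
    model: RandomForestRegressor
    params: dict
    cv_score: float
    features: list[str]


@dataclass
class EnsembleModel:
    spec: ModelSpec
    members: list[FittedMember]
    env_cols: list[str]
    human_cols: list[str]
    canopy_col: str


@dataclass
class EnsemblePrediction:
    """Per-pixel ensemble mean, coefficient of variation and 5/95% quantiles."""
    mean: xr.DataArray
    cv: xr.DataArray
    q05: xr.DataArray
    q95: xr.DataArray


def spatial_subsample(table: pd.DataFrame, grid_deg: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """One uniformly chosen row per non-empty ``grid_deg`` lat/lon cell."""
    if len(table) == 0:
        raise ValueError("empty table")
    cell = (np.floor(table["lat"].to_numpy() / grid_deg).astype(np.int64) * 2**20
            + np.floor(table["lon"].to_numpy() / grid_deg).astype(np.int64))
    order = rng.permutation(len(table))
    shuffled_cell = cell[order]
    _, first = np.unique(shuffled_cell, return_index=True)
    picked = order[first]
    return table.iloc[np.sort(picked)].reset_index(drop=True)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray,
                         grid: list[dict], n_folds: int,
                         seed: int) -> tuple[dict, float]:
    """Grid search by mean tenfold-CV R^2; returns (best params, best score)."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for train, test in splits:
            rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
            rf.fit(X[train], y[train])
            scores.append(r2_score(y[test], rf.predict(X[test])))
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score


def fit_current_model(subsample: pd.DataFrame, spec: ModelSpec,
                      features: list[str], response: str,
                      seed: int | None = None) -> FittedMember:
    """Fit one ensemble member with grid-searched hyperparameters."""
    if len(subsample) < MIN_TRAINING_ROWS:
        raise ValueError(
            f"only {len(subsample)} training rows; need >= {MIN_TRAINING_ROWS}")
    seed = spec.seed if seed is None else seed
    X = subsample[features].to_numpy(dtype=float)
    y = subsample[response].to_numpy(dtype=float)
    params, score = tune_hyperparameters(X, y, spec.hyperparameter_grid,
                                         spec.n_cv_folds, seed)
    rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    rf.fit(X, y)
    return FittedMember(model=rf, params=params, cv_score=score,
                        features=list(features))


def fit_ensemble(table: pd.DataFrame, spec: ModelSpec,
                 env_cols: list[str], human_cols: list[str],
                 canopy_col: str, response: str,
                 minimal_col: str = "minimal_disturbance") -> EnsembleModel:
    """Bootstrapped spatial subsampling + per-subsample grid search."""
    if spec.is_type1:
        data = table
        features = env_cols + human_cols + [canopy_col]
    else:
        data = table[table[minimal_col] >= 0.5]
        features = env_cols + [canopy_col]
    if len(data) < MIN_TRAINING_ROWS:
        raise ValueError("too few training rows for design " + spec.design)

    members = []
    for b in range(spec.n_bootstrap):
        rng = np.random.default_rng([spec.seed, b])
        member_seed = int(rng.integers(2**31 - 1))
        if spec.subsample_grid_deg is None:
            n = min(spec.sd_sample_target, len(data))
            sub = data.iloc[rng.choice(len(data), size=n, replace=True)]
        else:
            sub = spatial_subsample(data, spec.subsample_grid_deg, rng)
        members.append(fit_current_model(sub, spec, features, response,
                                         seed=member_seed))
    log.info("fitted %d ensemble members for %s", len(members), spec.design)
    return EnsembleModel(spec=spec, members=members, env_cols=env_cols,
                         human_cols=human_cols, canopy_col=canopy_col)


def _grid_features(ensemble: EnsembleModel, stack: xr.Dataset,
                   canopy: xr.DataArray, zero_human: bool) -> np.ndarray:
    """Per-pixel feature matrix in ensemble feature order."""
    n_pix = stack.sizes["lat"] * stack.sizes["lon"]
    cols = []
    for name in ensemble.members[0].features:
        if name == ensemble.canopy_col:
            cols.append(canopy.values.ravel())
        elif name in ensemble.human_cols and zero_human:
            cols.append(np.zeros(n_pix))
        else:
            cols.append(stack[name].values.ravel())
    return np.column_stack(cols)


def _summarize(preds: np.ndarray, template: xr.DataArray,
               mask: np.ndarray) -> EnsemblePrediction:
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), 0.0)
    q05 = np.quantile(preds, 0.05, axis=0)
    q95 = np.quantile(preds, 0.95, axis=0)

    def wrap(v: np.ndarray) -> xr.DataArray:
        out = np.where(mask, v, np.nan).reshape(template.shape)
        return xr.DataArray(out, coords=template.coords, dims=template.dims)

    return EnsemblePrediction(mean=wrap(mean), cv=wrap(cv),
                              q05=wrap(q05), q95=wrap(q95))


def predict_potential(ensemble: EnsembleModel, stack: xr.Dataset,
                      potential_canopy: xr.DataArray) -> EnsemblePrediction:
    """Counterfactual prediction masked to potential canopy >= 10%.

    Type-1 ensembles predict with all human covariates set to zero; type-2
    ensembles carry no human covariates.  The canopy covariate is replaced
    by potential canopy for every member.
    """
    if potential_canopy is None:
        raise ValueError("potential canopy layer is required")
    check_aligned(stack, potential_canopy)
    X = _grid_features(ensemble, stack, potential_canopy, zero_human=True)
    preds = np.stack([m.model.predict(X) for m in ensemble.members])
    mask = potential_canopy.values.ravel() >= POTENTIAL_CANOPY_MIN
    return _summarize(preds, potential_canopy, mask)


def predict_current(ensemble: EnsembleModel, stack: xr.Dataset,
                    current_canopy: xr.DataArray,
                    mask_canopy: xr.DataArray | None = None) -> EnsemblePrediction:
    """As-observed prediction (human covariates at their observed values)."""
    check_aligned(stack, current_canopy)
    X = _grid_features(ensemble, stack, current_canopy, zero_human=False)
    preds = np.stack([m.model.predict(X) for m in ensemble.members])
    ref = mask_canopy if mask_canopy is not None else current_canopy
    mask = np.isfinite(ref.values.ravel())
    if mask_canopy is not None:
        mask &= ref.values.ravel() >= POTENTIAL_CANOPY_MIN
    return _summarize(preds, current_canopy, mask)


def add_root_carbon(agc: xr.DataArray, rmf: xr.DataArray,
                    rmf_bounds: tuple[xr.DataArray, xr.DataArray] | None = None,
                    agc_bounds: tuple[xr.DataArray, xr.DataArray] | None = None,
                    mode: str = "fraction_of_total",
                    ) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray]:
    """Total living carbon from aboveground carbon and root mass fraction.

    With ``mode="fraction_of_total"`` (RMF = root mass / total mass) the
    total is ``agc / (1 - rmf)``; with ``mode="multiplier"`` it is
    ``agc * (1 + rmf)``.  Bounds combine the AGC and RMF ranges by endpoint
    combinations.
    """
    def scale(a: xr.DataArray, r: xr.DataArray) -> xr.DataArray:
        if mode == "fraction_of_total":
            if float((r >= 1).sum()) > 0:
                raise ValueError("root mass fraction must be < 1")
            return a / (1.0 - r)
        if mode == "multiplier":
            return a * (1.0 + r)
        raise ValueError(f"unknown root scaling mode {mode!r}")

    total = scale(agc, rmf)
    a_lo, a_hi = agc_bounds if agc_bounds is not None else (agc, agc)
    r_lo, r_hi = rmf_bounds if rmf_bounds is not None else (rmf, rmf)
    corners = [scale(a, r) for a in (a_lo, a_hi) for r in (r_lo, r_hi)]
    low = xr.concat(corners, dim="corner").min("corner")
    high = xr.concat(corners, dim="corner").max("corner")
    return total, low, high


def total_stock(density: xr.DataArray,
                mask: xr.DataArray | np.ndarray | None = None) -> float:
    """Gt C stored over the masked pixels: sum(density * cos-lat pixel area)."""
    dens = density.values
    if np.any(dens[np.isfinite(dens)] < 0):
        raise ValueError("negative carbon densities")
    area = pixel_area_ha(density).values
    m = np.isfinite(dens)
    if mask is not None:
        m &= np.asarray(mask.values if hasattr(mask, "values") else mask, bool)
    return float(np.sum(dens[m] * area[m]) / 1e9)
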