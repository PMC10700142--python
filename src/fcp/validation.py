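"""Model diagnostics.

Covers the spatial-statistics checks used to validate the carbon models:
Moran's I of residuals in great-circle distance bands, spatially buffered
leave-one-out cross-validation, the R^2 against the 1:1 line, a PCA
convex-hull map of covariate-space extrapolation, and the partial regression
of carbon density on the first principal component of the human-disturbance
layers controlling for the environmental covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .raster import EARTH_RADIUS_KM

log = logging.getLogger(__name__)


def haversine_km(lat1: np.ndarray, lon1: np.ndarray,
                 lat2: np.ndarray, lon2: np.ndarray) -> np.ndarray:
    """Great-circle distance in km (inputs in degrees, broadcastable)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pairwise_distances_km(coords: np.ndarray) -> np.ndarray:
    lat = coords[:, 0]
    lon = coords[:, 1]
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


@dataclass
class MoranResult:
    distance_bins: np.ndarray        # (n_bins, 2) km edges
    moran_i: np.ndarray
    expected_i: float                # -1 / (n - 1)
    p_value: np.ndarray
    autocorrelation_range_km: float  # upper edge of last significantly
                                     # positive leading bin


def moran_statistic(residuals: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I for a fixed (not necessarily symmetric) weight matrix."""
    z = residuals - residuals.mean()
    s0 = weights.sum()
    if s0 == 0:
        return float("nan")
    n = residuals.size
    return float(n / s0 * (z @ weights @ z) / (z @ z))


def morans_i(residuals: np.ndarray, coords: np.ndarray,
             distance_bins: np.ndarray | None = None,
             n_permutations: int = 199, alpha: float = 0.05,
             seed: int = 0) -> MoranResult:
    """Moran's I per distance band with permutation p-values.

    ``coords`` is (n, 2) latitude/longitude in degrees; bands use binary
    weights on the great-circle distance.  ``p_value`` is the one-sided
    (positive autocorrelation) permutation p-value per band.
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n < 10:
        raise ValueError("need at least 10 residuals")
    if residuals.std() == 0:
        raise ValueError("zero-variance residuals")
    dist = pairwise_distances_km(np.asarray(coords, dtype=float))
    if distance_bins is None:
        top = float(dist.max())
        edges = np.arange(0.0, top + 20.0, 20.0)
        distance_bins = np.column_stack([edges[:-1], edges[1:]])
    distance_bins = np.asarray(distance_bins, dtype=float)

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_permutations)]

    i_obs = np.full(len(distance_bins), np.nan)
    p_val = np.full(len(distance_bins), np.nan)
    for k, (lo, hi) in enumerate(distance_bins):
        w = ((dist > lo) & (dist <= hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        if w.sum() == 0:
            continue
        i_obs[k] = moran_statistic(residuals, w)
        null = np.array([moran_statistic(residuals[p], w) for p in perms])
        p_val[k] = (1 + np.sum(null >= i_obs[k])) / (1 + n_permutations)

    significant = (p_val <= alpha) & np.isfinite(i_obs)
    auto_range = 0.0
    for k in range(len(distance_bins)):
        if significant[k]:
            auto_range = float(distance_bins[k, 1])
        else:
            break
    return MoranResult(distance_bins=distance_bins, moran_i=i_obs,
                       expected_i=-1.0 / (n - 1), p_value=p_val,
                       autocorrelation_range_km=auto_range)


def r2_one_to_one(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination relative to the 1:1 line; may be < 0."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size or o.size < 2:
        raise ValueError("need two equal-length vectors of n >= 2")
    denom = np.sum((o - o.mean()) ** 2)
    if denom == 0:
        raise ValueError("zero variance in observations")
    return float(1.0 - np.sum((o - p) ** 2) / denom)


def buffered_loocv(table: pd.DataFrame, model_factory: Callable,
                   features: list[str], response: str,
                   buffer_km: float) -> tuple[np.ndarray, float]:
    """Spatially buffered leave-one-out cross-validation.

    Each point is predicted by a model trained on all points farther than
    ``buffer_km`` away; returns (per-point predictions, R^2 to the 1:1 line).
    ``model_factory()`` must return an unfitted sklearn-style regressor.
    """
    if buffer_km < 0:
        raise ValueError("buffer must be >= 0")
    coords = table[["lat", "lon"]].to_numpy(dtype=float)
    dist = pairwise_distances_km(coords)
    X = table[features].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    n = len(table)
    preds = np.empty(n)
    for i in range(n):
        train = dist[i] > buffer_km
        train[i] = False
        if not np.any(train):
            raise ValueError(f"point {i}: buffer excludes all training data")
        model = model_factory()
        model.fit(X[train], y[train])
        preds[i] = model.predict(X[i:i + 1])[0]
    return preds, r2_one_to_one(y, preds)


@dataclass
class HullDiagnostic:
    n_components: int
    n_hulls: int
    inside_fraction: np.ndarray   # per prediction point
    summary: float                # share of points inside >= 95% of hulls


def hull_coverage(training_covariates: np.ndarray,
                  prediction_pixels: np.ndarray,
                  variance_target: float = 0.90) -> HullDiagnostic:
    """PCA convex-hull extrapolation diagnostic.

    Training covariates are standardized (training means/scales), projected
    on the principal components that cumulatively explain at least
    ``variance_target`` of the variance, and 2-D convex hulls are built for
    every component pair.  Each prediction pixel reports the fraction of
    hulls containing it (boundary counts as inside).
    """
    train = np.asarray(training_covariates, dtype=float)
    if train.shape[0] < 3:
        raise ValueError("need at least 3 training points")
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    scale[scale == 0] = 1.0
    pca = PCA()
    t_scores = pca.fit_transform((train - mean) / scale)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target) + 1)
    n_comp = min(n_comp, t_scores.shape[1])
    p_scores = ((np.asarray(prediction_pixels, dtype=float) - mean) / scale) \
        @ pca.components_.T

    n_points = p_scores.shape[0]
    inside_counts = np.zeros(n_points)
    n_hulls = 0
    for a in range(n_comp):
        for b in range(a + 1, n_comp):
            pts = t_scores[:, [a, b]]
            try:
                hull = ConvexHull(pts)
            except QhullError:
                log.warning("degenerate hull for component pair (%d, %d); "
                            "skipped", a, b)
                continue
            n_hulls += 1
            # inside iff every facet inequality A x + b <= 0 (within tol)
            A = hull.equations[:, :2]
            c = hull.equations[:, 2]
            vals = p_scores[:, [a, b]] @ A.T + c
            inside_counts += np.all(vals <= 1e-9, axis=1)
    frac = inside_counts / max(n_hulls, 1)
    return HullDiagnostic(n_components=n_comp, n_hulls=n_hulls,
                          inside_fraction=frac,
                          summary=float(np.mean(frac >= 0.95)))


@dataclass
class PartialRegressionResult:
    slope: float
    conf_int: tuple[float, float]
    p_value: float
    pc1_scores: np.ndarray
    loadings: np.ndarray


def disturbance_partial_regression(carbon: np.ndarray,
                                   covariates_env: np.ndarray,
                                   human_layers: np.ndarray,
                                   relative: bool = True,
                                   ) -> PartialRegressionResult:
    """Partial regression of carbon on the human-disturbance PC1.

    PC1 of the (standardized) human layers is oriented so that larger scores
    mean more disturbance (sign of the loading sum); carbon and PC1 are both
    residualized on the environmental controls (Frisch-Waugh) and the slope
    of the residual-on-residual regression is reported with its 95% CI.
    With ``relative=True`` carbon is first divided by its global mean.
    """
    y = np.asarray(carbon, dtype=float)
    env = np.asarray(covariates_env, dtype=float)
    hum = np.asarray(human_layers, dtype=float)
    n = y.size
    if n <= env.shape[1]:
        raise ValueError("need more observations than environmental controls")
    if relative:
        y = y / y.mean()

    scale = hum.std(axis=0)
    scale[scale == 0] = 1.0
    pca = PCA(n_components=1)
    pc1 = pca.fit_transform((hum - hum.mean(axis=0)) / scale)[:, 0]
    loadings = pca.components_[0]
    sign = np.sign(loadings.sum()) or 1.0
    pc1, loadings = sign * pc1, sign * loadings

    # drop collinear control columns before residualizing
    controls = sm.add_constant(env)
    rank = np.linalg.matrix_rank(controls)
    if rank < controls.shape[1]:
        q, r = np.linalg.qr(controls)
        keep = np.abs(np.diag(r)) > 1e-10 * np.abs(np.diag(r)).max()
        log.warning("dropped %d collinear control columns",
                    int(np.sum(~keep)))
        controls = controls[:, keep]
    ry = sm.OLS(y, controls).fit().resid
    rx = sm.OLS(pc1, controls).fit().resid
    fit = sm.OLS(ry, sm.add_constant(rx)).fit()
    ci = fit.conf_int()[1]
    return PartialRegressionResult(slope=float(fit.params[1]),
                                   conf_int=(float(ci[0]), float(ci[1])),
                                   p_value=float(fit.pvalues[1]),
                                   pc1_scores=pc1, loadings=loadings)


def disturbance_shift_test(carbon: np.ndarray, env_layers: np.ndarray,
                           human_layers: np.ndarray, step: int = 4,
                           n_shifts: int = 99, seed: int = 0,
                           ) -> tuple[float, float]:
    """Partial-regression slope with a toroidal-shift permutation p-value.

    Inputs are gridded: ``carbon`` (H, W), ``env_layers`` (n_env, H, W) and
    ``human_layers`` (n_hum, H, W).  The slope of carbon on the human PC1
    (controlling for the environment) is compared against a null built by
    circularly shifting the human layers relative to the rest — a permutation
    scheme that preserves each field's spatial autocorrelation, so the test
    keeps its nominal level where naive OLS inference under smooth spatial
    confounding does not.  Returns (slope, one-sided p for slope < 0).
    """
    sl = (slice(None, None, step), slice(None, None, step))
    y = carbon[sl].ravel()
    env = np.stack([e[sl].ravel() for e in env_layers], axis=1)

    def slope_for(hum_stack: np.ndarray) -> float:
        hum = np.stack([h[sl].ravel() for h in hum_stack], axis=1)
        return disturbance_partial_regression(y, env, hum).slope

    obs = slope_for(human_layers)
    rng = np.random.default_rng(seed)
    h, w = carbon.shape
    null = np.empty(n_shifts)
    for i in range(n_shifts):
        dy = int(rng.integers(1, h))
        dx = int(rng.integers(1, w))
        rolled = np.roll(human_layers, (dy, dx), axis=(1, 2))
        null[i] = slope_for(rolled)
    p = (1 + np.sum(null <= obs)) / (1 + n_shifts)
    return obs, float(p)


def gam_residuals(table: pd.DataFrame, features: list[str], response: str,
                  n_top: int = 5, df_spline: int = 6, seed: int = 0) -> np.ndarray:
    """Residuals of a smooth covariate-only surface for Moran's-I testing.

    Fits a generalized additive model (B-splines) on the ``n_top`` covariates
    ranked by random-forest importance; the smoother is intentionally simple
    and pluggable — any residual vector can be handed to :func:`morans_i`.
    """
    from sklearn.ensemble import RandomForestRegressor
    from statsmodels.gam.api import BSplines, GLMGam

    X = table[features].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    rf = RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    top = np.argsort(rf.feature_importances_)[::-1][:n_top]
    Xs = X[:, top]
    bs = BSplines(Xs, df=[df_spline] * Xs.shape[1], degree=[3] * Xs.shape[1])
    gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs).fit()
    return np.asarray(y - gam.fittedvalues)
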