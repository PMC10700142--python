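"""Allometry: biomass prediction, pseudo-data refitting, plot carbon, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcp import (AllometricEquation, WoodParams, fit_biome_equation,
                 generate_pseudo_data, mad_filter, plot_carbon_density,
                 predict_biomass, predict_biomass_tropical, apply_plot_filters)
from fcp.allometry import MAX_FOREST_DENSITY, PSEUDO_DBH_GRID


@pytest.mark.parametrize("dbh,beta0,beta1,expected", [
    (1.0, 0.0, 2.3, 1.0),                      # ln 1 = 0
    (10.0, 0.0, 2.0, 100.0),                   # pure square law
    (30.0, -2.0, 2.4, np.exp(-2.0 + 2.4 * np.log(30.0))),
])
def test_predict_biomass_closed_form(dbh, beta0, beta1, expected):
    eq = AllometricEquation(beta0=beta0, beta1=beta1)
    assert predict_biomass(dbh, eq) == pytest.approx(expected, rel=1e-12)


def test_predict_biomass_rejects_nonpositive_dbh():
    eq = AllometricEquation(beta0=0.0, beta1=2.0)
    with pytest.raises(ValueError):
        predict_biomass(0.0, eq)
    with pytest.raises(ValueError):
        AllometricEquation(beta0=0.0, beta1=-1.0)


def test_tropical_power_law():
    # identity coefficients: W = rho * dbh^2
    assert predict_biomass_tropical(10.0, 0.5, coeffs=(1.0, 1.0)) == 50.0
    # doubling rho multiplies W by 2^b
    a, b = 0.0673, 0.976
    w1 = predict_biomass_tropical(25.0, 0.3, coeffs=(a, b))
    w2 = predict_biomass_tropical(25.0, 0.6, coeffs=(a, b))
    assert w2 / w1 == pytest.approx(2 ** b, rel=1e-12)
    # default coefficients match an independent evaluation
    assert predict_biomass_tropical(25.0, 0.6) == pytest.approx(
        a * (0.6 * 25.0 ** 2) ** b, rel=1e-12)
    # missing wood density falls back to the biome median
    w = predict_biomass_tropical(np.array([10.0]), np.array([np.nan]),
                                 fallback_density=0.5, coeffs=(1.0, 1.0))
    assert w[0] == 50.0


def test_pseudo_data_grid():
    eq = AllometricEquation(beta0=-2.0, beta1=2.4)
    pseudo = generate_pseudo_data(eq)
    assert len(pseudo) == 56          # 21 + 15 + 20, endpoints emitted once
    assert pseudo["dbh_cm"].min() == 5.0
    assert pseudo["dbh_cm"].max() == 300.0
    assert pseudo["dbh_cm"].is_unique
    # pairs lie exactly on the generating line
    refit = fit_biome_equation(pseudo)
    assert refit.beta0 == pytest.approx(-2.0, abs=1e-10)
    assert refit.beta1 == pytest.approx(2.4, abs=1e-10)


def test_pooled_fit_is_between_source_slopes():
    eqs = [AllometricEquation(beta0=-2.0, beta1=2.2),
           AllometricEquation(beta0=-2.0, beta1=2.6)]
    pooled = pd.concat([generate_pseudo_data(e) for e in eqs])
    fit = fit_biome_equation(pooled)
    assert 2.2 < fit.beta1 < 2.6
    # independent brute-force OLS on the pooled grid
    x = np.log(pooled["dbh_cm"].to_numpy())
    y = np.log(pooled["biomass_kg"].to_numpy())
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert fit.beta1 == pytest.approx(slope, rel=1e-12)


def test_fit_rejects_degenerate_designs():
    with pytest.raises(ValueError):
        fit_biome_equation(pd.DataFrame({"dbh_cm": [], "biomass_kg": []}))
    with pytest.raises(ValueError):
        fit_biome_equation(pd.DataFrame({"dbh_cm": [10.0, 10.0],
                                         "biomass_kg": [5.0, 5.0]}))


def _plot_frame(rows):
    return pd.DataFrame(rows, columns=["plot_id", "lat", "lon", "year",
                                       "area_m2", "tree_id", "dbh_cm",
                                       "wood_density"])


def test_plot_carbon_density_unit_arithmetic():
    """One 500-kg tree on 250 m2 with carbon fraction 0.5 -> 10 t C/ha."""
    eq = AllometricEquation(beta0=np.log(500.0), beta1=1e-9)  # W ~ 500 kg
    trees = _plot_frame([(0, 0.0, 0.0, 2000, 250.0, 0, 1.0, 0.6)])
    wood = WoodParams(carbon_fraction=0.5)
    pc = plot_carbon_density(trees, 250.0, {"b": eq}, wood, biome="b")
    assert pc.carbon_density == pytest.approx(10.0, rel=1e-6)


def test_plot_carbon_density_empty_and_year_average():
    eq = AllometricEquation(beta0=0.0, beta1=2.0)
    wood = WoodParams(carbon_fraction=0.5)
    empty = _plot_frame([])
    assert plot_carbon_density(empty, 250.0, {"b": eq}, wood, "b").carbon_density == 0.0
    # same plot measured in two years -> mean of the yearly densities
    one = _plot_frame([(0, 0, 0, 2000, 250.0, 0, 10.0, 0.6)])
    two = _plot_frame([(0, 0, 0, 2001, 250.0, 0, 10.0, 0.6),
                       (0, 0, 0, 2001, 250.0, 1, 10.0, 0.6)])
    d1 = plot_carbon_density(one, 250.0, {"b": eq}, wood, "b").carbon_density
    d2 = plot_carbon_density(pd.concat([one, two]), 250.0, {"b": eq},
                             wood, "b").carbon_density
    assert d2 == pytest.approx(1.5 * d1, rel=1e-9)


def test_plot_carbon_density_additive_and_order_invariant(rng):
    eq = AllometricEquation(beta0=-2.0, beta1=2.4)
    wood = WoodParams()
    dbhs = rng.uniform(5, 80, 20)
    rows = [(0, 0, 0, 2000, 250.0, i, d, 0.6) for i, d in enumerate(dbhs)]
    full = _plot_frame(rows)
    shuffled = full.sample(frac=1.0, random_state=0)
    d_full = plot_carbon_density(full, 250.0, {"b": eq}, wood, "b").carbon_density
    d_shuf = plot_carbon_density(shuffled, 250.0, {"b": eq}, wood, "b").carbon_density
    assert d_full == pytest.approx(d_shuf, rel=1e-12)
    d_a = plot_carbon_density(full.iloc[:7], 250.0, {"b": eq}, wood, "b").carbon_density
    d_b = plot_carbon_density(full.iloc[7:], 250.0, {"b": eq}, wood, "b").carbon_density
    assert d_full == pytest.approx(d_a + d_b, rel=1e-12)


def _mad_filter_bruteforce(x, k, transform):
    # log1p, not log(x + 1): keeps the oracle exact for sub-ulp inputs
    t = np.log1p(np.asarray(x)) if transform else np.asarray(x, float)
    med = np.median(t)
    mad = np.median(np.abs(t - med))
    return np.abs(t - med) <= k * mad


def test_mad_filter_hand_example():
    keep = mad_filter(np.array([1.0, 2, 3, 4, 100]), k=2.5, transform=True)
    assert keep.tolist() == [True, True, True, True, False]


def test_mad_filter_edge_cases(rng):
    x = np.full(10, 3.7)
    assert mad_filter(x).all()                       # zero deviations
    y = rng.gamma(2.0, 50.0, 50)
    assert mad_filter(y, k=1e12).all()               # unbounded window
    # MAD = 0 keeps only the median value
    z = np.array([5.0, 5.0, 5.0, 9.0])
    assert mad_filter(z, k=2.5).tolist() == [True, True, True, False]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=3, max_size=40),
       st.floats(0.5, 5.0), st.booleans())
def test_mad_filter_matches_bruteforce(values, k, transform):
    x = np.asarray(values)
    np.testing.assert_array_equal(mad_filter(x, k, transform),
                                  _mad_filter_bruteforce(x, k, transform))


def test_mad_filter_bruteforce_agreement_random_vectors(rng):
    for _ in range(1000):
        n = int(rng.integers(3, 30))
        x = rng.gamma(1.5, 60.0, n)
        k = float(rng.uniform(0.5, 4.0))
        np.testing.assert_array_equal(mad_filter(x, k, True),
                                      _mad_filter_bruteforce(x, k, True))


def test_apply_plot_filters_cap_and_exception():
    base = dict(carbon_density=[50.0, 55, 60, 52, 58, 45, 2000.0, 0.01, 0.01],
                human_index=[0, 0, 0, 0, 0, 0, 0, 0.5, 0.0],
                canopy_pixel=[0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.05, 0.9],
                biome=["t"] * 9)
    out = apply_plot_filters(pd.DataFrame(base))
    dens = out["carbon_density"].tolist()
    assert 2000.0 not in dens                 # above the recorded maximum
    assert 0.01 in dens                       # kept: human-modified non-forest
    # the same low outlier in pristine forest is removed
    assert (np.array(dens) == 0.01).sum() == 1
    assert dens.count(50.0) == 1
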