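"""GEMM hazard, attributable deaths and Monte Carlo uncertainty."""

import math

import numpy as np
import pytest

import pmburden as pb
from pmburden.gemm import AGE_BANDS


def rr_oracle(conc, theta, alpha, mu, nu, c0=2.4):
    """Scalar-arithmetic evaluation of the GEMM hazard."""
    z = max(0.0, conc - c0)
    return math.exp(theta * math.log(1 + z / alpha)
                    / (1 + math.exp(-(z - mu) / nu)))


# -- relative risk ---------------------------------------------------------

def test_rr_is_one_at_and_below_counterfactual(gemm_params):
    for band, row in gemm_params.iterrows():
        assert pb.relative_risk(2.4, row) == 1.0
        assert pb.relative_risk(1.0, row) == 1.0
        assert pb.relative_risk(0.0, row) == 1.0


def test_rr_worked_value_for_band_60_64(gemm_params):
    row = gemm_params.loc["60-64"]
    assert (row.theta, row.alpha, row.mu, row.nu) == (0.2919, 1.9, 12.0, 40.2)
    rr = pb.relative_risk(50.0, row)
    assert rr == pytest.approx(1.96, abs=0.005)
    assert rr == pytest.approx(rr_oracle(50.0, 0.2919, 1.9, 12.0, 40.2),
                               rel=1e-12)


def test_rr_matches_oracle_over_concentration_range(gemm_params):
    row = gemm_params.loc["40-44"]
    for conc in np.linspace(0, 150, 31):
        assert pb.relative_risk(conc, row) == pytest.approx(
            rr_oracle(conc, row.theta, row.alpha, row.mu, row.nu), rel=1e-12)


def test_rr_strictly_increasing_above_counterfactual(gemm_params):
    conc = np.linspace(2.4, 120, 200)
    for band in ("25-29", "60-64", "80+"):
        rr = pb.relative_risk(conc, gemm_params.loc[band])
        assert np.all(np.diff(rr) > 0)


def test_rr_decreases_with_age_at_fixed_concentration(gemm_params):
    rrs = [pb.relative_risk(60.0, gemm_params.loc[b]) for b in AGE_BANDS]
    assert np.all(np.diff(rrs) < 0)  # theta decreases with age


def test_literal_variant_differs_only_in_logistic_argument(gemm_params):
    row = gemm_params.loc["50-54"]
    literal = pb.GEMMConfig(variant="literal")
    z = 30.0 - 2.4
    expected = math.exp(row.theta * math.log(1 + z / row.alpha)
                        / (1 + math.exp(-(30.0 - row.mu) / row.nu)))
    assert pb.relative_risk(30.0, row, literal) == pytest.approx(expected, rel=1e-12)
    assert pb.relative_risk(2.4, row, literal) == 1.0  # clamp still exact


def test_rr_input_validation(gemm_params):
    row = gemm_params.loc["25-29"]
    with pytest.raises(ValueError):
        pb.relative_risk(-1.0, row)
    with pytest.raises(ValueError):
        pb.relative_risk(10.0, {"theta": 0.3, "alpha": 0.0, "mu": 12, "nu": 40.2})
    with pytest.raises(ValueError):
        pb.GEMMConfig(variant="nonsense")


# -- attributable deaths ---------------------------------------------------

def test_attributable_deaths_examples():
    assert pb.attributable_deaths(0.002, 100_000, 1.0) == 0.0
    assert pb.attributable_deaths(0.002, 100_000, 2.0) == pytest.approx(100.0)
    big = pb.attributable_deaths(0.002, 100_000, 1e6)
    assert big == pytest.approx(200.0, rel=1e-5)  # limiting fraction 1
    with pytest.raises(ValueError):
        pb.attributable_deaths(0.002, 100_000, 0.9)


def test_attributable_fraction_bounds(gemm_params, rng):
    conc = rng.uniform(0, 150, 100)
    rr = pb.relative_risk(conc, gemm_params.loc["45-49"])
    dm = pb.attributable_deaths(0.00124, 1000.0, rr)
    assert np.all(dm >= 0)
    assert np.all(dm < 0.00124 * 1000.0)


# -- gridded impact --------------------------------------------------------

def _single_band_fractions(band):
    return {b: (1.0 if b == band else 0.0) for b in AGE_BANDS}


def test_uniform_grid_single_band_matches_closed_form(gemm_params):
    conc = np.full((10, 10), 47.0)
    pop = np.full((10, 10), 250.0)
    y0 = 0.00124
    res = pb.grid_impact({
        "exposure": conc, "population": pop,
        "age_fractions": _single_band_fractions("60-64"),
        "baseline_rate": y0,
    }, config=pb.GEMMConfig(n_draws=2, seed=0))
    rr = pb.relative_risk(47.0, gemm_params.loc["60-64"])
    oracle = pb.attributable_deaths(y0, pop.sum(), rr)
    assert res.national_deaths == pytest.approx(oracle, rel=1e-12)


def test_cell_deaths_are_additive_over_age_bands(gemm_params, rng):
    conc = rng.uniform(5, 90, (6, 6))
    pop = rng.integers(0, 500, (6, 6)).astype(float)
    fractions = pb.SyntheticStudyConfig().age_fraction_series()
    full = pb.grid_impact({"exposure": conc, "population": pop,
                           "age_fractions": fractions, "baseline_rate": 0.0015},
                          config=pb.GEMMConfig(n_draws=2, seed=0))
    per_band = np.zeros_like(conc)
    for band in AGE_BANDS:
        rr = pb.relative_risk(conc, gemm_params.loc[band])
        per_band += pb.attributable_deaths(0.0015, pop * fractions[band], rr)
    assert np.allclose(full.deaths_grid, per_band, rtol=1e-9)
    assert np.all(full.deaths_grid[pop == 0] == 0)


def test_zero_population_gives_zero_totals():
    res = pb.grid_impact({
        "exposure": np.full((4, 4), 80.0), "population": np.zeros((4, 4)),
        "age_fractions": pb.SyntheticStudyConfig().age_fraction_series(),
        "baseline_rate": 0.002}, config=pb.GEMMConfig(n_draws=2, seed=0))
    assert res.national_deaths == 0.0


def test_national_total_invariant_to_region_relabeling(rng):
    conc = rng.uniform(5, 90, (8, 8))
    pop = rng.integers(0, 300, (8, 8)).astype(float)
    fr = pb.SyntheticStudyConfig().age_fraction_series()
    base = {"exposure": conc, "population": pop, "age_fractions": fr,
            "baseline_rate": 0.0015}
    a = pb.grid_impact(dict(base, regions=np.zeros((8, 8), dtype=int)),
                       config=pb.GEMMConfig(n_draws=2, seed=0))
    b = pb.grid_impact(dict(base, regions=rng.integers(0, 4, (8, 8))),
                       config=pb.GEMMConfig(n_draws=2, seed=0))
    assert a.national_deaths == pytest.approx(b.national_deaths, rel=1e-12)
    assert sum(b.region_deaths.values()) == pytest.approx(b.national_deaths,
                                                          rel=1e-9)


def test_missing_age_row_is_an_error(gemm_params):
    broken = gemm_params.drop(index="60-64")
    with pytest.raises(ValueError, match="60-64"):
        pb.GEMMMortalityModel(np.full((2, 2), 50.0), np.full((2, 2), 10.0),
                              pb.SyntheticStudyConfig().age_fraction_series(),
                              0.001, params=broken)


# -- Monte Carlo -----------------------------------------------------------

def _mc_inputs(rng, shape=(12, 12)):
    return {
        "exposure": rng.uniform(5, 90, shape),
        "population": rng.integers(0, 400, shape).astype(float),
        "age_fractions": pb.SyntheticStudyConfig().age_fraction_series(),
        "baseline_rate": 0.00124,
    }


def test_zero_theta_sd_collapses_ci_to_point(gemm_params, rng):
    params = gemm_params.copy()
    params["theta_sd"] = 0.0
    point, lo, hi = pb.monte_carlo_ci(_mc_inputs(rng), params=params,
                                      config=pb.GEMMConfig(n_draws=200, seed=5))
    assert lo == pytest.approx(point, rel=1e-12)
    assert hi == pytest.approx(point, rel=1e-12)


def test_fixed_seed_reproduces_ci_and_point_is_inside(rng):
    inputs = _mc_inputs(rng)
    cfg = pb.GEMMConfig(n_draws=400, seed=21)
    a = pb.monte_carlo_ci(inputs, config=cfg)
    b = pb.monte_carlo_ci(inputs, config=cfg)
    assert a == b
    point, lo, hi = a
    assert lo <= point <= hi
    assert lo < hi


def test_halving_theta_sd_shrinks_ci_width(gemm_params, rng):
    inputs = _mc_inputs(rng)
    cfg = pb.GEMMConfig(n_draws=1000, seed=8)
    _, lo, hi = pb.monte_carlo_ci(inputs, params=gemm_params, config=cfg)
    halved = gemm_params.copy()
    halved["theta_sd"] = halved["theta_sd"] / 2.0
    _, lo2, hi2 = pb.monte_carlo_ci(inputs, params=halved, config=cfg)
    assert (hi2 - lo2) < (hi - lo)


def test_ci_covers_a_planted_truth_at_nominal_rate(gemm_params, rng):
    """Draw a 'true' theta vector per replicate, score whether its burden
    falls in the 95% interval; coverage should sit near 0.95."""
    inputs = _mc_inputs(rng, shape=(6, 6))
    theta = gemm_params.loc[list(AGE_BANDS), "theta"].to_numpy()
    sd = gemm_params.loc[list(AGE_BANDS), "theta_sd"].to_numpy()
    covered = 0
    n_rep = 80
    for rep in range(n_rep):
        true_theta = np.maximum(theta + sd * rng.standard_normal(len(theta)), 0)
        params = gemm_params.copy()
        params.loc[list(AGE_BANDS), "theta"] = true_theta
        truth = pb.grid_impact(inputs, params=params,
                               config=pb.GEMMConfig(n_draws=1, seed=0))
        _, lo, hi = pb.monte_carlo_ci(
            inputs, params=gemm_params,
            config=pb.GEMMConfig(n_draws=250, seed=1000 + rep))
        covered += int(lo <= truth.national_deaths <= hi)
    assert 0.87 <= covered / n_rep <= 1.0


def test_monte_carlo_requires_at_least_two_draws(rng):
    with pytest.raises(ValueError):
        pb.monte_carlo_ci(_mc_inputs(rng), config=pb.GEMMConfig(n_draws=1))


# -- rates and results -----------------------------------------------------

def test_mortality_rate_definition():
    assert pb.mortality_rate(619.6, 1_000_000) == pytest.approx(61.96)
    assert pb.mortality_rate(0.0, 123.0) == 0.0
    with pytest.raises(ValueError):
        pb.mortality_rate(1.0, 0.0)


def test_results_summary_and_table(rng):
    inputs = _mc_inputs(rng)
    res = pb.grid_impact(inputs, config=pb.GEMMConfig(n_draws=50, seed=3))
    table = res.regional_table()
    nat = table[table.region == "__national__"].iloc[0]
    assert nat.deaths == pytest.approx(res.national_deaths)
    assert nat.rate_per_1e5 == pytest.approx(
        res.national_deaths / inputs["population"].sum() * 1e5)
    assert "GEMM attributable IHD mortality" in res.summary()
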