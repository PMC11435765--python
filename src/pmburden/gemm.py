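"""Age-stratified GEMM relative risk and attributable IHD mortality.

The Global Exposure Mortality Model (GEMM, Burnett et al. 2018) expresses
the relative risk of death from long-term PM2.5 exposure as

    RR(C) = exp( theta * log(1 + z/alpha) / (1 + exp(-(z - mu)/nu)) ),
    z = max(0, C - C0),

with a counterfactual concentration C0 = 2.4 ug/m3 below which no excess
risk is attributed.  Parameters (theta, alpha, mu, nu) are age-band
specific; for ischemic heart disease (IHD) the Chinese-cohort parameter
set has twelve five-year adult age bands (25-29 ... 75-79, 80+) plus an
aggregate 25+ row, with theta decreasing with age.

Attributable deaths in a population stratum follow the attributable
fraction:

    dM = y0 * pop * (RR - 1) / RR,

where y0 is the baseline IHD mortality rate (deaths per person-year).

The module exposes a statsmodels-style pair: :class:`GEMMMortalityModel`
holds aligned gridded inputs (exposure, population, age structure,
baseline rates, region labels) and :meth:`GEMMMortalityModel.fit` returns
an :class:`ImpactResults` with per-cell and per-region attributable
deaths, Monte Carlo confidence intervals on the theta parameters, and
rates per 100 000.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GEMMConfig",
    "GEMMMortalityModel",
    "ImpactResults",
    "load_gemm_parameters",
    "relative_risk",
    "attributable_deaths",
    "grid_impact",
    "monte_carlo_ci",
    "mortality_rate",
    "AGE_BANDS",
    "AGGREGATE_BAND",
]

#: Twelve age-specific bands, youngest to oldest.
AGE_BANDS = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)
#: Aggregate adult band, used only when age fractions are unavailable.
AGGREGATE_BAND = "25+"


def load_gemm_parameters() -> pd.DataFrame:
    """Load the bundled IHD GEMM parameter table (Chinese cohort).

    Returns a DataFrame indexed by ``age_band`` with columns
    ``theta, theta_sd, alpha, mu, nu`` (alpha, mu, nu in ug/m3).
    Contains the twelve age-specific rows plus the ``25+`` aggregate.
    """
    ref = importlib.resources.files("pmburden.data") / "gemm_ihd_parameters.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    return table.set_index("age_band")


@dataclass(frozen=True)
class GEMMConfig:
    """Settings for the GEMM hazard and its Monte Carlo uncertainty.

    Parameters
    ----------
    counterfactual : float
        Concentration C0 (ug/m3) below which no excess risk is
        attributed.  Default 2.4, the lowest exposure observed across
        the GEMM cohorts.
    variant : {"canonical", "literal"}
        "canonical" evaluates the logistic weight at z = max(0, C - C0)
        (the Burnett form).  "literal" evaluates it at the raw
        concentration C, a variant that circulates in some secondary
        write-ups; the log term always uses z.
    n_draws : int
        Monte Carlo draws for the confidence interval (default 1000).
    ci_level : float
        Central coverage of the interval in percent (default 95).
    shared_theta_quantile : bool
        If True, one standard-normal deviate per draw is shared across
        age bands; default False draws independently per band.
    seed : int
        Seed for the Monte Carlo stream.
    """

    counterfactual: float = 2.4
    variant: str = "canonical"
    n_draws: int = 1000
    ci_level: float = 95.0
    shared_theta_quantile: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.counterfactual < 0:
            raise ValueError("counterfactual concentration must be >= 0")
        if self.variant not in ("canonical", "literal"):
            raise ValueError(f"unknown equation variant {self.variant!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0 < self.ci_level < 100:
            raise ValueError("ci_level must be in (0, 100)")


def _hazard_shape(conc, alpha, mu, nu, counterfactual, variant):
    """log(1+z/alpha) / (1+exp(-(x-mu)/nu)) with x = z or raw C."""
    z = np.maximum(np.asarray(conc, dtype=float) - counterfactual, 0.0)
    x = np.asarray(conc, dtype=float) if variant == "literal" else z
    logistic = 1.0 / (1.0 + np.exp(-(x - mu) / nu))
    return np.log1p(z / alpha) * logistic


def relative_risk(conc, row, config: GEMMConfig | None = None):
    """GEMM relative risk at concentration ``conc`` for one age band.

    Parameters
    ----------
    conc : array_like
        Ambient annual-mean PM2.5 (ug/m3), scalar or array; must be >= 0.
    row : mapping
        Parameter row with keys ``theta, alpha, mu, nu`` (a pandas Series
        from :func:`load_gemm_parameters` works directly).
    config : GEMMConfig, optional
        Counterfactual and equation-variant settings.

    Returns
    -------
    ndarray or float
        RR >= 1, with RR = 1 exactly at or below the counterfactual.
    """
    config = config or GEMMConfig()
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("PM2.5 concentration must be >= 0")
    alpha, mu, nu = float(row["alpha"]), float(row["mu"]), float(row["nu"])
    if alpha <= 0 or nu <= 0:
        raise ValueError("alpha and nu must be > 0")
    shape = _hazard_shape(conc, alpha, mu, nu, config.counterfactual, config.variant)
    rr = np.exp(float(row["theta"]) * shape)
    return rr if rr.ndim else float(rr)


def attributable_deaths(y0, pop, rr):
    """Deaths attributable to exposure: y0 * pop * (RR - 1)/RR.

    ``y0`` is the baseline mortality rate in deaths per person-year,
    ``pop`` the exposed population, ``rr`` the relative risk (>= 1).
    The result is bounded by [0, y0*pop); fractional deaths are kept.
    """
    y0 = np.asarray(y0, dtype=float)
    pop = np.asarray(pop, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(rr < 1):
        raise ValueError("relative risk must be >= 1")
    if np.any(y0 < 0) or np.any(pop < 0):
        raise ValueError("y0 and pop must be >= 0")
    out = y0 * pop * (rr - 1.0) / rr
    return out if out.ndim else float(out)


def mortality_rate(deaths, pop):
    """Deaths per 100 000 persons."""
    pop = np.asarray(pop, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be > 0 for a rate")
    out = np.asarray(deaths, dtype=float) / pop * 1e5
    return out if out.ndim else float(out)


class GEMMMortalityModel:
    """Gridded attributable-mortality model for one study year.

    Parameters
    ----------
    exposure : 2-D array
        Annual-mean PM2.5 per cell (ug/m3).
    population : 2-D array
        Adult (25+) population per cell; zero-population cells
        contribute nothing.
    age_fractions : mapping or Series
        Fraction of the adult population in each of the twelve age
        bands; must sum to 1.
    baseline_rate : float or mapping
        Baseline IHD mortality rate y0 (deaths per person-year), either
        one national value or a mapping from region label to rate.
    regions : 2-D int array, optional
        Region label per cell; omitted => a single region ``0``.
    params : DataFrame, optional
        GEMM parameter table indexed by age band (default: bundled IHD
        Chinese-cohort table).
    config : GEMMConfig, optional
    """

    def __init__(self, exposure, population, age_fractions, baseline_rate,
                 regions=None, params: pd.DataFrame | None = None,
                 config: GEMMConfig | None = None):
        self.exposure = np.asarray(exposure, dtype=float)
        self.population = np.asarray(population, dtype=float)
        if self.exposure.shape != self.population.shape:
            raise ValueError("exposure and population rasters are misaligned")
        if np.any(self.exposure < 0):
            raise ValueError("exposure must be >= 0")
        if np.any(self.population < 0):
            raise ValueError("population must be >= 0")
        if regions is None:
            regions = np.zeros(self.exposure.shape, dtype=int)
        self.regions = np.asarray(regions)
        if self.regions.shape != self.exposure.shape:
            raise ValueError("region raster is misaligned")
        self.config = config or GEMMConfig()
        self.params = load_gemm_parameters() if params is None else params
        missing = [b for b in AGE_BANDS if b not in self.params.index]
        if missing:
            raise ValueError(f"missing GEMM parameter rows: {missing}")

        fractions = pd.Series(age_fractions, dtype=float).reindex(AGE_BANDS)
        if fractions.isna().any():
            raise ValueError("age_fractions must cover all twelve age bands")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("age_fractions must sum to 1")
        self.age_fractions = fractions

        self.region_labels = np.unique(self.regions)
        if np.isscalar(baseline_rate) or isinstance(baseline_rate, float):
            baseline_rate = {r: float(baseline_rate) for r in self.region_labels}
        self.baseline_rate = {r: float(baseline_rate[r]) for r in self.region_labels}
        if any(v < 0 for v in self.baseline_rate.values()):
            raise ValueError("baseline rates must be >= 0")

    # -- internals ---------------------------------------------------------

    def _cell_y0(self) -> np.ndarray:
        y0 = np.empty(self.exposure.shape, dtype=float)
        for r in self.region_labels:
            y0[self.regions == r] = self.baseline_rate[r]
        return y0

    def _band_shapes(self) -> np.ndarray:
        """Hazard shape h_b(C) per band, stacked (n_bands, *grid)."""
        cfg = self.config
        return np.stack([
            _hazard_shape(self.exposure, row["alpha"], row["mu"], row["nu"],
                          cfg.counterfactual, cfg.variant)
            for _, row in self.params.loc[list(AGE_BANDS)].iterrows()
        ])

    def _deaths_grid(self, thetas: np.ndarray, shapes: np.ndarray,
                     y0_pop: np.ndarray) -> np.ndarray:
        """Per-cell dM for one theta vector (len 12): sum over bands of
        y0 * pop*frac_b * (1 - exp(-theta_b h_b))."""
        af = 1.0 - np.exp(-thetas[:, None, None] * shapes)  # (bands, r, c)
        fr = self.age_fractions.to_numpy()[:, None, None]
        return y0_pop * np.sum(fr * af, axis=0)

    # -- API ---------------------------------------------------------------

    def fit(self) -> "ImpactResults":
        """Compute point estimates and Monte Carlo confidence intervals.

        Point estimates use the central theta values; uncertainty draws
        theta_b ~ Normal(theta_b, SD_b) truncated at zero (n_draws
        times, seeded), recomputing the full grid impact each draw and
        taking empirical percentiles of the regional totals.
        """
        cfg = self.config
        shapes = self._band_shapes()
        y0_pop = self._cell_y0() * self.population
        rows = self.params.loc[list(AGE_BANDS)]
        theta = rows["theta"].to_numpy(dtype=float)
        theta_sd = rows["theta_sd"].to_numpy(dtype=float)
        if np.any(np.isnan(theta_sd)) or np.any(theta_sd < 0):
            raise ValueError("theta_sd must be present and >= 0 for Monte Carlo")

        deaths_grid = self._deaths_grid(theta, shapes, y0_pop)
        region_ids = self.region_labels
        flat_regions = self.regions.ravel()
        flat_deaths = deaths_grid.ravel()
        region_deaths = {r: flat_deaths[flat_regions == r].sum() for r in region_ids}

        # Monte Carlo over theta; totals only, vectorised per band over cells.
        rng = np.random.default_rng(cfg.seed)
        if cfg.shared_theta_quantile:
            eps = np.repeat(rng.standard_normal((cfg.n_draws, 1)), len(AGE_BANDS), axis=1)
        else:
            eps = rng.standard_normal((cfg.n_draws, len(AGE_BANDS)))
        theta_draws = np.maximum(theta[None, :] + theta_sd[None, :] * eps, 0.0)

        draw_region = np.zeros((cfg.n_draws, len(region_ids)))
        flat_shapes = shapes.reshape(len(AGE_BANDS), -1)
        flat_y0pop = y0_pop.ravel()
        region_masks = [flat_regions == r for r in region_ids]
        fr = self.age_fractions.to_numpy()
        chunk = max(1, int(2e7 // max(flat_shapes.shape[1], 1)))
        for start in range(0, cfg.n_draws, chunk):
            td = theta_draws[start:start + chunk]  # (d, bands)
            cell = np.zeros((td.shape[0], flat_shapes.shape[1]))
            for b in range(len(AGE_BANDS)):
                cell += fr[b] * (1.0 - np.exp(-np.outer(td[:, b], flat_shapes[b])))
            cell *= flat_y0pop[None, :]
            for j, mask in enumerate(region_masks):
                draw_region[start:start + td.shape[0], j] = cell[:, mask].sum(axis=1)

        lo_q = (100.0 - cfg.ci_level) / 2.0
        hi_q = 100.0 - lo_q
        ci = {}
        for j, r in enumerate(region_ids):
            lo, hi = np.percentile(draw_region[:, j], [lo_q, hi_q])
            ci[r] = (float(lo), float(hi))
        nat_draws = draw_region.sum(axis=1)
        nat_lo, nat_hi = np.percentile(nat_draws, [lo_q, hi_q])

        region_pop = {r: float(self.population.ravel()[m].sum())
                      for r, m in zip(region_ids, region_masks)}
        return ImpactResults(
            model=self,
            deaths_grid=deaths_grid,
            region_deaths=region_deaths,
            region_pop=region_pop,
            region_ci=ci,
            national_ci=(float(nat_lo), float(nat_hi)),
        )


@dataclass
class ImpactResults:
    """Results of a fitted :class:`GEMMMortalityModel`.

    Attributes
    ----------
    deaths_grid : 2-D array
        Attributable deaths per cell (fractional deaths retained).
    region_deaths, region_pop : dict
        Totals per region label.
    region_ci, national_ci : Monte Carlo percentile intervals on totals.
    """

    model: GEMMMortalityModel
    deaths_grid: np.ndarray
    region_deaths: dict
    region_pop: dict
    region_ci: dict
    national_ci: tuple
    excess_concentration: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.excess_concentration = np.maximum(
            self.model.exposure - self.model.config.counterfactual, 0.0)

    @property
    def national_deaths(self) -> float:
        return float(sum(self.region_deaths.values()))

    @property
    def national_pop(self) -> float:
        return float(sum(self.region_pop.values()))

    def regional_table(self) -> pd.DataFrame:
        """Per-region deaths, CI bounds and rate per 1e5, plus a national row."""
        rows = []
        for r in self.model.region_labels:
            pop = self.region_pop[r]
            deaths = float(self.region_deaths[r])
            lo, hi = self.region_ci[r]
            rows.append({
                "region": r, "deaths": deaths, "ci_lower": lo, "ci_upper": hi,
                "population": pop,
                "rate_per_1e5": mortality_rate(deaths, pop) if pop > 0 else np.nan,
            })
        lo, hi = self.national_ci
        rows.append({
            "region": "__national__", "deaths": self.national_deaths,
            "ci_lower": lo, "ci_upper": hi, "population": self.national_pop,
            "rate_per_1e5": (mortality_rate(self.national_deaths, self.national_pop)
                             if self.national_pop > 0 else np.nan),
        })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table of the fitted burden."""
        cfg = self.model.config
        head = (
            "GEMM attributable IHD mortality\n"
            f"  grid: {self.model.exposure.shape}, regions: {len(self.model.region_labels)}\n"
            f"  counterfactual: {cfg.counterfactual} ug/m3, variant: {cfg.variant}\n"
            f"  Monte Carlo: {cfg.n_draws} draws, {cfg.ci_level}% CI, seed {cfg.seed}\n"
        )
        table = self.regional_table().to_string(
            index=False, float_format=lambda v: f"{v:.2f}")
        return head + table


# -- functional surface ----------------------------------------------------

def grid_impact(inputs: dict, params: pd.DataFrame | None = None,
                config: GEMMConfig | None = None) -> ImpactResults:
    """One-call gridded impact: build the model from an inputs mapping
    (keys ``exposure, population, age_fractions, baseline_rate`` and
    optional ``regions``) and fit it."""
    model = GEMMMortalityModel(
        inputs["exposure"], inputs["population"], inputs["age_fractions"],
        inputs["baseline_rate"], regions=inputs.get("regions"),
        params=params, config=config)
    return model.fit()


def monte_carlo_ci(inputs: dict, params: pd.DataFrame | None = None,
                   config: GEMMConfig | None = None):
    """National point estimate and CI bounds: ``(point, lower, upper)``."""
    config = config or GEMMConfig()
    if config.n_draws < 2:
        raise ValueError("n_draws must be >= 2 for a confidence interval")
    res = grid_impact(inputs, params=params, config=config)
    lo, hi = res.national_ci
    return res.national_deaths, lo, hi
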