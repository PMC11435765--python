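# pmburden

Gridded health-impact assessment of long-term PM2.5 exposure: age-stratified
GEMM relative risk, attributable premature mortality from ischemic heart
disease (IHD) with Monte Carlo uncertainty, and Lorenz/Gini analysis of how
that burden distributes across income groups.

## Who this is for

Environmental-health and exposure-assessment researchers who have (or want to
simulate) aligned rasters of annual PM2.5 concentration, population,
per-capita GDP and region labels, plus age-structure and baseline-mortality
tables, and want reproducible regional burden and equity summaries. A
synthetic-study generator with known ground truth makes the whole pipeline
runnable and testable with no downloads.

## The model

Relative risk follows the Global Exposure Mortality Model (GEMM, Burnett et
al. 2018), with the Chinese-cohort IHD parameters bundled per age band
(25–29 … 75–79, ≥80, plus a ≥25 aggregate):

    RR(C) = exp( θ · ln(1 + z/α) / (1 + e^{−(z−μ)/ν}) ),   z = max(0, C − C₀)

with counterfactual C₀ = 2.4 μg/m³ (RR ≡ 1 at or below it) and θ decreasing
with age. Attributable deaths in an age stratum use the attributable
fraction:

    ΔM = y₀ · pop · (RR − 1)/RR

where y₀ is the baseline IHD mortality rate. Cell-level ΔM sums the twelve
age bands (population × age-fraction vector); uncertainty comes from 1000
Monte Carlo draws of θ ~ Normal(θ, SD(θ)) truncated at 0, with the 95% CI
read off the empirical percentiles of the recomputed totals.

Equity is summarised by ordering populated cells by per-capita GDP, plotting
cumulative population share x against cumulative burden share y, and taking
the trapezoid concentration index

    G_signed = 1 − Σᵢ (xᵢ − xᵢ₋₁)(yᵢ + yᵢ₋₁)

(negative when the burden concentrates among low-GDP cells); the unsigned
Gini |G| is the headline value.

## Worked example

```python
import numpy as np
import pmburden as pb

cfg = pb.SyntheticStudyConfig(grid_rows=50, grid_cols=50, n_regions=3,
                              years=(2007, 2022), population_total=500_000,
                              seed=42)
study = pb.generate_study(cfg)
annual = pb.annual_mean_from_seasons(study.seasonal_exposure[2022])
rates = {int(r): float(study.baseline_mortality
                       .set_index(["region", "year"]).rate[(r, 2022)])
         for r in np.unique(study.regions)}
model = pb.GEMMMortalityModel(annual, study.population,
                              cfg.age_fraction_series(), rates,
                              regions=study.regions,
                              config=pb.GEMMConfig(n_draws=1000, seed=42))
res = model.fit()
print(res.summary())
```

prints

```
GEMM attributable IHD mortality
  grid: (50, 50), regions: 3
  counterfactual: 2.4 ug/m3, variant: canonical
  Monte Carlo: 1000 draws, 95.0% CI, seed 42
      region  deaths  ci_lower  ci_upper  population  rate_per_1e5
           0   65.69     64.21     67.06   150699.00         43.59
           1    7.57      7.41      7.71    13520.00         55.97
           2  186.04    181.95    189.83   335781.00         55.40
__national__  259.29    253.57    264.60   500000.00         51.86
```

Deaths are fractional by design (a cell is 1 km²-scale; 0.2 expected deaths
in a cell is meaningful over a larger neighbourhood), rates are per 100 000,
and the CI reflects parameter uncertainty in θ only. Feeding the per-cell
deaths into the equity stage,

```python
mask = study.population > 0
curve = pb.build_lorenz(study.percap_gdp[mask], study.population[mask],
                        res.deaths_grid[mask])
print(pb.gini(curve).unsigned)       # 0.0003 — income uncoupled from burden
```

gives a near-zero Gini because this study was generated with zero
income–exposure rank correlation; raising
`income_exposure_rank_corr` (or planting inequality with
`plant_burden_inequality`) moves it accordingly.

The same flow is scriptable end to end:

```
pmburden report --seed 7 --outdir report/     # concentration/mortality/Gini CSVs
pmburden verify                               # recompute bundled worked-example arithmetic
```

`pmburden verify` recomputes, from the bundled China 2007–2022 regional
summary tables, the derived statistics quoted with them — the −46.93%
national PM2.5 decline, the −33.23 and −29.70 μg/m³ Centre/East declines,
the −0.48% national IHD-rate change, the +5.57 and +1.04 per-10⁵ Northeast/
North rate increases, the 11-feature/96.99% cumulative-|SHAP| selection, and
the regional mean-Gini ranking (South 0.019 lowest … Northwest 0.035
highest) — and reports each check.

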