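# Methods

## Scope and data flow

The package chains four stages on a uniform cell grid (nominal 1 km² cells,
no map projection): input preparation → GEMM attributable mortality →
Lorenz/Gini equity → report tables. Real inputs enter as NetCDF rasters and
CSV tables; the synthetic generator produces the same objects in memory with
known ground truth, so every stage can be scored for recovery.

## Hazard model

The concentration–response function is the GEMM (Burnett et al. 2018)
log-linear–logistic hazard,

RR(C) = exp(θ·ln(1 + z/α) / (1 + exp(−(z − μ)/ν))), z = max(0, C − C₀),

with C₀ = 2.4 μg/m³ and the IHD Chinese-cohort parameter set per age band
(bundled CSV). Design choices:

- **Equation variant.** Some secondary write-ups of GEMM place the raw
  concentration C rather than the excess z inside the logistic term, and drop
  the division bar of the logistic weight. The default here is the canonical
  Burnett form (division, z throughout); `GEMMConfig(variant="literal")`
  exposes the C-in-logistic variant for comparison. Natural logarithm
  throughout. No regional summary in this package depends on the choice; at
  C = 50 μg/m³ the two differ by under 1% in RR.
- **Clamping.** z is clamped at 0 below the counterfactual: GEMM attributes
  no protective effect below 2.4 μg/m³, and RR(C₀) = 1 exactly.
- **Age allocation.** Cell population is split by a single study-wide
  age-fraction vector over the twelve adult bands; sub-national age rasters
  are out of scope. The ≥25 aggregate row is retained for use when age
  fractions are unavailable, but the default computation is always the
  twelve-band sum.
- **Monte Carlo.** θ is drawn independently per age band from
  Normal(θ, SD(θ)), truncated at zero (truncation probability is negligible,
  θ/SD ≈ 17–21; the truncation only guards the RR ≥ 1 contract).
  `shared_theta_quantile=True` instead shares one standard-normal deviate
  across bands for users who prefer perfectly correlated parameter
  uncertainty. Draws are paired by seed, so halving SD provably narrows the
  interval. The CI is the empirical 2.5/97.5 percentile of regional totals
  over 1000 draws (default); the point estimate always uses central θ.
  Fractional deaths are retained at full precision; rounding happens only at
  report formatting.

## Input preparation

- Annual exposure is the arithmetic mean of the four seasonal fields; missing
  seasons are an error, never imputed.
- GDP gap-fill chains GDP_x = GDP_{x−1} · P_x forward from the first observed
  year using district growth multipliers; present values are never modified,
  so the fill is idempotent on complete series.
- Provincial baseline IHD mortality follows the national trend exactly:
  rate(p, y) = base(p) · national(y)/national(base year). The operation works
  on any labelled partition (provinces and macro-regions are both just label
  sets).
- Feature selection for the upstream PM2.5 retrieval model consumes a
  precomputed mean-|SHAP| table (bundled), ranks features descending (ties
  keep input order) and returns the smallest prefix reaching the cumulative
  share threshold. Training the retrieval model and computing SHAP values are
  out of scope.
- Regional concentration summaries default to the unweighted cell mean (area
  statistics); population weighting is available as population-weighted
  exposure, with zero-weight cells excluded. Which convention a published
  regional table used is often unstated, hence both.

## Equity measure

Populated cells are ordered by per-capita GDP ascending; cells tied on the
key are pooled into one curve segment, which makes the index independent of
their input order and equal to the per-person double-sum concentration
index. Zero-population cells are excluded (per-capita GDP undefined);
all-zero burden is an error rather than Gini 0. The signed trapezoid index
1 − Σ Δx(yᵢ + yᵢ₋₁) is negative when the burden sits with low-GDP cells;
tables report the unsigned value, which equals the area-ratio Gini of the
Lorenz construction (a naive 1 − Σ Δx·Δy product formula is not used: it
tends to 1 on any fine grid and does not measure the area ratio). GDP
concentration curves reuse the same operation with GDP as the burden.
Multi-year regional summaries take arithmetic row means and rank regions
ascending; report formatting rounds half away from zero to 3 decimals (the
only rounding rule that reproduces the bundled reference means, e.g.
0.0185 → 0.019).

## Synthetic studies

The generator emulates the study conditions of a national 2007–2022
assessment, scaled to desk size:

- **Grid & regions** — default 100×100 cells, 7 regions as the Voronoi cells
  of seeded random centroids.
- **Exposure** — one persistent spatial relief (Gaussian-blurred white noise,
  σ = L/12, plus N(0, 0.15) regional offsets, floored at 0.05) rescaled each
  year so the national mean is exactly `exposure_mean_start − offset·decline`
  (defaults 47.41 μg/m³ and (47.41−25.16)/15 per year, the published national
  endpoints). Seasons modulate the annual field by (1+a, 1, 1−a, 1) for
  winter/spring/summer/autumn, a = 0.34 — chosen so the winter:summer ratio
  ≈ 2.0 matches the published 51.32:25.41 contrast; the annual arithmetic
  mean of the four seasons is exact by construction.
- **Population** — lognormal intensity exp(clustering·G) on a blurred field,
  lowest 12% of cells set uninhabited (to exercise exclusion rules), then
  largest-remainder integer apportionment conserving the total exactly
  (default 2 000 000 adults ≥25; a fractional-person mode is provided since
  gridded population products use both conventions). Age structure defaults
  to a China-2020-like adult pyramid over the twelve bands.
- **Income** — per-capita GDP via a Gaussian copula against year-one
  exposure ranks; the Pearson parameter is r = 2·sin(π·ρ_s/6) so the
  requested Spearman correlation ρ_s is hit to within sampling error
  (±0.05 at 10⁴ cells). Uniform national growth scales GDP per year,
  preserving ranks and hence the planted correlation. Regional GDP series
  follow the growth recurrence with ~30% of non-leading years flagged
  withheld as the gap-fill recovery target.
- **Baseline mortality** — national rate 124/10⁵ (a plausible adult IHD
  baseline) with a +0.4%/yr secular drift standing in for ageing, and
  regional multipliers U(0.85, 1.15) at the base year; the provincial table
  is generated by the same scaling rule the prep stage implements, so
  recovery is exact.
- **Planted inequality** — `plant_burden_inequality` places burden along the
  exponential Lorenz curve y(x) = (e^{sx}−1)/(e^s−1), solving the continuum
  Gini 1 − 2(1/s − 1/(e^s−1)) = target for s (Brent), and assigns each cell
  the exact integral of the density over its population interval, conserving
  total burden; discrete recovery is within ±0.01 at 10⁴ cells.
- **Reproducibility** — one seed per study; every field draws from a named
  substream (CRC32 of the field name mixed into the seed sequence), so
  identical (config, seed) is bit-identical across processes and editing one
  field's parameters does not shift another's draws.

What the generator does **not** emulate: satellite retrieval artefacts,
station networks, projection/area distortion, migration, sub-regional age
structure, or any causal income–health mechanism. Passing recovery tests
therefore demonstrates correctness of the pipeline arithmetic under
controlled conditions, not fidelity of real-world burden estimates.

## Report layer

The pipeline writes regional concentration, mortality (deaths + CI + rate
per 10⁵) and Gini tables per year, a first-vs-last-year derived-change table
(absolute and percent), and a JSON manifest (config, seed, version). Internal
math is full precision; printed rounding is 2 decimals for concentrations,
changes and rates, 3 for Gini, with percent decreases carried as negative
values. Reruns with identical config and seed are byte-identical. Default
problem sizes (100×100 grids, 1000 draws) run in seconds; tests use 20×20 to
50×50 grids and reduced draws where full size adds nothing to the property
being checked.

## Known limitations

- IHD is the only endpoint; no other causes, no life-table YLL.
- The CI propagates θ uncertainty only — exposure, population and baseline
  rate errors are not modelled.
- Real-raster ingestion is NetCDF + CSV; the pipeline entry point currently
  drives synthetic studies, with the io module providing the readers for
  assembling real-data runs programmatically.
- Per-cell "Gini" is undefined; equity is always computed over the cells of
  a region (or the whole grid).
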