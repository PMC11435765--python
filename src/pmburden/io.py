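"""On-disk formats: NetCDF rasters (scipy backend, NetCDF3), CSV tables,
YAML configs.  All writers are deterministic so identical runs produce
byte-identical files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

FLOAT_FMT = "%.10g"


def write_raster(path, array: np.ndarray, name: str, units: str = "",
                 dim_names=("y", "x"), coords=None, attrs=None):
    """Write a 2-D (or stacked 3-D) field to NetCDF3."""
    array = np.asarray(array, dtype=float)
    dims = (("band",) + tuple(dim_names)) if array.ndim == 3 else tuple(dim_names)
    da = xr.DataArray(array, dims=dims, coords=coords or {}, name=name,
                      attrs={"units": units, **(attrs or {})})
    da.to_netcdf(path, engine="scipy")


def read_raster(path, name: str | None = None) -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds[name] if name else ds[list(ds.data_vars)[0]]
        return da.values.copy()


def write_table(path, frame: pd.DataFrame):
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_yaml(path, obj: dict):
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_study(study, outdir):
    """Serialise a synthetic study: seasonal exposure NetCDF per year,
    demographic/mortality CSVs, ground truth CSVs and the config YAML."""
    from .synthetic import SEASONS  # re-exported there via prep

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for year, stack in study.seasonal_exposure.items():
        write_raster(out / f"exposure_{year}.nc", stack, "pm25", units="ug m-3",
                     coords={"band": list(SEASONS)}, attrs={"year": year})
    write_raster(out / "population.nc", study.population, "population", "persons")
    write_raster(out / "percap_gdp.nc", study.percap_gdp, "percap_gdp")
    write_raster(out / "regions.nc", study.regions.astype(float), "region")
    write_raster(out / "burden.nc", study.burden, "burden", "deaths")
    write_table(out / "baseline_mortality.csv", study.baseline_mortality)
    truth = study.ground_truth
    write_table(out / "gdp_truth.csv", truth.gdp_table)
    write_table(out / "national_mortality.csv", truth.national_mortality)
    means = pd.DataFrame({"year": list(truth.true_annual_means),
                          "mean_pm25": list(truth.true_annual_means.values())})
    write_table(out / "true_annual_means.csv", means)
    cfg = study.config
    write_yaml(out / "config.yaml", {
        "grid_rows": cfg.grid_rows, "grid_cols": cfg.grid_cols,
        "n_regions": cfg.n_regions, "years": list(cfg.years),
        "seasonal_amplitude": cfg.seasonal_amplitude,
        "exposure_mean_start": cfg.exposure_mean_start,
        "exposure_annual_decline": cfg.exposure_annual_decline,
        "population_total": cfg.population_total,
        "population_clustering": cfg.population_clustering,
        "income_exposure_rank_corr": cfg.income_exposure_rank_corr,
        "age_fractions": dict(cfg.age_fractions),
        "baseline_mortality_per_1e5": cfg.baseline_mortality_per_1e5,
        "integer_population": cfg.integer_population,
        "seed": cfg.seed,
    })
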