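"""Input preparation: seasonal-to-annual exposure, GDP gap-fill,
baseline-mortality scaling, regional summaries and cumulative-Shapley
feature selection.

These are the deterministic transforms that turn raw gridded and tabular
inputs into the aligned annual fields the mortality and equity stages
consume.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GdpSeries",
    "annual_mean_from_seasons",
    "gdp_gap_fill",
    "scale_baseline_mortality",
    "select_features",
    "regional_summary",
    "load_shap_importance",
]

SEASONS = ("winter", "spring", "summer", "autumn")


def annual_mean_from_seasons(seasonal) -> np.ndarray:
    """Annual PM2.5 field as the arithmetic mean of the four seasons.

    ``seasonal`` is a sequence of exactly four aligned 2-D fields (or a
    single array with a leading season axis of length 4).  Inputs must
    be nonnegative; missing seasons are an error, never imputed.
    """
    grids = [np.asarray(g, dtype=float) for g in seasonal]
    if len(grids) != 4:
        raise ValueError(f"expected exactly 4 seasonal grids, got {len(grids)}")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("seasonal grids have mismatched shapes")
    stack = np.stack(grids)
    if np.any(stack < 0):
        raise ValueError("seasonal concentrations must be >= 0")
    return stack.mean(axis=0)


@dataclass
class GdpSeries:
    """GDP of one spatial unit over consecutive years.

    ``gdp`` may contain NaN for missing years; ``growth`` holds the
    dimensionless year-on-year growth multiplier P_i used to fill them
    (value for year x fills GDP_x = GDP_{x-1} * P_x).
    """

    unit: str
    years: list[int]
    gdp: list[float]
    growth: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if len(self.gdp) != len(self.years):
            raise ValueError("gdp and years length mismatch")
        if self.growth and len(self.growth) != len(self.years):
            raise ValueError("growth and years length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": self.unit, "year": self.years, "gdp": self.gdp,
            "growth": self.growth if self.growth else np.nan,
        })


def gdp_gap_fill(series: GdpSeries) -> GdpSeries:
    """Fill missing GDP years by chaining the growth recurrence
    GDP_x = GDP_{x-1} * P_x forward; present values are never touched.

    Requires the first year to be present and a positive growth
    multiplier for every missing year.
    """
    gdp = [np.nan if v is None else float(v) for v in series.gdp]
    if np.isnan(gdp[0]):
        raise ValueError("leading GDP value is missing; cannot chain forward")
    growth = list(series.growth) if series.growth else [np.nan] * len(gdp)
    filled = list(gdp)
    for i in range(1, len(filled)):
        if np.isnan(filled[i]):
            p = growth[i]
            if p is None or np.isnan(p):
                raise ValueError(
                    f"missing growth rate for gap year {series.years[i]}")
            if p <= 0:
                raise ValueError("growth multiplier must be > 0")
            filled[i] = filled[i - 1] * p
    return GdpSeries(series.unit, list(series.years), filled, list(series.growth))


def scale_baseline_mortality(national: pd.DataFrame,
                             provincial_base: pd.DataFrame,
                             base_year: int) -> pd.DataFrame:
    """Province-level baseline mortality from a national trend.

    Each province's rate in year y is its base-year rate scaled by the
    national ratio: ``rate(p, y) = base(p) * national(y)/national(base_year)``
    — provincial series follow the national trend exactly.

    ``national`` needs columns (year, rate); ``provincial_base`` columns
    (region, rate) at ``base_year``.  Returns columns (region, year, rate).
    """
    nat = national.set_index("year")["rate"].astype(float)
    if base_year not in nat.index:
        raise ValueError(f"national series does not cover base year {base_year}")
    if nat.loc[base_year] == 0:
        raise ValueError("national rate at base year is zero; ratio undefined")
    if (nat < 0).any():
        raise ValueError("national rates must be >= 0")
    base = provincial_base.set_index("region")["rate"].astype(float)
    if base.isna().any():
        raise ValueError("missing provincial base rate")
    ratio = nat / nat.loc[base_year]
    out = pd.DataFrame(
        [(region, int(year), float(base[region] * ratio[year]))
         for region in base.index for year in nat.index],
        columns=["region", "year", "rate"],
    )
    return out


def load_shap_importance() -> pd.DataFrame:
    """Bundled mean-|SHAP| feature-importance table of the PM2.5
    retrieval model (columns: feature, mean_abs_shap)."""
    ref = importlib.resources.files("pmburden.data") / "shap_importance.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def select_features(table: pd.DataFrame, threshold: float = 0.95):
    """Smallest descending-importance prefix reaching a cumulative share.

    Features are ranked by descending mean absolute Shapley value (ties
    keep input order); the returned prefix is the shortest whose share
    of the total importance is >= ``threshold``.

    Returns ``(selected_features, cumulative_share)`` with the share as
    a fraction in (0, 1].
    """
    if table.empty:
        raise ValueError("feature importance table is empty")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    values = table["mean_abs_shap"].astype(float)
    if (values < 0).any():
        raise ValueError("importance values must be >= 0")
    total = values.sum()
    if total == 0:
        raise ValueError("all feature importances are zero")
    order = values.sort_values(ascending=False, kind="stable").index
    cum = values.loc[order].cumsum() / total
    n_keep = int(np.searchsorted(cum.to_numpy(), threshold - 1e-12) + 1)
    selected = table.loc[order[:n_keep], "feature"].tolist()
    return selected, float(cum.iloc[n_keep - 1])


def regional_summary(grid, regions, weights=None) -> pd.DataFrame:
    """Mean concentration per region.

    Unweighted cell mean by default; population-weighted exposure when
    ``weights`` is given (zero-weight cells then drop out, and a region
    whose every cell has zero weight is an error).
    Returns columns (region, mean).
    """
    grid = np.asarray(grid, dtype=float)
    regions = np.asarray(regions)
    if grid.shape != regions.shape:
        raise ValueError("grid and region rasters are misaligned")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != grid.shape:
            raise ValueError("weight raster is misaligned")
        if np.any(weights < 0):
            raise ValueError("weights must be >= 0")
    rows = []
    for r in np.unique(regions):
        mask = regions == r
        if weights is None:
            rows.append((r, float(grid[mask].mean())))
        else:
            w = weights[mask]
            if w.sum() == 0:
                raise ValueError(f"region {r!r} has zero total weight")
            rows.append((r, float(np.average(grid[mask], weights=w))))
    return pd.DataFrame(rows, columns=["region", "mean"])
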