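"""Lorenz-curve and Gini analysis of attributable-mortality burden.

Grid cells are ordered by per-capita GDP (a proxy for income); the
Lorenz curve plots cumulative population share x against cumulative
burden share y.  The concentration index is twice the signed area
between the curve and the equality diagonal, computed by trapezoid
integration:

    signed = 1 - sum_i (x_i - x_{i-1}) * (y_i + y_{i-1})

It is negative when the burden concentrates among low-GDP cells (curve
above the diagonal) and positive when it concentrates among high-GDP
cells.  The headline Gini coefficient is its absolute value, the
area-ratio definition: 0 is perfect equality, values near 1 extreme
concentration.  The same machinery yields GDP Lorenz curves by passing
GDP itself as the burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LorenzCurve",
    "GiniResult",
    "build_lorenz",
    "gini",
    "mean_gini",
    "equity_table",
    "round_half_away",
    "plot_lorenz",
]


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative (population share, burden share) points.

    ``x`` and ``y`` are nondecreasing arrays of length n+1 starting at
    (0, 0) and ending at (1, 1), where n is the number of contributing
    (populated) cells, ordered by ``key`` ascending.
    """

    x: np.ndarray
    y: np.ndarray
    key: str = "per-capita GDP"

    @property
    def n(self) -> int:
        return len(self.x) - 1

    def validate(self) -> None:
        x, y = self.x, self.y
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("malformed Lorenz curve: bad point count")
        if abs(x[0]) > 1e-9 or abs(y[0]) > 1e-9 or abs(x[-1] - 1) > 1e-9 \
                or abs(y[-1] - 1) > 1e-9:
            raise ValueError("Lorenz curve must run from (0,0) to (1,1)")
        if np.any(np.diff(x) < -1e-12) or np.any(np.diff(y) < -1e-12):
            raise ValueError("Lorenz shares must be nondecreasing")


@dataclass(frozen=True)
class GiniResult:
    """Signed concentration index and unsigned (area-ratio) Gini."""

    signed: float
    region: object = None
    year: int | None = None

    @property
    def unsigned(self) -> float:
        return abs(self.signed)


def build_lorenz(percap_gdp, pop, burden, key: str = "per-capita GDP") -> LorenzCurve:
    """Lorenz curve of ``burden`` against population, cells ordered by
    ascending per-capita GDP (stable order on ties).

    Zero-population cells are excluded (their per-capita GDP is
    undefined); zero total burden or population is an error, not
    perfect equality.  Cells tied on the ordering key are pooled into a
    single curve segment, so the index does not depend on their input
    order; ``n`` counts the resulting distinct-key points.
    """
    gdp = np.asarray(percap_gdp, dtype=float).ravel()
    pop = np.asarray(pop, dtype=float).ravel()
    burden = np.asarray(burden, dtype=float).ravel()
    if not (len(gdp) == len(pop) == len(burden)):
        raise ValueError("per-capita GDP, population and burden length mismatch")
    if np.any(pop < 0) or np.any(burden < 0):
        raise ValueError("population and burden must be >= 0")
    keep = pop > 0
    gdp, pop, burden = gdp[keep], pop[keep], burden[keep]
    if pop.sum() == 0:
        raise ValueError("no populated cells")
    if burden.sum() == 0:
        raise ValueError("total burden is zero; Lorenz curve undefined")
    order = np.argsort(gdp, kind="stable")
    g, p, b = gdp[order], pop[order], burden[order]
    # cells sharing a key value are one straight segment of the curve:
    # merge them so the index is invariant to their input order
    boundaries = np.flatnonzero(np.diff(g)) + 1
    p = np.add.reduceat(p, np.concatenate(([0], boundaries)))
    b = np.add.reduceat(b, np.concatenate(([0], boundaries)))
    x = np.concatenate(([0.0], np.cumsum(p) / p.sum()))
    y = np.concatenate(([0.0], np.cumsum(b) / b.sum()))
    curve = LorenzCurve(x=x, y=y, key=key)
    curve.validate()
    return curve


def gini(curve: LorenzCurve, region=None, year=None) -> GiniResult:
    """Concentration index of a Lorenz curve by trapezoid integration.

    ``signed = 1 - sum (x_i - x_{i-1})(y_i + y_{i-1})`` equals twice the
    signed area between the diagonal and the curve; the diagonal gives 0
    and full concentration in the richest cells gives +1 in the limit.
    """
    curve.validate()
    dx = np.diff(curve.x)
    signed = 1.0 - float(np.sum(dx * (curve.y[1:] + curve.y[:-1])))
    return GiniResult(signed=signed, region=region, year=year)


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (0.0185 -> 0.019 at 3 decimals),
    matching how the summary tables are printed."""
    factor = 10.0 ** decimals
    scaled = value * factor
    return np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor


def mean_gini(values) -> float:
    """Arithmetic mean of per-year Gini values (full precision; report
    formatting rounds half away from zero to 3 decimals)."""
    values = list(values)
    if not values:
        raise ValueError("empty Gini list")
    return float(np.mean(values))


def equity_table(gini_by_region_year: pd.DataFrame) -> pd.DataFrame:
    """Region x year Gini matrix with multi-year means and ranking.

    Input columns: (region, year, gini) — unsigned Gini values.  A
    region missing a year keeps NaN in that cell (absent, not imputed);
    its mean uses the years it has.  Output is indexed by region,
    sorted ascending by multi-year mean (ties alphabetical), with
    columns per year plus ``mean`` and ``rank`` (1 = most equitable).
    """
    wide = gini_by_region_year.pivot(index="region", columns="year", values="gini")
    wide["mean"] = wide.mean(axis=1, skipna=True)
    wide = wide.sort_values(["mean", "region"], kind="stable")
    wide["rank"] = np.arange(1, len(wide) + 1)
    return wide


def plot_lorenz(curves: dict, path=None, title="Lorenz curves"):
    """Render one or more Lorenz curves against the equality diagonal.

    ``curves`` maps a label to a :class:`LorenzCurve`.  Returns the
    matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k-", lw=1, label="equality")
    for label, curve in curves.items():
        ax.plot(curve.x, curve.y, lw=1.2, label=str(label))
    ax.set_xlabel("cumulative population share")
    ax.set_ylabel("cumulative burden share")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
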