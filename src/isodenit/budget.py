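"""Global nitrogen-budget accounting on f_denit and flux maps.

Converts denitrification-fraction maps and N-flux fields into global
numbers: N-input-weighted means, steady-state denitrification loss
(loss = input at steady state), ESM-style f_denit from simulated flux
pairs, budget closure (input = sink + losses), reallocation of simulated
total losses by a benchmark f_denit, bias percentages, latitudinal
gradients, bound histograms, and managed-land masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec, cell_areas, global_total_tg, require_aligned


@dataclass
class ESMBundle:
    """One Earth-System-Model-style output set.

    Flux grids are climatological means (g N m^-2 yr^-1); the N-stock and
    NPP/T/P/CO2 series are annual, on a shared year axis.  The NPP, T and
    P series are regional aggregates (the boreal 50-90N band in this
    package's workflow).
    """

    model_id: str
    denit_flux: xr.DataArray
    leach_flux: xr.DataArray
    n_stock_series: pd.Series          # Tg N, indexed by year
    years: np.ndarray
    npp: np.ndarray                    # g C m^-2 yr^-1, regional mean
    t: np.ndarray                      # deg C, regional mean
    p: np.ndarray                      # mm yr^-1, regional mean
    co2: np.ndarray                    # ppm
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        require_aligned(self.denit_flux, self.leach_flux)
        if float(self.denit_flux.min(skipna=True)) < 0 or float(
            self.leach_flux.min(skipna=True)
        ) < 0:
            raise ValueError("flux fields must be non-negative")
        n = len(self.years)
        for name in ("npp", "t", "p", "co2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series '{name}' does not share the year axis")


@dataclass(frozen=True)
class BudgetSummary:
    """Global N budget (Tg N yr^-1) closing input = sink + denit + leach."""

    total_input: float
    total_denit: float
    total_leach: float
    sink: float
    fdenit_weighted_mean: float

    def __post_init__(self) -> None:
        closure = self.sink + self.total_denit + self.total_leach
        if abs(self.total_input - closure) > 1e-6 * max(abs(self.total_input), 1.0):
            raise ValueError("budget does not close: input != sink + losses")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def weighted_global_mean(value: xr.DataArray, n_input_flux: xr.DataArray) -> float:
    """Global mean of ``value`` weighted by N-input flux times cell area.

    At steady state soil N content is proportional to N input, so this is
    the soil-N-weighted global mean.
    """
    require_aligned(value, n_input_flux)
    if float(n_input_flux.min(skipna=True)) < 0:
        raise ValueError("weights must be non-negative")
    area = cell_areas(GridSpec.from_field(value))
    w = (n_input_flux * area).where(value.notnull())
    wsum = float(w.sum(skipna=True))
    if wsum <= 0:
        raise ValueError("all weights are zero over unmasked cells")
    return float((value * w).sum(skipna=True)) / wsum


def steady_state_denit(fdenit: xr.DataArray, n_input_flux: xr.DataArray) -> float:
    """Steady-state denitrification loss, Tg N yr^-1: sum f * input * area."""
    require_aligned(fdenit, n_input_flux)
    return global_total_tg(fdenit * n_input_flux)


def esm_fdenit(bundle: ESMBundle) -> xr.DataArray:
    """Simulated f_denit = denit / (denit + leach); masked where total loss is 0."""
    total = bundle.denit_flux + bundle.leach_flux
    return (bundle.denit_flux / total.where(total > 0)).rename("fdenit")


def close_budget(bundle: ESMBundle) -> BudgetSummary:
    """Close the model's N budget: input = N sink + denitrification + leaching.

    The terrestrial N sink is the mean annual increase of the land N
    stock; the model's implied N input is back-computed as sink + losses.
    """
    stocks = bundle.n_stock_series.sort_index()
    if len(stocks) < 2:
        raise ValueError("need at least 2 years of N stocks to estimate the sink")
    sink = float(np.mean(np.diff(stocks.to_numpy(float))))
    denit = global_total_tg(bundle.denit_flux)
    leach = global_total_tg(bundle.leach_flux)
    f = esm_fdenit(bundle)
    return BudgetSummary(
        total_input=sink + denit + leach,
        total_denit=denit,
        total_leach=leach,
        sink=sink,
        fdenit_weighted_mean=weighted_global_mean(
            f, bundle.denit_flux + bundle.leach_flux
        ),
    )


def reallocate_losses(
    total_loss: xr.DataArray, benchmark_fdenit: xr.DataArray
) -> tuple[xr.DataArray, xr.DataArray]:
    """Split a simulated total-loss field by the benchmark f_denit.

    Conservation is exact per cell: denit + leach = total.
    """
    require_aligned(total_loss, benchmark_fdenit)
    denit = (benchmark_fdenit * total_loss).rename("denit_flux")
    leach = ((1.0 - benchmark_fdenit) * total_loss).rename("leach_flux")
    return denit, leach


def overestimation_percent(model_value: float, benchmark_value: float) -> int:
    """100 * (model - benchmark) / benchmark, rounded half-up to an integer."""
    if benchmark_value == 0:
        raise ZeroDivisionError("benchmark value is zero")
    return _round_half_up(100.0 * (model_value - benchmark_value) / benchmark_value)


def sink_bias_percent(delta_f: float, global_f: float) -> int:
    """Bound on the f_denit bias from non-steady-state N sinks, in percent."""
    if global_f == 0:
        raise ZeroDivisionError("global f_denit is zero")
    return _round_half_up(100.0 * delta_f / global_f)


def latitudinal_gradient(
    value: xr.DataArray, band_width: float = 1.0, absolute: bool = True
) -> float:
    """OLS slope of area-weighted zonal means against latitude, per 10 deg.

    Zonal means are taken on ``band_width``-degree bands of |latitude|
    (or signed latitude with ``absolute=False``); the slope of band mean
    vs band center is scaled to per-10-degrees.
    """
    spec = GridSpec.from_field(value)
    area = cell_areas(spec)
    lat = value["lat"].values
    key = np.abs(lat) if absolute else lat
    band = np.floor(key / band_width) * band_width + band_width / 2
    w = (area * value.notnull()).values
    v = np.nan_to_num(value.values)
    df = pd.DataFrame(
        {
            "band": np.repeat(band, value.shape[1]),
            "wv": (w * v).ravel(),
            "w": w.ravel(),
        }
    )
    g = df.groupby("band").sum()
    g = g[g["w"] > 0]
    if len(g) < 2:
        raise ValueError("need at least two occupied latitude bands")
    x = g.index.to_numpy(float)
    y = (g["wv"] / g["w"]).to_numpy(float)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope * 10.0)


@dataclass(frozen=True)
class FdenitHistogram:
    frequencies: np.ndarray
    bin_edges: np.ndarray
    frac_near_zero: float
    frac_near_one: float


def fdenit_histogram(fdenit: xr.DataArray, bin_width: float = 0.05) -> FdenitHistogram:
    """Frequency distribution of f_denit over unmasked cells on [0, 1].

    ESMs with near-binary denitrification pile >90% of cells within one
    bin of 1; the near-bound fractions expose that directly.
    """
    v = fdenit.values
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no unmasked cells")
    nbins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
    return FdenitHistogram(
        frequencies=counts / v.size,
        bin_edges=edges,
        frac_near_zero=float(np.mean(v <= bin_width)),
        frac_near_one=float(np.mean(v >= 1.0 - bin_width)),
    )


def mask_managed(value: xr.DataArray, landcover: xr.DataArray) -> xr.DataArray:
    """Mask crop and pasture cells; natural cells pass through unchanged."""
    require_aligned(value, landcover)
    managed = landcover.isin(["crop", "cropland", "pasture"])
    return value.where(~managed)
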