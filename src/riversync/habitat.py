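"""Thermal-habitat area indices from monthly gridded SST and sea-ice fields.

The growth-potential curve maps a cell-month's SST and ice concentration to
a weight in [0, 1]: zero below 1 degC, a linear ramp up to the optimal band
(6-14 degC in the first year at sea, 6-12 degC in the second), a linear
ramp back down to zero at 18 degC (first year) or 15 degC (second year),
and zero whenever ice concentration is at least 0.5.  Weights are
multiplied by the spherical-Earth area of each 1-degree block and summed
over the age-specific ocean polygon, then averaged over the months of the
season window, giving an annual index in km^2 of growth-weighted habitat.

Season windows: first-year summer Aug-Nov, winter Dec-Apr (labelled by the
January year), second-year summer May-Nov.  The first-year polygon spans
45-61N x 64-40W; the second-year polygon adds the northern Labrador Sea
(to 70N), the Irminger Sea / eastern Atlantic to 66N, and extends east to
6W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "HabitatConfig",
    "growth_potential_weight",
    "cell_area",
    "thermal_habitat_index",
    "open_grid",
    "RETURN_YEAR_LAGS",
]

EARTH_RADIUS_KM = 6371.0

#: Lag (years) added to a window's label year to obtain the return year it
#: affects: a 1SW return in year t fed during first-summer of t-1 (lag 1)
#: and first-winter Dec(t-1)-Apr(t) (lag 0, winter labelled by the January
#: year); each 2SW window shifts one further year back.
RETURN_YEAR_LAGS: dict[tuple[str, str], int] = {
    ("1SW", "summer1"): 1,
    ("1SW", "winter1"): 0,
    ("2SW", "summer1"): 2,
    ("2SW", "winter1"): 1,
    ("2SW", "summer2"): 1,
    ("2SW", "winter2"): 0,
}

#: Month sets per season window; winter months 1-4 belong to the label
#: year, December to the preceding year.
SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "summer1": (8, 9, 10, 11),
    "winter": (12, 1, 2, 3, 4),
    "summer2": (5, 6, 7, 8, 9, 10, 11),
}


@dataclass(frozen=True)
class _Box:
    """Latitude/longitude rectangle, degrees, lon in [-180, 180]."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


FIRST_YEAR_POLYGON = (_Box(45.0, 61.0, -64.0, -40.0),)
# Second year: the first-year area plus the northern extension; the
# Labrador Sea / Irminger Sea split meridian is 45W (Cape Farewell) by
# default and configurable through HabitatConfig.
def _second_year_polygon(split_lon: float = -45.0) -> tuple[_Box, ...]:
    return (
        _Box(45.0, 70.0, -64.0, split_lon),
        _Box(45.0, 66.0, split_lon, -6.0),
    )


@dataclass
class HabitatConfig:
    """Growth-potential curve, polygon and season for one sea-year.

    Knots (degC): weight 0 at ``t_zero_low``, 1 on [``t_opt_low``,
    ``t_opt_high``], 0 again at ``t_zero_high``; zero outside and wherever
    ice >= ``ice_cutoff``.
    """

    sea_year: str = "first"
    t_zero_low: float = 1.0
    t_opt_low: float = 6.0
    t_opt_high: float = 14.0
    t_zero_high: float = 18.0
    ice_cutoff: float = 0.5
    season: str = "summer1"
    labrador_split_lon: float = -45.0
    month_agg: str = "mean"  # or "sum"
    polygon: tuple[_Box, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.t_zero_low < self.t_opt_low <= self.t_opt_high < self.t_zero_high):
            raise ValueError("curve knots must satisfy t0low < toptlow <= topthigh < t0high")
        if not (0.0 < self.ice_cutoff <= 1.0):
            raise ValueError("ice_cutoff must be in (0, 1]")
        if self.month_agg not in {"mean", "sum"}:
            raise ValueError("month_agg must be 'mean' or 'sum'")
        if self.polygon is None:
            self.polygon = (
                FIRST_YEAR_POLYGON
                if self.sea_year == "first"
                else _second_year_polygon(self.labrador_split_lon)
            )

    @classmethod
    def first_year(cls, season: str = "summer1", **kw) -> "HabitatConfig":
        return cls(sea_year="first", season=season, **kw)

    @classmethod
    def second_year(cls, season: str = "summer2", **kw) -> "HabitatConfig":
        return cls(
            sea_year="second",
            t_opt_high=12.0,
            t_zero_high=15.0,
            season=season,
            **kw,
        )


def growth_potential_weight(sst, ice, config: HabitatConfig):
    """Growth-potential weight in [0, 1] for SST (degC) and ice fraction.

    Vectorized; NaN inputs propagate to NaN (cells excluded from sums).
    Weight is 0 at exactly ``t_zero_low`` (start of the ramp) and wherever
    ice >= ``ice_cutoff``.
    """
    sst = np.asarray(sst, dtype=float)
    ice = np.asarray(ice, dtype=float)
    knots_x = [config.t_zero_low, config.t_opt_low, config.t_opt_high, config.t_zero_high]
    knots_y = [0.0, 1.0, 1.0, 0.0]
    w = np.interp(sst, knots_x, knots_y)
    w = np.where((sst < config.t_zero_low) | (sst > config.t_zero_high), 0.0, w)
    w = np.where(ice >= config.ice_cutoff, 0.0, w)
    w = np.where(np.isnan(sst) | np.isnan(ice), np.nan, w)
    return w if w.ndim else float(w)


def cell_area(lat_south: float, lat_north: float, lon_width: float = 1.0) -> float:
    """Area (km^2) of a latitude band segment on a spherical Earth.

    ``R^2 * dlambda * (sin(lat_n) - sin(lat_s))`` with R = 6371 km.
    """
    if not (-90.0 <= lat_south < lat_north <= 90.0):
        raise ValueError("need -90 <= lat_south < lat_north <= 90")
    dlam = np.deg2rad(lon_width)
    return float(
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.deg2rad(lat_north)) - np.sin(np.deg2rad(lat_south)))
    )


def _season_key(season: str) -> str:
    if season in SEASON_MONTHS:
        return season
    if season in {"winter1", "winter2"}:
        return "winter"
    raise ValueError(f"unknown season {season!r}")


def _polygon_mask(lat: np.ndarray, lon: np.ndarray, config: HabitatConfig) -> np.ndarray:
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    mask = np.zeros(glat.shape, dtype=bool)
    for box in config.polygon:
        mask |= box.contains(glat, glon)
    return mask


def thermal_habitat_index(grid: xr.Dataset, config: HabitatConfig) -> pd.Series:
    """Annual growth-weighted habitat area (km^2) over the polygon.

    ``grid`` must provide ``sst(time, lat, lon)`` and ``ice(time, lat,
    lon)`` with monthly time steps on a regular 1-degree grid (cell-center
    coordinates; HadISST-style ``latitude``/``longitude`` names are
    accepted).  Cell weights are multiplied by the spherical block areas
    and summed within the polygon per month; monthly values are then
    aggregated (mean by default) over the season window.  Winter windows
    (Dec-Apr) are labelled by the January year.  Cells with missing SST in
    every month are treated as land and excluded.
    """
    grid = _normalize_grid(grid)
    lat = grid["lat"].values
    lon = grid["lon"].values
    in_poly = _polygon_mask(lat, lon, config)
    if not in_poly.any():
        raise ValueError("polygon lies entirely outside the grid")

    areas = np.array([cell_area(phi - 0.5, phi + 0.5, 1.0) for phi in lat])
    area_grid = np.broadcast_to(areas[:, None], in_poly.shape)

    time = pd.DatetimeIndex(grid["time"].values)
    months = SEASON_MONTHS[_season_key(config.season)]
    is_winter = set(months) == set(SEASON_MONTHS["winter"])

    monthly: dict[int, list[float]] = {}
    for k, ts in enumerate(time):
        if ts.month not in months:
            continue
        label = ts.year + 1 if (is_winter and ts.month == 12) else ts.year
        sst = grid["sst"].values[k]
        ice = grid["ice"].values[k]
        w = growth_potential_weight(sst, ice, config)
        vals = np.where(in_poly, w * area_grid, np.nan)
        monthly.setdefault(label, []).append(float(np.nansum(vals)))

    n_expected = len(months)
    agg = np.nanmean if config.month_agg == "mean" else np.nansum
    out = {
        yr: float(agg(v)) for yr, v in sorted(monthly.items()) if len(v) == n_expected
    }
    return pd.Series(out, name=f"thermal_habitat_{config.sea_year}_{config.season}")


def _normalize_grid(grid: xr.Dataset) -> xr.Dataset:
    """Accept HadISST-style naming (latitude/longitude, sic)."""
    renames = {}
    for old, new in (("latitude", "lat"), ("longitude", "lon"), ("sic", "ice")):
        if old in grid or old in grid.coords:
            renames[old] = new
    return grid.rename(renames) if renames else grid


def open_grid(path: str | Path) -> xr.Dataset:
    """Read a NetCDF grid written by the synthetic generator (or any
    HadISST-like layout) using the NetCDF3/scipy backend."""
    return _normalize_grid(xr.open_dataset(path, engine="scipy"))
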