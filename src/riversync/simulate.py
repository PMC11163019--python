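"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the structures the analysis assumes: fork-length
panels drawn from the dynamic factor model itself (latent random walks,
river loadings, structured observation noise, contiguous missing-data
gaps), smooth monthly SST/ice fields on a 1-degree grid with a seasonal
cycle and an interannual trend, and autocorrelated AR(1) covariate series.
All generators are pure functions of their configuration plus a seed.

Default panel dimensions follow the study system: 19 rivers, 51 years
(1971-2021), 3 latent trends, observation SD 15 mm, river mean lengths
around 543 mm, and 20-51 observed years per river with head/tail gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from riversync.covariates import CovariateTable
from riversync.panel import LengthPanel
from riversync.records import FishRecord

__all__ = [
    "DFATruth",
    "simulate_panel",
    "default_truth",
    "head_tail_missing_mask",
    "SyntheticGridSpec",
    "simulate_grid",
    "simulate_covariates",
    "simulate_fish_records",
]

DEFAULT_COVARIATE_NAMES = (
    "AMO",
    "NAO",
    "NLCI",
    "th_summer1",
    "th_winter1",
    "food_pc1",
    "pfa_density_first",
    "ER_NAC_small",
)


# ---------------------------------------------------------------------------
# fork-length panels


@dataclass
class DFATruth:
    """Known data-generating parameters for a synthetic length panel.

    Trends are generated as random walks ``x_t = x_{t-1} + w_t`` with
    standard-normal innovations (Q = I, the identifiability convention;
    loadings carry the scale).  ``obs_cov`` adds a common covariance to the
    observation noise (compound symmetry).  ``missing_mask`` is True where
    a cell is unobserved.
    """

    m: int = 3
    loadings: np.ndarray = None  # (S, m)
    offsets: np.ndarray = None   # (S,) river mean lengths, mm
    obs_sd: np.ndarray | float = 15.0
    obs_cov: float = 0.0
    missing_mask: np.ndarray = None  # (S, T) bool
    years: np.ndarray = None
    rivers: list[str] = None
    latitudes: np.ndarray = None
    seed: int = 0
    trends: np.ndarray = field(default=None, repr=False)  # filled by simulate_panel

    @property
    def S(self) -> int:
        return self.loadings.shape[0]

    @property
    def T(self) -> int:
        return len(self.years)


def head_tail_missing_mask(
    rng: np.random.Generator,
    S: int,
    T: int,
    min_obs: int = 20,
    max_missing_frac: float = 0.3,
) -> np.ndarray:
    """Contiguous-gap missingness: each river observed in one unbroken run
    of ``min_obs``..T years, with head/tail gaps, capped at an overall
    missing fraction."""
    if not 0 <= max_missing_frac <= 0.8:
        raise ValueError("max_missing_frac must be in [0, 0.8]")
    n_obs = rng.integers(min_obs, T + 1, size=S)
    # lengthen the shortest runs until the overall gap fraction is in cap
    while (S * T - n_obs.sum()) / (S * T) > max_missing_frac:
        n_obs[np.argmin(n_obs)] = min(T, n_obs.min() + 5)
    mask = np.ones((S, T), dtype=bool)
    for i in range(S):
        start = int(rng.integers(0, T - n_obs[i] + 1))
        mask[i, start : start + int(n_obs[i])] = False
    return mask


def default_truth(
    seed: int = 0,
    S: int = 19,
    T: int = 51,
    m: int = 3,
    obs_sd: float = 15.0,
    obs_cov: float = 0.0,
    loading_scale: float = 2.0,
    mean_length: float = 543.0,
    mean_length_sd: float = 20.0,
    first_year: int = 1971,
    missing: bool = True,
    min_obs: int = 20,
) -> DFATruth:
    """Study-scale truth: loadings U(-scale, scale), river means around
    ``mean_length`` mm, contiguous observation runs of >= ``min_obs`` years."""
    rng = np.random.default_rng(seed)
    loadings = rng.uniform(-loading_scale, loading_scale, size=(S, m))
    offsets = rng.normal(mean_length, mean_length_sd, size=S)
    mask = (
        head_tail_missing_mask(rng, S, T, min_obs=min_obs)
        if missing
        else np.zeros((S, T), dtype=bool)
    )
    lats = np.sort(rng.uniform(45.0, 58.0, size=S))
    return DFATruth(
        m=m,
        loadings=loadings,
        offsets=offsets,
        obs_sd=obs_sd,
        obs_cov=obs_cov,
        missing_mask=mask,
        years=np.arange(first_year, first_year + T),
        rivers=[f"river_{i + 1:02d}" for i in range(S)],
        latitudes=lats,
        seed=seed,
    )


def simulate_panel(truth: DFATruth) -> tuple[LengthPanel, DFATruth]:
    """Draw a length panel from the factor-model truth.

    ``y = Z x + a + v`` with compound-symmetric noise when ``obs_cov`` is
    nonzero; cells under ``missing_mask`` become NaN.  The realized trends
    are stored back on the returned truth.  Same seed, same output.
    """
    if truth.loadings.shape[1] != truth.m:
        raise ValueError(
            f"loadings have {truth.loadings.shape[1]} columns, expected m={truth.m}"
        )
    rng = np.random.default_rng(truth.seed)
    S, T, m = truth.S, truth.T, truth.m
    x = np.cumsum(rng.standard_normal((m, T)), axis=1)

    sd = np.broadcast_to(np.asarray(truth.obs_sd, dtype=float), (S,))
    if truth.obs_cov:
        R = np.full((S, S), truth.obs_cov)
        np.fill_diagonal(R, sd**2)
        noise = rng.multivariate_normal(np.zeros(S), R, size=T).T
    else:
        noise = sd[:, None] * rng.standard_normal((S, T))

    y = truth.loadings @ x + truth.offsets[:, None] + noise
    y = np.where(truth.missing_mask, np.nan, y)
    panel = LengthPanel(
        values=y,
        rivers=truth.rivers or [f"river_{i + 1:02d}" for i in range(S)],
        years=truth.years,
        latitudes=truth.latitudes,
    )
    truth.trends = x
    return panel, truth


# ---------------------------------------------------------------------------
# gridded SST / ice


def _default_mean_field(lat: np.ndarray, month: int) -> np.ndarray:
    """Smooth north-cold/south-warm field with an August-peaked cycle."""
    seasonal = 5.0 * np.cos(2.0 * np.pi * (month - 8.5) / 12.0)
    return 12.0 - 0.35 * (lat - 45.0) + seasonal


def _default_ice_rule(sst: np.ndarray) -> np.ndarray:
    """Logistic ramp below 0 degC; open water above 2 degC."""
    ice = 1.0 / (1.0 + np.exp(sst / 0.5))
    return np.where(sst >= 2.0, 0.0, np.clip(ice, 0.0, 1.0))


@dataclass
class SyntheticGridSpec:
    """Configuration of the synthetic monthly SST/ice field.

    ``mean_field(lat_array, month) -> degC`` sets the deterministic part,
    ``trend_per_decade`` adds a linear interannual warming, ``noise_sd``
    i.i.d. cell noise, and ``ice_rule(sst) -> fraction`` derives ice
    concentration from the (noise-free would-be) SST.
    """

    lat_min: float = 44.5
    lat_max: float = 70.5
    lon_min: float = -64.5
    lon_max: float = -5.5
    year_min: int = 1971
    year_max: int = 2021
    months: Sequence[int] = tuple(range(1, 13))
    mean_field: Callable[[np.ndarray, int], np.ndarray] = None
    trend_per_decade: float = 0.25
    noise_sd: float = 0.3
    ice_rule: Callable[[np.ndarray], np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("invalid lat/lon bounds")
        if self.mean_field is None:
            self.mean_field = _default_mean_field
        if self.ice_rule is None:
            self.ice_rule = _default_ice_rule


def simulate_grid(spec: SyntheticGridSpec) -> xr.Dataset:
    """Monthly ``sst(time, lat, lon)`` and ``ice(time, lat, lon)`` on a
    regular 1-degree grid of cell centers."""
    rng = np.random.default_rng(spec.seed)
    lat = np.arange(np.ceil(spec.lat_min - 0.5) + 0.5, spec.lat_max, 1.0)
    lon = np.arange(np.ceil(spec.lon_min - 0.5) + 0.5, spec.lon_max, 1.0)
    times = []
    sst_layers = []
    ice_layers = []
    for year in range(spec.year_min, spec.year_max + 1):
        warming = spec.trend_per_decade * (year - spec.year_min) / 10.0
        for month in spec.months:
            base = spec.mean_field(lat, month)[:, None] + warming
            base = np.broadcast_to(base, (len(lat), len(lon))).copy()
            ice = spec.ice_rule(base)
            if spec.noise_sd:
                base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
            times.append(np.datetime64(f"{year:04d}-{month:02d}-15"))
            sst_layers.append(base)
            ice_layers.append(ice)
    return xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), np.array(sst_layers)),
            "ice": (("time", "lat", "lon"), np.array(ice_layers)),
        },
        coords={"time": np.array(times), "lat": lat, "lon": lon},
        attrs={"description": "synthetic monthly SST and sea-ice concentration"},
    )


# ---------------------------------------------------------------------------
# covariate series


def simulate_covariates(
    years: int | Sequence[int],
    ar_coef: float = 0.6,
    seed: int = 0,
    names: Sequence[str] = DEFAULT_COVARIATE_NAMES,
) -> CovariateTable:
    """Stationary AR(1) series (unit marginal variance) per covariate name.

    ``x_t = phi x_{t-1} + sqrt(1 - phi^2) eps_t`` with ``x_0 ~ N(0, 1)``;
    the table is returned unscaled (``center_scale`` is a later step).
    """
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1")
    if isinstance(years, (int, np.integer)):
        years = np.arange(1971, 1971 + int(years))
    else:
        years = np.asarray(list(years), dtype=int)
    rng = np.random.default_rng(seed)
    T = len(years)
    data = {}
    for name in names:
        x = np.empty(T)
        x[0] = rng.standard_normal()
        innov_sd = np.sqrt(1.0 - ar_coef**2)
        for t in range(1, T):
            x[t] = ar_coef * x[t - 1] + innov_sd * rng.standard_normal()
        data[name] = x
    return CovariateTable(pd.DataFrame(data, index=pd.Index(years, name="year")))


# ---------------------------------------------------------------------------
# individual fish records


def simulate_fish_records(
    seed: int = 0,
    rivers: dict[str, tuple[float, float]] | None = None,
    year_min: int = 1990,
    year_max: int = 2015,
    n_range: tuple[int, int] = (5, 60),
    within_year_sd: float = 30.0,
    hatchery_frac: float = 0.05,
    unaged_river: str | None = None,
    unaged_years: set[int] | None = None,
) -> tuple[list[FishRecord], pd.DataFrame]:
    """Individual 1SW/2SW records with known river-year means and counts.

    ``rivers`` maps name -> (latitude, mean 1SW length mm); 2SW means sit
    ~210 mm above 1SW.  Each river-year draws a wild-fish count from
    ``n_range`` (so some years fall below the n>=10 screen), adds a
    fraction of hatchery fish, and optionally leaves small fish unaged in
    one river/year scope.  Returns the records and a truth table of
    river-year wild counts and mean lengths per age class.
    """
    rng = np.random.default_rng(seed)
    if rivers is None:
        rivers = {
            "Alder": (46.2, 535.0),
            "Birch": (48.9, 545.0),
            "Cedar": (51.3, 550.0),
            "Dogwood": (54.0, 540.0),
        }
    records: list[FishRecord] = []
    truth_rows = []
    for name, (lat, mean1) in rivers.items():
        for year in range(year_min, year_max + 1):
            for age, mean in (("1SW", mean1), ("2SW", mean1 + 210.0)):
                n = int(rng.integers(*n_range))
                lengths = rng.normal(mean, within_year_sd, size=n)
                lengths = np.clip(lengths, 300.0, 1100.0)
                for L in lengths:
                    sea_age = age
                    if (
                        unaged_river == name
                        and unaged_years
                        and year in unaged_years
                        and L < 630.0
                    ):
                        sea_age = "unknown"
                    records.append(
                        FishRecord(
                            river=name,
                            year=year,
                            fork_length=float(L),
                            sea_age=sea_age,
                            origin="wild",
                            latitude=lat,
                        )
                    )
                n_hatch = rng.binomial(n, hatchery_frac)
                for L in rng.normal(mean, within_year_sd, size=n_hatch):
                    records.append(
                        FishRecord(
                            river=name,
                            year=year,
                            fork_length=float(np.clip(L, 300.0, 1100.0)),
                            sea_age=age,
                            origin="hatchery",
                            latitude=lat,
                        )
                    )
                truth_rows.append(
                    {
                        "river": name,
                        "year": year,
                        "age": age,
                        "n_wild": n,
                        "mean_length": float(np.mean(lengths)),
                    }
                )
    return records, pd.DataFrame(truth_rows)
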