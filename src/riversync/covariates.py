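"""Annual marine covariate series for the factor model.

Climate window means (calendar-year AMO, Dec-Mar NAO), the food-availability
index (PC1 of zooplankton and capelin biomass), at-sea density indices built
from pre-fishery abundance (PFA) with the 7-month 3%/month mortality
back-adjustment to 1 January, fishery exploitation rates, and the
center-and-scale step applied before covariates enter the DFA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CovariateTable",
    "climate_means",
    "food_availability_index",
    "adjust_pfa_to_jan",
    "density_index",
    "exploitation_rates",
    "center_scale",
    "MONTHLY_MORTALITY",
    "MONTHS_ADJUSTED",
]

MONTHLY_MORTALITY = 0.03
MONTHS_ADJUSTED = 7


@dataclass
class CovariateTable:
    """Year-indexed covariate series, optionally centered and scaled.

    When ``scaled`` is True each series has mean 0 and SD 1 (ddof=1) over
    its non-missing years; the original means/SDs are stored so the
    transform is invertible.
    """

    data: pd.DataFrame
    scaled: bool = False
    means: pd.Series | None = field(default=None, repr=False)
    sds: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.sort_index()
        self.data.index = self.data.index.astype(int)
        self.data.index.name = "year"

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.data[name]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CovariateTable":
        return cls(pd.read_csv(path, index_col="year"))


def climate_means(monthly: pd.Series, window: str = "Jan-Dec") -> pd.Series:
    """Annual mean of a monthly climate index over a named window.

    ``monthly`` is indexed by (year, month).  ``"Jan-Dec"`` means are
    labelled by the calendar year; ``"Dec-Mar"`` means combine December
    with the following January-March and are labelled by the year of the
    January-March block.  Years with missing window months are dropped.
    """
    if window not in {"Jan-Dec", "Dec-Mar"}:
        raise ValueError("window must be 'Jan-Dec' or 'Dec-Mar'")
    s = monthly.copy()
    s.index = pd.MultiIndex.from_tuples(
        [(int(y), int(m)) for y, m in s.index], names=["year", "month"]
    )
    out = {}
    years = sorted({y for y, _ in s.index})
    for y in years:
        if window == "Jan-Dec":
            keys = [(y, m) for m in range(1, 13)]
        else:
            keys = [(y - 1, 12)] + [(y, m) for m in (1, 2, 3)]
        try:
            vals = [s.loc[k] for k in keys]
        except KeyError:
            continue
        out[y] = float(np.mean(vals))
    return pd.Series(out, name=monthly.name)


def food_availability_index(
    zoop: pd.Series,
    capelin_next: pd.Series,
    *extra_series: pd.Series,
) -> tuple[pd.Series, float]:
    """PC1 of annual prey-biomass series as a single food-availability index.

    Series are aligned on overlapping years, centered and scaled, and the
    first principal component of their correlation matrix is extracted.
    The sign is oriented so that a positive loading sum on the biomass
    inputs makes low-biomass years score negative.  Returns the PC1 score
    series and the fraction of variance explained (largest eigenvalue of
    the correlation matrix divided by the number of series).
    """
    series = [zoop, capelin_next, *extra_series]
    if len(series) < 2:
        raise ValueError("need at least two biomass series")
    frame = pd.concat(series, axis=1, join="inner").dropna()
    if len(frame) < 3:
        raise ValueError("fewer than 3 overlapping years")
    X = frame.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Xs, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v1 = evecs[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    scores = Xs @ v1
    var_explained = float(evals[-1] / corr.shape[0])
    return pd.Series(scores, index=frame.index, name="food_pc1"), var_explained


def adjust_pfa_to_jan(pfa_aug1):
    """Back-adjust a 1 August PFA to 1 January of the same year.

    Applies the assumed at-sea mortality of 0.03 per month over the 7
    months January-August: ``PFA * exp(0.03 * 7)``.
    """
    return pfa_aug1 * np.exp(MONTHLY_MORTALITY * MONTHS_ADJUSTED)


def density_index(pfa: pd.DataFrame, sea_year: str = "first") -> pd.Series:
    """At-sea density (abundance) index from PFA components.

    ``pfa`` is year-indexed with columns ``nac_maturing`` and
    ``nac_nonmaturing`` (thousands of fish as of 1 August) and, for the
    second sea-year, ``sneac_nonmaturing`` (as of 1 January).  First year:
    the whole North American smolt cohort, adjusted to 1 January.  Second
    year: 1 Jan-adjusted NAC non-maturing plus the SNEAC non-maturing
    component (already a 1 January value).  Years missing any needed
    component are dropped.
    """
    if sea_year == "first":
        needed = pfa[["nac_maturing", "nac_nonmaturing"]].dropna()
        out = adjust_pfa_to_jan(needed["nac_maturing"] + needed["nac_nonmaturing"])
    elif sea_year == "second":
        needed = pfa[["nac_nonmaturing", "sneac_nonmaturing"]].dropna()
        out = adjust_pfa_to_jan(needed["nac_nonmaturing"]) + needed["sneac_nonmaturing"]
    else:
        raise ValueError("sea_year must be 'first' or 'second'")
    out.name = f"pfa_density_{sea_year}"
    return out


def exploitation_rates(
    fishery: pd.DataFrame,
    pfa_nonmaturing: pd.Series | None = None,
    denominator: str = "catch_plus_returns",
) -> pd.DataFrame:
    """Annual exploitation rates of the marine salmon fisheries.

    ``fishery`` is year-indexed with catch counts ``catch_nl``,
    ``catch_lab``, ``catch_spm``, ``catch_wg`` and return counts
    ``returns_nac_small`` / ``returns_nac_large``.  The NAC rate pools the
    Newfoundland, Labrador and Saint-Pierre-et-Miquelon catches of a size
    class; with the default denominator it is catch / (catch + returns),
    the standard exploitation rate in [0, 1] (returns are counted after
    the fishery); ``denominator="returns"`` keeps the literal catch /
    returns ratio.  The West Greenland rate divides ``catch_wg`` by the
    NAC non-maturing PFA for the year.  Zero denominators yield missing
    values with a warning.
    """
    if denominator not in {"catch_plus_returns", "returns"}:
        raise ValueError("denominator must be 'catch_plus_returns' or 'returns'")
    nac_catch = fishery[["catch_nl", "catch_lab", "catch_spm"]].sum(axis=1)
    out = {}
    for size in ("small", "large"):
        returns = fishery[f"returns_nac_{size}"]
        denom = nac_catch + returns if denominator == "catch_plus_returns" else returns
        rate = nac_catch / denom
        bad = denom <= 0
        if bad.any():
            warnings.warn(f"zero denominator for ER_NAC_{size} in {list(fishery.index[bad])}",
                          stacklevel=2)
            rate = rate.mask(bad)
        rate = rate.where(~((nac_catch == 0) & ~bad), 0.0)
        out[f"ER_NAC_{size}"] = rate
    if pfa_nonmaturing is not None:
        pfa = pfa_nonmaturing.reindex(fishery.index)
        bad = (pfa <= 0) | pfa.isna()
        if (pfa <= 0).any():
            warnings.warn("zero non-maturing PFA for ER_WG", stacklevel=2)
        out["ER_WG"] = (fishery["catch_wg"] / pfa).mask(bad)
    return pd.DataFrame(out, index=fishery.index)


def center_scale(table: CovariateTable) -> CovariateTable:
    """Z-score each covariate over its non-missing years (ddof=1).

    Idempotent; the original means and SDs are stored on the returned
    table so :func:`invert_scaling` can reproduce the input.
    """
    if table.scaled:
        return table
    means = table.data.mean()
    sds = table.data.std(ddof=1)
    if (sds == 0).any():
        const = list(sds.index[sds == 0])
        raise ValueError(f"constant series cannot be scaled: {const}")
    return CovariateTable(
        data=(table.data - means) / sds, scaled=True, means=means, sds=sds
    )


def invert_scaling(table: CovariateTable) -> CovariateTable:
    """Undo :func:`center_scale` using the stored means and SDs."""
    if not table.scaled:
        return table
    if table.means is None or table.sds is None:
        raise ValueError("scaled table has no stored means/SDs")
    return CovariateTable(data=table.data * table.sds + table.means, scaled=False)
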