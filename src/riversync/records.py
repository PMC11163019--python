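"""Individual fish records and the inclusion filters that build the panel.

The filter chain applies the inclusion protocol for returning adult salmon:
drop fish positively identified as non-wild, keep the requested sea-age
class within the analysis window, drop river-years with fewer than 10
retained fish of that age class, and drop rivers with fewer than 20
qualifying years.  Unknown-origin fish are retained (only identified
hatchery/aquaculture/captive releases are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from riversync.panel import LengthPanel

__all__ = [
    "FishRecord",
    "filter_records",
    "assign_small_unaged",
    "build_panel",
    "records_to_frame",
    "records_from_csv",
]

MIN_FISH_PER_YEAR = 10
MIN_YEARS_PER_RIVER = 20
SMALL_1SW_THRESHOLD_MM = 630.0

#: Origin labels that identify a fish as not wild.
NON_WILD_ORIGINS = frozenset({"hatchery", "captive", "sas", "captive/SAS", "aquaculture"})


@dataclass(frozen=True)
class FishRecord:
    """One returning adult salmon.

    ``sea_age`` is one of ``{"1SW", "2SW", "other", "unknown"}``; ``origin``
    is ``"wild"``, ``"unknown"`` or a non-wild label such as ``"hatchery"``.
    """

    river: str
    year: int
    fork_length: float
    sea_age: str = "unknown"
    origin: str = "wild"
    latitude: float | None = None
    doy: int | None = None
    gear: str | None = None

    def __post_init__(self) -> None:
        if not self.fork_length > 0:
            raise ValueError(f"fork_length must be positive, got {self.fork_length}")
        if not (1970 <= self.year <= 2022):
            raise ValueError(f"year {self.year} outside 1970-2022")


def records_to_frame(records: Iterable[FishRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.river, r.latitude, r.year, r.doy, r.fork_length, r.sea_age, r.origin, r.gear)
            for r in records
        ],
        columns=[
            "river",
            "latitude",
            "year",
            "doy",
            "fork_length_mm",
            "sea_age",
            "origin",
            "gear",
        ],
    )


def records_from_csv(path: str | Path) -> list[FishRecord]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            FishRecord(
                river=str(row.river),
                year=int(row.year),
                fork_length=float(row.fork_length_mm),
                sea_age=str(row.sea_age),
                origin=str(row.origin),
                latitude=None if pd.isna(row.latitude) else float(row.latitude),
                doy=None if pd.isna(row.doy) else int(row.doy),
                gear=None if pd.isna(row.gear) else str(row.gear),
            )
        )
    return out


def assign_small_unaged(
    records: Sequence[FishRecord],
    river: str,
    years: set[int],
    threshold_mm: float = SMALL_1SW_THRESHOLD_MM,
) -> list[FishRecord]:
    """Relabel small unaged fish as 1SW in a configured river/year scope.

    In years where scale-reading of small fish was unavailable, fish of
    unknown sea age with fork length strictly below ``threshold_mm`` are
    assumed to be 1SW (the size classes barely overlap at the threshold).
    Only unknown-age records inside the scope are touched.
    """
    out = []
    for r in records:
        if (
            r.river == river
            and r.year in years
            and r.sea_age == "unknown"
            and r.fork_length < threshold_mm
        ):
            out.append(replace(r, sea_age="1SW"))
        else:
            out.append(r)
    return out


def filter_records(
    records: Sequence[FishRecord],
    age_class: str,
    year_min: int,
    year_max: int,
    min_fish_per_year: int = MIN_FISH_PER_YEAR,
    min_years_per_river: int = MIN_YEARS_PER_RIVER,
) -> list[FishRecord]:
    """Apply the inclusion filters for one sea-age class.

    Order: origin exclusion, age selection, year-range crop, per-river-year
    n >= ``min_fish_per_year``, per-river >= ``min_years_per_river``
    qualifying years.  Unknown-origin fish count as wild.
    """
    if age_class not in {"1SW", "2SW"}:
        raise ValueError(f"age_class must be 1SW or 2SW, got {age_class!r}")
    kept = [
        r
        for r in records
        if r.origin not in NON_WILD_ORIGINS
        and r.sea_age == age_class
        and year_min <= r.year <= year_max
    ]
    if not kept:
        warnings.warn("no records survive the origin/age/year filters", stacklevel=2)
        return []

    counts: dict[tuple[str, int], int] = {}
    for r in kept:
        counts[(r.river, r.year)] = counts.get((r.river, r.year), 0) + 1
    kept = [r for r in kept if counts[(r.river, r.year)] >= min_fish_per_year]

    years_per_river: dict[str, set[int]] = {}
    for r in kept:
        years_per_river.setdefault(r.river, set()).add(r.year)
    kept = [r for r in kept if len(years_per_river[r.river]) >= min_years_per_river]

    if not kept:
        warnings.warn("all rivers fell below the year-count threshold", stacklevel=2)
    return kept


def build_panel(records: Sequence[FishRecord], center: bool = False) -> LengthPanel:
    """Average fork length per river-year into a :class:`LengthPanel`.

    Records are assumed already filtered.  Rivers are ordered by latitude
    when known (south to north), otherwise alphabetically; the year axis
    spans the min..max observed years.
    """
    if not records:
        raise ValueError("no records to build a panel from")
    frame = records_to_frame(records)
    lat = frame.groupby("river")["latitude"].mean()
    rivers = sorted(lat.index, key=lambda r: (lat[r] if np.isfinite(lat[r]) else np.inf, r))
    years = np.arange(frame["year"].min(), frame["year"].max() + 1)

    grouped = frame.groupby(["river", "year"])["fork_length_mm"]
    means = grouped.mean().unstack().reindex(index=rivers, columns=years)
    counts = grouped.size().unstack().reindex(index=rivers, columns=years).fillna(0)

    panel = LengthPanel(
        values=means.to_numpy(dtype=float),
        rivers=rivers,
        years=years,
        n=counts.to_numpy(dtype=float),
        latitudes=lat.reindex(rivers).to_numpy(dtype=float),
    )
    return panel.center() if center else panel
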