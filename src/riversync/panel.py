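"""River x year panel of mean fork lengths, the observation set of the DFA.

Missing river-years are encoded as NaN and mean "no observation"; they are
never zeros.  A panel can be centered on the river-specific means (the scale
the factor model is fitted on); the means are retained so centering is
invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LengthPanel"]


@dataclass
class LengthPanel:
    """Mean fork length (mm) by river and calendar year.

    Parameters
    ----------
    values : (S, T) array
        Mean fork length per river-year; NaN marks missing cells.
    rivers : sequence of str
        River identifiers, one per row.
    years : sequence of int
        Contiguous calendar years, one per column.
    n : (S, T) array, optional
        Number of fish behind each cell (0 where missing).
    latitudes : sequence of float, optional
        River latitude in decimal degrees, used only for presentation order.
    centered : bool
        True when each river's non-missing values have been centered on the
        river-specific mean.
    river_means : (S,) array, optional
        The river means removed by centering (mm); stored for inversion.
    """

    values: np.ndarray
    rivers: list[str]
    years: np.ndarray
    n: np.ndarray | None = None
    latitudes: np.ndarray | None = None
    centered: bool = False
    river_means: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.rivers = list(self.rivers)
        if self.values.shape != (len(self.rivers), len(self.years)):
            raise ValueError(
                f"values shaped {self.values.shape}, expected "
                f"({len(self.rivers)}, {len(self.years)})"
            )
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must form a contiguous range")
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=float)
            if self.n.shape != self.values.shape:
                raise ValueError("n must match values in shape")
        if self.latitudes is not None:
            self.latitudes = np.asarray(self.latitudes, dtype=float)
        if self.river_means is not None:
            self.river_means = np.asarray(self.river_means, dtype=float)

    # -- basic geometry -------------------------------------------------

    @property
    def n_rivers(self) -> int:
        return len(self.rivers)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_obs(self) -> int:
        """Number of non-missing cells."""
        return int(np.isfinite(self.values).sum())

    @property
    def mask(self) -> np.ndarray:
        """Boolean (S, T) array, True where observed."""
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rivers, columns=self.years)

    # -- centering ------------------------------------------------------

    def center(self) -> "LengthPanel":
        """Center each river on its mean over non-missing years."""
        if self.centered:
            return self
        means = np.nanmean(self.values, axis=1)
        return LengthPanel(
            values=self.values - means[:, None],
            rivers=self.rivers,
            years=self.years,
            n=self.n,
            latitudes=self.latitudes,
            centered=True,
            river_means=means,
        )

    def uncenter(self) -> "LengthPanel":
        """Add back the stored river means, reproducing the raw panel."""
        if not self.centered:
            return self
        if self.river_means is None:
            raise ValueError("centered panel has no stored river means")
        return LengthPanel(
            values=self.values + self.river_means[:, None],
            rivers=self.rivers,
            years=self.years,
            n=self.n,
            latitudes=self.latitudes,
            centered=False,
        )

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the matrix as CSV (rivers as rows, empty string = missing).

        A JSON sidecar holds river means, latitudes and per-cell counts so
        the panel round-trips exactly.
        """
        path = Path(path)
        self.to_frame().to_csv(path, na_rep="")
        if sidecar is None:
            sidecar = path.with_suffix(".json")
        meta = {
            "centered": self.centered,
            "river_means": None
            if self.river_means is None
            else self.river_means.tolist(),
            "latitudes": None if self.latitudes is None else self.latitudes.tolist(),
            "n": None if self.n is None else self.n.tolist(),
        }
        Path(sidecar).write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "LengthPanel":
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        frame.columns = frame.columns.astype(int)
        meta = {}
        if sidecar is None:
            sidecar = path.with_suffix(".json")
        sidecar = Path(sidecar)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            values=frame.to_numpy(dtype=float),
            rivers=[str(r) for r in frame.index],
            years=frame.columns.to_numpy(),
            n=None if meta.get("n") is None else np.asarray(meta["n"], dtype=float),
            latitudes=None
            if meta.get("latitudes") is None
            else np.asarray(meta["latitudes"], dtype=float),
            centered=bool(meta.get("centered", False)),
            river_means=None
            if meta.get("river_means") is None
            else np.asarray(meta["river_means"], dtype=float),
        )
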