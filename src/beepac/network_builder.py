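"""Daily quantitative bipartite visitation networks and floral density.

Visitation records are pooled across transects within each sampling day
into a bee x plant count matrix (one :class:`DailyNetwork` per date).
Floral density for a day is the mean number of open floral units per
4 m^2 plot, restricted to plant species visited at least once by a bee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

__all__ = [
    "DailyNetwork",
    "build_daily_networks",
    "visited_plants",
    "floral_density",
    "floral_density_series",
]


@dataclass
class DailyNetwork:
    """Quantitative visitation matrix for one sampling day.

    ``counts[i, k]`` is the number of visits of bee species
    ``bee_labels[i]`` to plant species ``plant_labels[k]`` summed over all
    transects walked that day.  Species with zero interactions that day are
    absent (no zero rows or columns are kept).
    """

    date: Date
    year: int
    bee_labels: list[str]
    plant_labels: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.bee_labels), len(self.plant_labels)):
            raise ValueError("counts shape does not match label lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.size and (
            (self.counts.sum(axis=1) == 0).any() or (self.counts.sum(axis=0) == 0).any()
        ):
            raise ValueError("zero row/column present; prune species first")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def links(self) -> set[tuple[str, str]]:
        """Distinct (bee, plant) pairs with at least one visit."""
        ii, kk = np.nonzero(self.counts)
        return {(self.bee_labels[i], self.plant_labels[k]) for i, k in zip(ii, kk)}

    def to_long(self) -> pd.DataFrame:
        """Edge list ``date,bee,plant,count`` (observed links only)."""
        ii, kk = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "date": [self.date] * len(ii),
                "bee": [self.bee_labels[i] for i in ii],
                "plant": [self.plant_labels[k] for k in kk],
                "count": self.counts[ii, kk],
            }
        )

    def to_wide(self) -> pd.DataFrame:
        """Bees x plants count matrix as a labelled frame."""
        return pd.DataFrame(self.counts, index=self.bee_labels, columns=self.plant_labels)


def build_daily_networks(records: pd.DataFrame) -> list[DailyNetwork]:
    """Pool records into one :class:`DailyNetwork` per distinct date."""
    if len(records) == 0:
        raise ValueError("no visitation records")
    networks = []
    for day, sub in records.groupby("date"):
        mat = (
            sub.groupby(["bee_species", "plant_species"])["count"]
            .sum()
            .unstack(fill_value=0)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
        networks.append(
            DailyNetwork(
                date=day,
                year=int(sub["year"].iloc[0]),
                bee_labels=list(mat.index),
                plant_labels=list(mat.columns),
                counts=mat.to_numpy(dtype=np.int64),
            )
        )
    networks.sort(key=lambda n: n.date)
    return networks


def visited_plants(records: pd.DataFrame) -> set[str]:
    """Plant species visited at least once anywhere in the record set."""
    return set(records["plant_species"].unique())


def floral_density(
    plots: pd.DataFrame, date: Date, visited: set[str]
) -> float:
    """Mean open floral units per plot on ``date``, bee-visited species only.

    Units are summed within each surveyed (transect, plot) and the mean is
    taken across plots.  Raises if no plots were surveyed that date.
    """
    day = plots[plots["date"] == date]
    if len(day) == 0:
        raise ValueError(f"no floral plots surveyed on {date}")
    relevant = day[day["plant_species"].isin(visited)]
    per_plot = relevant.groupby(["transect_id", "plot_id"])["floral_units"].sum()
    # plots where no visited species flowered still contribute zero
    all_plots = day.groupby(["transect_id", "plot_id"]).size()
    per_plot = per_plot.reindex(all_plots.index, fill_value=0.0)
    return float(per_plot.mean())


def floral_density_series(
    plots: pd.DataFrame, dates, visited: set[str]
) -> pd.Series:
    """Floral density for each date in ``dates`` (index: date)."""
    out = pd.Series(
        {d: floral_density(plots, d, visited) for d in dates}, name="floral_density"
    )
    out.index.name = "date"
    return out
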