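"""Tabular data model for bumblebee visitation surveys.

Visitation records, floral plot counts and a species trait table are the
three inputs of the pipeline.  They are held as plain :class:`pandas.DataFrame`
objects with fixed schemas; this module provides validated readers, the
season/rarity filters applied before any network is built, the
flowering-period classifier, and the descriptive visitation summary
(per-species shares and multi-year link persistence).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VISIT_COLUMNS",
    "FLORAL_COLUMNS",
    "TRAIT_COLUMNS",
    "VisitationSummary",
    "read_visitation",
    "read_floral_plots",
    "read_traits",
    "restrict_to_core_season",
    "filter_rare_species",
    "classify_flowering_period",
    "summarize_visitation",
]

VISIT_COLUMNS = ["year", "date", "transect_id", "bee_species", "plant_species", "count"]
FLORAL_COLUMNS = ["date", "transect_id", "plot_id", "plant_species", "floral_units"]
TRAIT_COLUMNS = ["bee_species", "proboscis_mm"]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_dates(raw: pd.Series, path) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.astype(bool)
    bad |= parsed.isna() & ~raw.astype(bool)
    if bad.any():
        rows = [i + 2 for i in raw.index[bad][:5]]  # +2: header + 1-based
        raise SchemaError(
            f"{path}: unparseable ISO date(s), e.g. {raw[bad].iloc[0]!r} "
            f"at file line(s) {rows}"
        )
    return parsed.dt.date


def read_visitation(path: str | Path) -> pd.DataFrame:
    """Read a visitation CSV/TSV into the canonical record frame.

    The ``count`` column is optional (one individual per row when absent).
    Rows with ``count == 0`` carry no observation and are dropped with a
    warning; negative counts, invalid dates, or a date outside its stated
    year are hard errors that name the offending file line.
    """
    df = _read_table(path, [c for c in VISIT_COLUMNS if c != "count"])
    if "count" not in df.columns:
        df["count"] = "1"
    df["date"] = _parse_dates(df["date"], path)
    try:
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer year or count ({exc})") from exc
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0]) + 2
        raise SchemaError(f"{path}: negative count at file line {row}")
    mismatch = df["date"].map(lambda d: d.year) != df["year"]
    if mismatch.any():
        row = int(df.index[mismatch][0]) + 2
        raise SchemaError(f"{path}: date outside its stated year at file line {row}")
    empty = (df["bee_species"].str.strip() == "") | (df["plant_species"].str.strip() == "")
    if empty.any():
        row = int(df.index[empty][0]) + 2
        raise SchemaError(f"{path}: empty species name at file line {row}")
    zero = df["count"] == 0
    if zero.any():
        warnings.warn(
            f"{path}: dropped {int(zero.sum())} row(s) with count 0", stacklevel=2
        )
        df = df[~zero].reset_index(drop=True)
    return df[VISIT_COLUMNS]


def read_floral_plots(path: str | Path) -> pd.DataFrame:
    """Read floral plot counts (open floral units per 2x2 m plot)."""
    df = _read_table(path, FLORAL_COLUMNS)
    df["date"] = _parse_dates(df["date"], path)
    df["floral_units"] = df["floral_units"].astype(float)
    if (df["floral_units"] < 0).any():
        row = int(df.index[df["floral_units"] < 0][0]) + 2
        raise SchemaError(f"{path}: negative floral_units at file line {row}")
    return df[FLORAL_COLUMNS]


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read the bee trait table (proboscis length, mm)."""
    df = _read_table(path, TRAIT_COLUMNS)
    df["proboscis_mm"] = df["proboscis_mm"].astype(float)
    if (df["proboscis_mm"] <= 0).any():
        raise SchemaError(f"{path}: proboscis_mm must be positive")
    if df["bee_species"].duplicated().any():
        dup = df["bee_species"][df["bee_species"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate trait entry for {dup!r}")
    return df[TRAIT_COLUMNS]


def restrict_to_core_season(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only July and August records (the analysed core season)."""
    months = records["date"].map(lambda d: d.month)
    return records[months.isin([7, 8])].reset_index(drop=True)


def filter_rare_species(records: pd.DataFrame, min_total: int = 20) -> pd.DataFrame:
    """Drop bee species whose total individual count is below ``min_total``.

    The survey retains only species recorded often enough to support the
    competition analysis; the default threshold of 20 separates the seven
    rarely caught species (max 13 individuals) from the retained set.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = records.groupby("bee_species")["count"].sum()
    keep = totals.index[totals >= min_total]
    return records[records["bee_species"].isin(keep)].reset_index(drop=True)


def classify_flowering_period(
    date: Date,
    early_end: tuple[int, int] = (7, 20),
    middle_end: tuple[int, int] = (8, 20),
) -> str:
    """Classify a date into the early / middle / late flowering stage.

    Default boundaries: early through July 20, middle July 21 - August 20,
    late from August 21 on.  July 20 is assigned to *early* (the middle
    stage explicitly starts on July 21); both boundaries are configurable.
    """
    md = (date.month, date.day)
    if md <= early_end:
        return "early"
    if md <= middle_end:
        return "middle"
    return "late"


@dataclass(frozen=True)
class VisitationSummary:
    """Descriptive summary: species shares and multi-year link persistence."""

    species_shares: pd.DataFrame  # bee_species, total, share_pct (desc by total)
    link_persistence: pd.Series  # n_years_observed -> n_links
    total_links: int
    grand_total: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "grand_total": self.grand_total,
                "total_links": self.total_links,
                "species_shares": self.species_shares.to_dict(orient="records"),
                "link_persistence": {
                    int(k): int(v) for k, v in self.link_persistence.items()
                },
            },
            indent=2,
        )


def summarize_visitation(records: pd.DataFrame) -> VisitationSummary:
    """Per-species totals/shares and link persistence across years.

    Shares are ``100 * total / grand_total`` rounded to two decimals.  A
    link is a distinct (bee, plant) pair; its persistence is the number of
    distinct years in which it was observed.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    totals = (
        records.groupby("bee_species")["count"].sum().sort_values(ascending=False)
    )
    grand = int(totals.sum())
    shares = pd.DataFrame(
        {
            "bee_species": totals.index,
            "total": totals.to_numpy(dtype=int),
            "share_pct": np.round(100.0 * totals.to_numpy() / grand, 2),
        }
    ).reset_index(drop=True)
    years_per_link = records.groupby(["bee_species", "plant_species"])["year"].nunique()
    persistence = years_per_link.value_counts().sort_index()
    persistence.index.name = "n_years_observed"
    persistence.name = "n_links"
    return VisitationSummary(
        species_shares=shares,
        link_persistence=persistence,
        total_links=int(len(years_per_link)),
        grand_total=grand,
    )
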