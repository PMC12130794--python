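"""Synthetic multi-year plant-bumblebee visitation communities.

Two generators:

* :func:`generate_community` draws a full multi-year survey — visitation
  records, floral plot counts and a trait table — from a mass-action
  visitation model with proboscis-corolla trait matching and a seasonal
  floral-density curve, mirroring a five-year alpine-meadow bumblebee
  survey (weekly sampling in July-August, ~14 bee species with strongly
  skewed abundances, ~50 bee-visited plant species).  A truth bundle
  records every latent parameter so pipeline stages can be checked against
  known ground truth.

* :func:`generate_competition_scenario` plants known regression effects
  directly into a model-ready competition table (covariates with
  study-like distributions; responses drawn from the planted coefficient
  vector plus a species random intercept and Gaussian noise), giving the
  mixed models a parameter-recovery target with exact expected values.

Expected visits per (bee, plant, transect) follow the mass-action form
mean = E * x_bee * w_plant(day) * c(proboscis, corolla), realized as
Poisson counts; the trait-matching kernel is a Gaussian in the
proboscis-corolla depth mismatch with an additive floor, so short-tongued
generalists still visit open flowers broadly while long-tongued species
concentrate on deep-tubed flowers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd

from .glmm import add_transforms

__all__ = [
    "SyntheticConfig",
    "ScenarioCoefficients",
    "generate_community",
    "generate_competition_scenario",
]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the five-year study design."""

    seed: int  # mandatory for reproducibility
    n_years: int = 5
    start_year: int = 2018
    days_per_year: tuple[int, ...] = (5, 9, 9, 8, 7)  # weekly sampling days
    first_month_day: tuple[int, int] = (7, 1)  # weekly steps keep dates in Jul-Aug
    n_bees: int = 14
    n_plants: int = 50
    bee_abundance_sigma: float = 2.0  # log-normal sd -> strongly skewed
    proboscis_mm: tuple[float, ...] | None = None  # drawn if None
    corolla_mm: tuple[float, ...] | None = None
    kernel_width_mm: float = 3.0
    kernel_floor: float = 0.2
    season_peak_doy: float = 200.0  # ~July 19
    season_width_days: float = 18.0
    late_decline_rate: float = 0.02  # extra decay per day past the peak
    peak_density_units: float = 150.0  # open floral units per 4 m^2 at peak
    transects_per_day: int = 30
    plots_per_transect: int = 5
    expected_visits_per_transect: float = 8.0

    def __post_init__(self) -> None:
        if self.n_bees < 1 or self.n_plants < 1:
            raise ValueError("need at least one bee and one plant species")
        if len(self.days_per_year) != self.n_years:
            if len(self.days_per_year) == 1:
                self.days_per_year = self.days_per_year * self.n_years
            else:
                raise ValueError("days_per_year must have one entry per year")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _sampling_dates(config: SyntheticConfig) -> list[Date]:
    dates = []
    for y_off, n_days in enumerate(config.days_per_year):
        year = config.start_year + y_off
        first = Date(year, *config.first_month_day)
        for w in range(n_days):
            dates.append(first + timedelta(days=7 * w))
    return dates


def _season_curve(doy: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    bump = np.exp(-((doy - config.season_peak_doy) ** 2) / (2 * config.season_width_days**2))
    decline = np.exp(-config.late_decline_rate * np.clip(doy - config.season_peak_doy, 0, None))
    return config.peak_density_units * bump * decline


def _draw_traits(rng: np.random.Generator, config: SyntheticConfig):
    if config.proboscis_mm is not None:
        proboscis = np.asarray(config.proboscis_mm, dtype=float)
    else:
        # mostly short-tongued species (~7.5 mm) with a couple of long-tongued
        n_long = max(1, round(0.15 * config.n_bees))
        short = np.clip(rng.normal(7.5, 1.2, config.n_bees - n_long), 5.5, 10.0)
        long_ = np.clip(rng.normal(13.0, 1.0, n_long), 11.0, 15.0)
        proboscis = np.concatenate([short, long_])
    if config.corolla_mm is not None:
        corolla = np.asarray(config.corolla_mm, dtype=float)
    else:
        n_deep = round(0.3 * config.n_plants)
        open_ = rng.uniform(2.0, 8.0, config.n_plants - n_deep)
        deep = rng.uniform(9.0, 16.0, n_deep)
        corolla = np.concatenate([open_, deep])
    return proboscis, corolla


def generate_community(config: SyntheticConfig):
    """Draw (visits, plots, traits, truth) under the mass-action model."""
    rng = np.random.default_rng(config.seed)
    bees = [f"Bombus_sp{i + 1:02d}" for i in range(config.n_bees)]
    plants = [f"Plant_sp{j + 1:02d}" for j in range(config.n_plants)]
    x_bee = rng.lognormal(0.0, config.bee_abundance_sigma, config.n_bees)
    x_bee /= x_bee.sum()
    proboscis, corolla = _draw_traits(rng, config)
    c = config.kernel_floor + np.exp(
        -((proboscis[:, None] - corolla[None, :]) ** 2) / (2 * config.kernel_width_mm**2)
    )
    plant_base = rng.lognormal(0.0, 1.0, config.n_plants)
    doy0 = Date(config.start_year, *config.first_month_day).timetuple().tm_yday
    plant_peak = rng.uniform(doy0 + 3, doy0 + 58, config.n_plants)
    plant_width = rng.uniform(10.0, 25.0, config.n_plants)

    dates = _sampling_dates(config)
    visit_rows, plot_rows = [], []
    truth_daily = {}
    for d in dates:
        doy = d.timetuple().tm_yday
        w = plant_base * np.exp(-((doy - plant_peak) ** 2) / (2 * plant_width**2))
        plant_share = w / w.sum()
        density = _season_curve(np.array([doy]), config)[0]
        # expected visits per transect distributed by mass action
        mean_cell = (
            config.expected_visits_per_transect
            * (x_bee[:, None] * plant_share[None, :] * c)
            / (x_bee[:, None] * plant_share[None, :] * c).sum()
        )
        for t in range(config.transects_per_day):
            tid = f"{d.isoformat()}-T{t + 1:02d}"
            counts = rng.poisson(mean_cell)
            ii, jj = np.nonzero(counts)
            for i, j in zip(ii, jj):
                visit_rows.append(
                    {
                        "year": d.year,
                        "date": d,
                        "transect_id": tid,
                        "bee_species": bees[i],
                        "plant_species": plants[j],
                        "count": int(counts[i, j]),
                    }
                )
            for p in range(config.plots_per_transect):
                units = rng.poisson(plant_share * density / config.plots_per_transect)
                for j in np.nonzero(units)[0]:
                    plot_rows.append(
                        {
                            "date": d,
                            "transect_id": tid,
                            "plot_id": f"P{p + 1}",
                            "plant_species": plants[j],
                            "floral_units": float(units[j]),
                        }
                    )
        truth_daily[d.isoformat()] = {
            "density": float(density),
            "plant_share": plant_share.tolist(),
        }

    visits = pd.DataFrame(
        visit_rows, columns=["year", "date", "transect_id", "bee_species", "plant_species", "count"]
    )
    plots = pd.DataFrame(
        plot_rows, columns=["date", "transect_id", "plot_id", "plant_species", "floral_units"]
    )
    traits = pd.DataFrame({"bee_species": bees, "proboscis_mm": proboscis})
    truth = {
        "x_bee": dict(zip(bees, x_bee.tolist())),
        "proboscis_mm": dict(zip(bees, proboscis.tolist())),
        "corolla_mm": dict(zip(plants, corolla.tolist())),
        "preference": c.tolist(),
        "plant_base": dict(zip(plants, plant_base.tolist())),
        "daily": truth_daily,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
    }
    return visits, plots, traits, truth


@dataclass
class ScenarioCoefficients:
    """Planted fixed effects on the transformed-covariate scale."""

    intercept: float = 0.45
    abundance: float = 0.07
    density: float = 0.01
    proboscis: float = 0.08
    interaction: float = -0.02
    period_middle: float = 0.01
    period_late: float = 0.05
    year: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ScenarioConfig:
    seed: int
    coefficients: ScenarioCoefficients = field(default_factory=ScenarioCoefficients)
    n_species: int = 7
    n_years: int = 5
    start_year: int = 2018
    days_per_year: tuple[int, ...] = (5, 9, 9, 8, 7)
    first_month_day: tuple[int, int] = (7, 1)
    random_intercept_sd: float = 0.05
    residual_sd: float = 0.10
    abundance_sigma: float = 1.0
    density_noise_sd: float = 0.3


def generate_competition_scenario(config: ScenarioConfig):
    """Model-ready competition table with known planted coefficients.

    Covariates: a seasonal floral-density curve with log-uniform day noise,
    per-(day, species) log-uniform abundances, fixed per-species proboscis
    lengths.  Bounded (uniform) covariate tails keep the planted linear
    predictor inside the index bounds [0, 1] at the default effect sizes;
    it is checked and a violation raises.  Both responses (interspecific
    and intraspecific index) are drawn from the same planted coefficient
    vector applied to the log-z/z-transformed covariates, plus a
    (clipped-normal) species random intercept and Gaussian residual.

    Returns ``(table, truth)`` where truth holds the coefficient vector and
    the per-species random intercepts.
    """
    rng = np.random.default_rng(config.seed)
    coef = config.coefficients
    species = [f"Bombus_sp{i + 1:02d}" for i in range(config.n_species)]
    proboscis = np.concatenate(
        [
            np.clip(rng.normal(7.5, 1.2, config.n_species - 1), 5.5, 10.0),
            [rng.uniform(12.0, 15.0)],
        ]
    )
    scfg = SyntheticConfig(seed=int(rng.integers(2**31)), n_years=config.n_years,
                           start_year=config.start_year,
                           days_per_year=config.days_per_year,
                           first_month_day=config.first_month_day)
    dates = _sampling_dates(scfg)
    rows = []
    half = np.sqrt(3.0)  # uniform(-h, h) has unit sd at h = sqrt(3)
    for d in dates:
        doy = d.timetuple().tm_yday
        density = _season_curve(np.array([doy]), scfg)[0] * np.exp(
            rng.uniform(-half, half) * config.density_noise_sd
        )
        abund = np.exp(rng.uniform(-half, half, config.n_species) * config.abundance_sigma)
        for i, sp in enumerate(species):
            rows.append(
                {
                    "date": d,
                    "year": d.year,
                    "species": sp,
                    "abundance_est": abund[i],
                    "floral_density": density,
                    "proboscis_mm": proboscis[i],
                }
            )
    table = pd.DataFrame(rows)
    from .data_model import classify_flowering_period

    table["flowering_period"] = table["date"].map(classify_flowering_period)
    table = add_transforms(table)
    b_species = np.clip(
        rng.normal(0.0, config.random_intercept_sd, config.n_species),
        -2 * config.random_intercept_sd,
        2 * config.random_intercept_sd,
    )
    year_eff = dict(
        zip(range(config.start_year, config.start_year + config.n_years), coef.year)
    )
    period_eff = {"early": 0.0, "middle": coef.period_middle, "late": coef.period_late}
    lin = (
        coef.intercept
        + coef.abundance * table["abundance_lz"]
        + coef.density * table["floral_density_lz"]
        + coef.proboscis * table["proboscis_z"]
        + coef.interaction * table["abundance_lz"] * table["floral_density_lz"]
        + table["year"].map(year_eff)
        + table["flowering_period"].map(period_eff)
        + b_species[[species.index(s) for s in table["species"]]]
    )
    if lin.min() < 0 or lin.max() > 1:
        raise ValueError(
            "planted effects push the expected index outside [0, 1]: "
            f"range ({lin.min():.3f}, {lin.max():.3f})"
        )
    table["inter_acting"] = lin + rng.normal(0.0, config.residual_sd, len(table))
    table["intra"] = lin + rng.normal(0.0, config.residual_sd, len(table))
    truth = {
        "coefficients": vars(coef) | {"year": list(coef.year)},
        "random_intercepts": dict(zip(species, b_species.tolist())),
        "residual_sd": config.residual_sd,
        "n_rows": len(table),
    }
    return table, truth
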