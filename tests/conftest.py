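"""Shared fixtures: small hand-built record frames and synthetic runs."""

from datetime import date

import pandas as pd
import pytest

from beepac.network_builder import DailyNetwork
from beepac.synthetic import ScenarioConfig, SyntheticConfig, generate_community


def make_visits(rows):
    """Build a visitation frame from (year, date, transect, bee, plant, count)."""
    return pd.DataFrame(
        rows, columns=["year", "date", "transect_id", "bee_species", "plant_species", "count"]
    )


@pytest.fixture
def worked_network():
    """The 2x2 worked example: bees B1,B2 x plants P1,P2, a=[[2,0],[1,1]]."""
    return DailyNetwork(
        date=date(2020, 7, 15),
        year=2020,
        bee_labels=["B1", "B2"],
        plant_labels=["P1", "P2"],
        counts=[[2, 0], [1, 1]],
    )


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down community: 3 years, 4 days each, 6 bees, 12 plants."""
    return SyntheticConfig(
        seed=42,
        n_years=3,
        days_per_year=(4, 4, 4),
        n_bees=6,
        n_plants=12,
        transects_per_day=8,
        expected_visits_per_transect=10.0,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def scenario_table():
    from beepac.synthetic import generate_competition_scenario

    return generate_competition_scenario(ScenarioConfig(seed=7))
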