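import pytest

import evactwin as et
from evactwin.population import Marginal, PopulationConfig, ZoneConfig


@pytest.fixture(scope="session")
def catalog():
    return et.load_catalog()


@pytest.fixture(scope="session")
def grouping():
    return et.default_grouping()


@pytest.fixture(scope="session")
def published_table():
    return et.load_published_counts()


@pytest.fixture(scope="session")
def shipped_weights():
    return et.load_default_weights()


@pytest.fixture(scope="session")
def default_pop_config():
    return et.load_population_config()


def make_single_zone_config(
    n_agents,
    seed=0,
    p_flood_zone=0.3,
    p_prior_hurricane=0.5,
    shelter_distance_km=10.0,
    constraint_prevalences=None,
    income_probs=(0.5, 0.3, 0.2),
    education_probs=(0.1, 0.4, 0.3, 0.2),
):
    zone = ZoneConfig(
        zone_id="Z1",
        weight=1.0,
        age_marginal=Marginal(("18_34", "35_64", "65_plus"), (0.3, 0.5, 0.2)),
        income_marginal=Marginal(("low", "middle", "high"), income_probs),
        education_marginal=Marginal(
            ("no_hs", "hs", "some_college", "bachelor_plus"), education_probs
        ),
        ethnicity_marginal=Marginal(("a", "b", "c"), (0.5, 0.3, 0.2)),
        p_flood_zone=p_flood_zone,
        p_prior_hurricane=p_prior_hurricane,
        shelter_distance_km=shelter_distance_km,
        constraint_prevalences=constraint_prevalences or {},
    )
    return PopulationConfig(n_agents=n_agents, zones=(zone,), seed=seed)
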