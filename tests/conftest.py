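import numpy as np
import pandas as pd
import pytest

from webrds import (
    InvalidInjection,
    PopulationConfig,
    SimulationConfig,
    TraitSpec,
    fabricate_submissions,
    generate_population,
    simulate_recruitment,
)


@pytest.fixture(scope="session")
def small_population():
    """500 individuals, Poisson(6) degrees, one homophilous binary trait."""
    config = PopulationConfig(
        n_individuals=500,
        degree_model="poisson",
        degree_params={"mean": 6.0},
        trait_specs=[TraitSpec("group", ["a", "b"], [0.4, 0.6], 0.5)],
        province_distribution={"north": 0.5, "south": 0.5},
        province_homophily=0.4,
    )
    return generate_population(config, rng_seed=11)


@pytest.fixture(scope="session")
def injected_run(small_population):
    """A recruitment forest plus fabricated submissions with every invalid
    kind injected, and the injection bookkeeping."""
    sim = SimulationConfig(
        n_seeds=8,
        participation_probability=0.5,
        invalid_injection=InvalidInjection(
            underage_rate=0.05,
            duplicate_token_rate=0.08,
            shared_ip_rate=0.08,
            fast_completion_rate=0.04,
        ),
        network_size_missing_rate=0.1,
        rng_seed=7,
    )
    forest = simulate_recruitment(small_population, sim)
    fab = fabricate_submissions(forest, small_population, sim)
    return forest, fab


def make_records(rows):
    """Build a minimal submissions frame from dicts, filling defaults."""
    defaults = {
        "recruiter_id": None,
        "is_seed": False,
        "timestamp": None,
        "stated_age": 25,
        "completion_minutes": 10.0,
        "phone_token": None,
        "email_token": None,
        "chat_token": None,
        "ip_token": None,
        "education": "university",
        "partners_6mo": 2,
        "reported_network_size": 5,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, id=i, **row)
        if r["timestamp"] is None:
            r["timestamp"] = float(i)
        out.append(r)
    df = pd.DataFrame(out)
    df.index = pd.Index(df["id"])
    df.index.name = None
    return df
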