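import numpy as np
import pytest

from radflow import (LocalityTable, SyntheticScenario, generate_localities,
                     generate_migration_truth)


@pytest.fixture
def square_localities() -> LocalityTable:
    """Four localities on a small lat/lon square with hand-set populations."""
    return LocalityTable(
        ids=np.array(["A", "B", "C", "D"]),
        names=np.array(["a", "b", "c", "d"]),
        latitude=np.array([0.0, 0.0, 1.0, 1.0]),
        longitude=np.array([0.0, 1.0, 0.0, 1.0]),
        land_area=np.array([50.0, 100.0, 150.0, 200.0]),
        populations={2007: np.array([1000.0, 2000.0, 500.0, 4000.0]),
                     2010: np.array([1100.0, 1900.0, 600.0, 4100.0])},
    )


@pytest.fixture
def small_scenario() -> SyntheticScenario:
    return SyntheticScenario(n_localities=30, seed=11,
                             amenity_types=("school", "shop", "tourism"))


@pytest.fixture
def small_truth(small_scenario):
    localities, features = generate_localities(small_scenario)
    flows, advanced = generate_migration_truth(localities, features, small_scenario)
    return small_scenario, advanced, features, flows


def random_locality_table(rng: np.random.Generator, n: int) -> LocalityTable:
    """Random valid locality table for property tests."""
    return LocalityTable(
        ids=np.array([f"L{i}" for i in range(n)]),
        names=np.array([f"loc{i}" for i in range(n)]),
        latitude=rng.uniform(-60, 60, n),
        longitude=rng.uniform(-170, 170, n),
        land_area=rng.uniform(10, 500, n),
        populations={2007: rng.uniform(100, 50000, n)},
    )
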