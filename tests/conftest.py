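"""Shared fixtures: small synthetic cities and their derived analysis objects."""

import numpy as np
import pandas as pd
import pytest

from mobishift import (
    aggregate_outflow,
    compute_lambda,
    coverage_container,
    find_excluded_pairs,
)
from mobishift.synthetic import CityConfig, simulate_city


@pytest.fixture(scope="session")
def small_city():
    """12x12 city with straddling origins; cheap enough for most tests."""
    cfg = CityConfig(grid_n=12, dzn_block=3, straddle_fraction=0.05, seed=11)
    return simulate_city(cfg)


@pytest.fixture(scope="session")
def grid6_city():
    """6x6 / 3x3 city without straddlers, used for brute-force geometric oracles."""
    cfg = CityConfig(grid_n=6, dzn_block=2, straddle_fraction=0.0, seed=5)
    return simulate_city(cfg)


@pytest.fixture(scope="session")
def small_lambda(small_city):
    """MobilityChange computed from the small city."""
    excluded = find_excluded_pairs(small_city.origins, small_city.destinations)
    out_t = aggregate_outflow(small_city.visits, excluded, "test", origins=small_city.origins.ids)
    out_b = aggregate_outflow(
        small_city.visits, excluded, "baseline", origins=small_city.origins.ids
    )
    return compute_lambda(out_t, out_b, small_city.coverage)


@pytest.fixture()
def toy_visits():
    """Hand-written three-origin edge list for arithmetic-level checks."""
    return pd.DataFrame(
        {
            "origin_id": ["a", "a", "b", "a", "a", "b"],
            "destination_id": ["z1", "z2", "z1", "z1", "z2", "z1"],
            "period": ["test", "test", "test", "baseline", "baseline", "baseline"],
            "mean_daily_visits": [5.0, 3.0, 2.0, 10.0, 6.0, 4.0],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
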