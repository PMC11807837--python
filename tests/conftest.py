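import logging

import numpy as np
import pytest

from traitshift.io import CommunityData, DisturbanceTable, TraitTable
from traitshift.synthetic import ScenarioConfig, simulate_scenario

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_scenario():
    """Two regions x 40 plots, 400-species pool, sorting on wood density and seed mass."""
    cfg = ScenarioConfig(seed=7, n_regions=2, plots_per_region=40, n_species_pool=400)
    abundance, meta, traits, disturbance, truth = simulate_scenario(cfg)
    return cfg, abundance, meta, traits, disturbance, truth


@pytest.fixture(scope="session")
def small_tables(small_scenario):
    cfg, abundance, meta, traits, disturbance, truth = small_scenario
    community = CommunityData(abundance, meta)
    trait_table = TraitTable(traits)
    deg = (meta["plot_area"] / meta["basal_area"]).rename("degradation")
    dist = DisturbanceTable(disturbance.drop(columns="degradation"), deg)
    return community, trait_table, dist, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
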