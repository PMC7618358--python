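import dataclasses

import pandas as pd
import pytest

from hoplandscape.calling import call_pool_integrations, default_blacklist
from hoplandscape.pipeline import _pool_classes, simulate_replicate
from hoplandscape.synthetic import default_scenario


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def experiment(scenario):
    """Default two-replicate synthetic experiment: (reads, populations, integrations)."""
    all_reads, pops = [], []
    for i in (1, 2):
        _, reads, p = simulate_replicate(scenario, f"rep{i}", seed=10 * i)
        all_reads.append(reads)
        pops.extend(p)
    reads = pd.concat(all_reads, ignore_index=True)
    blacklist = default_blacklist(origin_launchpad=scenario.hopping.launch_position)
    integrations = call_pool_integrations(reads, _pool_classes(scenario), blacklist=blacklist)
    return reads, pops, integrations


@pytest.fixture()
def small_scenario(scenario):
    """Cheap variant for smoke tests."""
    return dataclasses.replace(
        scenario, hopping=dataclasses.replace(scenario.hopping, n_cells=800)
    )
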