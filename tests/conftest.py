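import numpy as np
import pytest

from musakaryo.ancestry import identify_diagnostic_alleles
from musakaryo.chromosomes import default_chromosomes
from musakaryo.simulate import SimulationConfig, simulate_panels


@pytest.fixture(scope="session")
def chroms():
    """Full-size 11-chromosome metadata."""
    return default_chromosomes()


@pytest.fixture(scope="session")
def small_chroms():
    """Scaled-down chromosomes (~3-8 Mb) for fast simulations."""
    return default_chromosomes(scale=0.2)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        n_panel_a=4, n_panel_b=4, sites_per_chrom=500, diagnostic_fraction=0.5, seed=11
    )


@pytest.fixture(scope="session")
def panels_with_truth(sim_config, small_chroms):
    """(panel_a, panel_b, truth diagnostics) on the small chromosomes."""
    return simulate_panels(sim_config, small_chroms)


@pytest.fixture(scope="session")
def diagnostics(panels_with_truth):
    panel_a, panel_b, _truth = panels_with_truth
    return identify_diagnostic_alleles(panel_a, panel_b)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
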