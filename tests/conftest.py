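import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ctmarker.simulate import (
    SimulationConfig,
    make_dataset,
    simulate_species_panel,
    synthetic_reference_fragment,
)


@pytest.fixture(scope="session")
def reference():
    """Synthetic reference fragment and its landmark geometry."""
    return synthetic_reference_fragment()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact multi-species dataset with ground truth."""
    config = SimulationConfig(
        n_species=5, samples_per_species=6, alleles_per_species=3, seed=101
    )
    return make_dataset(config)


@pytest.fixture(scope="session")
def diploid_panel():
    """Single-species diploid panel with one homozygote per allele."""
    return simulate_species_panel(n_samples=20, n_alleles=5, seed=7)
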