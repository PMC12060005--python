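import numpy as np
import pytest

from chromland.core import GenomeModel, Interval
from chromland.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Compact full dataset: 2 autosomes + Z + W, ~1.1k genes."""
    cfg = SimulationConfig(
        seed=7,
        n_autosomes=2,
        autosome_length=1_200_000,
        z_length=1_200_000,
        w_length=100_000,
        genes_per_autosome=400,
        n_s0_genes=139,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def toy_genome():
    return GenomeModel(
        chromosomes=[("chr1", 10_000), ("chr2", 5_000)],
        regions=[(Interval("chr2", 0, 2_000), "S0")],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
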