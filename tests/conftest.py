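import numpy as np
import pytest

from chromoci import (
    ContactMap,
    GenomeAssembly,
    SimulationConfig,
    bin_genome,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def tiny_assembly():
    return GenomeAssembly((("chr1", 1_200_000), ("chr2", 800_000)))


@pytest.fixture(scope="session")
def tiny_bins(tiny_assembly):
    # 6 + 4 bins of 200 kb
    return bin_genome(tiny_assembly, 200_000)


def random_map(bins, rng, density=0.5, max_count=9):
    """Random sparse symmetric map over a bin table."""
    n = bins.n_bins
    iu, ju = np.triu_indices(n)
    keep = rng.random(iu.size) < density
    counts = rng.integers(1, max_count + 1, size=keep.sum())
    return ContactMap(bins, iu[keep], ju[keep], counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def effect_sim():
    """Planted-effect simulation shared across tests: f=0.4, gamma=2."""
    cfg = SimulationConfig(seed=11, local_loss=0.4, trans_gain=2.0)
    genome, maps, truth = simulate_experiment(
        cfg, conditions=("growing", "senescent", "esc")
    )
    return cfg, genome, maps, truth


@pytest.fixture(scope="session")
def null_sim():
    """Null simulation (no planted effects) shared across tests."""
    cfg = SimulationConfig(seed=7)
    genome, maps, truth = simulate_experiment(cfg)
    return cfg, genome, maps, truth
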