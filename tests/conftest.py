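import numpy as np
import pytest

from wormsweep.genome import GenomeLayout, PopulationState, default_layout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture
def toy_layout():
    """Two short chromosomes; enough structure to exercise recombination."""
    return GenomeLayout((("I", 4), ("II", 3)), window_size_bp=200_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_population(layout, genotypes, male=None):
    """Build a PopulationState from an explicit (N, 2, W) label array."""
    haps = np.asarray(genotypes, dtype=np.int8)
    if male is None:
        male = np.zeros(haps.shape[0], dtype=bool)
    return PopulationState(layout=layout, haplotypes=haps, male=np.asarray(male))


def het_population(layout, n, bg_a=0, bg_b=1):
    """n worms all heterozygous bg_a|bg_b at every window."""
    w = layout.total_windows
    haps = np.empty((n, 2, w), dtype=np.int8)
    haps[:, 0, :] = bg_a
    haps[:, 1, :] = bg_b
    return uniform_population(layout, haps)
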