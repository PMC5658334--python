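import numpy as np
import pytest

from dropevo.arena import make_empty_arena, make_lsystem_arena, make_pillar_arena
from dropevo.genome import Genome, Individual


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arenas():
    return {
        "empty": make_empty_arena(),
        "pillars": make_pillar_arena(),
        "lsystem": make_lsystem_arena(seed=7),
    }


@pytest.fixture
def uniform_population():
    """Twenty identical-fitness individuals with distinct genomes."""
    rng = np.random.default_rng(7)
    pop = []
    for _ in range(20):
        v = rng.dirichlet(np.ones(4))
        pop.append(Individual(genome=Genome.from_array(v), repeat_fitnesses=[2.0] * 5))
    return pop


def stub_evaluator(value: float = 3.0):
    """Evaluator returning a constant regardless of genome/arena/seed."""

    def _eval(genome, arena, seed):
        return value

    return _eval
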