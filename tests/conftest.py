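import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from citrosat import Genome
from citrosat.simulate import PlantSpec, generate_genome

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def planted_genome():
    """A 20 kb chromosome with one extremely variable di, one class I tri,
    and one class II tetra tract, far enough apart for independent primers."""
    specs = [
        PlantSpec("AT", 25, "chr1", 3001),       # 50 nt, class I, extremely variable
        PlantSpec("AAG", 14, "chr1", 9001),      # 42 nt, class I, extremely variable
        PlantSpec("AGAT", 6, "chr1", 15001),     # 24 nt, class II
    ]
    genome, truth = generate_genome({"chr1": 20_000}, specs, gc_background=0.45, seed=11)
    return genome, truth
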