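import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from endomine.simulate import SimulationConfig, make_dataset


@pytest.fixture(scope="session")
def fixture_dataset():
    """The default synthetic study (scaled scaffold anatomy, seed 11)."""
    return make_dataset(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna_str(n, rng, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def mutate_subs(seq, n_subs, rng):
    """Exactly n substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)
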