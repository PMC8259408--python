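import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from dirpred.alignio import Alignment
from dirpred.fixtures import FixtureSpec, make_synthetic_system
from dirpred.null_model import load_wag

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def wag():
    return load_wag()


@pytest.fixture(scope="session")
def default_system():
    """One default synthetic system (7 paralogs x 12 species)."""
    return make_synthetic_system(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced system for fast end-to-end runs."""
    return FixtureSpec(
        n_paralogs=4,
        n_species=6,
        ligand_length=20,
        receptor_length=30,
        planted_sites=((8, "DIR"), (3, "cysteine-like")),
        seed=5,
    )


@pytest.fixture(scope="session")
def small_system(small_spec):
    return make_synthetic_system(small_spec)


def random_alignment(rng, n_rows, n_cols, gap_prob=0.0, prefix="s"):
    aa = np.array(list(AA + "-"))
    probs = np.full(21, (1 - gap_prob) / 20)
    probs[20] = gap_prob
    seqs = [
        "".join(aa[rng.choice(21, size=n_cols, p=probs)]) for _ in range(n_rows)
    ]
    return Alignment([f"{prefix}{i}_sp{i}" for i in range(n_rows)], seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
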