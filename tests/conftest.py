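import numpy as np
import pytest

from pedcaller import Individual, Pedigree
from pedcaller.simulate import pedigree_template


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("F", sex="male"),
            Individual("M", sex="female"),
            Individual("C", father_id="F", mother_id="M"),
        ]
    )


@pytest.fixture
def sib2() -> Pedigree:
    return pedigree_template("Sib2")


@pytest.fixture
def nuc4() -> Pedigree:
    return pedigree_template("Nuc4")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)


def random_likelihoods(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random per-member likelihood triples, max-normalized."""
    L = rng.random((size, 3)) ** 2 + 1e-6
    return L / L.max(axis=1, keepdims=True)
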