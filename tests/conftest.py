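import numpy as np
import pytest

from flockherit.pedigree import Pedigree


def random_pedigree(rng: np.random.Generator, n: int, p_known: float = 0.7) -> Pedigree:
    """Sequential random pedigree: each individual may draw parents from
    any earlier individuals (or have them unknown)."""
    records = []
    for i in range(n):
        sire = dam = None
        if i >= 2 and rng.uniform() < p_known:
            sire, dam = (f"i{k}" for k in rng.choice(i, size=2, replace=False))
        records.append((f"i{i}", sire, dam))
    return Pedigree.from_records(records)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([("A", None, None), ("B", None, None), ("C", "A", "B")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
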