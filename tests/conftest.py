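import numpy as np
import pytest

from toxqsar import synthdata
from toxqsar.chemfeat import MoleculeRecord, parse_and_clean


@pytest.fixture(scope="session")
def toy_records():
    """A fixed small toy molecule set (shared, read-only)."""
    return synthdata.gen_toy_molecules(120, seed=42)


@pytest.fixture(scope="session")
def toy_molset(toy_records):
    molset, _ = parse_and_clean(toy_records)
    return molset


@pytest.fixture()
def rng():
    return np.random.default_rng(20160201)


@pytest.fixture()
def simple_records():
    return [
        MoleculeRecord("m1", "c1ccccc1", 2.0),
        MoleculeRecord("m2", "CCO", 3.5),
        MoleculeRecord("m3", "CC(=O)O", 1.0),
        MoleculeRecord("m4", "c1ccncc1", 4.2),
    ]
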