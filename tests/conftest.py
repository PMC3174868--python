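import pytest

from nmrcase import (
    constitution_from_smiles,
    make_reference_corpus,
    make_toy_structures,
)


@pytest.fixture(scope="session")
def toy_structures():
    """Twenty random small structures, shared across tests (read-only)."""
    return make_toy_structures(seed=11, n=20, heavy_atom_range=(2, 6))


@pytest.fixture(scope="session")
def reference_corpus():
    return make_reference_corpus(seed=7, n=60)


@pytest.fixture()
def ethanol():
    return constitution_from_smiles("CCO", atom_ids=("C1", "C2", "O1"))


@pytest.fixture()
def dimethyl_ether():
    return constitution_from_smiles("COC", atom_ids=("C1", "O1", "C2"))
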