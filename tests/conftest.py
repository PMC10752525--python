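import pytest

from divlib.core_io import CompoundSet, record_from_smiles
from divlib.synthetic_data import FixtureSpec, generate_pool


def make_set(smiles, prefix="C"):
    return CompoundSet(
        records=[record_from_smiles(f"{prefix}{i + 1}", s) for i, s in enumerate(smiles)]
    )


@pytest.fixture
def benzene_set():
    return make_set(["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"])


@pytest.fixture
def mixed_set():
    return make_set(
        [
            "c1ccccc1",
            "c1ccncc1",
            "CCO",
            "CC(=O)Nc1ccccc1",
            "O=C(O)c1ccccc1",
            "NCCc1ccccc1",
            "C1CCOCC1",
            "c1ccc2occc2c1",
            "CC(C)Cc1ccc(C)cc1C(C)C(=O)O",
            "CN1CCC[C@H]1c1cccnc1",
        ]
    )


@pytest.fixture(scope="session")
def small_pools():
    """Two-sublibrary synthetic pool reused across read-only tests."""
    return generate_pool(FixtureSpec(n_sublibraries=2, size_per_sublibrary=60, seed=11))
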