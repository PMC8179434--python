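import pytest
from rdkit import Chem

from mcspace.synthetic import generate_library

CYCLODODECANE = "C1CCCCCCCCCCC1"
CYCLODECANE = "C1CCCCCCCCC1"
HEXAGLYCINE = "O=C1CNC(=O)CNC(=O)CNC(=O)CNC(=O)CNC(=O)CN1"
# 12-membered carbocycle ortho-fused to a benzene ring
FUSED_BENZO_12 = "C1CCCCCCCCCc2ccccc21"


@pytest.fixture
def cyclododecane():
    return Chem.MolFromSmiles(CYCLODODECANE)


@pytest.fixture
def hexaglycine():
    return Chem.MolFromSmiles(HEXAGLYCINE)


@pytest.fixture
def fused_benzo_12():
    return Chem.MolFromSmiles(FUSED_BENZO_12)


@pytest.fixture(scope="session")
def small_library():
    """60 mixed-profile molecules with ground truth, shared across tests."""
    mols = []
    for profile, seed in (("oral-like", 11), ("sparse", 12),
                          ("kinase-like", 13), ("random", 14)):
        lib, _ = generate_library(15, profile=profile, seed=seed)
        mols.extend(lib)
    return mols
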