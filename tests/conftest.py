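import numpy as np
import pytest

from pepmpc.structure_model import build_nanocluster, build_peptide


@pytest.fixture(scope="session")
def h1_peptide():
    return build_peptide("HWDDD", ["extended", "horseshoe"])


@pytest.fixture(scope="session")
def h3_peptide():
    return build_peptide("HHHWDDD", ["extended", "horseshoe"])


@pytest.fixture(scope="session")
def nanocluster():
    return build_nanocluster()


@pytest.fixture(scope="session")
def small_cluster():
    # light-weight cluster for docking-loop tests
    return build_nanocluster(n_core=20, n_ligands=12, chain_beads=3,
                             core_radius=0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
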