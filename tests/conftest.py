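import numpy as np
import pytest

import loopcg as lc
from loopcg.lattice import default_vector_set


@pytest.fixture(scope="session")
def vset():
    return default_vector_set()


@pytest.fixture(scope="session")
def hlh():
    """The standard helix-loop-helix fixture with its 4-residue loop."""
    return lc.make_fixture(lc.FixtureSpec())


@pytest.fixture(scope="session")
def hlh_case(hlh):
    structure, loopspec = hlh
    return lc.excise_loop(structure, loopspec)


@pytest.fixture(scope="session")
def hlh_conf(hlh, vset):
    structure, _ = hlh
    conf, rmsd = lc.project_chain(structure.ca_coords(), vset, structure.sequence)
    return conf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tiny_pdb_text():
    """A hand-written 3-residue PDB used by parser tests."""
    return "\n".join([
        "HEADER    TEST",
        "ATOM      1  N   ALA A   1       0.100   0.200   0.300  1.00  0.00",
        "ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00",
        "ATOM      3  CA  GLY A   2       4.500   2.500   3.500  1.00  0.00",
        "ATOM      4  CA  SER A   3       7.800   3.000   4.200  1.00  0.00",
        "TER",
        "END",
    ]) + "\n"
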