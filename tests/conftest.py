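import numpy as np
import pytest

import saxsbm as sb

TOY_ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
"""


@pytest.fixture(scope="session")
def toy_ala():
    return sb.parse_pdb(TOY_ALA_PDB)


@pytest.fixture(scope="session")
def helix():
    return sb.build_ideal_helix("AVLSKEQ")


@pytest.fixture(scope="session")
def helix21():
    return sb.build_ideal_helix("A" * 21)


@pytest.fixture(scope="session")
def helix_topology(helix):
    return sb.build_topology(helix)


@pytest.fixture(scope="session")
def polymer_pair():
    return sb.build_two_state_polymer(16, seed=1)


@pytest.fixture(scope="session")
def polymer_topology(polymer_pair):
    hairpin, _ = polymer_pair
    return sb.build_topology(hairpin, cutoff=0.7)


@pytest.fixture(scope="session")
def q_grid():
    return sb.default_q_grid(30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def finite_difference_gradient(energy_fn, x, eps=1e-6):
    """Central finite differences of a scalar function of coordinates."""
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp = x.copy()
            xp[i, d] += eps
            xm = x.copy()
            xm[i, d] -= eps
            g[i, d] = (energy_fn(xp) - energy_fn(xm)) / (2.0 * eps)
    return g
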