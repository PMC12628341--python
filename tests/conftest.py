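import numpy as np
import pytest

import ucjkit as u


@pytest.fixture(scope="session")
def h2_sto3g_17():
    """H2/STO-3G at 1.7 angstrom: integrals, Hamiltonian, references."""
    mol = u.h2_molecule(1.7, "sto-3g")
    ints = u.active_space_integrals(mol)
    H = u.build_qubit_hamiltonian(ints)
    return ints, H


@pytest.fixture(scope="session")
def h2_631g_12():
    mol = u.h2_molecule(1.2, "6-31g")
    ints = u.active_space_integrals(mol)
    H = u.build_qubit_hamiltonian(ints)
    return ints, H


@pytest.fixture(scope="session")
def synthetic_m2():
    ints = u.make_synthetic_integrals(2, 1, 1, seed=11)
    return ints, u.build_qubit_hamiltonian(ints)


def random_ucj_x(variant, M, n_alpha, n_beta, rng, scale=0.3):
    n = u.n_parameters(variant, M, n_alpha, n_beta)
    return rng.normal(scale=scale, size=n)
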