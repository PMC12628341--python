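"""Exact uCJ circuits, Trotter comparators, and resource counts."""

import numpy as np
import pytest
from scipy.linalg import expm

import ucjkit as u
from ucjkit.circuits import Gate

from conftest import random_ucj_x


def circuit_state(params, ref):
    c = u.build_exact_ucj_circuit(params, ref)
    return u.apply_circuit(c, u.SparseState.vacuum(2 * params.M)), c


def operator_state(params, ref):
    khat, jhat = u.build_operators(params)[0]
    v = u.SparseState.basis_state(ref.bitstring(params.M)).to_dense()
    return expm(khat.dense()) @ (expm(jhat.dense()) @ (expm(-khat.dense()) @ v))


def test_zero_parameters_give_reference():
    params = u.UCJParameters.zeros("g", 3, 1, 1)
    ref = u.ReferenceDeterminant.aufbau(1, 1)
    st, _ = circuit_state(params, ref)
    assert set(st.amplitudes) == {ref.bitstring(3)}
    assert st.amplitudes[ref.bitstring(3)] == pytest.approx(1.0)


@pytest.mark.parametrize("variant", ["re", "im", "g"])
@pytest.mark.parametrize("M,na,nb", [(2, 1, 1), (3, 1, 1), (3, 2, 1)])
def test_circuit_matches_dense_operator(variant, M, na, nb):
    rng = np.random.default_rng(hash((variant, M, na)) % 2 ** 31)
    ref = u.ReferenceDeterminant.aufbau(na, nb)
    for _ in range(5):
        x = random_ucj_x(variant, M, na, nb, rng, scale=0.5)
        params = u.unpack(x, variant, M, na, nb)
        st, c = circuit_state(params, ref)
        v = operator_state(params, ref)
        fid = abs(np.vdot(v, st.to_dense()))
        assert fid >= 1 - 1e-10
        assert st.norm() == pytest.approx(1.0, abs=1e-12)
        for g in c.gates:
            if g.kind == "GIVENS2":
                assert g.qubits[1] == g.qubits[0] + 1
                # rotations never straddle the spin-block boundary
                assert not (g.qubits[0] < M <= g.qubits[1])


def test_particle_number_sector_preserved():
    rng = np.random.default_rng(9)
    params = u.unpack(random_ucj_x("g", 3, 2, 1, rng), "g", 3, 2, 1)
    st, _ = circuit_state(params, u.ReferenceDeterminant.aufbau(2, 1))
    for bits in st.amplitudes:
        assert bits[:3].count("1") == 2 and bits[3:].count("1") == 1


@pytest.mark.parametrize("M,na,nb,expected", [
    (2, 1, 1, 20),      # H2 / STO-3G family
    (3, 1, 1, 54),      # H3+ / STO-3G
    (4, 1, 1, 104),     # H2 / 6-31G
    (4, 2, 2, 128),     # H4 / STO-3G family
])
def test_exact_cnot_counts_match_benchmark_table(M, na, nb, expected):
    assert u.cnot_count_formula(M, na, nb) == expected
    rng = np.random.default_rng(M * 10 + na)
    ref = u.ReferenceDeterminant.aufbau(na, nb)
    for variant in ("re", "im", "g"):
        x = random_ucj_x(variant, M, na, nb, rng, scale=0.4)
        params = u.unpack(x, variant, M, na, nb)
        c = u.build_exact_ucj_circuit(params, ref, prune=False)
        assert u.count_cnots(c) == expected


@pytest.mark.parametrize("M,na,nb", [(5, 2, 2), (6, 1, 1), (6, 3, 3)])
def test_count_identity_generalizes(M, na, nb):
    rng = np.random.default_rng(M)
    ref = u.ReferenceDeterminant.aufbau(na, nb)
    x = random_ucj_x("g", M, na, nb, rng, scale=0.3)
    params = u.unpack(x, "g", M, na, nb)
    c = u.build_exact_ucj_circuit(params, ref, prune=False)
    assert u.count_cnots(c) == u.cnot_count_formula(M, na, nb)


def test_trotter_of_commuting_j_is_exact():
    rng = np.random.default_rng(3)
    x = np.zeros(u.n_parameters("im", 3, 1, 1))
    x[6:] = rng.normal(size=9)
    params = u.unpack(x, "im", 3, 1, 1)
    _, jhat = u.build_operators(params)[0]
    c = u.build_trotter_circuit(jhat)
    ref = u.SparseState.basis_state("100100")
    out = u.apply_circuit(c, ref)
    v = expm(jhat.dense()) @ ref.to_dense()
    np.testing.assert_allclose(out.to_dense(), v, atol=1e-12)


def test_trotter_error_vanishes_quadratically():
    """Fidelity loss of the Trotterized uCJ scales as ||params||^2 or better."""
    rng = np.random.default_rng(4)
    base = random_ucj_x("g", 2, 1, 1, rng, scale=1.0)
    ref = u.ReferenceDeterminant.aufbau(1, 1)
    losses = []
    scales = [0.3, 0.03, 0.003]
    for s in scales:
        params = u.unpack(base * s, "g", 2, 1, 1)
        khat, jhat = u.build_operators(params)[0]
        gen = khat                                  # non-commuting part
        ct = u.build_trotter_circuit(gen)
        trotter = u.apply_circuit(ct, u.SparseState.basis_state(ref.bitstring(2)))
        exact = expm(khat.dense()) @ u.SparseState.basis_state(ref.bitstring(2)).to_dense()
        losses.append(max(1 - abs(np.vdot(exact, trotter.to_dense())), 1e-16))
    # slope in log-log at least ~2
    slope = (np.log(losses[0]) - np.log(losses[2])) / (np.log(scales[0]) - np.log(scales[2]))
    assert slope >= 1.8


def test_pauli_evol_staircase_count():
    c = u.Circuit(4)
    c.add(Gate("PAULI_EVOL", (0, 1, 3), (0.2,), "XYIZ"))
    assert u.count_cnots(c) == 2 * (3 - 1)


def test_t_gate_estimates():
    empty = u.Circuit(2)
    assert u.estimate_t_gates(empty, 0.5) == 0.0
    c = u.Circuit(2)
    c.add(Gate("RZ", (0,), (0.1,)))
    assert u.estimate_t_gates(c, 1.0) == pytest.approx(9.2)
    c10 = u.Circuit(2)
    for _ in range(10):
        c10.add(Gate("RZ", (0,), (0.1,)))
    assert u.estimate_t_gates(c10, 2.0 ** -10) == pytest.approx(207.0)
    with pytest.raises(ValueError):
        u.estimate_t_gates(c, 2.0)


def test_uccsd_generator_antihermitian_and_countable():
    ref = u.ReferenceDeterminant.aufbau(1, 1)
    gen = u.uccsd_generator(ref, 2)
    dense = gen.dense()
    np.testing.assert_allclose(dense, -dense.conj().T, atol=1e-12)
    c = u.build_trotter_circuit(gen)
    assert u.count_cnots(c) > 0


def test_circuit_json_roundtrip():
    rng = np.random.default_rng(5)
    params = u.unpack(random_ucj_x("im", 2, 1, 1, rng), "im", 2, 1, 1)
    c = u.build_exact_ucj_circuit(params, u.ReferenceDeterminant.aufbau(1, 1))
    c2 = u.Circuit.from_json(c.to_json())
    a = u.apply_circuit(c, u.SparseState.vacuum(4))
    b = u.apply_circuit(c2, u.SparseState.vacuum(4))
    assert abs(u.overlap(a, b)) == pytest.approx(1.0, abs=1e-12)
    assert "givens2" in c.to_qasm_like()
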