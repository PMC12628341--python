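"""Sparse statevector simulation and shot sampling."""

import numpy as np
import pytest

import ucjkit as u
from ucjkit.circuits import Circuit, Gate

import oracles


def dense_gate_matrix(g: Gate, n: int) -> np.ndarray:
    """Independent dense matrix of each gate kind (kron construction)."""
    I2 = np.eye(2, dtype=complex)
    X = np.array([[0, 1], [1, 0]], dtype=complex)
    dim = 2 ** n
    if g.kind == "PREP_X":
        mats = [X if k == g.qubits[0] else I2 for k in range(n)]
        from functools import reduce
        return reduce(np.kron, mats)
    if g.kind == "RZ":
        mats = [np.diag([1.0, np.exp(1j * g.params[0])]) if k == g.qubits[0]
                else I2 for k in range(n)]
        from functools import reduce
        return reduce(np.kron, mats)
    if g.kind == "GLOBAL_PHASE":
        return np.exp(1j * g.params[0]) * np.eye(dim)
    if g.kind == "ZZ_PHASE":
        i, j = g.qubits
        m = np.eye(dim, dtype=complex)
        for idx in range(dim):
            bits = format(idx, f"0{n}b")
            if bits[i] == "1" and bits[j] == "1":
                m[idx, idx] = np.exp(1j * g.params[0])
        return m
    if g.kind == "GIVENS2":
        # exponential of the fermionic generator on adjacent modes
        from scipy.linalg import expm
        theta, phi = g.params
        p, q = g.qubits
        gen = theta * (-np.exp(1j * phi) * oracles.creation(p, n) @ oracles.annihilation(q, n)
                       + np.exp(-1j * phi) * oracles.creation(q, n) @ oracles.annihilation(p, n))
        return expm(gen)
    raise ValueError(g.kind)


def test_prep_x_on_vacuum():
    c = Circuit(3)
    c.add(Gate("PREP_X", (0,)))
    c.add(Gate("PREP_X", (2,)))
    s = u.apply_circuit(c, u.SparseState.vacuum(3))
    assert s.amplitudes == {"101": 1.0 + 0j}


def test_full_givens_rotation_swaps_occupation():
    c = Circuit(2)
    c.add(Gate("GIVENS2", (0, 1), (np.pi / 2, 0.0)))
    s = u.apply_circuit(c, u.SparseState.basis_state("10"))
    assert set(s.amplitudes) == {"01"}
    assert abs(abs(s.amplitudes["01"]) - 1.0) < 1e-12


def test_givens2_matches_fermionic_exponential():
    """The gate is defined as the matrix exponential of the hop generator."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        theta, phi = rng.normal(size=2)
        g = Gate("GIVENS2", (1, 2), (theta, phi))
        c = Circuit(4)
        c.add(g)
        mat = dense_gate_matrix(g, 4)
        for bits in ("0100", "0010", "0110", "1111"):
            out = u.apply_circuit(c, u.SparseState.basis_state(bits))
            np.testing.assert_allclose(out.to_dense(),
                                       mat @ u.SparseState.basis_state(bits).to_dense(),
                                       atol=1e-12)


def test_random_circuits_match_dense_simulation():
    rng = np.random.default_rng(1)
    n = 6
    for trial in range(10):
        c = Circuit(n)
        v = np.zeros(2 ** n, complex)
        start = format(int(rng.integers(0, 2 ** n)), f"0{n}b")
        v[int(start, 2)] = 1.0
        state = u.SparseState.basis_state(start)
        for _ in range(12):
            kind = rng.choice(["GIVENS2", "RZ", "ZZ_PHASE", "GLOBAL_PHASE"])
            if kind == "GIVENS2":
                p = int(rng.integers(0, n - 1))
                g = Gate(kind, (p, p + 1), tuple(rng.normal(size=2)))
            elif kind == "RZ":
                g = Gate(kind, (int(rng.integers(0, n)),), (float(rng.normal()),))
            elif kind == "ZZ_PHASE":
                i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
                g = Gate(kind, (int(i), int(j)), (float(rng.normal()),))
            else:
                g = Gate(kind, (), (float(rng.normal()),))
            c.add(g)
            v = dense_gate_matrix(g, n) @ v
        out = u.apply_circuit(c, state)
        np.testing.assert_allclose(out.to_dense(), v, atol=1e-10)
        assert out.norm() == pytest.approx(1.0, abs=1e-12)


def test_expectation_basics(h2_sto3g_17):
    ints, H = h2_sto3g_17
    vac = u.SparseState.vacuum(4)
    z0 = u.PauliSum(4, {"ZIII": 1.0})
    assert u.expectation(z0, vac) == pytest.approx(1.0)
    ref = u.SparseState.basis_state("1010")
    assert u.expectation(H.terms, ref) == pytest.approx(
        u.reference_energy(ints, u.ReferenceDeterminant.aufbau(1, 1)), abs=1e-10)
    e, gs = u.exact_ground_state(H, 1, 1)
    assert u.expectation(H.terms, gs) == pytest.approx(e, abs=1e-10)


def test_expectation_linear_and_real(synthetic_m2):
    _, H = synthetic_m2
    _, gs = u.exact_ground_state(H, 1, 1)
    a = u.expectation(H.terms, gs)
    b = u.expectation(2.0 * H.terms, gs)
    assert b == pytest.approx(2 * a, abs=1e-9)


def test_overlap_properties():
    s = u.SparseState(2, {"10": 0.6, "01": 0.8j})
    assert u.overlap(s, s) == pytest.approx(1.0)
    t = u.SparseState.basis_state("11")
    assert u.overlap(s, t) == 0
    rng = np.random.default_rng(2)
    va = rng.normal(size=4) + 1j * rng.normal(size=4)
    vb = rng.normal(size=4) + 1j * rng.normal(size=4)
    va /= np.linalg.norm(va)
    vb /= np.linalg.norm(vb)
    bits = ["00", "01", "10", "11"]
    sa = u.SparseState(2, dict(zip(bits, va)))
    sb = u.SparseState(2, dict(zip(bits, vb)))
    assert u.overlap(sa, sb) == pytest.approx(np.vdot(va, vb), abs=1e-12)


def test_sampled_diagonal_is_exact_zero_variance():
    H = u.PauliSum(2, {"ZI": 0.3, "IZ": -0.2, "II": 1.0})
    s = u.SparseState.basis_state("10")
    mean, err = u.sampled_expectation(H, s, u.ShotPlan(50, seed=0))
    # qubit 0 occupied: <Z_0> = -1; qubit 1 empty: <Z_1> = +1
    assert mean == pytest.approx(1.0 + 0.3 * (-1) + (-0.2) * (+1), abs=1e-12)
    assert err == pytest.approx(0.0, abs=1e-12)


def test_sampled_seeded_reproducibility(h2_sto3g_17):
    _, H = h2_sto3g_17
    _, gs = u.exact_ground_state(H, 1, 1)
    a = u.sampled_expectation(H.terms, gs, u.ShotPlan(500, seed=9, n_trials=3))
    b = u.sampled_expectation(H.terms, gs, u.ShotPlan(500, seed=9, n_trials=3))
    assert a == b


def test_sampled_unbiased_within_3_sigma(h2_sto3g_17):
    _, H = h2_sto3g_17
    e, gs = u.exact_ground_state(H, 1, 1)
    mean, err = u.sampled_expectation(H.terms, gs,
                                      u.ShotPlan(10000, seed=1, n_trials=10))
    assert abs(mean - e) < 3 * max(err, 1e-6)


def test_stderr_scales_as_inverse_sqrt_shots(h2_sto3g_17):
    _, H = h2_sto3g_17
    _, gs = u.exact_ground_state(H, 1, 1)
    errs = []
    shots = [100, 10000]
    for s in shots:
        _, err = u.sampled_expectation(H.terms, gs, u.ShotPlan(s, seed=2,
                                                               n_trials=4))
        errs.append(err)
    ratio = errs[0] / errs[1]
    assert ratio == pytest.approx(10.0, rel=0.25)
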