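"""Integral containers, FCIDUMP interchange, JW Hamiltonian, sector FCI."""

import itertools

import numpy as np
import pytest

import ucjkit as u

import oracles


def test_read_one_orbital_file(tmp_path):
    p = tmp_path / "one.fcidump"
    p.write_text("&FCI NORB=1,NELEC=2,MS2=0,\n ORBSYM=1,\n ISYM=1,\n&END\n"
                 "-1.25 1 1 0 0\n0.7 0 0 0 0\n")
    ints = u.read_fcidump(str(p))
    assert ints.one_body[0, 0] == pytest.approx(-1.25)
    assert ints.core_energy == pytest.approx(0.7)


def test_fcidump_roundtrip(tmp_path):
    ints = u.make_synthetic_integrals(3, 1, 1, seed=5)
    path = tmp_path / "synthetic_M3.fcidump"
    u.write_fcidump(ints, str(path))
    back = u.read_fcidump(str(path))
    np.testing.assert_allclose(back.one_body, ints.one_body, atol=1e-12)
    np.testing.assert_allclose(back.two_body, ints.two_body, atol=1e-12)
    assert back.core_energy == pytest.approx(ints.core_energy, abs=1e-12)
    assert (back.n_alpha, back.n_beta) == (1, 1)


def test_fcidump_canonical_entries_fill_all_permutations(tmp_path):
    ints = u.make_synthetic_integrals(2, 1, 1, seed=1)
    path = tmp_path / "m2.fcidump"
    u.write_fcidump(ints, str(path))
    g = u.read_fcidump(str(path)).two_body
    for p, q, r, s in itertools.product(range(2), repeat=4):
        for (i, j, k, l) in [(q, p, r, s), (p, q, s, r), (r, s, p, q),
                             (s, r, q, p)]:
            assert g[p, q, r, s] == pytest.approx(g[i, j, k, l], abs=1e-12)


def test_malformed_header_raises(tmp_path):
    p = tmp_path / "bad.fcidump"
    p.write_text("no header at all\n1.0 1 1 0 0\n")
    with pytest.raises(ValueError):
        u.read_fcidump(str(p))


def test_index_out_of_range_raises(tmp_path):
    p = tmp_path / "bad2.fcidump"
    p.write_text("&FCI NORB=1,NELEC=2,MS2=0,\n&END\n1.0 2 1 0 0\n")
    with pytest.raises(ValueError):
        u.read_fcidump(str(p))


def test_synthetic_integrals_deterministic_and_symmetric():
    a = u.make_synthetic_integrals(3, 2, 1, seed=42)
    b = u.make_synthetic_integrals(3, 2, 1, seed=42)
    np.testing.assert_array_equal(a.one_body, b.one_body)
    np.testing.assert_array_equal(a.two_body, b.two_body)
    a.validate(1e-12)


def test_synthetic_m2_jw_hamiltonian_hermitian():
    ints = u.make_synthetic_integrals(2, 1, 1, seed=0)
    H = u.build_qubit_hamiltonian(ints).terms.dense()
    assert H.shape == (16, 16)
    np.testing.assert_allclose(H, H.conj().T, atol=1e-10)


def test_diagonal_one_body_gives_iz_words_only():
    ints = u.make_synthetic_integrals(2, 1, 1, seed=0)
    ints.one_body = np.diag(np.diag(ints.one_body))
    ints.two_body = np.zeros_like(ints.two_body)
    H = u.build_qubit_hamiltonian(ints)
    assert all(set(t.word) <= {"I", "Z"} for t in H.terms.terms)


def test_single_mode_spectrum():
    eps = 0.37
    ints = u.ActiveSpaceIntegrals(0.0, np.array([[eps]]),
                                  np.zeros((1, 1, 1, 1)), 1, 1)
    w = np.linalg.eigvalsh(u.build_qubit_hamiltonian(ints).terms.dense())
    np.testing.assert_allclose(sorted(w), [0.0, eps, eps, 2 * eps], atol=1e-12)


def test_qubit_hamiltonian_matches_ladder_oracle():
    ints = u.make_synthetic_integrals(2, 1, 1, seed=7)
    H = u.build_qubit_hamiltonian(ints).terms.dense()
    np.testing.assert_allclose(H, oracles.dense_hamiltonian(ints), atol=1e-10)


def test_exact_ground_state_matches_dense_oracle_m3():
    ints = u.make_synthetic_integrals(3, 1, 1, seed=9)
    H = u.build_qubit_hamiltonian(ints)
    e, state = u.exact_ground_state(H, 1, 1)
    dense = oracles.dense_hamiltonian(ints)
    sel = oracles.sector_indices(3, 1, 1)
    w = np.linalg.eigvalsh(dense[np.ix_(sel, sel)])
    assert e == pytest.approx(w[0], abs=1e-10)
    assert state.norm() == pytest.approx(1.0, abs=1e-12)
    # support stays in the sector
    for bits in state.amplitudes:
        assert bits[:3].count("1") == 1 and bits[3:].count("1") == 1


def test_exact_ground_state_diagonal_hamiltonian():
    ints = u.make_synthetic_integrals(3, 1, 1, seed=2)
    ints.one_body = np.diag([-2.0, -1.0, -0.5])
    ints.two_body = np.zeros_like(ints.two_body)
    ints.core_energy = 0.0
    e, state = u.exact_ground_state(u.build_qubit_hamiltonian(ints), 1, 1)
    assert e == pytest.approx(-4.0, abs=1e-10)
    assert set(state.amplitudes) == {"100100"}


def test_empty_sector_raises():
    ints = u.make_synthetic_integrals(1, 1, 1, seed=0)
    H = u.build_qubit_hamiltonian(ints)
    with pytest.raises(ValueError):
        u.exact_ground_state(H, 2, 0)


def test_reference_energy_trivials():
    ints = u.make_synthetic_integrals(2, 1, 1, seed=3)
    empty = u.ReferenceDeterminant((), (), "custom")
    assert u.reference_energy(ints, empty) == pytest.approx(ints.core_energy)
    ints.two_body = np.zeros_like(ints.two_body)
    one_a = u.ReferenceDeterminant((1,), (), "custom")
    assert u.reference_energy(ints, one_a) == pytest.approx(
        ints.core_energy + ints.one_body[1, 1].real)


def test_reference_energy_matches_expectation_oracle():
    rng = np.random.default_rng(12)
    for seed in range(3):
        ints = u.make_synthetic_integrals(3, 2, 1, seed=seed)
        occ_a = tuple(sorted(rng.choice(3, size=2, replace=False).tolist()))
        occ_b = (int(rng.integers(0, 3)),)
        ref = u.ReferenceDeterminant(occ_a, occ_b, "custom")
        H = u.build_qubit_hamiltonian(ints)
        state = u.SparseState.basis_state(ref.bitstring(3))
        assert u.reference_energy(ints, ref) == pytest.approx(
            u.expectation(H.terms, state), abs=1e-10)


def test_variational_bound_and_number_conservation():
    for seed in (0, 1):
        ints = u.make_synthetic_integrals(3, 1, 1, seed=seed)
        H = u.build_qubit_hamiltonian(ints)
        e, _ = u.exact_ground_state(H, 1, 1)
        for pa in range(3):
            for pb in range(3):
                ref = u.ReferenceDeterminant((pa,), (pb,), "custom")
                assert e <= u.reference_energy(ints, ref) + 1e-10
        # [H, N_sigma] = 0 on dense matrices
        dense = H.terms.dense()
        for block in (range(0, 3), range(3, 6)):
            Nop = sum(oracles.number(p, 6) for p in block)
            np.testing.assert_allclose(dense @ Nop - Nop @ dense,
                                       np.zeros_like(dense), atol=1e-10)
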