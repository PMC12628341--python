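"""Independent dense oracles for the test suite.

Everything here is built directly from 2x2 kron products of ladder
matrices, with no use of the package's Pauli/JW machinery, so it can
serve as an independent cross-check of that machinery.
"""

from functools import reduce

import numpy as np

I2 = np.eye(2, dtype=complex)
Z2 = np.diag([1.0, -1.0]).astype(complex)
# |0> = unoccupied; a|1> = |0>
ANN = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex)


def annihilation(p: int, n: int) -> np.ndarray:
    """Dense JW annihilation operator; qubit 0 is the most significant bit."""
    mats = [Z2] * p + [ANN] + [I2] * (n - p - 1)
    return reduce(np.kron, mats)


def creation(p: int, n: int) -> np.ndarray:
    return annihilation(p, n).conj().T


def number(p: int, n: int) -> np.ndarray:
    return creation(p, n) @ annihilation(p, n)


def dense_hamiltonian(integrals) -> np.ndarray:
    """Second-quantized H from ladder matrices (spin-blocked, chemists')."""
    M = integrals.n_spatial
    N = 2 * M
    dim = 2 ** N
    a = [annihilation(p, N) for p in range(N)]
    ad = [m.conj().T for m in a]
    H = integrals.core_energy * np.eye(dim, dtype=complex)
    h, g = integrals.one_body, integrals.two_body
    for s in range(2):
        off = s * M
        for p in range(M):
            for q in range(M):
                if abs(h[p, q]) > 1e-14:
                    H += h[p, q] * (ad[off + p] @ a[off + q])
    for s1 in range(2):
        for s2 in range(2):
            o1, o2 = s1 * M, s2 * M
            for p in range(M):
                for q in range(M):
                    for r in range(M):
                        for s_ in range(M):
                            v = g[p, q, r, s_]
                            if abs(v) > 1e-14:
                                H += 0.5 * v * (ad[o1 + p] @ ad[o2 + r]
                                                @ a[o2 + s_] @ a[o1 + q])
    return H


def dense_state(sparse_state) -> np.ndarray:
    v = np.zeros(2 ** sparse_state.n_qubits, dtype=complex)
    for bits, amp in sparse_state.amplitudes.items():
        v[int(bits, 2)] = amp
    return v


def sector_indices(M: int, n_alpha: int, n_beta: int):
    """Indices of the dense basis belonging to a per-spin-number sector."""
    N = 2 * M
    out = []
    for idx in range(2 ** N):
        bits = format(idx, f"0{N}b")
        if bits[:M].count("1") == n_alpha and bits[M:].count("1") == n_beta:
            out.append(idx)
    return out
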