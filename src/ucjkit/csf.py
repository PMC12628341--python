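"""Spin-adapted configuration-state-function analysis.

For the two-electron, two-spatial-orbital sector (H2 in a minimal basis)
the Ms=0 space is four-dimensional and splits into three singlets and one
triplet:

* ``hf_singlet_g``       -- closed-shell ground determinant |1a 1b>,
* ``double_singlet_g``   -- closed-shell doubly excited |2a 2b>,
* ``open_singlet_u``     -- open-shell singlet (|1a 2b> + |2a 1b>)/sqrt(2)
  up to the fermionic sign convention,
* ``triplet_ms0_u``      -- the Ms=0 triplet partner.

The g/u tags are the gerade/ungerade spatial symmetries of the homonuclear
dimer.  Larger sectors are analyzed through <S^2> and raw determinant
weights only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List

import numpy as np

from .integrals import sector_matrix, QubitHamiltonian
from .paulis import PauliSum, jw_annihilation, jw_creation
from .simulator import SparseState, expectation, overlap

__all__ = [
    "CSFBasis",
    "CSFDecomposition",
    "build_csf_basis",
    "decompose",
    "s_squared_operator",
    "s_squared_expectation",
]


@dataclass
class CSFBasis:
    labels: List[str]
    vectors: List[SparseState]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class CSFDecomposition:
    weights: Dict[str, float]
    s_squared: float
    residual: float


@lru_cache(maxsize=None)
def s_squared_operator(M: int) -> PauliSum:
    """JW image of S^2 = S- S+ + Sz (Sz + 1) over M spatial orbitals."""
    N = 2 * M
    splus = PauliSum(N)
    for p in range(M):
        splus = splus + (jw_creation(p, N) @ jw_annihilation(M + p, N))
    sminus = splus.dagger()
    sz = PauliSum(N)
    for p in range(M):
        na = jw_creation(p, N) @ jw_annihilation(p, N)
        nb = jw_creation(M + p, N) @ jw_annihilation(M + p, N)
        sz = sz + 0.5 * na + (-0.5) * nb
    return sminus @ splus + sz @ sz + sz


def s_squared_expectation(state: SparseState, M: int) -> float:
    return expectation(s_squared_operator(M), state)


def build_csf_basis() -> CSFBasis:
    """The four Ms=0 CSFs of two electrons in two spatial orbitals.

    Qubit order is spin-blocked (alpha1 alpha2 beta1 beta2).  The
    open-shell singlet/triplet pair is fixed by diagonalizing S^2 in the
    open-shell subspace, with the sign convention of a positive |1a 2b>
    coefficient.
    """
    M = 2
    s2 = s_squared_operator(M)
    os_bits = ["1001", "0110"]          # |1a 2b>, |2a 1b>
    mat = sector_matrix(QubitHamiltonian(s2, 4), os_bits)
    w, v = np.linalg.eigh(mat)
    # eigenvalues {0, 2}
    vecs = {}
    for col, val in enumerate(w):
        coef = v[:, col]
        if coef[0].real < 0:
            coef = -coef
        key = "singlet" if abs(val) < 1e-9 else "triplet"
        vecs[key] = SparseState(4, {b: complex(c) for b, c in zip(os_bits, coef)
                                    if abs(c) > 1e-14})
    return CSFBasis(
        labels=["hf_singlet_g", "double_singlet_g",
                "open_singlet_u", "triplet_ms0_u"],
        vectors=[SparseState.basis_state("1010"),
                 SparseState.basis_state("0101"),
                 vecs["singlet"], vecs["triplet"]],
    )


def decompose(state: SparseState, basis: CSFBasis) -> CSFDecomposition:
    """Squared overlaps with each CSF; residual completes the norm."""
    if state.n_qubits != basis.vectors[0].n_qubits:
        raise ValueError("state and CSF basis have different qubit counts")
    weights = {}
    for label, vec in zip(basis.labels, basis.vectors):
        weights[label] = float(abs(overlap(vec, state)) ** 2)
    total = sum(weights.values())
    s2 = s_squared_expectation(state, state.n_qubits // 2)
    return CSFDecomposition(weights, float(s2), float(1.0 - total))
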