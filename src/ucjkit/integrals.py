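"""Active-space integrals, FCIDUMP interchange, and exact diagonalization.

The central container is :class:`ActiveSpaceIntegrals`: a core energy, an
M x M one-body matrix and an M x M x M x M two-body tensor in chemists'
notation ``(pq|rs)``, all in hartree over M spatial orbitals.  The
second-quantized Hamiltonian is

    H = E_core + sum_{pq,s} h_pq a+_ps a_qs
              + 1/2 sum_{pqrs,st} (pq|rs) a+_ps a+_rt a_st a_qs

with spin-blocked spin orbitals (alpha block first).  The FCIDUMP dialect
is Molpro-style: namelist header, 1-based indices, real orbitals, unique
8-fold-symmetric entries.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .paulis import PauliSum, jw_annihilation, jw_creation

__all__ = [
    "ActiveSpaceIntegrals",
    "ReferenceDeterminant",
    "QubitHamiltonian",
    "read_fcidump",
    "write_fcidump",
    "make_synthetic_integrals",
    "build_qubit_hamiltonian",
    "sector_basis",
    "sector_matrix",
    "exact_ground_state",
    "reference_energy",
]


def _eightfold(t: np.ndarray, p: int, q: int, r: int, s: int, v: float) -> None:
    for (i, j, k, l) in {(p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
                         (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p)}:
        t[i, j, k, l] = v


@dataclass
class ActiveSpaceIntegrals:
    """Active-space electronic integrals in hartree, chemists' notation."""

    core_energy: float
    one_body: np.ndarray          # (M, M), Hermitian
    two_body: np.ndarray          # (M, M, M, M), (pq|rs), 8-fold symmetric
    n_alpha: int
    n_beta: int
    metadata: Dict[str, str] = field(default_factory=dict)

    @property
    def n_spatial(self) -> int:
        return self.one_body.shape[0]

    @property
    def n_qubits(self) -> int:
        return 2 * self.n_spatial

    def validate(self, tol: float = 1e-12) -> None:
        M = self.n_spatial
        if self.one_body.shape != (M, M) or self.two_body.shape != (M, M, M, M):
            raise ValueError("inconsistent tensor shapes")
        if self.n_alpha + self.n_beta > 2 * M:
            raise ValueError("electron count exceeds 2M")
        if np.max(np.abs(self.one_body - self.one_body.conj().T)) > tol:
            raise ValueError("one-body matrix is not Hermitian")
        g = self.two_body
        for perm in (g.transpose(1, 0, 2, 3), g.transpose(0, 1, 3, 2),
                     g.transpose(2, 3, 0, 1)):
            if np.max(np.abs(g - perm)) > tol:
                raise ValueError("two-body tensor violates 8-fold symmetry")


@dataclass(frozen=True)
class ReferenceDeterminant:
    """Occupied spatial orbitals per spin for a single determinant."""

    occ_alpha: Tuple[int, ...]
    occ_beta: Tuple[int, ...]
    kind: str = "RHF"  # RHF | UHF | custom

    @classmethod
    def aufbau(cls, n_alpha: int, n_beta: int, kind: str = "RHF") -> "ReferenceDeterminant":
        return cls(tuple(range(n_alpha)), tuple(range(n_beta)), kind)

    def validate(self, n_spatial: int) -> None:
        for occ in (self.occ_alpha, self.occ_beta):
            if len(set(occ)) != len(occ):
                raise ValueError("duplicate occupied orbital")
            if any(not 0 <= p < n_spatial for p in occ):
                raise ValueError("occupied orbital index out of range")

    def bitstring(self, n_spatial: int) -> str:
        """Occupation bitstring in spin-blocked qubit order."""
        bits = ["0"] * (2 * n_spatial)
        for p in self.occ_alpha:
            bits[p] = "1"
        for p in self.occ_beta:
            bits[n_spatial + p] = "1"
        return "".join(bits)


@dataclass
class QubitHamiltonian:
    """Jordan-Wigner image of the active-space Hamiltonian."""

    terms: PauliSum
    n_qubits: int

    def __post_init__(self):
        if not self.terms.is_hermitian(1e-8):
            raise ValueError("qubit Hamiltonian must be Hermitian")


# ---------------------------------------------------------------------------
# FCIDUMP (Molpro dialect)
# ---------------------------------------------------------------------------

def read_fcidump(path: str) -> ActiveSpaceIntegrals:
    """Read a Molpro-dialect FCIDUMP file (1-based indices, real orbitals)."""
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, re.S | re.I)
    if not m:
        raise ValueError(f"{path}: missing &FCI namelist header")
    header = m.group(1)

    def _get(key: str) -> int:
        mm = re.search(rf"{key}\s*=\s*(\d+)", header, re.I)
        if not mm:
            raise ValueError(f"{path}: header lacks {key}")
        return int(mm.group(1))

    norb = _get("NORB")
    nelec = _get("NELEC")
    ms2 = _get("MS2")
    n_alpha = (nelec + ms2) // 2
    n_beta = (nelec - ms2) // 2

    one = np.zeros((norb, norb))
    two = np.zeros((norb, norb, norb, norb))
    core = 0.0
    body = text[m.end():]
    for line in body.splitlines():
        parts = line.split()
        if len(parts) != 5:
            continue
        v = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:])
        if max(i, j, k, l) > norb:
            raise ValueError(f"{path}: orbital index exceeds NORB={norb}")
        if i == j == k == l == 0:
            core = v
        elif k == l == 0:
            one[i - 1, j - 1] = v
            one[j - 1, i - 1] = v
        else:
            _eightfold(two, i - 1, j - 1, k - 1, l - 1, v)
    out = ActiveSpaceIntegrals(core, one, two, n_alpha, n_beta)
    out.validate(1e-10)
    return out


def write_fcidump(integrals: ActiveSpaceIntegrals, path: str) -> None:
    """Write unique canonical-order entries of real integrals."""
    M = integrals.n_spatial
    nelec = integrals.n_alpha + integrals.n_beta
    ms2 = integrals.n_alpha - integrals.n_beta
    lines = [
        f"&FCI NORB={M},NELEC={nelec},MS2={ms2},",
        "  ORBSYM=" + "1," * M,
        "  ISYM=1,",
        " &END",
    ]
    g = integrals.two_body
    for p in range(M):
        for q in range(p + 1):
            for r in range(p + 1):
                smax = q if r == p else r
                for s in range(smax + 1):
                    v = g[p, q, r, s]
                    if abs(v) > 1e-14:
                        lines.append(f"{v:23.16e} {p+1:3d} {q+1:3d} {r+1:3d} {s+1:3d}")
    h = integrals.one_body
    for p in range(M):
        for q in range(p + 1):
            if abs(h[p, q]) > 1e-14:
                lines.append(f"{h[p, q].real:23.16e} {p+1:3d} {q+1:3d}   0   0")
    lines.append(f"{integrals.core_energy:23.16e}   0   0   0   0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_synthetic_integrals(M: int, n_alpha: int, n_beta: int,
                             seed: int) -> ActiveSpaceIntegrals:
    """Reproducible pseudo-random integrals with all container invariants.

    The one-body matrix has well-separated diagonal levels (a generic
    non-degenerate mean field) plus small symmetric off-diagonal coupling;
    the two-body tensor is an 8-fold-symmetrized random tensor at
    repulsion-like scale.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    diag = np.sort(rng.uniform(-2.0, -0.2, size=M))
    off = rng.normal(scale=0.05, size=(M, M))
    one = np.diag(diag) + (off + off.T) / 2
    np.fill_diagonal(one, diag)

    raw = rng.normal(scale=0.1, size=(M, M, M, M))
    two = np.zeros_like(raw)
    for perm in ((0, 1, 2, 3), (1, 0, 2, 3), (0, 1, 3, 2), (1, 0, 3, 2),
                 (2, 3, 0, 1), (3, 2, 0, 1), (2, 3, 1, 0), (3, 2, 1, 0)):
        two += raw.transpose(perm)
    two /= 8.0
    core = float(rng.normal(scale=0.5))
    out = ActiveSpaceIntegrals(core, one, two, n_alpha, n_beta)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Jordan-Wigner Hamiltonian
# ---------------------------------------------------------------------------

def build_qubit_hamiltonian(integrals: ActiveSpaceIntegrals) -> QubitHamiltonian:
    """JW transform of the second-quantized active-space Hamiltonian."""
    integrals.validate(1e-10)
    M = integrals.n_spatial
    N = 2 * M
    h = integrals.one_body
    g = integrals.two_body

    cre = [jw_creation(p, N) for p in range(N)]
    ann = [jw_annihilation(p, N) for p in range(N)]

    H = PauliSum.identity(N, integrals.core_energy)
    for s in range(2):
        off = s * M
        for p in range(M):
            for q in range(M):
                if abs(h[p, q]) > 1e-14:
                    H = H + h[p, q] * (cre[off + p] @ ann[off + q])
    # 1/2 (pq|rs) a+_ps a+_rt a_st a_qs  (chemists' ordering)
    for s1 in range(2):
        for s2 in range(2):
            o1, o2 = s1 * M, s2 * M
            for p, q, r, s in itertools.product(range(M), repeat=4):
                v = g[p, q, r, s]
                if abs(v) > 1e-14:
                    term = cre[o1 + p] @ cre[o2 + r] @ ann[o2 + s] @ ann[o1 + q]
                    H = H + (0.5 * v) * term
    return QubitHamiltonian(H, N)


# ---------------------------------------------------------------------------
# Fixed-sector exact diagonalization
# ---------------------------------------------------------------------------

def sector_basis(M: int, n_alpha: int, n_beta: int) -> List[str]:
    """All spin-blocked occupation bitstrings with the given per-spin counts."""
    out = []
    for oa in itertools.combinations(range(M), n_alpha):
        for ob in itertools.combinations(range(M), n_beta):
            bits = ["0"] * (2 * M)
            for p in oa:
                bits[p] = "1"
            for p in ob:
                bits[M + p] = "1"
            out.append("".join(bits))
    return sorted(out)


def _apply_word(word: str, bits: str) -> Tuple[str, complex]:
    """P |bits> = phase |bits'> for a computational basis state."""
    phase = 1.0 + 0j
    out = list(bits)
    for k, c in enumerate(word):
        if c == "I":
            continue
        b = bits[k]
        if c == "Z":
            if b == "1":
                phase = -phase
        elif c == "X":
            out[k] = "0" if b == "1" else "1"
        else:  # Y |0> = i|1>,  Y |1> = -i|0>
            if b == "0":
                out[k] = "1"
                phase *= 1j
            else:
                out[k] = "0"
                phase *= -1j
    return "".join(out), phase


def sector_matrix(H: QubitHamiltonian, basis: Sequence[str]) -> np.ndarray:
    """Dense restriction of a PauliSum to a list of basis bitstrings."""
    index = {b: i for i, b in enumerate(basis)}
    dim = len(basis)
    mat = np.zeros((dim, dim), dtype=complex)
    for term in H.terms:
        for i, bits in enumerate(basis):
            out, phase = _apply_word(term.word, bits)
            j = index.get(out)
            if j is not None:
                mat[j, i] += term.coefficient * phase
    return mat


def exact_ground_state(H: QubitHamiltonian, n_alpha: int, n_beta: int):
    """Lowest eigenpair of H restricted to a fixed per-spin-number sector.

    Returns ``(energy, state)`` with ``state`` a
    :class:`~ucjkit.simulator.SparseState` normalized to 1e-12.
    """
    from .simulator import SparseState

    M = H.n_qubits // 2
    basis = sector_basis(M, n_alpha, n_beta)
    if not basis:
        raise ValueError("empty particle-number sector")
    mat = sector_matrix(H, basis)
    w, v = np.linalg.eigh(mat)
    vec = v[:, 0]
    amps = {b: vec[i] for i, b in enumerate(basis) if abs(vec[i]) > 1e-14}
    return float(w[0]), SparseState(H.n_qubits, amps)


def reference_energy(integrals: ActiveSpaceIntegrals,
                     ref: ReferenceDeterminant) -> float:
    """Slater-Condon energy of a single determinant.

    E = E_core + sum_occ h_pp + 1/2 sum_{occ i,j} [(ii|jj) - delta_spin (ij|ji)]
    """
    ref.validate(integrals.n_spatial)
    h = integrals.one_body
    g = integrals.two_body
    occ = [(p, 0) for p in ref.occ_alpha] + [(p, 1) for p in ref.occ_beta]
    e = integrals.core_energy
    for p, _ in occ:
        e += h[p, p].real
    for (p, sp), (q, sq) in itertools.product(occ, repeat=2):
        e += 0.5 * g[p, p, q, q]
        if sp == sq:
            e -= 0.5 * g[p, q, q, p]
    return float(e)
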