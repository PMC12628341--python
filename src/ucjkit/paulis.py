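"""Pauli-word algebra and the Jordan-Wigner transformation.

Conventions
-----------
* A Pauli word is a string over ``{I, X, Y, Z}``; position ``k`` acts on
  qubit ``k``.
* Jordan-Wigner with vacuum ``|0>`` = unoccupied and number operator
  ``n_p = (I - Z_p)/2``, so ``Z_p |0> = +|0>``.
* Spin orbitals are mapped to qubits in spin-blocked order: alpha spatial
  orbitals occupy qubits ``0..M-1``, beta spatial orbitals ``M..2M-1``.

Words are stored densely (desk scale, n <= 16 qubits); no symplectic
packing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

__all__ = [
    "PauliTerm",
    "PauliSum",
    "jw_annihilation",
    "jw_creation",
    "jw_number_operator",
    "jw_hop",
    "pauli_multiply",
    "qwc_group",
]

# single-qubit products: (a, b) -> (phase, c) with sigma_a sigma_b = phase * sigma_c
_PRODUCT: Dict[Tuple[str, str], Tuple[complex, str]] = {
    ("I", "I"): (1, "I"), ("I", "X"): (1, "X"), ("I", "Y"): (1, "Y"), ("I", "Z"): (1, "Z"),
    ("X", "I"): (1, "X"), ("Y", "I"): (1, "Y"), ("Z", "I"): (1, "Z"),
    ("X", "X"): (1, "I"), ("Y", "Y"): (1, "I"), ("Z", "Z"): (1, "I"),
    ("X", "Y"): (1j, "Z"), ("Y", "X"): (-1j, "Z"),
    ("Y", "Z"): (1j, "X"), ("Z", "Y"): (-1j, "X"),
    ("Z", "X"): (1j, "Y"), ("X", "Z"): (-1j, "Y"),
}

_MATS = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


@dataclass(frozen=True)
class PauliTerm:
    """A single weighted Pauli word."""

    coefficient: complex
    word: str

    @property
    def weight(self) -> int:
        """Number of non-identity letters."""
        return sum(1 for c in self.word if c != "I")

    def dense(self) -> np.ndarray:
        m = np.array([[1.0 + 0j]])
        for c in self.word:
            m = np.kron(m, _MATS[c])
        return self.coefficient * m


def pauli_multiply(a: PauliTerm, b: PauliTerm) -> PauliTerm:
    """Product of two Pauli terms with accumulated phase."""
    if len(a.word) != len(b.word):
        raise ValueError("Pauli word lengths differ")
    phase = a.coefficient * b.coefficient
    letters = []
    for ca, cb in zip(a.word, b.word):
        ph, c = _PRODUCT[(ca, cb)]
        phase *= ph
        letters.append(c)
    return PauliTerm(phase, "".join(letters))


class PauliSum:
    """A collected weighted sum of Pauli words over a fixed qubit register."""

    __slots__ = ("n_qubits", "_terms")

    def __init__(self, n_qubits: int, terms: Dict[str, complex] | None = None):
        self.n_qubits = n_qubits
        self._terms: Dict[str, complex] = {}
        if terms:
            for w, c in terms.items():
                self.add(w, c)

    # -- construction -------------------------------------------------
    @classmethod
    def identity(cls, n_qubits: int, coefficient: complex = 1.0) -> "PauliSum":
        return cls(n_qubits, {"I" * n_qubits: coefficient})

    @classmethod
    def from_terms(cls, terms: Iterable[PauliTerm], n_qubits: int) -> "PauliSum":
        s = cls(n_qubits)
        for t in terms:
            s.add(t.word, t.coefficient)
        return s

    def add(self, word: str, coefficient: complex, tol: float = 1e-14) -> None:
        if len(word) != self.n_qubits:
            raise ValueError(f"word length {len(word)} != n_qubits {self.n_qubits}")
        c = self._terms.get(word, 0.0) + coefficient
        if abs(c) <= tol:
            self._terms.pop(word, None)
        else:
            self._terms[word] = c

    # -- inspection ---------------------------------------------------
    @property
    def terms(self) -> List[PauliTerm]:
        return [PauliTerm(c, w) for w, c in sorted(self._terms.items())]

    def coefficient(self, word: str) -> complex:
        return self._terms.get(word, 0.0)

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self.terms)

    def __repr__(self) -> str:
        parts = [f"({c:+.6g})*{w}" for w, c in sorted(self._terms.items())]
        return " + ".join(parts) if parts else "0"

    # -- algebra ------------------------------------------------------
    def __add__(self, other: "PauliSum") -> "PauliSum":
        if other.n_qubits != self.n_qubits:
            raise ValueError("qubit count mismatch")
        out = PauliSum(self.n_qubits, dict(self._terms))
        for w, c in other._terms.items():
            out.add(w, c)
        return out

    def __sub__(self, other: "PauliSum") -> "PauliSum":
        return self + (other * -1.0)

    def __mul__(self, scalar: complex) -> "PauliSum":
        return PauliSum(self.n_qubits, {w: c * scalar for w, c in self._terms.items()})

    __rmul__ = __mul__

    def __matmul__(self, other: "PauliSum") -> "PauliSum":
        if other.n_qubits != self.n_qubits:
            raise ValueError("qubit count mismatch")
        out = PauliSum(self.n_qubits)
        for wa, ca in self._terms.items():
            for wb, cb in other._terms.items():
                t = pauli_multiply(PauliTerm(ca, wa), PauliTerm(cb, wb))
                out.add(t.word, t.coefficient)
        return out

    def dagger(self) -> "PauliSum":
        return PauliSum(self.n_qubits, {w: np.conj(c) for w, c in self._terms.items()})

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return all(abs(c.imag) < tol for c in self._terms.values())

    def dense(self) -> np.ndarray:
        """2^n x 2^n matrix; qubit 0 is the most significant bit."""
        dim = 2 ** self.n_qubits
        m = np.zeros((dim, dim), dtype=complex)
        for t in self.terms:
            m += t.dense()
        return m

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n_qubits": self.n_qubits,
            "terms": [[w, c.real, c.imag] for w, c in sorted(self._terms.items())],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PauliSum":
        payload = json.loads(text)
        s = cls(payload["n_qubits"])
        for w, re, im in payload["terms"]:
            s.add(w, complex(re, im))
        return s


# ---------------------------------------------------------------------------
# Jordan-Wigner images of ladder and number operators
# ---------------------------------------------------------------------------

def jw_annihilation(p: int, n_qubits: int) -> PauliSum:
    """JW image of a_p = Z_0 ... Z_{p-1} (X_p + i Y_p)/2."""
    if not 0 <= p < n_qubits:
        raise ValueError(f"orbital index {p} out of range for {n_qubits} qubits")
    zs = "Z" * p
    tail = "I" * (n_qubits - p - 1)
    return PauliSum(n_qubits, {zs + "X" + tail: 0.5, zs + "Y" + tail: 0.5j})


def jw_creation(p: int, n_qubits: int) -> PauliSum:
    return jw_annihilation(p, n_qubits).dagger()


def jw_number_operator(p: int, n_qubits: int) -> PauliSum:
    """JW image of the number operator n_p = (I - Z_p)/2."""
    if not 0 <= p < n_qubits:
        raise ValueError(f"orbital index {p} out of range for {n_qubits} qubits")
    word = "I" * p + "Z" + "I" * (n_qubits - p - 1)
    return PauliSum(n_qubits, {"I" * n_qubits: 0.5, word: -0.5})


def jw_hop(p: int, q: int, c: complex, n_qubits: int) -> PauliSum:
    """JW image of the anti-Hermitian pair c a^+_p a_q - conj(c) a^+_q a_p.

    For adjacent p, q the image consists of weight-2 XY/YX words (real c)
    or XX/YY words (imaginary c); non-adjacent pairs carry the Z string.
    """
    if p == q:
        raise ValueError("hop requires p != q")
    t1 = jw_creation(p, n_qubits) @ jw_annihilation(q, n_qubits)
    out = c * t1 + (-np.conj(c)) * (jw_creation(q, n_qubits) @ jw_annihilation(p, n_qubits))
    return out


# ---------------------------------------------------------------------------
# Qubit-wise commuting grouping
# ---------------------------------------------------------------------------

def _qwc_compatible(word: str, basis: List[str]) -> bool:
    for c, b in zip(word, basis):
        if c != "I" and b != "I" and c != b:
            return False
    return True


def qwc_group(H: PauliSum) -> List[List[PauliTerm]]:
    """Partition terms into qubit-wise commuting groups.

    Greedy first-fit over terms sorted by descending coefficient magnitude
    (ties broken lexicographically by word, for determinism).  Within a
    group every qubit position carries at most one non-identity letter
    across all member words, so the whole group is measurable in one
    single-qubit basis rotation.
    """
    order = sorted(H.terms, key=lambda t: (-abs(t.coefficient), t.word))
    groups: List[List[PauliTerm]] = []
    bases: List[List[str]] = []
    for term in order:
        for g, basis in zip(groups, bases):
            if _qwc_compatible(term.word, basis):
                g.append(term)
                for k, c in enumerate(term.word):
                    if c != "I":
                        basis[k] = c
                break
        else:
            groups.append([term])
            bases.append(list(term.word))
    return groups
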