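"""Exact uCJ circuit synthesis, Trotter comparators, and gate accounting.

Gate vocabulary (occupation-basis semantics, |0> = unoccupied):

* ``PREP_X q``            -- flip qubit q (reference-determinant prep).
* ``GIVENS2 p (theta,phi)`` -- the two-qubit image on adjacent JW modes
  (p, p+1) of the generalized fermionic plane rotation whose
  single-particle matrix block is
  ``[[cos t, -e^{i phi} sin t], [e^{-i phi} sin t, cos t]]``; it mixes
  the {01, 10} subspace and leaves 00 and 11 untouched.
* ``RZ q angle``          -- occupied-phase gate diag(1, e^{i angle}).
* ``ZZ_PHASE (i,j) angle``-- pair phase e^{i angle} on 11-coincidence of
  qubits i and j, i.e. exp(i angle n_i n_j).
* ``GLOBAL_PHASE angle``  -- scalar phase (bookkeeping only).
* ``PAULI_EVOL word angle``-- exp(i angle P_word), used by single
  Trotter-step comparator circuits.

CNOT compilation rule: GIVENS2 = 3 CNOTs, ZZ_PHASE = 2 CNOTs (plus one
R_z), PAULI_EVOL of weight w = 2(w-1) CNOTs (staircase), everything else
is free of two-qubit gates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ansatz import UCJParameters, enumerate_j_terms, k_to_unitary
from .givens import complex_givens_decompose
from .integrals import ReferenceDeterminant
from .paulis import PauliSum

__all__ = [
    "Gate",
    "Circuit",
    "build_exact_ucj_circuit",
    "build_trotter_circuit",
    "count_cnots",
    "cnot_count_formula",
    "estimate_t_gates",
    "UCCSDOperators",
    "uccsd_generator",
]


@dataclass(frozen=True)
class Gate:
    kind: str                      # PREP_X | GIVENS2 | RZ | ZZ_PHASE | GLOBAL_PHASE | PAULI_EVOL
    qubits: Tuple[int, ...]
    params: Tuple[float, ...] = ()
    word: str = ""                 # PAULI_EVOL only

    def __post_init__(self):
        if self.kind == "GIVENS2" and self.qubits[1] != self.qubits[0] + 1:
            raise ValueError("GIVENS2 must act on adjacent qubits")


@dataclass
class Circuit:
    n_qubits: int
    gates: List[Gate] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def add(self, gate: Gate) -> None:
        if any(q >= self.n_qubits or q < 0 for q in gate.qubits):
            raise ValueError("gate qubit index out of range")
        self.gates.append(gate)

    def __len__(self) -> int:
        return len(self.gates)

    # -- export --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "n_qubits": self.n_qubits,
            "metadata": self.metadata,
            "gates": [{"kind": g.kind, "qubits": list(g.qubits),
                       "params": list(g.params), "word": g.word}
                      for g in self.gates],
        })

    @classmethod
    def from_json(cls, text: str) -> "Circuit":
        d = json.loads(text)
        c = cls(d["n_qubits"], metadata=d.get("metadata", {}))
        for g in d["gates"]:
            c.add(Gate(g["kind"], tuple(g["qubits"]), tuple(g["params"]), g["word"]))
        return c

    def to_qasm_like(self) -> str:
        """Readable text export.

        GIVENS2 would compile to CNOT/RZ/RX as a standard three-CNOT
        two-qubit block; here gates are kept symbolic, one per line.
        """
        lines = [f"# qubits: {self.n_qubits}",
                 "# GIVENS2(theta,phi) = 3-CNOT two-qubit block; "
                 "ZZ_PHASE(a) = CNOT RZ(a) CNOT"]
        for g in self.gates:
            qs = ",".join(f"q[{q}]" for q in g.qubits)
            ps = ",".join(f"{p:.12g}" for p in g.params)
            lines.append(f"{g.kind.lower()}({ps}) {qs};" if ps or qs
                         else f"{g.kind.lower()};")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Exact uCJ circuit
# ---------------------------------------------------------------------------

def _orbital_rotation_gates(u: np.ndarray, offset: int,
                            prune: bool) -> List[Gate]:
    """Gate sequence (first applied first) realizing U(u) on one spin block.

    With the QR factorization u = r_1^dag ... r_L^dag D, the operator
    identity U(u) = R_1^dag ... R_L^dag U(D) means the circuit applies the
    phase layer first, then the inverted rotations in reverse elimination
    order.  ``prune=False`` keeps theta=0 rotations so gate counts do not
    depend on the parameter point.
    """
    M = u.shape[0]
    rotations, phases = complex_givens_decompose(u, prune=prune)
    gates: List[Gate] = []
    for k, ph in enumerate(phases.phases):
        if abs(ph) > 1e-14:
            gates.append(Gate("RZ", (offset + k,), (float(ph),)))
    for r in reversed(rotations):
        gates.append(Gate("GIVENS2", (offset + r.p, offset + r.p + 1),
                          (-r.theta, r.phi)))
    return gates


def build_exact_ucj_circuit(params: UCJParameters,
                            ref: ReferenceDeterminant,
                            prune: bool = True) -> Circuit:
    """Trotter-free circuit for prod_i e^{K_i} e^{J_i} e^{-K_i} |ref>."""
    params.validate()
    M, N = params.M, 2 * params.M
    ref.validate(M)
    c = Circuit(N, metadata={
        "variant": params.variant, "k": params.k, "M": M,
        "n_alpha": len(ref.occ_alpha), "n_beta": len(ref.occ_beta),
    })
    for k, bit in enumerate(ref.bitstring(M)):
        if bit == "1":
            c.add(Gate("PREP_X", (k,)))
    jt = params.j_terms.entries
    for rep in params.replicas:
        # e^{-K}
        for off, K in ((0, rep.k_alpha), (M, rep.k_beta)):
            for g in _orbital_rotation_gates(k_to_unitary(-K), off, prune):
                c.add(g)
        # e^{J}: J = i R, exp(J) = prod exp(i 2 R_ij n_i n_j)
        for (i, j) in jt:
            angle = 2.0 * rep.j_real[i, j]
            if prune and abs(angle) < 1e-15:
                continue
            c.add(Gate("ZZ_PHASE", (i, j), (float(angle),)))
        # e^{+K}
        for off, K in ((0, rep.k_alpha), (M, rep.k_beta)):
            for g in _orbital_rotation_gates(k_to_unitary(K), off, prune):
                c.add(g)
    return c


# ---------------------------------------------------------------------------
# Single Trotter-step comparator
# ---------------------------------------------------------------------------

def build_trotter_circuit(op: PauliSum, order: str = "lex") -> Circuit:
    """One PAULI_EVOL per surviving word of an anti-Hermitian PauliSum.

    The generator must be i times a Hermitian operator with purely
    imaginary coefficients, so each factor is exp(i angle P).  For a
    mutually commuting term family the product equals the exact
    exponential; otherwise it is the single-step Trotter approximation.
    """
    c = Circuit(op.n_qubits, metadata={"kind": "trotter"})
    terms = op.terms
    if order == "lex":
        terms = sorted(terms, key=lambda t: t.word)
    for t in terms:
        if abs(t.coefficient.real) > 1e-12:
            raise ValueError("generator is not anti-Hermitian (real coefficient)")
        angle = float(t.coefficient.imag)
        if t.word.strip("I") == "":
            c.add(Gate("GLOBAL_PHASE", (), (angle,)))
        else:
            c.add(Gate("PAULI_EVOL", tuple(k for k, ch in enumerate(t.word)
                                           if ch != "I"),
                       (angle,), t.word))
    return c


# ---------------------------------------------------------------------------
# Resource accounting
# ---------------------------------------------------------------------------

_CNOTS = {"PREP_X": 0, "RZ": 0, "GLOBAL_PHASE": 0, "GIVENS2": 3, "ZZ_PHASE": 2}


def count_cnots(c: Circuit) -> int:
    n = 0
    for g in c.gates:
        if g.kind == "PAULI_EVOL":
            w = sum(1 for ch in g.word if ch != "I")
            n += 2 * (w - 1)
        else:
            n += _CNOTS[g.kind]
    return n


def cnot_count_formula(M: int, n_alpha: int, n_beta: int, k: int = 1,
                       screen: bool = True) -> int:
    """Closed-form CNOT count of the exact k-fold uCJ circuit.

    Two orbital-rotation passes (e^K and e^-K) of C(M,2) adjacent Givens
    rotations per spin block at 3 CNOTs each, plus 2 CNOTs per surviving
    Jastrow pair term:  k * (12 C(M,2) + 2 |J|).
    """
    nj = len(enumerate_j_terms(M, n_alpha, n_beta, screen))
    return k * (2 * 3 * 2 * (M * (M - 1) // 2) + 2 * nj)


def _rz_equivalents(c: Circuit) -> int:
    """Arbitrary-angle rotations needing T-gate synthesis.

    GIVENS2 compiles to three R_z rotations inside its three-CNOT block;
    ZZ_PHASE carries one R_z; RZ is itself one.
    """
    per = {"PREP_X": 0, "GLOBAL_PHASE": 0, "RZ": 1, "ZZ_PHASE": 1, "GIVENS2": 3,
           "PAULI_EVOL": 1}
    return sum(per[g.kind] for g in c.gates)


def estimate_t_gates(c: Circuit, eps_syn: float) -> float:
    """T-gate estimate: rotations x (1.15 log2(1/eps_syn) + 9.2)."""
    if not 0 < eps_syn <= 1:
        raise ValueError("eps_syn must lie in (0, 1]")
    return _rz_equivalents(c) * (1.15 * np.log2(1.0 / eps_syn) + 9.2)


# ---------------------------------------------------------------------------
# UCCSD comparator (structural gate counting only)
# ---------------------------------------------------------------------------

@dataclass
class UCCSDOperators:
    """Singles/doubles amplitudes for the anti-Hermitian UCC generator."""

    t1: Dict[Tuple[int, int], float]                    # (occ, virt) spin-orbital
    t2: Dict[Tuple[int, int, int, int], float]          # (occ, occ, virt, virt)


def uccsd_generator(ref: ReferenceDeterminant, M: int,
                    amplitudes: Optional[UCCSDOperators] = None) -> PauliSum:
    """JW image of T - T^dag with placeholder (unit) amplitudes.

    Used only for circuit-structure comparisons; no energies are attached
    to these amplitudes.
    """
    from .paulis import jw_annihilation, jw_creation

    N = 2 * M
    occ = [p for p in ref.occ_alpha] + [M + p for p in ref.occ_beta]
    virt = [p for p in range(N) if p not in occ]
    if amplitudes is None:
        t1 = {(i, a): 1.0 for i in occ for a in virt
              if (i < M) == (a < M)}
        t2 = {}
        for ii, i in enumerate(occ):
            for j in occ[ii + 1:]:
                for ai, a in enumerate(virt):
                    for b in virt[ai + 1:]:
                        if ((i < M) + (j < M)) == ((a < M) + (b < M)):
                            t2[(i, j, a, b)] = 1.0
        amplitudes = UCCSDOperators(t1, t2)
    gen = PauliSum(N)
    for (i, a), t in amplitudes.t1.items():
        term = jw_creation(a, N) @ jw_annihilation(i, N)
        gen = gen + t * term + (-t) * term.dagger()
    for (i, j, a, b), t in amplitudes.t2.items():
        term = (jw_creation(a, N) @ jw_creation(b, N)
                @ jw_annihilation(j, N) @ jw_annihilation(i, N))
        gen = gen + t * term + (-t) * term.dagger()
    return gen
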