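"""Sparse statevector simulation, exact and shot-sampled expectations.

States are maps from occupation bitstrings (string of '0'/'1', position =
qubit index) to complex amplitudes.  Particle-number-conserving circuits
keep the support inside one sector, so dictionaries stay small at desk
scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .circuits import Circuit, Gate
from .paulis import PauliSum, PauliTerm, qwc_group

__all__ = [
    "SparseState",
    "ShotPlan",
    "apply_circuit",
    "expectation",
    "sampled_expectation",
    "overlap",
]

_PRUNE = 1e-14


@dataclass
class SparseState:
    """Occupation-basis sparse statevector."""

    n_qubits: int
    amplitudes: Dict[str, complex]

    @classmethod
    def vacuum(cls, n_qubits: int) -> "SparseState":
        return cls(n_qubits, {"0" * n_qubits: 1.0 + 0j})

    @classmethod
    def basis_state(cls, bits: str) -> "SparseState":
        return cls(len(bits), {bits: 1.0 + 0j})

    def norm(self) -> float:
        return math.sqrt(sum(abs(a) ** 2 for a in self.amplitudes.values()))

    def prune(self) -> "SparseState":
        self.amplitudes = {b: a for b, a in self.amplitudes.items()
                           if abs(a) > _PRUNE}
        return self

    def to_dense(self) -> np.ndarray:
        """Dense vector; qubit 0 is the most significant bit."""
        v = np.zeros(2 ** self.n_qubits, dtype=complex)
        for bits, a in self.amplitudes.items():
            v[int(bits, 2)] = a
        return v

    def to_json(self) -> str:
        return json.dumps({
            "n_qubits": self.n_qubits,
            "amplitudes": {b: [a.real, a.imag]
                           for b, a in sorted(self.amplitudes.items())},
        })

    @classmethod
    def from_json(cls, text: str) -> "SparseState":
        d = json.loads(text)
        return cls(d["n_qubits"], {b: complex(re, im)
                                   for b, (re, im) in d["amplitudes"].items()})


@dataclass(frozen=True)
class ShotPlan:
    """Measurement budget for sampled expectation values."""

    shots_per_group: int
    seed: int
    n_trials: int = 1

    def __post_init__(self):
        if self.shots_per_group <= 0 or self.n_trials <= 0:
            raise ValueError("shot and trial counts must be positive")


# ---------------------------------------------------------------------------
# Gate application
# ---------------------------------------------------------------------------

def _apply_gate(g: Gate, amps: Dict[str, complex], n: int) -> Dict[str, complex]:
    kind = g.kind
    if kind == "PREP_X":
        (q,) = g.qubits
        return {b[:q] + ("1" if b[q] == "0" else "0") + b[q + 1:]: a
                for b, a in amps.items()}
    if kind == "RZ":
        (q,) = g.qubits
        ph = complex(np.exp(1j * g.params[0]))
        return {b: (a * ph if b[q] == "1" else a) for b, a in amps.items()}
    if kind == "GLOBAL_PHASE":
        ph = complex(np.exp(1j * g.params[0]))
        return {b: a * ph for b, a in amps.items()}
    if kind == "ZZ_PHASE":
        i, j = g.qubits
        ph = complex(np.exp(1j * g.params[0]))
        return {b: (a * ph if b[i] == "1" and b[j] == "1" else a)
                for b, a in amps.items()}
    if kind == "GIVENS2":
        p, q = g.qubits
        theta, phi = g.params
        c, s = math.cos(theta), math.sin(theta)
        e = complex(np.exp(1j * phi))
        out: Dict[str, complex] = {}

        def _acc(bits: str, a: complex) -> None:
            if abs(a) > _PRUNE:
                out[bits] = out.get(bits, 0.0) + a

        for b, a in amps.items():
            bp, bq = b[p], b[q]
            if bp == bq:
                _acc(b, a)
                continue
            # single-particle block: |10> -> c|10> + conj(e) s |01>,
            #                        |01> -> -e s |10> + c |01>
            b10 = b[:p] + "1" + b[p + 1:q] + "0" + b[q + 1:]
            b01 = b[:p] + "0" + b[p + 1:q] + "1" + b[q + 1:]
            if bp == "1":          # |10>
                _acc(b10, c * a)
                _acc(b01, np.conj(e) * s * a)
            else:                  # |01>
                _acc(b10, -e * s * a)
                _acc(b01, c * a)
        return out
    if kind == "PAULI_EVOL":
        # exp(i angle P) = cos(angle) I + i sin(angle) P
        angle = g.params[0]
        c, s = math.cos(angle), math.sin(angle)
        from .integrals import _apply_word
        out = {}
        for b, a in amps.items():
            out[b] = out.get(b, 0.0) + c * a
            nb, ph = _apply_word(g.word, b)
            v = out.get(nb, 0.0) + 1j * s * ph * a
            out[nb] = v
        return {b: a for b, a in out.items() if abs(a) > _PRUNE}
    raise ValueError(f"unknown gate kind {kind!r}")


def apply_circuit(c: Circuit, state: SparseState) -> SparseState:
    if c.n_qubits != state.n_qubits:
        raise ValueError("qubit count mismatch between circuit and state")
    amps = dict(state.amplitudes)
    for g in c.gates:
        amps = _apply_gate(g, amps, c.n_qubits)
    return SparseState(state.n_qubits, amps).prune()


# ---------------------------------------------------------------------------
# Expectations
# ---------------------------------------------------------------------------

def expectation(H: PauliSum, state: SparseState) -> float:
    """Exact <s|H|s> for a Hermitian PauliSum."""
    if not H.is_hermitian(1e-8):
        raise ValueError("expectation requires a Hermitian operator")
    from .integrals import _apply_word

    val = 0.0 + 0j
    amps = state.amplitudes
    for term in H.terms:
        acc = 0.0 + 0j
        for b, a in amps.items():
            nb, ph = _apply_word(term.word, b)
            conj_amp = amps.get(nb)
            if conj_amp is not None:
                acc += np.conj(conj_amp) * ph * a
        val += term.coefficient * acc
    return float(val.real)


def overlap(a: SparseState, b: SparseState) -> complex:
    if a.n_qubits != b.n_qubits:
        raise ValueError("qubit count mismatch")
    keys = a.amplitudes.keys() if len(a.amplitudes) <= len(b.amplitudes) \
        else b.amplitudes.keys()
    return complex(sum(np.conj(a.amplitudes[k]) * b.amplitudes[k]
                       for k in keys
                       if k in a.amplitudes and k in b.amplitudes))


# ---------------------------------------------------------------------------
# Shot sampling over qubit-wise commuting groups
# ---------------------------------------------------------------------------

def _group_distribution(group: List[PauliTerm],
                        state: SparseState) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Outcome distribution in the group's shared measurement basis.

    Rotating each X (Y) qubit by a Hadamard (S^dag then Hadamard) maps
    the group to I/Z words; the rotated state's computational-basis
    probabilities are the exact measurement distribution.
    """
    n = state.n_qubits
    basis = ["I"] * n
    for t in group:
        for k, ch in enumerate(t.word):
            if ch != "I":
                basis[k] = ch
    amps = dict(state.amplitudes)
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for q, b in enumerate(basis):
        if b not in ("X", "Y"):
            continue
        out: Dict[str, complex] = {}
        for bits, a in amps.items():
            b0 = bits[:q] + "0" + bits[q + 1:]
            b1 = bits[:q] + "1" + bits[q + 1:]
            if b == "X":           # H
                if bits[q] == "0":
                    out[b0] = out.get(b0, 0.0) + inv_sqrt2 * a
                    out[b1] = out.get(b1, 0.0) + inv_sqrt2 * a
                else:
                    out[b0] = out.get(b0, 0.0) + inv_sqrt2 * a
                    out[b1] = out.get(b1, 0.0) - inv_sqrt2 * a
            else:                  # H S^dag : Y basis
                if bits[q] == "0":
                    out[b0] = out.get(b0, 0.0) + inv_sqrt2 * a
                    out[b1] = out.get(b1, 0.0) + inv_sqrt2 * a
                else:
                    out[b0] = out.get(b0, 0.0) - 1j * inv_sqrt2 * a
                    out[b1] = out.get(b1, 0.0) + 1j * inv_sqrt2 * a
        amps = {k: v for k, v in out.items() if abs(v) > _PRUNE}
    keys = sorted(amps)
    probs = np.array([abs(amps[k]) ** 2 for k in keys])
    probs = probs / probs.sum()
    return probs, np.arange(len(keys)), keys


def sampled_expectation(H: PauliSum, state: SparseState,
                        plan: ShotPlan) -> Tuple[float, float]:
    """Unbiased shot-sampled estimate of <H> over QWC groups.

    Returns ``(mean, stderr)`` where mean averages the ``n_trials``
    independent trial estimates and stderr combines the per-group
    multinomial sampling variances across trials.
    """
    groups = qwc_group(H)
    rng = np.random.default_rng(plan.seed)
    trial_means = []
    trial_vars = []
    for _ in range(plan.n_trials):
        total = 0.0
        var = 0.0
        for group in groups:
            ident = [t for t in group if t.word.strip("I") == ""]
            meas = [t for t in group if t.word.strip("I") != ""]
            total += sum(t.coefficient.real for t in ident)
            if not meas:
                continue
            probs, _, keys = _group_distribution(group, state)
            counts = rng.multinomial(plan.shots_per_group, probs)
            shots = plan.shots_per_group
            for t in meas:
                signs = np.array([
                    (-1) ** sum(1 for k, ch in enumerate(t.word)
                                if ch != "I" and key[k] == "1")
                    for key in keys], dtype=float)
                est = float(np.dot(counts, signs)) / shots
                total += t.coefficient.real * est
                # sample variance of the +-1 estimator
                var += (t.coefficient.real ** 2) * max(0.0, (1 - est ** 2)) / shots
        trial_means.append(total)
        trial_vars.append(var)
    mean = float(np.mean(trial_means))
    stderr = float(math.sqrt(np.mean(trial_vars) / plan.n_trials))
    return mean, stderr
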