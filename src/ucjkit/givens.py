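"""Exact decomposition of complex orbital-rotation unitaries.

A generalized Givens rotation on adjacent modes (p, p+1) is the M x M
identity with the 2 x 2 block

    [[ cos(theta),              -exp(+i*phi) sin(theta) ],
     [ exp(-i*phi) sin(theta),   cos(theta)             ]]

at rows/columns (p, p+1).  A QR-like sweep of such rotations brings any
unitary u to diagonal form, so

    u = r_1^dag r_2^dag ... r_L^dag diag(exp(i phases))

with L <= M(M-1)/2 and every rotation acting on adjacent modes only.
Restricting to adjacent modes is what keeps the Jordan-Wigner image of
each rotation a two-qubit gate, free of Z strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "GivensRotation",
    "PhaseLayer",
    "rotation_matrix",
    "complex_givens_decompose",
    "reconstruct",
    "rotation_count",
]


@dataclass(frozen=True)
class GivensRotation:
    """Adjacent-mode plane rotation with relative phase."""

    p: int          # lower mode; acts on (p, p+1)
    theta: float
    phi: float

    @property
    def q(self) -> int:
        return self.p + 1


@dataclass(frozen=True)
class PhaseLayer:
    """Residual per-mode phases exp(i*phase_p)."""

    phases: Tuple[float, ...]

    def matrix(self) -> np.ndarray:
        return np.diag(np.exp(1j * np.asarray(self.phases)))


def rotation_matrix(r: GivensRotation, M: int) -> np.ndarray:
    if not 0 <= r.p < M - 1:
        raise ValueError(f"rotation modes ({r.p},{r.p+1}) out of range for M={M}")
    m = np.eye(M, dtype=complex)
    c, s = np.cos(r.theta), np.sin(r.theta)
    e = np.exp(1j * r.phi)
    m[r.p, r.p] = c
    m[r.q, r.q] = c
    m[r.p, r.q] = -e * s
    m[r.q, r.p] = np.conj(e) * s
    return m


def _elimination_angles(a: complex, b: complex) -> Tuple[float, float]:
    """Angles so that row q of r @ [[a],[b]] vanishes.

    Row q after rotation: exp(-i*phi) sin(theta) * a + cos(theta) * b = 0.
    Degenerate pivot |a| < 1e-12 takes theta = pi/2, phi = 0 (a plain swap).
    """
    if abs(a) < 1e-12:
        return np.pi / 2, 0.0
    theta = -np.arctan2(abs(b), abs(a))
    phi = float(np.angle(a) - np.angle(b)) if abs(b) > 1e-15 else 0.0
    return float(theta), phi


def complex_givens_decompose(u: np.ndarray, tol: float = 1e-10,
                             prune: bool = True) -> Tuple[List[GivensRotation], PhaseLayer]:
    """QR-like reduction of a unitary by adjacent generalized Givens rotations.

    Sub-diagonal entries are zeroed column by column, each elimination
    using only the two adjacent rows that straddle the entry; with
    ``prune=True`` rotations whose target entry is already zero are
    dropped, with ``prune=False`` they are kept at theta=0 so the full
    C(M,2) elimination schedule is always emitted.  Returns the rotation
    list and the residual diagonal phase layer such that
    ``reconstruct(rotations, phases)`` reproduces ``u``.
    """
    u = np.asarray(u, dtype=complex)
    M = u.shape[0]
    if u.shape != (M, M) or np.max(np.abs(u.conj().T @ u - np.eye(M))) > tol:
        raise ValueError("input matrix is not unitary")
    w = u.copy()
    rotations: List[GivensRotation] = []
    for col in range(M - 1):
        for row in range(M - 1, col, -1):
            b = w[row, col]
            if abs(b) <= 1e-14:
                if not prune:
                    rotations.append(GivensRotation(row - 1, 0.0, 0.0))
                continue
            a = w[row - 1, col]
            theta, phi = _elimination_angles(a, b)
            r = GivensRotation(row - 1, theta, phi)
            w = rotation_matrix(r, M) @ w
            rotations.append(r)
    phases = PhaseLayer(tuple(float(np.angle(w[k, k])) for k in range(M)))
    return rotations, phases


def reconstruct(rotations: List[GivensRotation], phases: PhaseLayer) -> np.ndarray:
    """u = r_1^dag ... r_L^dag diag(e^{i phases})."""
    M = len(phases.phases)
    u = phases.matrix()
    for r in reversed(rotations):
        u = rotation_matrix(r, M).conj().T @ u
    return u


def rotation_count(M: int) -> int:
    """Worst-case rotations to diagonalize an M x M unitary: C(M,2)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return M * (M - 1) // 2


def decomposition_to_json(rotations: List[GivensRotation], phases: PhaseLayer) -> str:
    return json.dumps({
        "rotations": [[r.p, r.theta, r.phi] for r in rotations],
        "phases": list(phases.phases),
    })


def decomposition_from_json(text: str) -> Tuple[List[GivensRotation], PhaseLayer]:
    d = json.loads(text)
    return ([GivensRotation(int(p), float(t), float(f)) for p, t, f in d["rotations"]],
            PhaseLayer(tuple(float(x) for x in d["phases"])))
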