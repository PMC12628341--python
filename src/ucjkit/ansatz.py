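"""Parameterization of the unitary cluster Jastrow ansatz family.

The k-fold uCJ state is ``prod_i e^{K_i} e^{J_i} e^{-K_i} |ref>``.  Each
replica carries:

* ``K_alpha``, ``K_beta`` -- M x M anti-Hermitian orbital-rotation
  generators, one per spin block (independent parameters).  The variants
  restrict them: ``re`` real antisymmetric, ``im`` purely imaginary
  (i times a real symmetric matrix, zero diagonal), ``g`` fully complex.
* ``j_real`` -- the real symmetric zero-diagonal N x N matrix R behind
  the purely imaginary symmetric Jastrow matrix J = i R over spin
  orbitals.

Free real coordinates per replica: C(M,2) per K block for ``re``/``im``
(the imaginary diagonal of an ``im`` block only generates orbital phases
absorbable into J and a global phase, so it is excluded), 2*C(M,2) for
``g``, plus one real per surviving Jastrow pair term.  Same-spin pair
terms are screened out for any spin sector holding <= 1 electron, where
the paired number operators annihilate every state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .paulis import PauliSum, jw_hop, jw_number_operator

__all__ = [
    "VARIANTS",
    "UCJParameters",
    "JTermList",
    "enumerate_j_terms",
    "n_parameters",
    "pack",
    "unpack",
    "k_to_unitary",
    "build_operators",
]

VARIANTS = ("re", "im", "g")


@dataclass(frozen=True)
class JTermList:
    """Surviving Jastrow pair terms (spin-orbital indices, p < q)."""

    entries: Tuple[Tuple[int, int], ...]
    screened: bool

    def __len__(self) -> int:
        return len(self.entries)


def enumerate_j_terms(M: int, n_alpha: int, n_beta: int,
                      screen: bool = True) -> JTermList:
    """All distinct off-diagonal spin-orbital pairs, optionally screened.

    Screening removes same-spin pairs for a spin sector with at most one
    electron: ``n_p n_q`` with both orbitals in that sector then
    annihilates every state of the sector.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    N = 2 * M
    entries = []
    for i in range(N):
        for j in range(i + 1, N):
            if screen:
                same_alpha = i < M and j < M
                same_beta = i >= M and j >= M
                if same_alpha and n_alpha <= 1:
                    continue
                if same_beta and n_beta <= 1:
                    continue
            entries.append((i, j))
    return JTermList(tuple(entries), screen)


@dataclass
class UCJReplica:
    k_alpha: np.ndarray           # (M, M) anti-Hermitian
    k_beta: np.ndarray
    j_real: np.ndarray            # (N, N) real symmetric, zero diagonal


@dataclass
class UCJParameters:
    """Variational state of a k-fold uCJ ansatz."""

    variant: str
    M: int
    n_alpha: int
    n_beta: int
    replicas: List[UCJReplica]
    screen: bool = True

    @property
    def k(self) -> int:
        return len(self.replicas)

    @property
    def j_terms(self) -> JTermList:
        return enumerate_j_terms(self.M, self.n_alpha, self.n_beta, self.screen)

    @classmethod
    def zeros(cls, variant: str, M: int, n_alpha: int, n_beta: int,
              k: int = 1, screen: bool = True) -> "UCJParameters":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        reps = [UCJReplica(np.zeros((M, M), complex), np.zeros((M, M), complex),
                           np.zeros((2 * M, 2 * M))) for _ in range(k)]
        return cls(variant, M, n_alpha, n_beta, reps, screen)

    def validate(self, tol: float = 1e-12) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for rep in self.replicas:
            for K in (rep.k_alpha, rep.k_beta):
                if np.max(np.abs(K + K.conj().T)) > tol:
                    raise ValueError("K block is not anti-Hermitian")
                if self.variant == "re" and np.max(np.abs(K.imag)) > tol:
                    raise ValueError("re-uCJ requires a real K block")
                if self.variant == "im" and np.max(np.abs(K.real)) > tol:
                    raise ValueError("im-uCJ requires a purely imaginary K block")
            R = rep.j_real
            if np.max(np.abs(R - R.T)) > tol or np.max(np.abs(np.diag(R))) > tol:
                raise ValueError("j_real must be symmetric with zero diagonal")

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant, "M": self.M,
            "n_alpha": self.n_alpha, "n_beta": self.n_beta,
            "screen": self.screen,
            "replicas": [{
                "k_alpha_re": r.k_alpha.real.tolist(),
                "k_alpha_im": r.k_alpha.imag.tolist(),
                "k_beta_re": r.k_beta.real.tolist(),
                "k_beta_im": r.k_beta.imag.tolist(),
                "j_real": r.j_real.tolist(),
            } for r in self.replicas],
        })

    @classmethod
    def from_json(cls, text: str) -> "UCJParameters":
        d = json.loads(text)
        reps = [UCJReplica(
            np.array(r["k_alpha_re"]) + 1j * np.array(r["k_alpha_im"]),
            np.array(r["k_beta_re"]) + 1j * np.array(r["k_beta_im"]),
            np.array(r["j_real"]),
        ) for r in d["replicas"]]
        return cls(d["variant"], d["M"], d["n_alpha"], d["n_beta"], reps,
                   d["screen"])


# ---------------------------------------------------------------------------
# Real coordinate packing
# ---------------------------------------------------------------------------

def _tri(M: int) -> List[Tuple[int, int]]:
    return [(p, q) for p in range(M) for q in range(p + 1, M)]


def n_k_parameters(variant: str, M: int) -> int:
    """Free reals per K spin block."""
    base = M * (M - 1) // 2
    return 2 * base if variant == "g" else base


def n_parameters(variant: str, M: int, n_alpha: int, n_beta: int,
                 k: int = 1, screen: bool = True) -> int:
    nj = len(enumerate_j_terms(M, n_alpha, n_beta, screen))
    return k * (2 * n_k_parameters(variant, M) + nj)


def pack(params: UCJParameters) -> np.ndarray:
    """Minimal real coordinate vector; inverse of :func:`unpack`."""
    params.validate()
    M = params.M
    tri = _tri(M)
    jt = params.j_terms.entries
    out: List[float] = []
    for rep in params.replicas:
        for K in (rep.k_alpha, rep.k_beta):
            if params.variant in ("re", "g"):
                out.extend(K[p, q].real for p, q in tri)
            if params.variant in ("im", "g"):
                out.extend(K[p, q].imag for p, q in tri)
        out.extend(rep.j_real[i, j] for i, j in jt)
    return np.asarray(out)


def unpack(x: Sequence[float], variant: str, M: int, n_alpha: int, n_beta: int,
           k: int = 1, screen: bool = True) -> UCJParameters:
    x = np.asarray(x, dtype=float)
    expected = n_parameters(variant, M, n_alpha, n_beta, k, screen)
    if x.size != expected:
        raise ValueError(f"expected {expected} coordinates, got {x.size}")
    tri = _tri(M)
    jt = enumerate_j_terms(M, n_alpha, n_beta, screen).entries
    nk = n_k_parameters(variant, M)
    reps = []
    pos = 0
    for _ in range(k):
        Ks = []
        for _blk in range(2):
            K = np.zeros((M, M), complex)
            if variant in ("re", "g"):
                for (p, q) in tri:
                    K[p, q] += x[pos]
                    K[q, p] -= x[pos]
                    pos += 1
            if variant in ("im", "g"):
                for (p, q) in tri:
                    K[p, q] += 1j * x[pos]
                    K[q, p] += 1j * x[pos]
                    pos += 1
            Ks.append(K)
        R = np.zeros((2 * M, 2 * M))
        for (i, j) in jt:
            R[i, j] = R[j, i] = x[pos]
            pos += 1
        reps.append(UCJReplica(Ks[0], Ks[1], R))
    return UCJParameters(variant, M, n_alpha, n_beta, reps, screen)


def k_to_unitary(K: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """u = exp(K) for anti-Hermitian K."""
    K = np.asarray(K, dtype=complex)
    if np.max(np.abs(K + K.conj().T)) > tol:
        raise ValueError("K must be anti-Hermitian")
    return expm(K)


# ---------------------------------------------------------------------------
# Jordan-Wigner operator construction
# ---------------------------------------------------------------------------

def build_operators(params: UCJParameters) -> List[Tuple[PauliSum, PauliSum]]:
    """JW images (K_hat, J_hat) per replica.

    K_hat is the anti-Hermitian one-body generator; J_hat = i * sum over
    surviving pairs of 2 R_ij n_i n_j consists of I/Z words only, so all
    of its terms commute and its exponential factorizes exactly.
    """
    params.validate()
    M, N = params.M, 2 * params.M
    jt = params.j_terms.entries
    out = []
    for rep in params.replicas:
        khat = PauliSum(N)
        for blk, K in ((0, rep.k_alpha), (1, rep.k_beta)):
            off = blk * M
            for p in range(M):
                for q in range(p + 1, M):
                    if abs(K[p, q]) > 1e-15:
                        khat = khat + jw_hop(off + p, off + q, K[p, q], N)
        jhat = PauliSum(N)
        for (i, j) in jt:
            if abs(rep.j_real[i, j]) > 1e-15:
                nn = jw_number_operator(i, N) @ jw_number_operator(j, N)
                jhat = jhat + (2j * rep.j_real[i, j]) * nn
        out.append((khat, jhat))
    return out
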