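"""Minimal ab initio backend for hydrogen clusters in s-function bases.

Analytic one- and two-electron integrals over contracted s-type Gaussians
(closed forms via the zeroth Boys function), restricted and unrestricted
Hartree-Fock, and the MO transformation that yields
:class:`~ucjkit.integrals.ActiveSpaceIntegrals`.

Scope: every atom is a hydrogen (point charge +1, s shells only).  This
covers the benchmark systems built from H atoms (H2, linear H3+, square
H4) in the STO-3G and 6-31G bases, whose active space is the full orbital
space.  Heavier elements, p/d shells and frozen cores are out of scope.

The RHF solve uses a deterministic core-Hamiltonian guess with plain
Roothaan iterations.  The UHF solve is stability-followed in a global
sense: a seeded batch of random orthogonal orbital starts is relaxed to
self-consistency and the lowest solution kept, which reliably locates the
broken-symmetry minimum when one exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.linalg import eigh
from scipy.special import erf

from .integrals import ActiveSpaceIntegrals

__all__ = [
    "BOHR_PER_ANGSTROM",
    "Molecule",
    "h2_molecule",
    "h3_plus_linear",
    "h4_square",
    "RHFResult",
    "UHFResult",
    "run_rhf",
    "run_uhf",
    "active_space_integrals",
    "BASIS_SETS",
]

ANGSTROM_IN_BOHR = 0.529177210903   # CODATA 2018 Bohr radius in angstrom
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_IN_BOHR

# hydrogen s-shell contractions: list of (exponents, contraction coeffs)
BASIS_SETS: Dict[str, List[Tuple[Tuple[float, ...], Tuple[float, ...]]]] = {
    "sto-3g": [
        ((3.42525091, 0.62391373, 0.16885540),
         (0.15432897, 0.53532814, 0.44463454)),
    ],
    "6-31g": [
        ((18.7311370, 2.8253937, 0.6401217),
         (0.03349460, 0.23472695, 0.81375733)),
        ((0.1612778,), (1.0,)),
    ],
}


@dataclass
class Molecule:
    """A cluster of hydrogen-like point charges with s-shell bases."""

    centers: np.ndarray            # (n_atoms, 3) in bohr
    charges: np.ndarray            # nuclear charges
    basis: str = "sto-3g"
    label: str = ""
    charge: int = 0                # net molecular charge

    @property
    def n_electrons(self) -> int:
        return int(round(self.charges.sum())) - self.charge

    def shells(self) -> List[Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per basis function: (center, exponents, normalized coefficients)."""
        out = []
        for c in self.centers:
            for alphas, coeffs in BASIS_SETS[self.basis.lower()]:
                a = np.asarray(alphas)
                d = np.asarray(coeffs) * (2 * a / np.pi) ** 0.75
                # normalize the contracted function
                ss = ((np.pi / np.add.outer(a, a)) ** 1.5 * np.outer(d, d)).sum()
                out.append((c, a, d / np.sqrt(ss)))
        return out

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(len(self.centers)):
            for j in range(i + 1, len(self.centers)):
                r = np.linalg.norm(self.centers[i] - self.centers[j])
                e += self.charges[i] * self.charges[j] / r
        return float(e)


def h2_molecule(r_angstrom: float, basis: str = "sto-3g") -> Molecule:
    r = r_angstrom * BOHR_PER_ANGSTROM
    centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    return Molecule(centers, np.ones(2), basis, f"H2/{basis} R={r_angstrom:g}A")


def h3_plus_linear(r_angstrom: float, basis: str = "sto-3g") -> Molecule:
    r = r_angstrom * BOHR_PER_ANGSTROM
    centers = np.array([[0.0, 0.0, -r], [0.0, 0.0, 0.0], [0.0, 0.0, r]])
    return Molecule(centers, np.ones(3), basis,
                    f"H3+/{basis} R={r_angstrom:g}A", charge=1)


def h4_square(side_angstrom: float, basis: str = "sto-3g") -> Molecule:
    a = side_angstrom * BOHR_PER_ANGSTROM
    centers = np.array([[0.0, 0.0, 0.0], [a, 0.0, 0.0],
                        [a, a, 0.0], [0.0, a, 0.0]])
    return Molecule(centers, np.ones(4), basis,
                    f"H4-square/{basis} a={side_angstrom:g}A")


# ---------------------------------------------------------------------------
# Gaussian integrals (s functions only)
# ---------------------------------------------------------------------------

def _boys0(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    m = t > 1e-12
    out[m] = 0.5 * np.sqrt(np.pi / t[m]) * erf(np.sqrt(t[m]))
    return out


def ao_integrals(mol: Molecule):
    """Overlap, kinetic, nuclear-attraction and (pq|rs) ERI matrices."""
    shells = mol.shells()
    nb = len(shells)
    S = np.zeros((nb, nb))
    T = np.zeros((nb, nb))
    V = np.zeros((nb, nb))
    for i, (Ai, ai, di) in enumerate(shells):
        for j, (Aj, aj, dj) in enumerate(shells):
            AB2 = float(np.dot(Ai - Aj, Ai - Aj))
            for a, da in zip(ai, di):
                for b, db in zip(aj, dj):
                    p = a + b
                    mu = a * b / p
                    pre = (np.pi / p) ** 1.5 * np.exp(-mu * AB2)
                    S[i, j] += da * db * pre
                    T[i, j] += da * db * mu * (3 - 2 * mu * AB2) * pre
                    P = (a * Ai + b * Aj) / p
                    for C, Z in zip(mol.centers, mol.charges):
                        PC2 = float(np.dot(P - C, P - C))
                        V[i, j] -= Z * da * db * 2 * np.pi / p * \
                            np.exp(-mu * AB2) * float(_boys0(np.array(p * PC2)))
    eri = np.zeros((nb, nb, nb, nb))
    for i, (Ai, ai, di) in enumerate(shells):
        for j, (Aj, aj, dj) in enumerate(shells):
            if j > i:
                continue
            AB2 = float(np.dot(Ai - Aj, Ai - Aj))
            for k, (Ak, ak, dk) in enumerate(shells):
                for l, (Al, al, dl) in enumerate(shells):
                    if l > k or (k, l) > (i, j):
                        continue
                    CD2 = float(np.dot(Ak - Al, Ak - Al))
                    val = 0.0
                    for a, da in zip(ai, di):
                        for b, db in zip(aj, dj):
                            p = a + b
                            P = (a * Ai + b * Aj) / p
                            for c, dc in zip(ak, dk):
                                for d, dd in zip(al, dl):
                                    q = c + d
                                    Q = (c * Ak + d * Al) / q
                                    PQ2 = float(np.dot(P - Q, P - Q))
                                    val += da * db * dc * dd * \
                                        2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q)) * \
                                        np.exp(-a * b / p * AB2 - c * d / q * CD2) * \
                                        float(_boys0(np.array(p * q / (p + q) * PQ2)))
                    for (x, y) in {(i, j), (j, i)}:
                        for (z, w) in {(k, l), (l, k)}:
                            eri[x, y, z, w] = val
                            eri[z, w, x, y] = val
    return S, T + V, eri


# ---------------------------------------------------------------------------
# Mean field
# ---------------------------------------------------------------------------

@dataclass
class RHFResult:
    energy: float                 # total, incl. nuclear repulsion
    mo_coeff: np.ndarray          # (nb, nb)
    mo_energy: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class UHFResult:
    energy: float
    mo_coeff_alpha: np.ndarray
    mo_coeff_beta: np.ndarray
    converged: bool
    spin_broken: bool


def _tiebreak_operator(mol: Molecule, S: np.ndarray) -> np.ndarray:
    """AO matrix of a fixed linear functional of position.

    Degenerate Fock eigenvectors are arbitrary mixtures within their
    eigenspace (point-group degeneracies of symmetric clusters); LAPACK's
    choice is implementation-dependent.  Re-diagonalizing this operator
    inside each degenerate cluster fixes the orbitals deterministically
    and aligns them with the coordinate axes (an anisotropic
    second-moment functional; first moments vanish by symmetry inside
    such clusters).  For s Gaussians
    <a|x^2|b> = S_ab (P_x^2 + 1/(2p)) with P the product-Gaussian center.
    """
    dirs = np.array([[1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    weights = np.array([1.0, 0.37, 0.11])
    shells = mol.shells()
    nb = len(shells)
    T = np.zeros((nb, nb))
    for i, (Ai, ai, di) in enumerate(shells):
        for j, (Aj, aj, dj) in enumerate(shells):
            AB2 = float(np.dot(Ai - Aj, Ai - Aj))
            for a, da in zip(ai, di):
                for b, db in zip(aj, dj):
                    p = a + b
                    P = (a * Ai + b * Aj) / p
                    s_ab = (np.pi / p) ** 1.5 * np.exp(-a * b / p * AB2)
                    for w, u_dir in zip(weights, dirs):
                        T[i, j] += w * da * db * s_ab * \
                            (float(np.dot(u_dir, P)) ** 2 + 1.0 / (2.0 * p))
    return T


def _resolve_degeneracies(eps: np.ndarray, C: np.ndarray,
                          T: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    out = C.copy()
    i = 0
    n = eps.size
    while i < n:
        j = i + 1
        while j < n and eps[j] - eps[i] < tol:
            j += 1
        if j - i > 1:
            block = out[:, i:j]
            sub = block.T @ T @ block
            _, v = np.linalg.eigh(0.5 * (sub + sub.T))
            block = block @ v
            out[:, i:j] = block
        # fix overall signs deterministically
        for k in range(i, j):
            col = out[:, k]
            lead = col[np.argmax(np.abs(col))]
            if lead < 0:
                out[:, k] = -col
        i = j
    return out


def run_rhf(mol: Molecule, max_iter: int = 200, tol: float = 1e-12,
            _ao=None) -> RHFResult:
    if mol.n_electrons % 2:
        raise ValueError("RHF requires an even electron count")
    nocc = mol.n_electrons // 2
    S, Hc, eri = _ao if _ao is not None else ao_integrals(mol)
    Tie = _tiebreak_operator(mol, S)
    F = Hc
    e_old, conv, it = 0.0, False, 0
    eps = C = None
    for it in range(1, max_iter + 1):
        eps, C = eigh(F, S)
        C = _resolve_degeneracies(eps, C, Tie)
        D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        J = np.einsum("pqrs,rs->pq", eri, D)
        K = np.einsum("prqs,rs->pq", eri, D)
        F = Hc + J - 0.5 * K
        e = 0.5 * np.sum(D * (Hc + F))
        if abs(e - e_old) < tol and it > 2:
            conv = True
            break
        e_old = e
    return RHFResult(float(e + mol.nuclear_repulsion()), C, eps, conv, it)


def _uhf_iterate(S, Hc, eri, Ca, Cb, na, nb_, max_iter=2000, tol=1e-13):
    e_old = 0.0
    for it in range(max_iter):
        Da = Ca[:, :na] @ Ca[:, :na].T
        Db = Cb[:, :nb_] @ Cb[:, :nb_].T
        Jt = np.einsum("pqrs,rs->pq", eri, Da + Db)
        Ka = np.einsum("prqs,rs->pq", eri, Da)
        Kb = np.einsum("prqs,rs->pq", eri, Db)
        Fa = Hc + Jt - Ka
        Fb = Hc + Jt - Kb
        e = 0.5 * np.sum((Da + Db) * Hc) + 0.5 * np.sum(Da * Fa) + 0.5 * np.sum(Db * Fb)
        if abs(e - e_old) < tol and it > 2:
            return e, Ca, Cb, True
        e_old = e
        _, Ca = eigh(Fa, S)
        _, Cb = eigh(Fb, S)
    return e, Ca, Cb, False


def run_uhf(mol: Molecule, n_alpha: int | None = None, n_beta: int | None = None,
            n_starts: int = 12, seed: int = 7, _ao=None) -> UHFResult:
    """Lowest self-consistent UHF solution over seeded random orbital starts.

    Relaxing many random orthogonal starts and keeping the minimum follows
    every internal instability downhill, so the returned determinant is
    the broken-symmetry minimum whenever the restricted solution is
    unstable.
    """
    ne = mol.n_electrons
    if n_alpha is None:
        n_alpha = (ne + 1) // 2
    if n_beta is None:
        n_beta = ne - n_alpha
    S, Hc, eri = _ao if _ao is not None else ao_integrals(mol)
    _, C0 = eigh(Hc, S)
    rng = np.random.default_rng(seed)
    nb = S.shape[0]
    best = None
    starts = [(C0, C0)]
    for _ in range(n_starts):
        Ra = np.linalg.qr(rng.standard_normal((nb, nb)))[0]
        Rb = np.linalg.qr(rng.standard_normal((nb, nb)))[0]
        starts.append((C0 @ Ra, C0 @ Rb))
    for Ca0, Cb0 in starts:
        e, Ca, Cb, conv = _uhf_iterate(S, Hc, eri, Ca0, Cb0, n_alpha, n_beta)
        if conv and (best is None or e < best[0]):
            best = (e, Ca, Cb)
    if best is None:
        raise RuntimeError("UHF failed to converge from any start")
    e, Ca, Cb = best
    Da = Ca[:, :n_alpha] @ Ca[:, :n_alpha].T
    Db = Cb[:, :n_beta] @ Cb[:, :n_beta].T
    broken = bool(np.max(np.abs(Da - Db)) > 1e-6)
    return UHFResult(float(e + mol.nuclear_repulsion()), Ca, Cb, True, broken)


# ---------------------------------------------------------------------------
# MO-basis active-space integrals
# ---------------------------------------------------------------------------

def active_space_integrals(mol: Molecule, mo_coeff: np.ndarray | None = None,
                           _ao=None) -> ActiveSpaceIntegrals:
    """Full-space MO integrals (chemists' notation) for a hydrogen cluster.

    With the default ``mo_coeff=None`` the RHF orbitals are used; the
    active space is the whole orbital space, so the core energy is just
    the nuclear repulsion.
    """
    ao = _ao if _ao is not None else ao_integrals(mol)
    S, Hc, eri = ao
    if mo_coeff is None:
        mo_coeff = run_rhf(mol, _ao=ao).mo_coeff
    C = mo_coeff
    h = C.T @ Hc @ C
    g = np.einsum("pi,qj,pqrs,rk,sl->ijkl", C, C, eri, C, C, optimize=True)
    ne = mol.n_electrons
    na = (ne + 1) // 2
    out = ActiveSpaceIntegrals(mol.nuclear_repulsion(), h, g, na, ne - na,
                               metadata={"system": mol.label, "basis": mol.basis})
    out.validate(1e-8)
    return out
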