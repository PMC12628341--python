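"""Variational optimization of uCJ energies.

The noiseless path minimizes the exact expectation of the Hamiltonian
restricted to the particle-number sector of the reference, using SLSQP
with central finite-difference gradients.  The shot-noise path minimizes
a sampled expectation (qubit-wise-commuting grouped measurement) with the
derivative-free Powell method.

Because every uCJ factor conserves particle number, the whole computation
lives in the sector of the reference determinant: the Hamiltonian and the
one-body generators are projected onto that sector once, and each energy
evaluation is two small matrix exponentials plus a diagonal Jastrow
phase.  Circuit-level simulation reproduces these states exactly (tested
separately); it is used on the shot-noise path where the measurement
model is the point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .ansatz import (UCJParameters, enumerate_j_terms,
                     n_parameters, unpack)
from .circuits import build_exact_ucj_circuit
from .integrals import (QubitHamiltonian, ReferenceDeterminant, sector_basis,
                        sector_matrix)
from .simulator import ShotPlan, SparseState, apply_circuit, sampled_expectation

__all__ = [
    "OptimizerSettings",
    "VQEResult",
    "ScanResult",
    "EnergyModel",
    "optimize",
    "optimize_sampled",
    "perfect_pairing_warmstart",
    "continuation_scan",
    "correlation_fraction",
]


@dataclass(frozen=True)
class OptimizerSettings:
    """Convergence controls for the classical minimization."""

    ftol: float = 1e-12            # SLSQP objective tolerance (hartree)
    gtol: float = 1e-6             # target max gradient component
    fd_step: float = 1e-6          # central-difference step
    max_iter: int = 3000
    n_starts: int = 8              # multi-start count (incl. zero init)
    perturbation: float = 0.1      # random-start scale


@dataclass
class VQEResult:
    energy: float
    params: UCJParameters
    x: np.ndarray
    converged: bool
    n_evals: int
    history: List[Tuple[int, float]]
    seed: int


@dataclass
class ScanResult:
    branch: str                    # association | dissociation | multistart
    points: List[Tuple[str, float, VQEResult]]


def correlation_fraction(E: float, E_ref: float, E_exact: float) -> float:
    """100 * (E_ref - E) / (E_ref - E_exact), the recovered correlation %."""
    denom = E_ref - E_exact
    if abs(denom) < 1e-12:
        raise ValueError("degenerate correlation denominator")
    return 100.0 * (E_ref - E) / denom


# ---------------------------------------------------------------------------
# Sector-projected energy evaluation
# ---------------------------------------------------------------------------

class EnergyModel:
    """Dense sector-restricted uCJ energy as a function of packed reals."""

    def __init__(self, H: QubitHamiltonian, n_alpha: int, n_beta: int,
                 variant: str, k: int = 1, screen: bool = True,
                 ref: Optional[ReferenceDeterminant] = None):
        self.M = H.n_qubits // 2
        self.n_alpha, self.n_beta = n_alpha, n_beta
        self.variant, self.k, self.screen = variant, k, screen
        self.basis = sector_basis(self.M, n_alpha, n_beta)
        self._index = {b: i for i, b in enumerate(self.basis)}
        self.hmat = sector_matrix(H, self.basis)
        if ref is None:
            ref = ReferenceDeterminant.aufbau(n_alpha, n_beta)
        self.ref = ref
        rbits = ref.bitstring(self.M)
        vec = np.zeros(len(self.basis), complex)
        vec[self._index[rbits]] = 1.0
        self.ref_vec = vec
        self._hops = self._build_hops()
        self._occ = np.array([[b[i] == "1" for b in self.basis]
                              for i in range(2 * self.M)], dtype=float)
        self.j_terms = enumerate_j_terms(self.M, n_alpha, n_beta, screen).entries
        self.n_params = n_parameters(variant, self.M, n_alpha, n_beta, k, screen)
        self.n_evals = 0

    def _build_hops(self) -> Dict[Tuple[int, int], np.ndarray]:
        """Sector matrices of a+_p a_q for same-spin spin-orbital pairs."""
        M = self.M
        dim = len(self.basis)
        out: Dict[Tuple[int, int], np.ndarray] = {}
        for blk in range(2):
            off = blk * M
            for p in range(M):
                for q in range(M):
                    if p == q:
                        continue
                    mat = np.zeros((dim, dim))
                    for i, bits in enumerate(self.basis):
                        if bits[off + q] != "1" or bits[off + p] != "0":
                            continue
                        lst = list(bits)
                        sign = (-1) ** lst[:off + q].count("1")
                        lst[off + q] = "0"
                        sign *= (-1) ** lst[:off + p].count("1")
                        lst[off + p] = "1"
                        j = self._index["".join(lst)]
                        mat[j, i] = sign
                    out[(off + p, off + q)] = mat
        return out

    # -- state and energy ---------------------------------------------
    def state_vector(self, x: np.ndarray) -> np.ndarray:
        params = unpack(x, self.variant, self.M, self.n_alpha, self.n_beta,
                        self.k, self.screen)
        v = self.ref_vec
        dim = len(self.basis)
        for rep in params.replicas:
            kop = np.zeros((dim, dim), complex)
            for blk, K in ((0, rep.k_alpha), (1, rep.k_beta)):
                off = blk * self.M
                for p in range(self.M):
                    for q in range(self.M):
                        if p != q and K[p, q] != 0:
                            kop = kop + K[p, q] * self._hops[(off + p, off + q)]
            jdiag = np.zeros(dim)
            for (i, j) in self.j_terms:
                r = rep.j_real[i, j]
                if r != 0.0:
                    jdiag = jdiag + (2.0 * r) * self._occ[i] * self._occ[j]
            ek = expm(kop)
            v = ek @ (np.exp(1j * jdiag) * (ek.conj().T @ v))
        return v

    def energy(self, x: np.ndarray) -> float:
        self.n_evals += 1
        v = self.state_vector(x)
        return float(np.real(v.conj() @ (self.hmat @ v)))

    def state(self, x: np.ndarray) -> SparseState:
        v = self.state_vector(x)
        amps = {b: v[i] for i, b in enumerate(self.basis) if abs(v[i]) > 1e-14}
        return SparseState(2 * self.M, amps)

    def parameters(self, x: np.ndarray) -> UCJParameters:
        return unpack(x, self.variant, self.M, self.n_alpha, self.n_beta,
                      self.k, self.screen)

    # -- coordinate geometry (for staged optimization) ----------------
    def coordinate_sites(self) -> List[Tuple[int, int]]:
        """Spatial-orbital pair touched by each packed coordinate."""
        tri = [(p, q) for p in range(self.M) for q in range(p + 1, self.M)]
        sites: List[Tuple[int, int]] = []
        for _ in range(self.k):
            for _blk in range(2):
                reps = 2 if self.variant == "g" else 1
                for _ in range(reps):
                    sites.extend(tri)
            sites.extend((min(i % self.M, j % self.M),
                          max(i % self.M, j % self.M))
                         for (i, j) in self.j_terms)
        return sites


def _central_diff(f: Callable[[np.ndarray], float], step: float):
    def jac(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = step
            g[i] = (f(x + e) - f(x - e)) / (2 * step)
        return g
    return jac


def _minimize_slsqp(model: EnergyModel, x0: np.ndarray,
                    settings: OptimizerSettings,
                    mask: Optional[np.ndarray] = None):
    """SLSQP descent, optionally over a frozen-coordinate subspace."""
    if mask is None:
        fun = model.energy
        x_full = None
    else:
        x_full = x0.copy()

        def fun(v):
            x = x_full.copy()
            x[mask] = v
            return model.energy(x)
        x0 = x0[mask]
    jac = _central_diff(fun, settings.fd_step)
    res = minimize(fun, x0, method="SLSQP", jac=jac,
                   options={"maxiter": settings.max_iter,
                            "ftol": settings.ftol})
    if mask is None:
        return res.fun, res.x, res.success
    x = x_full.copy()
    x[mask] = res.x
    return res.fun, x, res.success


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def optimize(H: QubitHamiltonian, n_alpha: int, n_beta: int, variant: str,
             init: Optional[np.ndarray] = None, seed: int = 0,
             settings: OptimizerSettings = OptimizerSettings(),
             k: int = 1, screen: bool = True,
             ref: Optional[ReferenceDeterminant] = None) -> VQEResult:
    """Multi-start SLSQP minimization of the exact uCJ energy.

    Starts: the zero vector (the reference determinant itself), seeded
    random perturbations, and optionally a supplied warm start; the
    lowest converged result is returned.
    """
    model = EnergyModel(H, n_alpha, n_beta, variant, k, screen, ref)
    rng = np.random.default_rng(seed)
    starts: List[np.ndarray] = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    starts.append(np.zeros(model.n_params))
    while len(starts) < settings.n_starts + (init is not None):
        starts.append(rng.normal(scale=settings.perturbation,
                                 size=model.n_params))
    history: List[Tuple[int, float]] = []
    best: Optional[Tuple[float, np.ndarray, bool]] = None
    for x0 in starts:
        e, x, ok = _minimize_slsqp(model, x0, settings)
        history.append((model.n_evals, e))
        if best is None or e < best[0] - 1e-14:
            best = (e, x, ok)
    e, x, ok = best
    return VQEResult(float(e), model.parameters(x), x, bool(ok),
                     model.n_evals, history, seed)


def perfect_pairing_warmstart(H: QubitHamiltonian, n_alpha: int, n_beta: int,
                              variant: str, seed: int = 0,
                              settings: OptimizerSettings = OptimizerSettings(),
                              k: int = 1, screen: bool = True) -> VQEResult:
    """Staged optimization: perfect-pairing subspace first, then full.

    Stage 1 frees only coordinates coupling each occupied orbital i to its
    antibonding partner n_occ + (n_occ - 1 - i) (searched with the usual
    multi-start); subsequent stages enlarge the connected orbital set one
    orbital at a time, warm-starting from the previous stage.
    """
    model = EnergyModel(H, n_alpha, n_beta, variant, k, screen)
    M = model.M
    nocc = max(n_alpha, n_beta)
    pairs = [frozenset((i, nocc + (nocc - 1 - i))) for i in range(nocc)
             if nocc + (nocc - 1 - i) < M]
    stages: List[List[frozenset]] = [pairs]
    for last in range(nocc + len(pairs), M + 1):
        stages.append([frozenset(range(last))])
    sites = model.coordinate_sites()
    rng = np.random.default_rng(seed)
    x = np.zeros(model.n_params)
    history: List[Tuple[int, float]] = []
    e = model.energy(x)
    stage_energies = [e]
    for si, groups in enumerate(stages):
        mask = np.array([any(p in g and q in g for g in groups)
                         for (p, q) in sites])
        if not mask.any():
            continue
        if si == 0:
            starts = [x.copy()]
            for _ in range(settings.n_starts - 1):
                xs = x.copy()
                xs[mask] = rng.normal(scale=settings.perturbation,
                                      size=int(mask.sum()))
                starts.append(xs)
        else:
            starts = [x.copy()]
            for _ in range(2):
                xs = x.copy()
                xs[mask] += rng.normal(scale=0.02, size=int(mask.sum()))
                starts.append(xs)
        best = None
        for x0 in starts:
            ee, xx, ok = _minimize_slsqp(model, x0, settings, mask)
            if best is None or ee < best[0] - 1e-14:
                best = (ee, xx, ok)
        e, x, ok = best
        history.append((model.n_evals, e))
        stage_energies.append(e)
    return VQEResult(float(e), model.parameters(x), x, True,
                     model.n_evals, history, seed)


def optimize_sampled(H: QubitHamiltonian, n_alpha: int, n_beta: int,
                     variant: str, plan: ShotPlan,
                     init: Optional[np.ndarray] = None, seed: int = 0,
                     k: int = 1, screen: bool = True,
                     max_iter: int = 400) -> VQEResult:
    """Powell minimization of the shot-sampled energy (noisy objective).

    Each objective evaluation prepares the uCJ state by simulating the
    exact circuit and samples every qubit-wise-commuting group with
    ``plan.shots_per_group`` shots and a fresh stream drawn from the
    master seed.
    """
    M = H.n_qubits // 2
    ref = ReferenceDeterminant.aufbau(n_alpha, n_beta)
    rng = np.random.default_rng(seed)
    n_par = n_parameters(variant, M, n_alpha, n_beta, k, screen)
    vac = SparseState.vacuum(H.n_qubits)
    evals = [0]

    def objective(x: np.ndarray) -> float:
        evals[0] += 1
        params = unpack(x, variant, M, n_alpha, n_beta, k, screen)
        circ = build_exact_ucj_circuit(params, ref)
        state = apply_circuit(circ, vac)
        sub = int(rng.integers(0, 2 ** 31 - 1))
        mean, _ = sampled_expectation(
            H.terms, state, ShotPlan(plan.shots_per_group, sub, 1))
        return mean

    x0 = np.asarray(init, float) if init is not None \
        else rng.normal(scale=0.1, size=n_par)
    res = minimize(objective, x0, method="Powell",
                   options={"maxiter": max_iter, "xtol": 1e-3, "ftol": 1e-5})
    params = unpack(res.x, variant, M, n_alpha, n_beta, k, screen)
    return VQEResult(float(res.fun), params, np.asarray(res.x),
                     bool(res.success), evals[0], [], seed)


def continuation_scan(geometries: Sequence[Tuple[str, float, QubitHamiltonian]],
                      n_alpha: int, n_beta: int, variant: str,
                      direction: str = "dissociation", seed: int = 0,
                      settings: OptimizerSettings = OptimizerSettings(),
                      k: int = 1, screen: bool = True) -> ScanResult:
    """Warm-started chain of optimizations along a geometry grid.

    ``dissociation`` walks the grid in increasing distance, ``association``
    in decreasing distance; each point is initialized from the previous
    optimum (the first point uses the full multi-start).
    """
    if direction not in ("association", "dissociation", "multistart"):
        raise ValueError(f"unknown direction {direction!r}")
    pts = sorted(geometries, key=lambda t: t[1],
                 reverse=(direction == "association"))
    if any(a[1] == b[1] for a, b in zip(pts, pts[1:])):
        raise ValueError("scan distances must be distinct")
    results: List[Tuple[str, float, VQEResult]] = []
    prev: Optional[np.ndarray] = None
    for label, dist, H in pts:
        if direction == "multistart" or prev is None:
            res = optimize(H, n_alpha, n_beta, variant, seed=seed,
                           settings=settings, k=k, screen=screen)
        else:
            one = OptimizerSettings(settings.ftol, settings.gtol,
                                    settings.fd_step, settings.max_iter,
                                    n_starts=1,
                                    perturbation=settings.perturbation)
            res = optimize(H, n_alpha, n_beta, variant, init=prev, seed=seed,
                           settings=one, k=k, screen=screen)
        prev = res.x
        results.append((label, dist, res))
    return ScanResult(direction, results)
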