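# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `ucjkit`.

## Hamiltonians and conventions

Active-space integrals are held in chemists' notation: a Hermitian
one-body matrix `h_pq` and a real two-body tensor `(pq|rs)` with full
8-fold permutation symmetry, plus a scalar core energy, all in hartree.
The second-quantized Hamiltonian is

    H = E_core + Σ_{pq,σ} h_pq a†_pσ a_qσ
               + ½ Σ_{pqrs,στ} (pq|rs) a†_pσ a†_rτ a_sτ a_qσ .

Spin orbitals map to qubits in *spin-blocked* order (α spatial orbitals
on qubits 0..M−1, β on M..2M−1), so same-spin orbital rotations act on
adjacent qubits and compile without Jordan–Wigner Z strings. The JW
convention is |0⟩ = unoccupied, n̂ = (I − Z)/2. FCIDUMP files use the
Molpro dialect (namelist header, 1-based indices, canonical unique
entries, real orbitals).

## The built-in mean-field backend

All benchmark molecules are hydrogen clusters, so the package carries a
compact ab initio backend for s-type contracted Gaussians: closed-form
overlap/kinetic/nuclear/ERI integrals through the zeroth Boys function,
RHF by Roothaan iteration from the core-Hamiltonian guess, and UHF by
relaxing a seeded batch of random orthogonal orbital starts and keeping
the lowest self-consistent solution (a global form of stability
following — with 12 starts the broken-symmetry minimum of every system
tested here is found by all starts). STO-3G and 6-31G hydrogen
contractions are built in; the unit conversion is 1 bohr =
0.529177210903 Å.

Degenerate Fock eigenvectors are fixed deterministically: inside every
degenerate eigenvalue cluster the orbitals are re-diagonalized against
an anisotropic second-moment operator whose principal axes lie along the
(1,1,0)/(1,−1,0)/(0,0,1) directions. Point-group degeneracies otherwise
leave the SCF fixed point at the mercy of the LAPACK eigenvector choice;
square H₄ is the canonical case — its degenerate HOMO pair supports two
distinct closed-shell SCF solutions (a diagonal-channel stationary
solution at −1.7109527 Ha and a lower edge-localized one at
−1.7825512 Ha for side 1.1 Å) and this convention selects the
diagonal channel, the reference used by the benchmark fractions. The
choice is a fixed convention of the package; both solutions are genuine
SCF fixed points.

## uCJ parameterization

Each replica holds independent α and β K blocks and one real symmetric
zero-diagonal matrix R with J = iR over spin orbitals. Free coordinates:
C(M,2) reals per K block for Re-uCJ (real antisymmetric) and Im-uCJ
(i × real symmetric; the imaginary *diagonal* is excluded because it
only generates orbital phases absorbable into J and a global phase),
2·C(M,2) for g-uCJ, plus one real per surviving Jastrow pair.

Jastrow screening is occupancy-based: same-spin pairs are dropped for
any spin sector holding ≤ 1 electron, where n̂_p n̂_q annihilates every
sector state. For a 2-electron singlet this leaves the M² α–β pairs; for
(2α, 2β) in 4 orbitals nothing is screened (28 pairs).

## Exact circuit synthesis

`exp(K)` per spin block is factored by a QR-like column-major sweep of
*adjacent* generalized Givens rotations r(θ, φ) with block
[[cos θ, −e^{iφ} sin θ], [e^{−iφ} sin θ, cos θ]], leaving a diagonal
phase layer: u = r₁† ... r_L† diag(e^{iφ_p}), L ≤ C(M,2). Correctness is
defined (and tested) by reconstruction to ‖Δ‖ < 1e−10; degenerate pivots
(|pivot| < 1e−12) take θ = π/2, φ = 0. The two-qubit GIVENS2 gate is
*defined* as the matrix exponential of the corresponding fermionic
generator on adjacent JW modes, which fixes every sign: it mixes the
{01, 10} subspace and leaves 00 and 11 invariant. `e^Ĵ` factorizes
exactly into pair phases e^{iλ n̂_i n̂_j} (ZZ_PHASE gates).

Resource accounting compiles GIVENS2 to 3 CNOTs, ZZ_PHASE to 2 CNOTs and
1 R_z, and a weight-w Pauli exponential (Trotter comparator circuits) to
2(w−1) CNOTs; T-gate estimates use 1.15·log₂(1/ε_syn) + 9.2 per R_z-type
rotation (3 per GIVENS2). With these rules the exact k=1 circuit costs
12·C(M,2) + 2·|J| CNOTs, identically for all three variants. Trotterized
uCJ and UCCSD circuits are built for structural comparison only; their
counts depend on term-cancellation conventions that are not fixed here.

## Simulation and measurement model

States are sparse occupation-basis maps; every uCJ factor conserves
particle number, so supports stay inside one sector. The variational
driver therefore projects the Hamiltonian and the one-body generators
onto the reference sector once and evaluates each energy as two small
matrix exponentials plus a diagonal phase — the circuit path reproduces
these states to fidelity 1 − 1e−10 (tested over hundreds of random
parameter draws) and is used where the measurement model matters.

Sampled expectations partition the Hamiltonian into qubit-wise-commuting
groups (greedy first-fit over terms in descending |coefficient|), rotate
the state into each group's shared single-qubit basis, and draw
multinomial shot counts from the exact outcome distribution; the
estimator is unbiased and seeded. No gate or readout noise is modeled.
The reported stderr combines per-group multinomial variances.

## Optimization protocol

Noiseless optimization is SLSQP with central finite-difference gradients
(step 1e−6, objective tolerance 1e−12 Ha — far below chemical accuracy).
The default multi-start uses 8 starts: the zero vector (the reference
determinant, which is a stationary point) plus seeded Gaussian
perturbations of scale 0.1, reporting the lowest minimum. For ≥ 8-qubit
problems a perfect-pairing staged warm start is provided: stage 1 frees
only coordinates coupling each occupied orbital i to its antibonding
partner n_occ + (n_occ−1−i) (multi-started), then the connected orbital
set grows one orbital at a time, each stage warm-started from the last.
Dissociation/association scans warm-start each geometry from the
previous optimum along the grid; the two branches genuinely differ for
Re-uCJ, which has multiple local minima, and the package exposes both.

Shot-noise optimization uses Powell on the sampled objective (a fresh
measurement stream per evaluation). Its converged energies sit a noise
floor (~the per-evaluation sampling σ) above the true minimum; the
shot-sampled benchmark therefore evaluates noiselessly optimized
parameters under measurement sampling, with `optimize_sampled` available
for fully noisy optimization studies.

Reported correlation fractions are 100·(E_RHF − E)/(E_RHF − E_FCI) with
both references computed in-package (sector diagonalization for FCI).

## Spin analysis

Ŝ² = Ŝ₋Ŝ₊ + Ŝ_z(Ŝ_z + 1) is built once per M as a Pauli sum and cached.
The explicit CSF basis covers the (2e, 2 orbital) Ms = 0 sector: the two
closed-shell gerade singlets, the ungerade open-shell singlet and the
Ms = 0 triplet, the last two fixed by diagonalizing Ŝ² in the open-shell
subspace with a deterministic sign convention. Larger sectors report
⟨S²⟩ and raw determinant weights without spin adaptation.

## Synthetic fixtures

`make_synthetic_integrals` draws a one-body matrix with well-separated
sorted diagonal levels (scale ~1 Ha) plus small symmetric off-diagonal
coupling (0.05) and an 8-fold-symmetrized random two-body tensor (0.1),
giving generically non-degenerate mean fields. These fixtures exercise
every code path without any chemistry backend, but they do not emulate
the near-degeneracies, point-group symmetries, or size-consistency
structure of real molecules — tests passing on them validate operator
algebra and optimization mechanics, not chemical accuracy; the
hydrogen-cluster backend covers that part.

## Problem sizes and limitations

Everything is desk scale by design: dense sector diagonalization
(sectors ≤ ~10⁴), dense-string Pauli words (n ≤ 16 qubits), and k = 1
numerics (k ≥ 1 is supported by the data model and round-trips through
pack/unpack, but only k = 1 is exercised numerically). The backend
handles hydrogen-like s-shell atoms only — no heavier elements, p/d
shells, or frozen-core bookkeeping; non-hydrogen benchmark systems enter
only through their (M, sector) gate-count signatures or an external
FCIDUMP. Optimized energies for multi-electron systems depend on the
multi-start/staging protocol since the uCJ energy landscape has multiple
local minima; the protocol above is deterministic given its seed, and
scan branches make the local-minimum structure explicit rather than
hiding it.
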