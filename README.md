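# ucjkit

Unitary cluster Jastrow (uCJ) ansätze for molecular electronic structure
on near-term quantum hardware: exact (Trotter-free) circuit synthesis,
variational optimization, resource accounting, and wavefunction analysis,
at desk scale.

## The problem and the model

Variational quantum eigensolvers need ansätze that are expressive enough
to capture electron correlation yet shallow enough for noisy devices.
The *k*-fold unitary cluster Jastrow ansatz replaces the quartic-scaling
two-body cluster operators of UCCSD with products of one-body orbital
rotations and a diagonal density–density correlator:

```
|Ψ⟩ = ∏ᵢ e^{K̂ᵢ} e^{Ĵᵢ} e^{−K̂ᵢ} |HF⟩,     i = 1..k
K̂ = Σ_{pq,σ} K_pq a†_{pσ} a_{qσ}          (K anti-Hermitian, same-spin)
Ĵ = Σ_{p<q}  J_pq n̂_p n̂_q                 (J purely imaginary, symmetric)
```

Three variants restrict the orbital-rotation generator **K**:

| variant | restriction on K | free K reals (per spin block) |
|---------|------------------|-------------------------------|
| Re-uCJ  | real antisymmetric | C(M,2) |
| Im-uCJ  | purely imaginary (i × real symmetric) | C(M,2) |
| g-uCJ   | general complex anti-Hermitian | 2·C(M,2) |

Under the Jordan–Wigner mapping `e^Ĵ` is a commuting product of `Z`/`ZZ`
phase factors (exact by construction), and `e^{±K̂}` is synthesized
*exactly* — no Trotterization — by factoring `u = exp(K)` into at most
C(M,2) generalized complex Givens rotations on adjacent modes plus a
phase layer. Each rotation is a two-qubit gate (3 CNOTs), each Jastrow
pair term costs 2 CNOTs, giving the closed-form circuit cost
`k·(12·C(M,2) + 2·|J|)` CNOTs with `|J|` the number of screened Jastrow
pair terms.

The package covers, for hydrogen-cluster benchmarks (H₂, linear H₃⁺,
square H₄ in STO-3G/6-31G, with a built-in s-Gaussian RHF/UHF backend):

* FCIDUMP read/write and synthetic-integral fixtures,
* JW qubit Hamiltonians and sector-exact (FCI) diagonalization,
* exact uCJ circuits, single-Trotter-step comparators, CNOT and T-gate
  accounting,
* sparse statevector simulation, qubit-wise-commuting (QWC) measurement
  grouping and shot-noise sampling,
* SLSQP/Powell variational drivers with multi-start, perfect-pairing
  staged warm starts, and warm-started dissociation/association scans,
* spin-adapted configuration-state-function (CSF) decomposition and ⟨S²⟩.

## Worked example

Optimize the Im-uCJ ansatz for stretched H₂ (STO-3G, R = 1.7 Å) and
analyze the resulting wavefunction:

```bash
$ ucjkit optimize --system h2-sto3g --distance 1.7 --variant im --seed 0 --out im.json
H2/sto-3g R=1.7A im-uCJ E = -0.9645562 Ha (94.13% correlation)

$ ucjkit csf --distance 1.7 --variant im --out csf.csv
$ cat csf.csv
distance_angstrom,label,weight,s_squared
1.7,hf_singlet_g,0.75862957,0.19554472
1.7,double_singlet_g,0.14359807,0.19554472
1.7,open_singlet_u,0.00000000,0.19554472
1.7,triplet_ms0_u,0.09777236,0.19554472
```

The optimized Im-uCJ energy (−0.9645562 Ha) recovers 94.1% of the
correlation energy between RHF (−0.8543376 Ha) and FCI (−0.9714267 Ha).
The CSF decomposition shows how it does so: besides the two gerade
singlets that span the exact ground state, the state borrows 9.8% weight
from the Ms=0 triplet — spin contamination (⟨S²⟩ = 0.196) traded for
energy, while the ungerade open-shell singlet stays exactly absent.
Running the same command with `--variant g` returns the FCI energy to
seven decimals with zero triplet weight: the generalized rotation makes
the two-electron ansatz exact.

Sampling the optimized state with 10 000 shots per QWC group over 20
trials emulates device-style measurement:

```bash
$ ucjkit sample --distance 1.7 --variant im --shots 10000 --trials 20 --seed 1 --out sample.csv
H2/sto-3g R=1.7A im-uCJ sampled: mean -0.964337 +- 0.000428 Ha (exact -0.964556)
```

Gate counts for the benchmark systems (`ucjkit counts`) confirm that all
three variants compile to identical exact-circuit CNOT counts: 20
(H₂/STO-3G), 54 (H₃⁺/STO-3G), 104 (H₂/6-31G), 128 (H₄/STO-3G).

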