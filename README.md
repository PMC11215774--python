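# csfrohf

Self-consistent field wave functions for **arbitrarily spin-coupled
configuration state functions** (CSF-ROHF): given any genealogical coupling
pattern of unpaired electrons — `+-`, `++--`, `+-+-+`, … — the package derives
the restricted open-shell Hartree–Fock vector-coupling coefficients for that
CSF, solves the resulting multi-open-shell SCF problem, and validates every
step against a dense determinant-CI oracle.

This is the mean-field machinery needed for polymetallic open-shell systems
(exchange-coupled transition-metal chains, iron–sulfur clusters, metal–radical
complexes): the wave function stays a proper spin eigenfunction for *any*
ferro- or antiferromagnetic coupling topology, not just the high-spin case,
at SCF cost — one Fock matrix per open shell.

## The method

A CSF over N singly occupied orbitals (SOMOs) is encoded by a branching
diagram path: signs `±` giving intermediate spins `S_k = S_{k−1} ± 1/2`,
`S_0 = 0`, `S_k ≥ 0`. Maximal runs of consecutive parallel couplings define
the open shells. The ROHF energy in the Edwards–Zerner shell-pair form is

    E = Σ_I 2 f_I tr(h D^I) + Σ_IJ f_I f_J [2 a^IJ tr(J[D^J] D^I) − b^IJ tr(K[D^J] D^I)]

with per-orbital occupations f = 1 (closed shell) and f = 1/2 (every open
shell, n^I = 1). Matching this term by term against the exact CSF expectation
value of the Hamiltonian gives, for unit occupations,

    a^IJ = 1,      b^IJ = 2 − 2 ⟨Φ| E_u^t E_t^u |Φ⟩,    t ∈ I, u ∈ J,

where `E_u^t = Σ_σ a†(t,σ) a(u,σ)` and the matrix element is the same for
every SOMO pair spanning a given shell pair (asserted, not assumed). The
element is evaluated *directly in the spin-coupling basis* — through the
Dirac identity `E_u^t E_t^u = 1 − P_tu` and the Young orthogonal
representation of the spin transposition `P_tu` on branching-diagram paths —
with the brute-force Slater-determinant expansion kept as an independent
oracle. For two SOMOs this yields the familiar open-singlet values
(`⟨EE⟩ = 2`, `b = −2`) and reduces to Roothaan's high-spin ROHF
(`a = 1, b = 2`) when a single shell remains.

Per shell, the Fock operator uses the special densities
`A^I = Σ_J α^IJ D^J`, `B^I = Σ_J β^IJ D^J` (α^IJ = n^J a^IJ,
β^IJ = n^J b^IJ / 2):

    F^I = h + J[A^I] − K[B^I],        dE/dD^I = 2 f_I F^I .

The SCF iterates densities → shell Fock matrices → a unified effective Fock
matrix (inter-space blocks are the orbital-rotation gradients) with DIIS,
maximum-overlap shell tracking for non-Aufbau couplings, and a trust-region
descent polish over inter-space rotations (see `docs/methods.md`).

A dense determinant CI (`csfrohf.detci`) in small active spaces provides
ground/excited states, spin-purity checks, and CSF-weight analysis — the
desk-scale stand-in for a selected-CI post-SCF step.

## Worked example

Coupling table for the two-shell antiferromagnetic CSF `++--`:

```
$ csfrohf coupling-table "++--"
# elements <E_u^t E_t^u>
0     1.5
1.5   0
# b
2    -1
-1    2
```

The cross-shell coupling element 1.5 gives `b = 2 − 2·1.5 = −1`; within a
shell the parallel-coupled value is `b = 2`.

Antiferromagnetic H4 chain (2.0 bohr spacing, minimal basis), alternating
(sublattice) shell assignment — the spins on sites {0,2} couple up, those on
{1,3} down:

```
$ csfrohf fixture h4 --out h4.fcidump
$ cat run.yaml
system:
  fcidump: h4.fcidump
pattern: '++--'
shells: [[0, 2], [1, 3]]
solver: {guess: lowdin, g_tol: 1.0e-8}
ci: {roots: 2, m: 0, weights: '++--,+-+-'}
output: demo_h4
$ csfrohf run --config run.yaml
E = -1.2817107668 Eh  converged=True (108 iterations)
```

The report (`demo_h4/report.json`) contains

```
energy_hartree          -1.2817107668181094     # single-CSF ROHF
ci_eigenvalues_hartree  [-2.1510071405, -1.9461037526]
ci_weights              {"++--": 0.3815, "+-+-": 0.0332}
```

The full-CI singlet (−2.151 Eh) lies well below the single neutral CSF: the
missing "ionic" configurations (an electron hopping between sublattices) are
what stabilize the antiferromagnetic state. Yet the CI ground state at the
CSF-ROHF orbitals is still *dominated* by the neutral `++--` CSF (weight
0.38, larger than any ionic configuration) — the mechanism of
antiferromagnetic coupling in miniature.

As a Python library:

```python
from csfrohf import (parse_pattern, vector_coupling_coefficients,
                     hydrogen_chain, ShellConfiguration, scf_solve, SCFOptions)
vct = vector_coupling_coefficients(parse_pattern("++-"))
print(vct.b)            # [[ 2. -1.], [-1.  2.]]
ints = hydrogen_chain(3, 2.0, "dz")
cfg = ShellConfiguration.from_pattern(vct, n_closed=0, n_basis=ints.n_basis)
state = scf_solve(ints, cfg, vct, SCFOptions(guess="lowdin"))
print(state.energy, state.converged)
```

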