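# Methods

## Model

The package solves the restricted open-shell Hartree–Fock problem for a
single configuration state function (CSF) with an arbitrary spin coupling of
its unpaired electrons. The wave function is a genealogically coupled spin
eigenfunction: electrons are added one at a time, each coupling its spin 1/2
up (`+`) or down (`-`) to the running total, so a CSF is labelled by a path
`S_0 = 0, S_k = S_{k−1} ± 1/2 ≥ 0` on the branching diagram. Every SOMO
carries occupation exactly 1 (no configuration averaging); the closed shell
is doubly occupied.

Key assumption inherited from the energy expression: the two-electron
interaction between open shells enters only through shell-pairwise Coulomb
and exchange weights (the vector-coupling coefficients a^IJ, b^IJ). That this
is exact for a genealogical CSF — i.e. that `⟨Φ|E_u^t E_t^u|Φ⟩` is constant
over all SOMO pairs spanning a fixed pair of shells, where a shell is a
maximal run of consecutive parallel couplings — is a theorem the code
*asserts* numerically every time a coupling table is built, rather than
assuming it.

## Energy and Fock conventions

With per-orbital occupation fractions f (1 closed, 1/2 open, 0 virtual) and
shell densities `D^I` the energy is

    E = Σ_I 2 f_I tr(h D^I)
      + Σ_IJ f_I f_J [ 2 a^IJ tr(J[D^J] D^I) − b^IJ tr(K[D^J] D^I) ] + E_nuc.

Matching against the second-quantized CSF expectation value gives, for unit
SOMO occupations, `a^IJ = 1` for every shell pair (each determinant of the
CSF has sharp occupations, so Coulomb terms carry no spin information) and

    b^IJ = 2 − 2 ⟨Φ| E_u^t E_t^u |Φ⟩        (I ≠ J, t ∈ I, u ∈ J),

with closed-shell couplings `a = b = 1` and the within-shell diagonal
`a^II = 1, b^II = 2` — the value the same formula produces for a
parallel-coupled pair (`⟨EE⟩ = 0`), chosen so that the diagonal term
`(2a − b) J_pp` cancels self-interaction exactly and a single shell reduces
to Roothaan's high-spin ROHF. An equivalent diagnostic identity,
`b^IJ = 1 + 4⟨S_t·S_u⟩`, is exercised in the tests as a second oracle.

The shell Fock operators follow the special-density formulation

    A^I = Σ_J α^IJ D^J,  B^I = Σ_J β^IJ D^J,  F^I = h + J[A^I] − K[B^I],

with `α^IJ = n^J a^IJ` and `β^IJ = (n^J/2) b^IJ` (n = 2 closed, 1 open).
These definitions make `F^I` exactly `dE/dD^I / (2 f_I)`, which is what the
orbital-rotation gradient and the finite-difference tests check. One Fock
matrix is built per shell, closed shell included.

## Evaluating the coupling matrix element

Production path (no determinant expansion): for two singly occupied orbitals
the Dirac identity gives `E_u^t E_t^u = 1 − P_tu` with `P_tu` the spin
transposition. `⟨P_tu⟩` is evaluated in the branching-path basis using the
Young orthogonal representation of the symmetric group: an adjacent
transposition (k, k+1) touches only the intermediate spin S_k; with
ρ = 2 S_{k−1} + 1 a parallel-coupled step pair is invariant (+1), while the
up–down/down–up pair mixes with diagonal ∓1/ρ and off-diagonal
√(1 − 1/ρ²). A general (t, u) is the standard product of adjacent
transpositions, restricted to the (small) set of sub-paths with pinned
endpoints. The result is independent of the spin projection by construction.

Oracle path: the CSF is expanded in Slater determinants by sequential
Clebsch–Gordan coupling along the path (Condon–Shortley phases, exact
rational arithmetic for the squared coefficients, floats only at the
interface), and `‖E_t^u|Φ⟩‖²` is computed with full fermionic phases in a
bitmask determinant algebra. The two routes agree to 1e−11 for every valid
pattern with N ≤ 8 in the test suite; the expansion itself is verified
against an independent angular-momentum library on small patterns.

Determinant phase convention throughout: orbitals ascending, all alpha
creation operators before all beta; CSF determinants are built by applying
creation operators in genealogical order and tracking signs against that
canonical order.

## SCF algorithm

Iteration: densities → shell Fock matrices → unified effective Fock R in the
current MO basis → DIIS extrapolation (error = the orbital-rotation
gradient, Löwdin-orthonormal AO frame) → diagonalization → assignment of the
new orbitals to spaces. R carries each space's own `F^I` on the diagonal
blocks (virtuals take the closed-shell Fock, or the average open-shell Fock
when no closed shell exists — this only affects virtual canonicalization)
and the gradient direction `2 f_I F^I − 2 f_J F^J` on the inter-space blocks
with a fixed orientation (closed < open₁ < … < virtual).

Orbital-to-space assignment uses the maximum-overlap method (MOM) whenever
the pattern contains an antiparallel coupling (default; switchable):
orbitals are matched to the previous iteration's spaces by maximal squared
projection, solved as an optimal assignment problem with a deterministic
eigenvalue tie-break. Without MOM, Aufbau filling by eigenvalue is used,
with SOMOs assigned to shells in pattern order above the closed space.

**Stabilized refinement.** For two open shells with equal occupations
(f = 1/2 each) no Roothaan-style coupling operator exists whose fixed-point
iteration is guaranteed to descend, and in practice the R-iteration can
settle on high-lying saddle points of the shell-constrained energy
functional (observed on the H4 `++--` problem, where it can land ~0.5 Eh
above the variational solution). The solver therefore finishes, by default,
with a trust-region Newton descent over the inter-space rotation parameters,
started from the lowest-energy iterate seen: the analytic gradient is exact
at each anchor, the Hessian is obtained by central differences of that
gradient and shifted to positive definiteness, and steps are accepted by
backtracking line search. Within-space rotations are excluded (the energy is
invariant under them). A start that is already stationary is returned
unchanged, so legitimately converged fixed points — including
symmetry-protected saddles and MOM-tracked excited solutions — are
preserved; the refinement only replaces a wandering iteration by the local
minimum of its own basin. Disable with `refine=False` for pure fixed-point
behaviour.

Initial guesses: `core` (core-Hamiltonian eigenvectors) and `lowdin`
(symmetrically orthogonalized basis functions — site-localized, the right
starting point for antiferromagnetic couplings between centers, emulating a
localize-then-recanonicalize guess protocol), or an explicit coefficient
matrix. `block_recanonicalize` diagonalizes a given Fock matrix within
disjoint orbital blocks without changing their span (energy invariant).

## Determinant CI

Dense full CI in active spaces of ≤ 12 orbitals: determinants are
(alpha-string, beta-string) bitmask pairs in lexicographic order, matrix
elements by the Slater–Condon rules with chemists' (pq|rs) integrals,
doubly occupied non-active orbitals folded into an effective one-electron
operator plus scalar, and a dense symmetric eigensolve (no Davidson — the
spaces are desk-scale by design). CSF weights are squared projections of a
root onto genealogical CSF vectors (optionally with doubly
occupied/empty active orbitals — the "ionic" configurations); over the
complete basis of a spin sector they sum to 1, which is tested.

## Numerical choices

| quantity | default | notes |
|---|---|---|
| energy tolerance `e_tol` | 1e−8 Eh | SCF convergence, together with `g_tol` |
| gradient tolerance `g_tol` | 1e−5 | max abs inter-space gradient element; tests/acceptance use 1e−8–1e−9 |
| DIIS subspace | 8 | started at iteration 3 |
| level shift | 0 (off) | static shift on virtual diagonal for hard cases |
| shell-constancy check | rel. 1e−9 | hard assertion when building a coupling table |
| overlap conditioning | 1e−10 | smallest eigenvalue admitted before the Löwdin inverse square root |
| Boys F0 | series below x = 1e−12 | erf closed form otherwise |
| units | bohr, hartree | XYZ read as angstrom (0.52917721092 Å/bohr); 219474.6313632 cm⁻¹/Eh |

Degenerate orbitals are ordered by a stable (eigenvalue, previous-space
overlap) sort; all fixtures are seed-free and deterministic, and reports
contain no timestamps, so identical configurations produce byte-identical
output.

## Synthetic systems and what the tests show

The built-in systems are hydrogen chains (H2 at 1.4/6.0 bohr; H3/H4/H6
equally spaced at 2.0 bohr; minimal STO-3G s-shells or an uncontracted
double-zeta s-pair) and Hubbard chains — desk-scale stand-ins for the
polymetallic chains and clusters the method targets. Problem sizes used in
the tests and acceptance checks: ≤ 8 SOMOs for coupling-element oracles,
≤ 7 basis functions for random-integral energy identities, ≤ 6 orbitals for
SCF and CI.

These systems exercise every structural feature of the method — multiple
open shells, non-Hund couplings, the neutral/ionic CSF decomposition of the
antiferromagnetic mechanism — but not features of real polymetallic
complexes: no p/d/f angular momenta, no ligand fields or covalency, no
relativistic corrections, no basis-set or guess-protocol effects, and no
near-degenerate SCF solution manifolds. Passing tests therefore establish
the correctness of the coupling algebra, energy expression, and solver on
exact desk-scale problems, not quantitative transferability to large
complexes. On the H4 chain the antiferromagnetic analog uses the alternating
(sublattice) shell assignment {0,2}/{1,3}, the faithful miniature of an
alternating spin chain: with that choice the CI ground state at the
CSF-ROHF orbitals is dominated by the neutral `++--` CSF, while grouping
adjacent sites instead yields a dimer-singlet-dominated ground state — the
shell-to-orbital assignment is part of the problem definition, exactly as
the choice of open-shell orbitals is for real clusters.

## Known limitations

* s-type Gaussians only in the built-in integral engine; anything else
  comes in through FCIDUMP files or explicit arrays.
* Dense CI only (active spaces ≤ 12 orbitals).
* No configuration-averaged (fractional-occupation) variants, no orbital
  localization utilities, no automated active-space/guess selection: the
  shell-to-orbital assignment is explicit and reproducible by design.
* The SCF targets stationary points of a fixed shell assignment; global
  exploration of multiple SCF solutions is left to the user's choice of
  guess (`core`, `lowdin`, explicit orbitals) and MOM.
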