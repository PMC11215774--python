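"""Multi-shell restricted open-shell Hartree-Fock for a single CSF.

The electronic energy is the shell-pair form of the Edwards-Zerner
expression,

    E = sum_I 2 f_I tr(h D^I)
      + sum_IJ f_I f_J [ 2 a^IJ tr(J[D^J] D^I) - b^IJ tr(K[D^J] D^I) ],

where ``D^I`` is the density of shell I (closed shell included), ``f_I`` is
the fractional per-orbital occupation (1 for closed, 1/2 for every open
shell), ``a^IJ = 1`` and ``b^IJ`` comes from the CSF's vector-coupling table
(``b^CC = b^CI = 1``, within-shell ``b^II = 2``, between open shells
``b^IJ = 2 - 2 <Phi|E_u^t E_t^u|Phi>``).  With the special densities
``A^I = sum_J alpha^IJ D^J`` and ``B^I = sum_J beta^IJ D^J`` the shell Fock
operator is

    F^I = h + J[A^I] - K[B^I],        dE/dD^I = 2 f_I F^I,

one Fock matrix per shell (closed included).  The SCF iterates densities ->
Fock matrices -> a unified effective Fock matrix whose inter-space blocks
are the orbital-rotation gradients -> new orbitals, with DIIS acceleration
and optional maximum-overlap (MOM) shell tracking so that non-Aufbau
(non-Hund) CSF solutions do not collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import linear_sum_assignment

from .integrals import IntegralSet, ao_to_mo
from .spin_coupling import CSF, VectorCouplingTable, vector_coupling_coefficients

__all__ = [
    "ShellConfiguration",
    "DensitySet",
    "SCFOptions",
    "SCFState",
    "build_densities",
    "build_shell_fock",
    "total_energy",
    "csf_energy_oracle",
    "scf_solve",
    "block_recanonicalize",
]


# ---------------------------------------------------------------------------
# Shell configuration and densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellConfiguration:
    """Assignment of orbitals to the closed shell and the open shells."""

    n_closed: int
    open_shells: tuple[tuple[int, ...], ...]  # orbital indices per open shell
    n_basis: int

    def __post_init__(self) -> None:
        flat = [p for sh in self.open_shells for p in sh]
        closed = list(range(self.n_closed))
        # closed orbitals occupy the lowest indices not claimed by a shell
        if set(flat) & set(self.closed_orbitals):
            raise ValueError("open-shell orbitals overlap the closed space")
        if len(set(flat)) != len(flat):
            raise ValueError("open shells share orbitals")
        if any(p < 0 or p >= self.n_basis for p in flat):
            raise ValueError("open-shell orbital index out of range")
        del closed

    @property
    def closed_orbitals(self) -> tuple[int, ...]:
        somo = {p for sh in self.open_shells for p in sh}
        out, p = [], 0
        while len(out) < self.n_closed:
            if p not in somo:
                out.append(p)
            p += 1
        return tuple(out)

    @property
    def n_somo(self) -> int:
        return sum(len(sh) for sh in self.open_shells)

    @property
    def n_electrons(self) -> int:
        return 2 * self.n_closed + self.n_somo

    @property
    def virtual_orbitals(self) -> tuple[int, ...]:
        used = set(self.closed_orbitals) | {p for sh in self.open_shells for p in sh}
        return tuple(p for p in range(self.n_basis) if p not in used)

    def spaces(self) -> list[tuple[int, ...]]:
        """Orbital spaces in order: closed, open shells..., virtual."""
        return [self.closed_orbitals, *self.open_shells, self.virtual_orbitals]

    def occupation_fractions(self) -> np.ndarray:
        """f per space (closed, opens..., virtual) = (1, 1/2, ..., 0)."""
        return np.array([1.0] + [0.5] * len(self.open_shells) + [0.0])

    @staticmethod
    def from_pattern(
        vct: VectorCouplingTable,
        n_closed: int,
        n_basis: int,
        shell_orbitals: list[list[int]] | None = None,
    ) -> "ShellConfiguration":
        """Default SOMO assignment: the N orbitals above the closed space,
        taken in pattern order; overridable per shell."""
        if shell_orbitals is None:
            sizes = [sh.size for sh in vct.partition.shells]
            start = n_closed
            shell_orbitals = []
            for sz in sizes:
                shell_orbitals.append(list(range(start, start + sz)))
                start += sz
        if [len(s) for s in shell_orbitals] != [sh.size for sh in vct.partition.shells]:
            raise ValueError("per-shell orbital counts do not match the pattern shells")
        return ShellConfiguration(
            n_closed, tuple(tuple(s) for s in shell_orbitals), n_basis
        )


@dataclass
class DensitySet:
    """Per-shell densities D^J and special densities A^I, B^I (AO basis).

    Index 0 is the closed shell; indices 1..n_shells the open shells.
    ``A^I = sum_J alpha^IJ D^J`` and ``B^I = sum_J beta^IJ D^J`` collect the
    Coulomb and exchange couplings of shell I to every shell J.
    """

    D: list[np.ndarray]
    A: list[np.ndarray]
    B: list[np.ndarray]


def build_densities(
    C: np.ndarray, config: ShellConfiguration, vct: VectorCouplingTable
) -> DensitySet:
    if len(config.open_shells) != vct.n_shells:
        raise ValueError("shell configuration inconsistent with coupling table")
    nb = C.shape[0]
    spaces = [config.closed_orbitals, *config.open_shells]
    D = []
    for sp in spaces:
        cols = C[:, list(sp)]
        D.append(cols @ cols.T if sp else np.zeros((nb, nb)))
    ns = len(spaces)
    A = [sum(vct.alpha[i, j] * D[j] for j in range(ns)) for i in range(ns)]
    B = [sum(vct.beta[i, j] * D[j] for j in range(ns)) for i in range(ns)]
    return DensitySet(D, A, B)


def _coulomb(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("pqrs,sr->pq", eri, D, optimize=True)


def _exchange(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("prqs,rs->pq", eri, D, optimize=True)


def build_shell_fock(
    ints: IntegralSet, dens: DensitySet
) -> list[np.ndarray]:
    """One Fock matrix per shell (closed first): F^I = h + J[A^I] - K[B^I]."""
    return [
        ints.h_core + _coulomb(ints.eri, a) - _exchange(ints.eri, b)
        for a, b in zip(dens.A, dens.B)
    ]


def total_energy(
    ints: IntegralSet,
    C: np.ndarray,
    config: ShellConfiguration,
    vct: VectorCouplingTable,
) -> float:
    """Vector-coupling-coefficient energy: E = sum_I f_I tr[(h+F^I) D^I] + E_nuc."""
    if config.n_electrons != ints.n_electrons:
        raise ValueError(
            f"shell configuration holds {config.n_electrons} electrons; "
            f"integrals declare {ints.n_electrons}"
        )
    dens = build_densities(C, config, vct)
    focks = build_shell_fock(ints, dens)
    f = config.occupation_fractions()[: 1 + vct.n_shells]
    e = ints.e_nuclear
    for fi, Fi, Di in zip(f, focks, dens.D):
        e += fi * np.einsum("pq,qp->", ints.h_core + Fi, Di)
    return float(e)


def csf_energy_oracle(
    ints: IntegralSet, C: np.ndarray, csf: CSF
) -> float:
    """<Phi|H|Phi> by expanding the CSF in Slater determinants.

    Exists solely to validate :func:`total_energy`: the CSF expectation value
    contracted with MO-transformed integrals must equal the coupling-
    coefficient energy expression at any orbitals, machine precision.
    """
    from .detci import build_hamiltonian, csf_vector

    mo = ao_to_mo(ints, C)
    docc = csf.closed_orbitals
    somo = csf.somo_orbitals
    expansion_orbs = sorted(set(docc) | set(somo))
    n_act = mo.n_basis
    # enumerate the expansion determinants directly from the spin strings
    from .spin_coupling import determinant_expansion
    from .detci import create

    dets = []
    for string, _ in determinant_expansion(csf.pattern, csf.spin_projection).terms:
        amask = bmask = 0
        for p in docc:
            amask |= 1 << p
            bmask |= 1 << p
        for p, s in zip(somo, string):
            if s == "a":
                amask |= 1 << p
            else:
                bmask |= 1 << p
        if (amask, bmask) not in dets:
            dets.append((amask, bmask))
    vec = csf_vector(dets, n_act, somo, csf.pattern, docc, csf.spin_projection)
    H = build_hamiltonian(dets, mo.h_core, mo.eri)
    return float(vec @ H @ vec / (vec @ vec) + mo.e_nuclear)


# ---------------------------------------------------------------------------
# SCF driver
# ---------------------------------------------------------------------------

@dataclass
class SCFOptions:
    e_tol: float = 1e-8          # hartree
    g_tol: float = 1e-5          # max inter-shell gradient element
    max_iter: int = 200
    diis: bool = True
    diis_size: int = 8
    diis_start: int = 3
    level_shift: float = 0.0     # hartree, added to virtual diagonal
    mom: bool | None = None      # None: on iff the pattern has a "-" coupling
    guess: str | np.ndarray = "core"
    refine: bool = True          # second-order descent polish (see scf_solve)


@dataclass
class SCFState:
    C: np.ndarray
    shell_fock: list[np.ndarray]
    energy: float
    gradient_norm: float
    iteration: int
    converged: bool
    history: list[tuple[float, float]] = field(default_factory=list)
    config: ShellConfiguration | None = None


def _gradient_mo(
    focks: list[np.ndarray], C: np.ndarray, config: ShellConfiguration
) -> np.ndarray:
    """Antisymmetric orbital-rotation gradient dE/dkappa in the MO basis.

    For p in space I and q in space J: G_pq = 2 (Ft^I - Ft^J)_pq with
    Ft^I = 2 f_I F^I (virtuals carry Ft = 0).
    """
    n = C.shape[1]
    f = config.occupation_fractions()
    fmo = [C.T @ Fi @ C for Fi in focks]
    fmo.append(np.zeros((n, n)))  # virtual space
    spaces = config.spaces()
    G = np.zeros((n, n))
    for i, sp_i in enumerate(spaces):
        for j, sp_j in enumerate(spaces):
            if i == j or not sp_i or not sp_j:
                continue
            blk = 2.0 * (
                2.0 * f[i] * fmo[i][np.ix_(sp_i, sp_j)]
                - 2.0 * f[j] * fmo[j][np.ix_(sp_i, sp_j)]
            )
            G[np.ix_(sp_i, sp_j)] = blk
    return G


def _unified_fock_mo(
    focks: list[np.ndarray], C: np.ndarray, config: ShellConfiguration,
    level_shift: float,
) -> np.ndarray:
    """Unified effective Fock matrix in the current MO basis.

    Intra-space blocks take the space's own shell Fock (virtuals take the
    closed-shell Fock, or the average open-shell Fock when no closed shell
    exists); inter-space blocks take the gradient direction Ft^I - Ft^J with
    a fixed orientation (I < J in the order closed, opens, virtual).
    """
    n = C.shape[1]
    f = config.occupation_fractions()
    fmo = [C.T @ Fi @ C for Fi in focks]
    if config.n_closed > 0:
        virt_f = fmo[0]
    else:
        virt_f = sum(fmo[1:]) / max(1, len(fmo) - 1)
    fmo.append(virt_f)
    spaces = config.spaces()
    R = np.zeros((n, n))
    for i, sp_i in enumerate(spaces):
        if not sp_i:
            continue
        R[np.ix_(sp_i, sp_i)] = fmo[i][np.ix_(sp_i, sp_i)]
        for j in range(i + 1, len(spaces)):
            sp_j = spaces[j]
            if not sp_j:
                continue
            fj = 0.0 if j == len(spaces) - 1 else f[j]
            blk = 2.0 * f[i] * fmo[i][np.ix_(sp_i, sp_j)] - 2.0 * fj * fmo[j][
                np.ix_(sp_i, sp_j)
            ]
            R[np.ix_(sp_i, sp_j)] = blk
            R[np.ix_(sp_j, sp_i)] = blk.T
    if level_shift:
        for p in config.virtual_orbitals:
            R[p, p] += level_shift
    return R


def _assign_spaces(
    U: np.ndarray, eps: np.ndarray, C_old_orth: np.ndarray,
    config: ShellConfiguration, mom: bool,
) -> np.ndarray:
    """Order the new orthonormal orbitals into spaces.

    With MOM, orbitals are assigned to the closed/open/virtual spaces by
    maximum squared projection onto the previous iteration's spaces (optimal
    assignment, deterministic tie-break by eigenvalue); otherwise the Aufbau
    ordering by eigenvalue fills closed, then the open shells in pattern
    order, then virtuals.
    """
    n = U.shape[1]
    spaces = config.spaces()
    perm = np.zeros(n, dtype=int)
    if not mom:
        order = np.argsort(eps, kind="stable")
        k = 0
        for sp in spaces:
            for slot in sp:
                perm[slot] = order[k]
                k += 1
        return perm
    # squared projection of each new orbital onto each old space
    proj = np.zeros((n, len(spaces)))
    for s, sp in enumerate(spaces):
        if not sp:
            continue
        ov = C_old_orth[:, list(sp)].T @ U  # (dim_space, n)
        proj[:, s] = np.sum(ov * ov, axis=0)
    # slot list: one column per orbital slot, cost = -projection (+ eps tiebreak)
    slots = [(s, slot) for s, sp in enumerate(spaces) for slot in sp]
    cost = np.empty((n, len(slots)))
    for c, (s, _) in enumerate(slots):
        cost[:, c] = -proj[:, s]
    cost += 1e-9 * np.abs(eps[:, None] - np.sort(eps)[None, : len(slots)])
    row, col = linear_sum_assignment(cost)
    for r, c in zip(row, col):
        perm[slots[c][1]] = r
    # within each space, order assigned orbitals by eigenvalue (stable)
    for s, sp in enumerate(spaces):
        if len(sp) < 2:
            continue
        assigned = sorted((perm[slot] for slot in sp), key=lambda k: (eps[k], k))
        for slot, k in zip(sp, assigned):
            perm[slot] = k
    return perm


class _DIIS:
    def __init__(self, size: int):
        self.size = size
        self.mats: list[np.ndarray] = []
        self.errs: list[np.ndarray] = []

    def push(self, mat: np.ndarray, err: np.ndarray) -> np.ndarray:
        self.mats.append(mat.copy())
        self.errs.append(err.ravel().copy())
        if len(self.mats) > self.size:
            self.mats.pop(0)
            self.errs.pop(0)
        m = len(self.mats)
        if m < 2:
            return mat
        B = -np.ones((m + 1, m + 1))
        B[-1, -1] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(m + 1)
        rhs[-1] = -1.0
        try:
            coef = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            self.mats = self.mats[-1:]
            self.errs = self.errs[-1:]
            return mat
        return sum(c * f for c, f in zip(coef, self.mats))


def _energy_and_gradient(
    ints: IntegralSet, C: np.ndarray, config: ShellConfiguration,
    vct: VectorCouplingTable,
) -> tuple[float, np.ndarray, list[np.ndarray]]:
    dens = build_densities(C, config, vct)
    focks = build_shell_fock(ints, dens)
    f = config.occupation_fractions()[: 1 + vct.n_shells]
    e = float(
        ints.e_nuclear
        + sum(
            fi * np.einsum("pq,qp->", ints.h_core + Fi, Di)
            for fi, Fi, Di in zip(f, focks, dens.D)
        )
    )
    return e, _gradient_mo(focks, C, config), focks


def _refine_minimize(
    ints: IntegralSet,
    C: np.ndarray,
    config: ShellConfiguration,
    vct: VectorCouplingTable,
    g_tol: float,
    max_iter: int = 80,
) -> tuple[np.ndarray, float, float, int]:
    """Locally minimize the energy over inter-space orbital rotations.

    Trust-region Newton on the rotation parameters: the analytic gradient is
    exact at each anchor, the Hessian comes from central differences of the
    gradient, shifted to positive definiteness so every step is a descent
    direction (backtracking line search).  Within-space rotations leave the
    energy invariant and are excluded.  Converges to the local minimum of
    the shell-constrained energy functional in the basin of the start.
    """
    spaces = config.spaces()
    pairs = [
        (p, q)
        for i, sp_i in enumerate(spaces)
        for j in range(i + 1, len(spaces))
        for p in sp_i
        for q in spaces[j]
    ]
    m = len(pairs)
    n = C.shape[1]

    def rotate(C0: np.ndarray, x: np.ndarray) -> np.ndarray:
        K = np.zeros((n, n))
        for k, (p, q) in enumerate(pairs):
            K[p, q] = x[k]
            K[q, p] = -x[k]
        return C0 @ sla.expm(K)

    def grad_vec(Cc: np.ndarray) -> tuple[float, np.ndarray]:
        e, G, _ = _energy_and_gradient(ints, Cc, config, vct)
        return e, np.array([G[q, p] for p, q in pairs])

    e0, g = grad_vec(C)
    it = 0
    for it in range(1, max_iter + 1):
        if m == 0 or np.abs(g).max() < g_tol:
            break
        h = 1e-5
        H = np.empty((m, m))
        for k in range(m):
            ek = np.zeros(m)
            ek[k] = h
            _, gp = grad_vec(rotate(C, ek))
            _, gm = grad_vec(rotate(C, -ek))
            H[:, k] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        w, V = np.linalg.eigh(H)
        floor = max(1e-4, 1e-2 * np.abs(w).max())
        w = np.where(w < floor, floor, w)
        step = -V @ ((V.T @ g) / w)
        alpha, accepted = 1.0, False
        for _ in range(30):
            Ct = rotate(C, alpha * step)
            et, gt = grad_vec(Ct)
            if et < e0 - 1e-14 * max(1.0, abs(e0)) or (
                et <= e0 and np.abs(gt).max() < np.abs(g).max()
            ):
                C, e0, g = Ct, et, gt
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    return C, e0, float(np.abs(g).max()) if m else 0.0, it


def scf_solve(
    ints: IntegralSet,
    config: ShellConfiguration,
    vct: VectorCouplingTable,
    options: SCFOptions | None = None,
) -> SCFState:
    """Drive the CSF-ROHF equations to self-consistency.

    The main loop iterates densities -> shell Fock matrices -> unified
    effective Fock -> new orbitals with DIIS and (for patterns containing
    antiparallel couplings) maximum-overlap shell tracking.  Because the
    unified-Fock fixed point is not guaranteed to be a descent map when two
    open shells carry equal occupations, the default ``refine=True`` follows
    up with a trust-region Newton descent over inter-space rotations started
    from the lowest-energy iterate, which converges to the local minimum of
    the shell-constrained energy functional in that basin (a stationary
    start is left untouched).  Returns an :class:`SCFState`; non-convergence
    is flagged on the state (``converged = False``), never silent.
    """
    opt = options or SCFOptions()
    if config.n_electrons != ints.n_electrons:
        raise ValueError(
            f"configuration holds {config.n_electrons} electrons, "
            f"integrals declare {ints.n_electrons}"
        )
    S = ints.overlap
    w, V = np.linalg.eigh(S)
    if w.min() < 1e-10:
        raise ValueError("overlap matrix is numerically singular")
    X = V @ np.diag(w**-0.5) @ V.T  # Lowdin orthogonalizer
    Xi = V @ np.diag(w**0.5) @ V.T
    if isinstance(opt.guess, np.ndarray):
        C = opt.guess.copy()
    elif opt.guess == "core":
        _, C = sla.eigh(ints.h_core, S)
    elif opt.guess == "lowdin":
        # symmetrically orthogonalized basis functions in input order; the
        # site-localized guess suited to antiferromagnetic coupling patterns
        C = X.copy()
    else:
        raise ValueError(f"unknown guess {opt.guess!r}")
    mom = opt.mom
    if mom is None:
        mom = vct.pattern is not None and any(s < 0 for s in vct.pattern.signs)
    diis = _DIIS(opt.diis_size) if opt.diis else None
    energy = np.inf
    history: list[tuple[float, float]] = []
    converged = False
    best_C, best_e = C.copy(), np.inf
    it = 0
    for it in range(1, opt.max_iter + 1):
        e_new, G, focks = _energy_and_gradient(ints, C, config, vct)
        g_norm = float(np.abs(G).max()) if G.size else 0.0
        de = e_new - energy
        energy = e_new
        history.append((energy, g_norm))
        if energy < best_e:
            best_C, best_e = C.copy(), energy
        if g_norm < opt.g_tol and abs(de) < opt.e_tol:
            converged = True
            break
        R = _unified_fock_mo(focks, C, config, opt.level_shift)
        C_orth = Xi @ C
        R_orth = C_orth @ R @ C_orth.T
        if diis is not None and it >= opt.diis_start:
            err_orth = C_orth @ G @ C_orth.T
            R_orth = diis.push(R_orth, err_orth)
            R_orth = 0.5 * (R_orth + R_orth.T)
        eps, U = np.linalg.eigh(R_orth)
        perm = _assign_spaces(U, eps, C_orth, config, mom)
        C = X @ U[:, perm]
    if opt.refine:
        # descend from the lowest-energy iterate; a stationary start returns
        # unchanged, so a legitimately converged fixed point is preserved
        # unless a lower iterate was seen on the way
        start = best_C if best_e < energy - 1e-12 else C
        C_ref, e_ref, g_ref, extra = _refine_minimize(
            ints, start, config, vct, opt.g_tol
        )
        if e_ref <= energy + 1e-12:
            C, energy = C_ref, e_ref
            history.append((energy, g_ref))
            it += extra
            converged = g_ref < opt.g_tol
    dens = build_densities(C, config, vct)
    focks = build_shell_fock(ints, dens)
    return SCFState(
        C=C,
        shell_fock=focks,
        energy=energy,
        gradient_norm=history[-1][1],
        iteration=it,
        converged=converged,
        history=history,
        config=config,
    )


def block_recanonicalize(
    C: np.ndarray, fock: np.ndarray, blocks: list[list[int]]
) -> np.ndarray:
    """Rotate orbitals within each block to diagonalize the given Fock (AO).

    Blocks must be disjoint; the span of each block (hence the energy) is
    preserved exactly.
    """
    flat = [p for b in blocks for p in b]
    if len(set(flat)) != len(flat):
        raise ValueError("recanonicalization blocks overlap")
    C_new = C.copy()
    for block in blocks:
        cols = C[:, block]
        fb = cols.T @ fock @ cols
        _, u = np.linalg.eigh(fb)
        C_new[:, block] = cols @ u
    return C_new
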