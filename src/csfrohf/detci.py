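"""Dense determinant-basis configuration interaction in small orbital spaces.

Determinants are (alpha-string, beta-string) bitmask pairs over the active
orbitals, enumerated in lexicographic order; the canonical operator order is
all alpha creation operators (ascending orbital) followed by all beta
creation operators.  Hamiltonian matrix elements follow the Slater-Condon
rules with chemists' (pq|rs) integrals; doubly occupied orbitals outside the
active space are folded into an effective one-electron operator plus a scalar.

This module is the validation oracle for the vector-coupling machinery (the
CSF expectation value must match the coupling-coefficient energy expression)
and provides CSF-weight analysis of CI roots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .integrals import IntegralSet
from .spin_coupling import (
    CSF,
    SpinCouplingPattern,
    determinant_expansion,
    enumerate_patterns,
    parse_pattern,
)

__all__ = [
    "CIResult",
    "ci_solve",
    "csf_weights",
    "enumerate_csf_basis",
    "csf_vector",
    "spin_squared_expectation",
    "coupling_element_brute",
]

HALF = Fraction(1, 2)


# ---------------------------------------------------------------------------
# Bitmask determinant algebra
# ---------------------------------------------------------------------------

def _occ_list(mask: int) -> list[int]:
    out = []
    p = 0
    while mask:
        if mask & 1:
            out.append(p)
        mask >>= 1
        p += 1
    return out


def _count_below(mask: int, p: int) -> int:
    return bin(mask & ((1 << p) - 1)).count("1")


def create(amask: int, bmask: int, p: int, spin: int) -> tuple[int, int, int]:
    """Apply a+(p, spin); returns (amask, bmask, phase), phase 0 if killed."""
    if spin == 0:
        if amask >> p & 1:
            return amask, bmask, 0
        return amask | 1 << p, bmask, (-1) ** _count_below(amask, p)
    if bmask >> p & 1:
        return amask, bmask, 0
    na = bin(amask).count("1")
    return amask, bmask | 1 << p, (-1) ** (na + _count_below(bmask, p))


def annihilate(amask: int, bmask: int, p: int, spin: int) -> tuple[int, int, int]:
    """Apply a(p, spin); returns (amask, bmask, phase), phase 0 if killed."""
    if spin == 0:
        if not amask >> p & 1:
            return amask, bmask, 0
        return amask & ~(1 << p), bmask, (-1) ** _count_below(amask, p)
    if not bmask >> p & 1:
        return amask, bmask, 0
    na = bin(amask).count("1")
    return amask, bmask & ~(1 << p), (-1) ** (na + _count_below(bmask, p))


def _single_phase(mask: int, i: int, a: int) -> int:
    """Phase of a+_a a_i within one spin string (i occupied, a empty)."""
    lo, hi = (i, a) if i < a else (a, i)
    between = bin(mask & (((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1))).count("1")
    return (-1) ** between


# ---------------------------------------------------------------------------
# Slater-Condon Hamiltonian
# ---------------------------------------------------------------------------

def _slater_condon(
    deti: tuple[int, int],
    detj: tuple[int, int],
    h: np.ndarray,
    eri: np.ndarray,
) -> float:
    ai, bi = deti
    aj, bj = detj
    da, db = ai ^ aj, bi ^ bj
    nda, ndb = bin(da).count("1"), bin(db).count("1")
    if nda + ndb > 4:
        return 0.0
    aocc, bocc = _occ_list(ai), _occ_list(bi)
    if nda + ndb == 0:
        e = sum(h[p, p] for p in aocc) + sum(h[p, p] for p in bocc)
        for p, q in itertools.combinations(aocc, 2):
            e += eri[p, p, q, q] - eri[p, q, q, p]
        for p, q in itertools.combinations(bocc, 2):
            e += eri[p, p, q, q] - eri[p, q, q, p]
        for p in aocc:
            for q in bocc:
                e += eri[p, p, q, q]
        return e
    if nda == 2 and ndb == 0:
        i_, = _occ_list(da & ai)
        a_, = _occ_list(da & aj)
        ph = _single_phase(ai, i_, a_)
        e = h[i_, a_]
        for p in aocc:
            if p != i_:
                e += eri[i_, a_, p, p] - eri[i_, p, p, a_]
        for p in bocc:
            e += eri[i_, a_, p, p]
        return ph * e
    if nda == 0 and ndb == 2:
        i_, = _occ_list(db & bi)
        a_, = _occ_list(db & bj)
        ph = _single_phase(bi, i_, a_)
        e = h[i_, a_]
        for p in bocc:
            if p != i_:
                e += eri[i_, a_, p, p] - eri[i_, p, p, a_]
        for p in aocc:
            e += eri[i_, a_, p, p]
        return ph * e
    if nda == 2 and ndb == 2:
        i_, = _occ_list(da & ai)
        a_, = _occ_list(da & aj)
        j_, = _occ_list(db & bi)
        b_, = _occ_list(db & bj)
        ph = _single_phase(ai, i_, a_) * _single_phase(bi, j_, b_)
        return ph * eri[i_, a_, j_, b_]
    if nda == 4:
        i_, j_ = _occ_list(da & ai)
        a_, b_ = _occ_list(da & aj)
        # phase from sequential application: i->a then j->b on the reduced string
        m1 = ai & ~(1 << i_) | (1 << a_)
        ph = _single_phase(ai, i_, a_) * _single_phase(m1, j_, b_)
        return ph * (eri[i_, a_, j_, b_] - eri[i_, b_, j_, a_])
    # ndb == 4
    i_, j_ = _occ_list(db & bi)
    a_, b_ = _occ_list(db & bj)
    m1 = bi & ~(1 << i_) | (1 << a_)
    ph = _single_phase(bi, i_, a_) * _single_phase(m1, j_, b_)
    return ph * (eri[i_, a_, j_, b_] - eri[i_, b_, j_, a_])


def build_hamiltonian(
    dets: list[tuple[int, int]], h: np.ndarray, eri: np.ndarray
) -> np.ndarray:
    n = len(dets)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            H[i, j] = H[j, i] = _slater_condon(dets[i], dets[j], h, eri)
    return H


# ---------------------------------------------------------------------------
# CI driver
# ---------------------------------------------------------------------------

@dataclass
class CIResult:
    """Eigenpairs of the active-space Hamiltonian (energies include core)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column per root, determinant basis
    dets: list[tuple[int, int]]
    active_orbitals: tuple[int, ...]
    n_active_el: int
    spin_projection: Fraction
    e_core: float

    @property
    def n_dets(self) -> int:
        return len(self.dets)


def _fold_core(
    ints: IntegralSet, active: tuple[int, ...], frozen: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fold doubly occupied frozen orbitals into (h_eff, eri_act, e_core)."""
    h, eri = ints.h_core, ints.eri
    e_core = ints.e_nuclear
    for i in frozen:
        e_core += 2.0 * h[i, i]
        for j in frozen:
            e_core += 2.0 * eri[i, i, j, j] - eri[i, j, j, i]
    act = np.asarray(active)
    h_eff = h[np.ix_(act, act)].copy()
    for i in frozen:
        h_eff += 2.0 * eri[np.ix_(act, act)][:, :, i, i] - eri[:, i, i, :][np.ix_(act, act)]
    eri_act = eri[np.ix_(act, act, act, act)]
    return h_eff, eri_act, e_core


def ci_solve(
    ints: IntegralSet,
    n_active_el: int,
    active_orbitals: list[int] | tuple[int, ...],
    M: Fraction | float = 0,
    n_roots: int | None = None,
    max_active: int = 12,
) -> CIResult:
    """Dense CI in the given active space at spin projection M.

    Orbitals not in the active space hold the remaining electrons as a
    doubly occupied frozen core, folded into an effective one-electron
    operator plus a scalar.  The integrals must be in the (orthonormal)
    molecular-orbital basis.
    """
    if not ints.orthonormal:
        raise ValueError("ci_solve requires MO-basis (orthonormal) integrals")
    active = tuple(active_orbitals)
    n_act = len(active)
    if n_act > max_active:
        raise ValueError(f"active space of {n_act} orbitals exceeds dense limit {max_active}")
    rem = ints.n_electrons - n_active_el
    if rem < 0 or rem % 2:
        raise ValueError(
            f"{n_active_el} active electrons inconsistent with "
            f"{ints.n_electrons} total (core must be doubly occupied)"
        )
    frozen = tuple(p for p in range(ints.n_basis) if p not in active)[: rem // 2]
    if len(frozen) < rem // 2:
        raise ValueError("not enough orbitals outside the active space for the core")
    M = Fraction(M)
    n_a = Fraction(n_active_el, 2) + M
    if n_a % 1 or not 0 <= n_a <= min(n_active_el, n_act):
        raise ValueError(f"projection M = {M} impossible for {n_active_el} electrons")
    n_a = int(n_a)
    n_b = n_active_el - n_a
    if n_b > n_act:
        raise ValueError("more beta electrons than active orbitals")
    h_eff, eri_act, e_core = _fold_core(ints, active, frozen)
    astrings = [sum(1 << p for p in occ) for occ in itertools.combinations(range(n_act), n_a)]
    bstrings = [sum(1 << p for p in occ) for occ in itertools.combinations(range(n_act), n_b)]
    dets = [(a, b) for a in astrings for b in bstrings]
    H = build_hamiltonian(dets, h_eff, eri_act)
    w, v = np.linalg.eigh(H)
    if n_roots is not None:
        w, v = w[:n_roots], v[:, :n_roots]
    return CIResult(w + e_core, v, dets, active, n_active_el, M, e_core)


# ---------------------------------------------------------------------------
# CSF vectors in the determinant basis
# ---------------------------------------------------------------------------

def csf_vector(
    dets: list[tuple[int, int]],
    n_act: int,
    somo: tuple[int, ...],
    pattern: SpinCouplingPattern,
    docc: tuple[int, ...] = (),
    M: Fraction | None = None,
) -> np.ndarray:
    """Expand a genealogical CSF over the given determinant list.

    ``somo`` lists the singly occupied active orbitals in genealogical order,
    ``docc`` the doubly occupied active orbitals.  Phases come from applying
    the creation operators (doubly occupied pairs first, then the SOMOs in
    genealogical order) against the canonical alpha-block/beta-block order.
    """
    index = {d: i for i, d in enumerate(dets)}
    vec = np.zeros(len(dets))
    expansion = determinant_expansion(pattern, M)
    for string, coeff in expansion.terms:
        amask = bmask = 0
        phase = 1
        ops: list[tuple[int, int]] = []
        for p in sorted(docc):
            ops += [(p, 0), (p, 1)]
        ops += [(p, 0 if s == "a" else 1) for p, s in zip(somo, string)]
        for p, spin in ops:
            amask, bmask, ph = create(amask, bmask, p, spin)
            phase *= ph
        if phase == 0:
            continue
        i = index.get((amask, bmask))
        if i is not None:
            vec[i] += phase * coeff
    return vec


def enumerate_csf_basis(
    n_act: int, n_el: int, S: Fraction | float
) -> list[tuple[tuple[int, ...], tuple[int, ...], SpinCouplingPattern | None]]:
    """All (docc, somo, pattern) configurations spanning the S sector.

    Includes the "ionic" configurations in which orbitals are doubly
    occupied or empty; a configuration with zero SOMOs carries pattern None
    (only valid for S = 0).
    """
    S = Fraction(S)
    out = []
    for n_open in range(n_el % 2, min(n_act, n_el) + 1, 2):
        n_docc = (n_el - n_open) // 2
        if n_docc + n_open > n_act or Fraction(n_open, 2) < S:
            continue
        patterns = list(enumerate_patterns(n_open, S)) if n_open else (
            [None] if S == 0 else []
        )
        if not patterns:
            continue
        for docc in itertools.combinations(range(n_act), n_docc):
            rest = [p for p in range(n_act) if p not in docc]
            for somo in itertools.combinations(rest, n_open):
                for pat in patterns:
                    out.append((docc, somo, pat))
    return out


def csf_weights(
    result: CIResult,
    root: int,
    patterns: list[str | SpinCouplingPattern] | None = None,
    configs: list[tuple] | None = None,
) -> dict[str, float]:
    """Squared projections of a CI root onto genealogical CSFs.

    ``patterns`` are "neutral" CSFs occupying every active orbital singly
    (in ascending orbital order).  Alternatively ``configs`` gives explicit
    (docc, somo, pattern) triples, e.g. from :func:`enumerate_csf_basis`;
    over a complete set of one spin sector the weights of a spin-pure root
    in that sector sum to one.
    """
    v = result.eigenvectors[:, root]
    n_act = len(result.active_orbitals)
    todo: list[tuple[tuple[int, ...], tuple[int, ...], SpinCouplingPattern | None]] = []
    if patterns is not None:
        for p in patterns:
            pat = parse_pattern(p) if isinstance(p, str) else p
            if pat.n_somo != result.n_active_el:
                raise ValueError(
                    f"pattern {pat} has {pat.n_somo} SOMOs; the active space "
                    f"holds {result.n_active_el} electrons"
                )
            todo.append(((), tuple(range(n_act)), pat))
    if configs is not None:
        todo += [tuple(c) for c in configs]
    out = {}
    for docc, somo, pat in todo:
        if pat is None:
            vec = np.zeros(result.n_dets)
            amask = bmask = 0
            phase = 1
            for p in sorted(docc):
                for spin in (0, 1):
                    amask, bmask, ph = create(amask, bmask, p, spin)
                    phase *= ph
            idx = {d: i for i, d in enumerate(result.dets)}.get((amask, bmask))
            if idx is not None:
                vec[idx] = phase
            label = f"docc={docc}"
        else:
            vec = csf_vector(
                result.dets, n_act, tuple(somo), pat, tuple(docc),
                result.spin_projection,
            )
            label = str(pat) if not docc else f"docc={docc} somo={somo} {pat}"
        nrm = vec @ vec
        out[label] = float((v @ vec) ** 2 / nrm) if nrm > 1e-14 else 0.0
    return out


# ---------------------------------------------------------------------------
# Spin diagnostics and brute-force coupling oracle
# ---------------------------------------------------------------------------

def spin_squared_expectation(
    vec: np.ndarray, dets: list[tuple[int, int]]
) -> float:
    """<v|S^2|v> in the determinant basis (S^2 = S-S+ + Sz(Sz+1))."""
    index = {d: i for i, d in enumerate(dets)}
    total = 0.0
    for (amask, bmask), ci in zip(dets, vec):
        if ci == 0.0:
            continue
        na, nb = bin(amask).count("1"), bin(bmask).count("1")
        sz = 0.5 * (na - nb)
        total += ci * ci * (sz * (sz + 1.0))
        # S-S+ = sum_pq a+_pb a_pa a+_qa a_qb
        for q in _occ_list(bmask):
            a1, b1, ph1 = annihilate(amask, bmask, q, 1)
            a1, b1, ph1b = create(a1, b1, q, 0)
            if ph1b == 0:
                continue
            for p in _occ_list(a1):
                a2, b2, ph2 = annihilate(a1, b1, p, 0)
                a2, b2, ph2b = create(a2, b2, p, 1)
                if ph2b == 0:
                    continue
                j = index.get((a2, b2))
                if j is not None:
                    total += ci * vec[j] * ph1 * ph1b * ph2 * ph2b
    return total


def coupling_element_brute(
    pattern: SpinCouplingPattern | str,
    t: int,
    u: int,
    M: Fraction | float | None = None,
) -> float:
    """``<Phi|E_u^t E_t^u|Phi>`` by brute force on the determinant expansion.

    Computed as the squared norm of ``E_t^u |Phi>`` with full fermionic
    phases; the independent oracle for
    :func:`csfrohf.spin_coupling.coupling_matrix_element`.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    n = pattern.n_somo
    expansion = determinant_expansion(pattern, M)
    amp: dict[tuple[int, int], float] = {}
    for string, coeff in expansion.terms:
        amask = bmask = 0
        phase = 1
        for p, s in enumerate(string):
            amask, bmask, ph = create(amask, bmask, p, 0 if s == "a" else 1)
            phase *= ph
        # E_t^u = sum_sigma a+(u,sigma) a(t,sigma)
        for spin in (0, 1):
            a1, b1, ph1 = annihilate(amask, bmask, t - 1, spin)
            if ph1 == 0:
                continue
            a2, b2, ph2 = create(a1, b1, u - 1, spin)
            if ph2 == 0:
                continue
            key = (a2, b2)
            amp[key] = amp.get(key, 0.0) + phase * ph1 * ph2 * coeff
    return float(sum(v * v for v in amp.values()))
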