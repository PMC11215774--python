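"""Genealogically coupled configuration state functions (CSFs).

A CSF over N singly occupied molecular orbitals (SOMOs) is encoded by a
branching-diagram path: a string of couplings ``+``/``-`` where the k-th sign
says whether the k-th unpaired spin raises or lowers the intermediate total
spin, ``S_k = S_{k-1} +- 1/2`` with ``S_0 = 0``.  The path fully determines

* the expansion of the CSF in Slater determinants (sequential Clebsch-Gordan
  coupling, exact rational arithmetic internally),
* the two-body substitution-operator matrix elements
  ``<Phi| E_u^t E_t^u |Phi>`` between SOMOs, and
* the vector-coupling coefficients ``a^IJ``/``b^IJ`` of the open-shell
  Hartree-Fock energy expression, one open shell per maximal run of
  consecutive parallel-coupled spins.

Conventions
-----------
``E_u^t = sum_sigma a+(t,sigma) a(u,sigma)`` moves an electron from orbital
``u`` to orbital ``t``.  Determinants are ordered with ascending orbitals,
alpha before beta; Clebsch-Gordan phases follow Condon-Shortley.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PatternError",
    "EmptyPatternError",
    "IllegalCharacterError",
    "FirstSpinDownError",
    "NegativeIntermediateSpinError",
    "SpinCouplingPattern",
    "CSF",
    "Shell",
    "ShellPartition",
    "DeterminantExpansion",
    "VectorCouplingTable",
    "parse_pattern",
    "enumerate_patterns",
    "weyl_count",
    "shell_partition",
    "determinant_expansion",
    "coupling_matrix_element",
    "spin_spin_correlation",
    "vector_coupling_coefficients",
    "closed_shell_table",
]

HALF = Fraction(1, 2)


# ---------------------------------------------------------------------------
# Pattern parsing and validation
# ---------------------------------------------------------------------------

class PatternError(ValueError):
    """Base class for spin-coupling pattern validation failures."""


class EmptyPatternError(PatternError):
    """The pattern contains no coupling symbols."""


class IllegalCharacterError(PatternError):
    """The pattern contains a character other than '+' or '-'."""


class FirstSpinDownError(PatternError):
    """The first spin must couple upward (S_1 = 1/2)."""


class NegativeIntermediateSpinError(PatternError):
    """The branching diagram crossed below zero."""


@dataclass(frozen=True)
class SpinCouplingPattern:
    """A validated genealogical coupling path.

    Attributes
    ----------
    signs:
        One entry of +1/-1 per SOMO.
    intermediate_spins:
        ``S_k`` after coupling spin k (exact half-integers), length N.
    """

    signs: tuple[int, ...]
    intermediate_spins: tuple[Fraction, ...] = field(repr=False)

    @property
    def n_somo(self) -> int:
        return len(self.signs)

    @property
    def total_spin(self) -> Fraction:
        return self.intermediate_spins[-1]

    @property
    def multiplicity(self) -> int:
        return int(2 * self.total_spin) + 1

    def __str__(self) -> str:
        return "".join("+" if s > 0 else "-" for s in self.signs)


# characters tolerated around/inside a pattern string
_IGNORED = set(" \t\n[](),;")
_MINUS_ALIASES = {"-", "−", "–"}  # ascii, minus sign, en-dash


def parse_pattern(text: str) -> SpinCouplingPattern:
    """Parse a ``+``/``-`` coupling string into a validated pattern.

    Whitespace and brackets are tolerated; unicode minus/en-dash are accepted
    as ``-``.  Raises a distinct :class:`PatternError` subclass for each
    failure mode (empty input, illegal character, first spin down, branching
    diagram below zero).
    """
    signs: list[int] = []
    for ch in text:
        if ch in _IGNORED:
            continue
        if ch == "+":
            signs.append(+1)
        elif ch in _MINUS_ALIASES:
            signs.append(-1)
        else:
            raise IllegalCharacterError(
                f"illegal character {ch!r} in spin-coupling pattern {text!r}; "
                "only '+' and '-' are allowed"
            )
    if not signs:
        raise EmptyPatternError("spin-coupling pattern is empty")
    if signs[0] < 0:
        raise FirstSpinDownError(
            "the first spin must couple upward ('+'): a single electron has S = 1/2"
        )
    spins: list[Fraction] = []
    s = Fraction(0)
    for k, sg in enumerate(signs, start=1):
        s = s + HALF if sg > 0 else s - HALF
        if s < 0:
            raise NegativeIntermediateSpinError(
                f"intermediate spin below zero at position {k}: "
                f"the branching diagram never crosses S < 0"
            )
        spins.append(s)
    return SpinCouplingPattern(tuple(signs), tuple(spins))


def enumerate_patterns(
    n_somo: int, total_spin: Fraction | float | None = None
) -> Iterator[SpinCouplingPattern]:
    """Yield every valid pattern with ``n_somo`` SOMOs (optionally fixed S)."""
    if total_spin is not None:
        total_spin = Fraction(total_spin)
    for bits in itertools.product((+1, -1), repeat=n_somo):
        s = Fraction(0)
        spins = []
        ok = True
        for sg in bits:
            s = s + HALF if sg > 0 else s - HALF
            if s < 0:
                ok = False
                break
            spins.append(s)
        if not ok or (total_spin is not None and s != total_spin):
            continue
        yield SpinCouplingPattern(bits, tuple(spins))


def weyl_count(n_somo: int, total_spin: Fraction | float) -> int:
    """Number of linearly independent spin eigenfunctions (branching count)."""
    s = Fraction(total_spin)
    k = Fraction(n_somo, 2) - s
    if k < 0 or k != int(k):
        return 0
    k = int(k)
    return int(Fraction(2 * s + 1, Fraction(n_somo, 2) + s + 1) * math.comb(n_somo, k))


# ---------------------------------------------------------------------------
# Shell partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shell:
    """A maximal run of consecutive parallel-coupled SOMOs."""

    sign: int
    slots: tuple[int, ...]  # 1-based SOMO slot indices, contiguous

    @property
    def size(self) -> int:
        return len(self.slots)


@dataclass(frozen=True)
class ShellPartition:
    shells: tuple[Shell, ...]
    pattern: SpinCouplingPattern

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    def shell_of_slot(self, slot: int) -> int:
        for i, sh in enumerate(self.shells):
            if slot in sh.slots:
                return i
        raise IndexError(f"SOMO slot {slot} out of range")


def shell_partition(pattern: SpinCouplingPattern) -> ShellPartition:
    """Group the pattern into open shells: maximal runs of equal signs."""
    shells: list[Shell] = []
    start = 0
    for k in range(1, pattern.n_somo + 1):
        if k == pattern.n_somo or pattern.signs[k] != pattern.signs[start]:
            shells.append(
                Shell(pattern.signs[start], tuple(range(start + 1, k + 1)))
            )
            start = k
    return ShellPartition(tuple(shells), pattern)


# ---------------------------------------------------------------------------
# CSF and determinant expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSF:
    """A configuration state function: a pattern bound to concrete orbitals.

    ``somo_orbitals`` lists the SOMO orbital indices in genealogical order;
    ``n_closed`` doubly occupied orbitals accompany them.  ``spin_projection``
    defaults to the highest projection M = S.
    """

    pattern: SpinCouplingPattern
    somo_orbitals: tuple[int, ...]
    n_closed: int = 0
    spin_projection: Fraction | None = None

    def __post_init__(self) -> None:
        if len(set(self.somo_orbitals)) != len(self.somo_orbitals):
            raise ValueError("SOMO orbitals must be distinct")
        if len(self.somo_orbitals) != self.pattern.n_somo:
            raise ValueError(
                f"{self.pattern.n_somo} SOMO slots but "
                f"{len(self.somo_orbitals)} orbitals supplied"
            )
        m = self.spin_projection
        if m is None:
            object.__setattr__(self, "spin_projection", self.pattern.total_spin)
        else:
            m = Fraction(m)
            if abs(m) > self.pattern.total_spin or (m - self.pattern.total_spin) % 1 != 0:
                raise ValueError(
                    f"spin projection {m} incompatible with S = {self.pattern.total_spin}"
                )
            object.__setattr__(self, "spin_projection", m)

    @property
    def closed_orbitals(self) -> tuple[int, ...]:
        """The ``n_closed`` lowest orbital indices not used as SOMOs."""
        out, p = [], 0
        somo = set(self.somo_orbitals)
        while len(out) < self.n_closed:
            if p not in somo:
                out.append(p)
            p += 1
        return tuple(out)


@dataclass(frozen=True)
class DeterminantExpansion:
    """Expansion of a CSF's open-shell part in spin strings.

    ``terms`` maps spin strings (one ``'a'``/``'b'`` per SOMO, genealogical
    order) to real coefficients; the squared coefficients sum to one.
    """

    terms: tuple[tuple[str, float], ...]
    spin_projection: Fraction

    def as_dict(self) -> dict[str, float]:
        return dict(self.terms)


def _cg_half(s_prev: Fraction, s_new: Fraction, m_total: Fraction, m: Fraction) -> Fraction:
    """Signed square of <s_prev, m_total - m; 1/2, m | s_new, m_total>.

    Returns a Fraction q with coefficient = sign(q) * sqrt(|q|)
    (Condon-Shortley phases).
    """
    denom = 2 * s_prev + 1
    if s_new == s_prev + HALF:
        num = s_prev + 2 * m * m_total + HALF
        q = Fraction(num, denom)
        return q
    # s_new == s_prev - 1/2
    num = s_prev - 2 * m * m_total + HALF
    q = Fraction(num, denom)
    return -q if m > 0 else q


def determinant_expansion(
    pattern: SpinCouplingPattern | CSF, M: Fraction | float | None = None
) -> DeterminantExpansion:
    """Expand a genealogically coupled CSF in spin strings.

    The coefficient of a string (m_1 ... m_N) is the product of the N
    Clebsch-Gordan factors along the branching path, evaluated in exact
    rational arithmetic and converted to float at the end.
    """
    if isinstance(pattern, CSF):
        if M is None:
            M = pattern.spin_projection
        pattern = pattern.pattern
    if M is None:
        M = pattern.total_spin
    M = Fraction(M)
    S = pattern.total_spin
    if abs(M) > S or (S - M) % 1 != 0:
        raise ValueError(f"projection M = {M} incompatible with S = {S}")
    n = pattern.n_somo
    n_alpha = Fraction(n, 2) + M
    if n_alpha % 1 != 0:
        raise ValueError(f"M = {M} impossible for {n} unpaired electrons")
    terms: list[tuple[str, float]] = []
    for alphas in itertools.combinations(range(n), int(n_alpha)):
        ms = [HALF if k in alphas else -HALF for k in range(n)]
        q = Fraction(1)
        m_run = Fraction(0)
        s_prev = Fraction(0)
        for k in range(n):
            m_run += ms[k]
            if abs(m_run) > pattern.intermediate_spins[k]:
                q = Fraction(0)
                break
            c = _cg_half(s_prev, pattern.intermediate_spins[k], m_run, ms[k])
            sign = -1 if (q < 0) != (c < 0) else 1
            q = Fraction(sign) * abs(q) * abs(c)
            s_prev = pattern.intermediate_spins[k]
            if q == 0:
                break
        if q == 0:
            continue
        coeff = math.copysign(math.sqrt(abs(q)), q)
        string = "".join("a" if m > 0 else "b" for m in ms)
        terms.append((string, coeff))
    return DeterminantExpansion(tuple(terms), M)


# ---------------------------------------------------------------------------
# Coupling matrix elements <Phi| E_u^t E_t^u |Phi>
# ---------------------------------------------------------------------------

def _transposition_expectation(pattern: SpinCouplingPattern, t: int, u: int) -> float:
    """<path|(t,u)|path>: expectation of the spin transposition of SOMOs t,u.

    Evaluated in the branching-path basis using the Young orthogonal
    representation of the symmetric group: an adjacent transposition (k,k+1)
    acts only on the intermediate spin S_k.  With rho = 2 S_{k-1} + 1,

    * S_{k+1} = S_{k-1} +- 1 (parallel pair)   ->  +1 on that path,
    * S_{k+1} = S_{k-1}: the up-down path gets -1/rho, the down-up path
      +1/rho, off-diagonal sqrt(1 - 1/rho^2).

    A general (t,u) is the standard product of adjacent transpositions; no
    determinant expansion is involved.
    """
    spins = (Fraction(0),) + pattern.intermediate_spins
    # basis: all valid sub-paths over positions t..u-1 with fixed endpoints
    lo, hi = t, u  # spins[lo-1] and spins[hi] are pinned
    partials: list[tuple[Fraction, ...]] = [(spins[lo - 1],)]
    for k in range(lo, hi):
        nxt = []
        for p in partials:
            for step in (HALF, -HALF):
                s = p[-1] + step
                if s >= 0:
                    nxt.append(p + (s,))
        partials = nxt
    paths = [p for p in partials if abs(p[-1] - spins[hi]) == HALF]
    # append pinned endpoint so each path covers spins[lo-1 .. hi]
    paths = [p + (spins[hi],) for p in paths]
    index = {p: i for i, p in enumerate(paths)}
    dim = len(paths)

    def adjacent_matrix(k: int) -> np.ndarray:
        # (k, k+1) with lo <= k <= hi-1; path position of S_j is j-(lo-1)
        mat = np.zeros((dim, dim))
        for p, i in index.items():
            a = p[k - 1 - (lo - 1)] if k - 1 >= lo - 1 else spins[k - 1]
            b = p[k + 1 - (lo - 1)]
            sk = p[k - (lo - 1)]
            if abs(b - a) == 1:
                mat[i, i] = 1.0
                continue
            rho = float(2 * a + 1)
            diag = -1.0 / rho if sk == a + HALF else 1.0 / rho
            mat[i, i] = diag
            other = a - HALF if sk == a + HALF else a + HALF
            if other >= 0:
                q = list(p)
                q[k - (lo - 1)] = other
                j = index.get(tuple(q))
                if j is not None:
                    mat[i, j] = math.sqrt(max(0.0, 1.0 - 1.0 / rho**2))
        return mat

    if u == t + 1:
        prod = adjacent_matrix(t)
    else:
        # (t,u) = (t,t+1)...(u-2,u-1) (u-1,u) (u-2,u-1)...(t,t+1)
        wings = [adjacent_matrix(k) for k in range(t, u - 1)]
        prod = adjacent_matrix(u - 1)
        for w in reversed(wings):
            prod = w @ prod @ w
    our = tuple(spins[lo - 1 : hi + 1])
    return float(prod[index[our], index[our]])


def coupling_matrix_element(
    csf: CSF | SpinCouplingPattern, t: int, u: int
) -> float:
    """``<Phi| E_u^t E_t^u |Phi>`` for SOMO slots ``t != u`` (1-based).

    Evaluated directly in the spin-coupling basis (no determinant expansion)
    through the Dirac identity ``E_u^t E_t^u = 1 - P_tu`` valid for two
    singly occupied orbitals, where ``P_tu`` exchanges the two spins.  The
    result is independent of the spin projection M and identical for every
    slot pair drawn from the same pair of open shells.
    """
    pattern = csf.pattern if isinstance(csf, CSF) else csf
    n = pattern.n_somo
    for slot in (t, u):
        if not 1 <= slot <= n:
            raise IndexError(f"SOMO slot {slot} out of range 1..{n}")
    if t == u:
        raise ValueError("coupling matrix element requires two distinct SOMO slots")
    if t > u:
        t, u = u, t
    return 1.0 - _transposition_expectation(pattern, t, u)


def spin_spin_correlation(
    csf: CSF | SpinCouplingPattern, t: int, u: int
) -> float:
    """``<S_t . S_u>`` for two SOMO slots (from ``P_tu = 2 S_t.S_u + 1/2``)."""
    pattern = csf.pattern if isinstance(csf, CSF) else csf
    if t > u:
        t, u = u, t
    return 0.5 * (_transposition_expectation(pattern, t, u) - 0.5)


# ---------------------------------------------------------------------------
# Vector-coupling coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VectorCouplingTable:
    """Coulomb/exchange vector-coupling coefficients for one CSF.

    ``a``/``b`` are symmetric ``n_shells x n_shells`` matrices over the open
    shells; ``alpha``/``beta`` are ``(n_shells+1) x (n_shells+1)`` with the
    closed shell at index 0, defined so that the shell Fock operator reads
    ``F^I = h + J[A^I] - K[B^I]`` with the special densities
    ``A^I = sum_J alpha^IJ D^J`` and ``B^I = sum_J beta^IJ D^J``:
    ``alpha^IJ = n^J a^IJ`` and ``beta^IJ = (n^J/2) b^IJ`` with per-orbital
    occupations ``n^J`` (2 for closed, 1 for every open shell).
    """

    pattern: SpinCouplingPattern
    partition: ShellPartition
    a: np.ndarray
    b: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    occupations: tuple[int, ...]  # per shell, closed first: (2, 1, 1, ...)
    elements: np.ndarray  # <E E> per open-shell pair (diagnostic)

    @property
    def n_shells(self) -> int:
        return self.a.shape[0]

    def off_diagonal_b(self) -> list[float]:
        """b^IJ for shell pairs (1,2), (1,3), ..., (2,3), ... in row order."""
        n = self.n_shells
        return [float(self.b[i, j]) for i in range(n) for j in range(i + 1, n)]


def closed_shell_table() -> VectorCouplingTable:
    """Degenerate coupling table for a system with no unpaired electrons."""
    return VectorCouplingTable(
        pattern=None,  # type: ignore[arg-type]
        partition=None,  # type: ignore[arg-type]
        a=np.zeros((0, 0)),
        b=np.zeros((0, 0)),
        alpha=np.array([[2.0]]),
        beta=np.array([[1.0]]),
        occupations=(2,),
        elements=np.zeros((0, 0)),
    )


def vector_coupling_coefficients(
    pattern: SpinCouplingPattern, rtol: float = 1e-9
) -> VectorCouplingTable:
    """Derive the a^IJ/b^IJ (and alpha/beta) coefficient matrices.

    For every pair of open shells the coupling matrix element is evaluated
    for *all* spanning SOMO pairs and verified to be constant (this is a
    theorem of the shell partition, asserted here rather than assumed); then

        b^IJ = 2 - 2 <Phi| E_u^t E_t^u |Phi>,   a^IJ = 1.

    Within a shell the parallel-coupled element vanishes, so the same formula
    gives the diagonal convention a^II = 1, b^II = 2 (single-orbital shells
    carry the same, vacuous, values).  The Coulomb coefficients are unity
    because every determinant of the CSF has unit SOMO occupations.
    """
    part = shell_partition(pattern)
    n = part.n_shells
    a = np.ones((n, n))
    b = np.full((n, n), 2.0)
    elements = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pairs = [
                (t, u)
                for t in part.shells[i].slots
                for u in part.shells[j].slots
                if t < u
            ]
            if not pairs:
                continue  # single-orbital diagonal shell: vacuous
            vals = [coupling_matrix_element(pattern, t, u) for t, u in pairs]
            ref = vals[0]
            spread = max(abs(v - ref) for v in vals)
            if spread > rtol * max(1.0, abs(ref)):
                raise AssertionError(
                    f"coupling element not constant over shell pair ({i+1},{j+1}) "
                    f"of pattern {pattern}: spread {spread:.3e}"
                )
            elements[i, j] = elements[j, i] = ref
            b[i, j] = b[j, i] = 2.0 - 2.0 * ref
    occ = (2,) + (1,) * n
    alpha = np.ones((n + 1, n + 1))
    beta = np.ones((n + 1, n + 1))
    alpha[:, 0] = 2.0  # closed-shell column: n^C a^IC = 2
    beta[:, 0] = 1.0   # n^C/2 b^IC = 1
    alpha[:, 1:] = 1.0  # n^J a^IJ = 1 for open J
    beta[0, 1:] = 0.5  # closed row vs open shells: b^CI = 1 -> 1/2
    beta[1:, 1:] = 0.5 * b
    return VectorCouplingTable(pattern, part, a, b, alpha, beta, occ, elements)
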