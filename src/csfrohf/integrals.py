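"""One- and two-electron integrals behind a single backend-agnostic contract.

Three interchangeable sources produce an :class:`IntegralSet`:

* :func:`read_fcidump` — Molpro-style FCIDUMP files (orthonormal basis,
  chemists' notation, 1-based indices, index-0 lines carry the scalar),
* :func:`sgto_integrals` — closed-form integrals over contracted s-type
  Gaussians for an XYZ geometry (enough for hydrogen/helium chains),
* :func:`model_hamiltonian` — synthetic orthonormal-basis Hamiltonians
  (Hubbard chains, or explicit arrays).

Units are bohr and hartree throughout; XYZ files are read as angstrom and
converted.  Two-electron integrals are stored as the full chemists' (pq|rs)
tensor with 8-fold permutational symmetry; Coulomb ``J_pq = (pp|qq)`` and
exchange ``K_pq = (pq|qp)`` are always derived from it, never stored.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import erf

__all__ = [
    "ANGSTROM_PER_BOHR",
    "HARTREE_TO_CM",
    "Geometry",
    "IntegralSet",
    "read_xyz",
    "read_fcidump",
    "write_fcidump",
    "sgto_integrals",
    "builtin_basis",
    "model_hamiltonian",
    "hubbard_chain",
    "hydrogen_chain",
    "ao_to_mo",
]

ANGSTROM_PER_BOHR = 0.52917721092
HARTREE_TO_CM = 219474.6313632

_ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}


@dataclass(frozen=True)
class Geometry:
    """Point nuclei: (symbol, Z, position/bohr) plus total charge."""

    atoms: tuple[tuple[str, int, tuple[float, float, float]], ...]
    total_charge: int = 0

    def __post_init__(self) -> None:
        for sym, z, pos in self.atoms:
            if not (isinstance(z, int) and z > 0):
                raise ValueError(f"nuclear charge of {sym} must be a positive integer")
            if not all(math.isfinite(x) for x in pos):
                raise ValueError(f"non-finite position for {sym}")

    @property
    def n_electrons(self) -> int:
        return sum(z for _, z, _ in self.atoms) - self.total_charge

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i, (_, zi, ri) in enumerate(self.atoms):
            for _, zj, rj in self.atoms[i + 1 :]:
                e += zi * zj / math.dist(ri, rj)
        return e


def read_xyz(path: str | Path, total_charge: int = 0) -> Geometry:
    """Read an XYZ file (angstrom) into a Geometry (bohr)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"XYZ file {path}: first line must be the atom count")
    atoms = []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        sym = parts[0].capitalize()
        if sym not in _ELEMENTS:
            raise ValueError(f"unknown element {sym!r} in {path}")
        xyz = tuple(float(x) / ANGSTROM_PER_BOHR for x in parts[1:4])
        atoms.append((sym, _ELEMENTS[sym], xyz))
    if len(atoms) != n:
        raise ValueError(f"XYZ file {path}: expected {n} atoms, found {len(atoms)}")
    return Geometry(tuple(atoms), total_charge)


# ---------------------------------------------------------------------------
# IntegralSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegralSet:
    """AO/orthonormal-basis integrals (hartree, chemists' notation)."""

    n_basis: int
    overlap: np.ndarray
    h_core: np.ndarray
    eri: np.ndarray  # (pq|rs), full n^4 storage
    e_nuclear: float
    n_electrons: int

    def __post_init__(self) -> None:
        n = self.n_basis
        if self.overlap.shape != (n, n) or self.h_core.shape != (n, n):
            raise ValueError("overlap/h_core shape mismatch with n_basis")
        if self.eri.shape != (n, n, n, n):
            raise ValueError("eri shape mismatch with n_basis")
        if not np.allclose(self.h_core, self.h_core.T, atol=1e-10):
            raise ValueError("h_core must be symmetric")
        if np.linalg.eigvalsh(self.overlap).min() <= 0:
            raise ValueError("overlap matrix must be positive definite")

    @property
    def orthonormal(self) -> bool:
        return bool(np.allclose(self.overlap, np.eye(self.n_basis), atol=1e-10))

    def coulomb(self) -> np.ndarray:
        """J_pq = (pp|qq)."""
        return np.einsum("ppqq->pq", self.eri)

    def exchange(self) -> np.ndarray:
        """K_pq = (pq|qp)."""
        return np.einsum("pqqp->pq", self.eri)

    def check_eri_symmetry(self, atol: float = 1e-10) -> None:
        e = self.eri
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            if not np.allclose(e, e.transpose(perm), atol=atol):
                raise ValueError(f"eri violates permutational symmetry {perm}")


# ---------------------------------------------------------------------------
# FCIDUMP
# ---------------------------------------------------------------------------

def _expand_eri(eri: np.ndarray, p: int, q: int, r: int, s: int, v: float) -> None:
    for a, b, c, d in {
        (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
        (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
    }:
        eri[a, b, c, d] = v


def read_fcidump(path: str | Path) -> IntegralSet:
    """Read a Molpro-style FCIDUMP file (free-format namelist header)."""
    text = Path(path).read_text()
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, re.S | re.I)
    if not m:
        raise ValueError(f"{path}: missing &FCI ... &END header")
    header = m.group(1)
    fields = {}
    for key, val in re.findall(r"([A-Za-z0-9_]+)\s*=\s*([^=]+?)(?=[,\s]+[A-Za-z0-9_]+\s*=|$)", header):
        fields[key.upper()] = val.strip().rstrip(",")
    for req in ("NORB", "NELEC", "MS2"):
        if req not in fields:
            raise ValueError(f"{path}: FCIDUMP header missing {req}")
    norb = int(fields["NORB"])
    nelec = int(fields["NELEC"])
    h = np.zeros((norb, norb))
    eri = np.zeros((norb, norb, norb, norb))
    e_nuc = 0.0
    seen: dict[tuple[int, int, int, int], float] = {}
    body = text[m.end():]
    for ln in body.splitlines():
        parts = ln.split()
        if not parts:
            continue
        v = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:5])
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise ValueError(f"{path}: orbital index {idx} out of range 1..{norb}")
        key = (i, j, k, l)
        if key in seen and abs(seen[key] - v) > 1e-10:
            raise ValueError(f"{path}: duplicate inconsistent entry for indices {key}")
        seen[key] = v
        if i == 0:
            e_nuc = v
        elif k == 0:
            h[i - 1, j - 1] = h[j - 1, i - 1] = v
        else:
            _expand_eri(eri, i - 1, j - 1, k - 1, l - 1, v)
    return IntegralSet(norb, np.eye(norb), h, eri, e_nuc, nelec)


def write_fcidump(ints: IntegralSet, path: str | Path, ms2: int = 0,
                  threshold: float = 1e-14) -> None:
    """Write an orthonormal-basis IntegralSet as FCIDUMP (unique integrals)."""
    if not ints.orthonormal:
        raise ValueError("FCIDUMP assumes an orthonormal basis; transform first")
    n = ints.n_basis
    lines = [
        f"&FCI NORB={n},NELEC={ints.n_electrons},MS2={ms2},",
        "  ORBSYM=" + ",".join(["1"] * n) + ",",
        "  ISYM=1,",
        "&END",
    ]
    def emit(v, i, j, k, l):
        lines.append(f"{v:23.16e} {i:3d} {j:3d} {k:3d} {l:3d}")
    for p in range(n):
        for q in range(p + 1):
            for r in range(p + 1):
                smax = q if r == p else r
                for s in range(smax + 1):
                    v = ints.eri[p, q, r, s]
                    if abs(v) > threshold:
                        emit(v, p + 1, q + 1, r + 1, s + 1)
    for p in range(n):
        for q in range(p + 1):
            if abs(ints.h_core[p, q]) > threshold:
                emit(ints.h_core[p, q], p + 1, q + 1, 0, 0)
    emit(ints.e_nuclear, 0, 0, 0, 0)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# s-type Gaussian integrals
# ---------------------------------------------------------------------------

def _boys0(x: float) -> float:
    if x < 1e-12:
        return 1.0 - x / 3.0
    return 0.5 * math.sqrt(math.pi / x) * erf(math.sqrt(x))


# built-in s-only basis sets: element -> list of contracted functions,
# each a list of (exponent, contraction coefficient) pairs
_BUILTIN_BASIS: dict[str, dict[str, list[list[tuple[float, float]]]]] = {
    # STO-3G s shells
    "sto-3g": {
        "H": [[(3.42525091, 0.15432897), (0.62391373, 0.53532814),
               (0.16885540, 0.44463454)]],
        "He": [[(6.36242139, 0.15432897), (1.15892300, 0.53532814),
                (0.31364979, 0.44463454)]],
    },
    # simple uncontracted double-zeta s set for H (inner/outer exponents)
    "dz": {
        "H": [[(1.33, 1.0)], [(0.2011, 1.0)]],
    },
}


def builtin_basis(name: str) -> dict[str, list[list[tuple[float, float]]]]:
    try:
        return _BUILTIN_BASIS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown built-in basis {name!r}; available: {sorted(_BUILTIN_BASIS)}"
        )


def sgto_integrals(
    geometry: Geometry,
    basis: str | dict[str, list[list[tuple[float, float]]]],
) -> IntegralSet:
    """Overlap, kinetic, nuclear-attraction and (ss|ss) repulsion integrals.

    Only s-type functions are supported; the closed-form primitive formulas
    with the Boys function F0 are exact for this case.
    """
    if isinstance(basis, str):
        basis = builtin_basis(basis)
    # flatten to normalized primitives per contracted function
    funcs: list[tuple[np.ndarray, list[tuple[float, float]]]] = []
    for sym, z, pos in geometry.atoms:
        if sym not in basis:
            raise ValueError(f"basis has no entry for element {sym} (s-type only)")
        for shell in basis[sym]:
            prims = [(a, c * (2.0 * a / math.pi) ** 0.75) for a, c in shell]
            funcs.append((np.asarray(pos), prims))
    n = len(funcs)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    for i, (ri, pi_) in enumerate(funcs):
        for j, (rj, pj_) in enumerate(funcs):
            if j > i:
                continue
            r2 = float(np.dot(ri - rj, ri - rj))
            s = t = v = 0.0
            for a, ca in pi_:
                for b, cb in pj_:
                    p = a + b
                    mu = a * b / p
                    pre = ca * cb * math.exp(-mu * r2)
                    s00 = pre * (math.pi / p) ** 1.5
                    s += s00
                    t += s00 * mu * (3.0 - 2.0 * mu * r2)
                    rp = (a * ri + b * rj) / p
                    for _, zc, rc in geometry.atoms:
                        pc2 = float(np.dot(rp - np.asarray(rc), rp - np.asarray(rc)))
                        v -= zc * pre * (2.0 * math.pi / p) * _boys0(p * pc2)
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            V[i, j] = V[j, i] = v
    # normalize contracted functions
    norm = 1.0 / np.sqrt(np.diag(S))
    S = S * norm[:, None] * norm[None, :]
    T = T * norm[:, None] * norm[None, :]
    V = V * norm[:, None] * norm[None, :]
    eri = np.zeros((n, n, n, n))
    for i, (ri, pi_) in enumerate(funcs):
        for j in range(i + 1):
            rj, pj_ = funcs[j]
            rij2 = float(np.dot(ri - rj, ri - rj))
            ij = i * (i + 1) // 2 + j
            for k in range(i + 1):
                rk, pk_ = funcs[k]
                for l in range(k + 1):
                    kl = k * (k + 1) // 2 + l
                    if kl > ij:
                        continue
                    rl, pl_ = funcs[l]
                    rkl2 = float(np.dot(rk - rl, rk - rl))
                    val = 0.0
                    for a, ca in pi_:
                        for b, cb in pj_:
                            p = a + b
                            rp = (a * ri + b * rj) / p
                            eab = math.exp(-a * b / p * rij2)
                            for c, cc in pk_:
                                for d, cd in pl_:
                                    q = c + d
                                    rq = (c * rk + d * rl) / q
                                    ecd = math.exp(-c * d / q * rkl2)
                                    pq2 = float(np.dot(rp - rq, rp - rq))
                                    val += (
                                        ca * cb * cc * cd * eab * ecd
                                        * 2.0 * math.pi ** 2.5
                                        / (p * q * math.sqrt(p + q))
                                        * _boys0(p * q / (p + q) * pq2)
                                    )
                    val *= norm[i] * norm[j] * norm[k] * norm[l]
                    _expand_eri(eri, i, j, k, l, val)
    return IntegralSet(
        n, S, T + V, eri, geometry.nuclear_repulsion(), geometry.n_electrons
    )


def hydrogen_chain(
    n_atoms: int, spacing: float = 2.0, basis: str = "sto-3g", charge: int = 0
) -> IntegralSet:
    """Equally spaced linear H chain (spacing in bohr)."""
    atoms = tuple(("H", 1, (0.0, 0.0, k * spacing)) for k in range(n_atoms))
    return sgto_integrals(Geometry(atoms, charge), basis)


# ---------------------------------------------------------------------------
# Model Hamiltonians
# ---------------------------------------------------------------------------

def model_hamiltonian(
    h: np.ndarray,
    eri: np.ndarray,
    e_nuclear: float = 0.0,
    n_electrons: int | None = None,
) -> IntegralSet:
    """Wrap explicit arrays as an orthonormal-basis IntegralSet (validated)."""
    h = np.asarray(h, dtype=float)
    eri = np.asarray(eri, dtype=float)
    n = h.shape[0]
    if h.shape != (n, n):
        raise ValueError("one-electron matrix must be square")
    if eri.shape != (n, n, n, n):
        raise ValueError("two-electron tensor dimension mismatch with h")
    if not np.allclose(h, h.T, atol=1e-10):
        raise ValueError("one-electron matrix must be symmetric")
    ints = IntegralSet(
        n, np.eye(n), h, eri, e_nuclear,
        n if n_electrons is None else n_electrons,
    )
    ints.check_eri_symmetry()
    return ints


def hubbard_chain(
    n_sites: int,
    t: float,
    u: float,
    n_electrons: int | None = None,
    periodic: bool = False,
) -> IntegralSet:
    """Hubbard chain: hopping -t on bonds, on-site repulsion U = (pp|pp)."""
    h = np.zeros((n_sites, n_sites))
    for i in range(n_sites - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    if periodic and n_sites > 2:
        h[0, -1] = h[-1, 0] = -t
    eri = np.zeros((n_sites,) * 4)
    for i in range(n_sites):
        eri[i, i, i, i] = u
    return model_hamiltonian(h, eri, 0.0, n_electrons)


# ---------------------------------------------------------------------------
# Basis transformation
# ---------------------------------------------------------------------------

def ao_to_mo(ints: IntegralSet, C: np.ndarray, tol: float = 1e-8) -> IntegralSet:
    """Transform to the MO basis of coefficients C (overlap-orthonormal)."""
    C = np.asarray(C, dtype=float)
    gram = C.T @ ints.overlap @ C
    if not np.allclose(gram, np.eye(C.shape[1]), atol=tol):
        raise ValueError("orbital coefficients are not orthonormal under the overlap")
    h = C.T @ ints.h_core @ C
    eri = np.einsum("pqrs,pi,qj,rk,sl->ijkl", ints.eri, C, C, C, C, optimize=True)
    m = C.shape[1]
    return IntegralSet(m, np.eye(m), h, eri, ints.e_nuclear, ints.n_electrons)
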