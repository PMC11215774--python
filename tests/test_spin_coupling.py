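"""Genealogical CSF construction, coupling elements, coefficient tables."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csfrohf.detci import coupling_element_brute, spin_squared_expectation, csf_vector
from csfrohf.spin_coupling import (
    EmptyPatternError,
    FirstSpinDownError,
    IllegalCharacterError,
    NegativeIntermediateSpinError,
    closed_shell_table,
    coupling_matrix_element,
    determinant_expansion,
    enumerate_patterns,
    parse_pattern,
    shell_partition,
    spin_spin_correlation,
    vector_coupling_coefficients,
    weyl_count,
)

HALF = Fraction(1, 2)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, n, total, spins",
    [
        ("+-", 2, 0, (HALF, 0)),
        ("++-", 3, HALF, (HALF, 1, HALF)),
        ("[+ -]", 2, 0, (HALF, 0)),
        ("+ + - + +", 5, Fraction(3, 2), (HALF, 1, HALF, 1, Fraction(3, 2))),
    ],
)
def test_parse_valid_patterns(text, n, total, spins):
    p = parse_pattern(text)
    assert p.n_somo == n
    assert p.total_spin == total
    assert p.intermediate_spins == spins


@pytest.mark.parametrize(
    "text, exc",
    [
        ("", EmptyPatternError),
        ("   ", EmptyPatternError),
        ("+x-", IllegalCharacterError),
        ("-+", FirstSpinDownError),
        ("+--", NegativeIntermediateSpinError),
        ("+-+--", NegativeIntermediateSpinError),
    ],
)
def test_parse_rejects_invalid_patterns(text, exc):
    with pytest.raises(exc):
        parse_pattern(text)


def test_total_spin_is_sign_balance():
    for n in range(1, 7):
        for p in enumerate_patterns(n):
            plus = sum(1 for s in p.signs if s > 0)
            assert p.total_spin == Fraction(plus - (n - plus), 2)
            assert all(s >= 0 for s in p.intermediate_spins)


# ---------------------------------------------------------------------------
# shell partition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, n_shells, sizes",
    [
        ("+++++", 1, [5]),
        ("+-+-+", 5, [1] * 5),
        ("+", 1, [1]),
        ("++-", 2, [2, 1]),
        ("++-++", 3, [2, 1, 2]),
    ],
)
def test_shell_partition_maximal_runs(text, n_shells, sizes):
    part = shell_partition(parse_pattern(text))
    assert part.n_shells == n_shells
    assert [sh.size for sh in part.shells] == sizes
    # concatenation reproduces the pattern
    flat = [sh.sign for sh in part.shells for _ in sh.slots]
    assert tuple(flat) == part.pattern.signs


# ---------------------------------------------------------------------------
# determinant expansion
# ---------------------------------------------------------------------------

def test_two_electron_expansions():
    singlet = determinant_expansion(parse_pattern("+-"), 0).as_dict()
    assert singlet["ab"] == pytest.approx(1 / math.sqrt(2))
    assert singlet["ba"] == pytest.approx(-1 / math.sqrt(2))
    triplet = determinant_expansion(parse_pattern("++"), 1).as_dict()
    assert triplet == {"aa": pytest.approx(1.0)}


def test_three_electron_doublet_expansion():
    got = determinant_expansion(parse_pattern("++-"), HALF).as_dict()
    want = {
        "aab": math.sqrt(2 / 3),
        "aba": -math.sqrt(1 / 6),
        "baa": -math.sqrt(1 / 6),
    }
    sign = math.copysign(1.0, got["aab"])
    for k, v in want.items():
        assert got[k] == pytest.approx(sign * v, abs=1e-12)


def sympy_expansion(pattern, M):
    """Independent Clebsch-Gordan recursion oracle (sympy)."""
    from sympy import Rational
    from sympy.physics.quantum.cg import CG

    n = pattern.n_somo
    out = {}
    n_alpha = int(Fraction(n, 2) + M)
    for alphas in itertools.combinations(range(n), n_alpha):
        ms = [Rational(1, 2) if k in alphas else Rational(-1, 2) for k in range(n)]
        coeff, mrun, sprev = 1, 0, 0
        for k in range(n):
            mrun += ms[k]
            coeff *= CG(
                Rational(sprev), Rational(mrun - ms[k]),
                Rational(1, 2), ms[k],
                Rational(pattern.intermediate_spins[k]), Rational(mrun),
            ).doit()
            sprev = pattern.intermediate_spins[k]
        c = float(coeff)
        if abs(c) > 1e-14:
            out["".join("a" if m > 0 else "b" for m in ms)] = c
    return out


def test_expansion_matches_clebsch_gordan_oracle():
    for n in range(1, 5):
        for p in enumerate_patterns(n):
            M = p.total_spin
            while M >= -p.total_spin:
                mine = determinant_expansion(p, M).as_dict()
                ref = sympy_expansion(p, M)
                assert set(mine) == set(ref)
                for k in ref:
                    assert mine[k] == pytest.approx(ref[k], abs=1e-12)
                M -= 1


def test_expansion_invariants_norm_projection_spin():
    for n in range(2, 7):
        for p in enumerate_patterns(n):
            exp = determinant_expansion(p)
            coeffs = np.array([c for _, c in exp.terms])
            assert np.sum(coeffs**2) == pytest.approx(1.0, abs=1e-12)
            for s, _ in exp.terms:
                m = Fraction(s.count("a") - s.count("b"), 2)
                assert m == exp.spin_projection
            # eigenfunction of S^2 with eigenvalue S(S+1)
            dets = []
            for s, _ in exp.terms:
                am = sum(1 << k for k, ch in enumerate(s) if ch == "a")
                bm = sum(1 << k for k, ch in enumerate(s) if ch == "b")
                dets.append((am, bm))
            vec = csf_vector(dets, n, tuple(range(n)), p, (), p.total_spin)
            s2 = spin_squared_expectation(vec, dets)
            S = float(p.total_spin)
            assert s2 == pytest.approx(S * (S + 1), abs=1e-10)


def test_expansion_rejects_overlarge_projection():
    with pytest.raises(ValueError):
        determinant_expansion(parse_pattern("+-"), 1)


# ---------------------------------------------------------------------------
# coupling matrix elements
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, pair, value",
    [
        ("+-", (1, 2), 2.0),
        ("++-", (1, 3), 1.5),
        ("++-", (2, 3), 1.5),
        ("+-+", (1, 2), 2.0),
        ("+-+", (1, 3), 0.5),
        ("+-+", (2, 3), 0.5),
        ("++", (1, 2), 0.0),
    ],
)
def test_coupling_elements_reference_values(text, pair, value):
    assert coupling_matrix_element(parse_pattern(text), *pair) == pytest.approx(
        value, abs=1e-12
    )


def test_coupling_element_argument_errors():
    p = parse_pattern("++-")
    with pytest.raises(ValueError):
        coupling_matrix_element(p, 2, 2)
    with pytest.raises(IndexError):
        coupling_matrix_element(p, 1, 4)


def test_coupling_elements_match_determinant_oracle():
    """Direct path-basis evaluation == brute-force second quantization."""
    for n in range(2, 8):
        for p in enumerate_patterns(n):
            for t, u in itertools.combinations(range(1, n + 1), 2):
                direct = coupling_matrix_element(p, t, u)
                brute = coupling_element_brute(p, t, u)
                assert direct == pytest.approx(brute, abs=1e-11), (str(p), t, u)


def test_coupling_elements_projection_independent():
    for text in ["++", "+++-", "++-+-", "+++++-"]:
        p = parse_pattern(text)
        n, S = p.n_somo, p.total_spin
        for t, u in [(1, n), (1, 2)]:
            vals = {
                coupling_element_brute(p, t, u, M)
                for M in np.arange(float(-S), float(S) + 0.5, 1.0)
            }
            assert max(vals) - min(vals) < 1e-11


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.sampled_from([1, -1]), min_size=2, max_size=8))
def test_shell_constancy_property(signs):
    """All slot pairs spanning one shell pair give the same element."""
    s = 0
    for sg in signs:
        s += sg
        if s < 0:
            return  # invalid path; property vacuous
    p = parse_pattern("".join("+" if x > 0 else "-" for x in signs))
    part = shell_partition(p)
    for i in range(part.n_shells):
        for j in range(i, part.n_shells):
            vals = [
                coupling_matrix_element(p, t, u)
                for t in part.shells[i].slots
                for u in part.shells[j].slots
                if t < u
            ]
            if vals:
                assert max(vals) - min(vals) < 1e-11


def test_spin_correlation_identity():
    """b^IJ = 1 + 4 <S_t . S_u> for representative slots (second oracle)."""
    for n in range(2, 7):
        for p in enumerate_patterns(n):
            part = shell_partition(p)
            vct = vector_coupling_coefficients(p)
            for i in range(part.n_shells):
                for j in range(i + 1, part.n_shells):
                    t = part.shells[i].slots[0]
                    u = part.shells[j].slots[0]
                    corr = spin_spin_correlation(p, t, u)
                    assert vct.b[i, j] == pytest.approx(1 + 4 * corr, abs=1e-11)


def test_weyl_branching_counts():
    assert weyl_count(5, Fraction(3, 2)) == 4
    assert weyl_count(5, HALF) == 5
    for n in range(1, 9):
        total = 0
        S = Fraction(n % 2, 2)
        while S <= Fraction(n, 2):
            cnt = len(list(enumerate_patterns(n, S)))
            assert cnt == weyl_count(n, S)
            total += cnt
            S += 1
        assert total == len(list(enumerate_patterns(n)))


# ---------------------------------------------------------------------------
# vector-coupling tables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, b_offdiag",
    [
        ("+-", [-2.0]),
        ("++-", [-1.0]),
        ("+-+", [-2.0, 1.0, 1.0]),
    ],
)
def test_vector_coupling_b_reference_rows(text, b_offdiag):
    vct = vector_coupling_coefficients(parse_pattern(text))
    assert vct.off_diagonal_b() == pytest.approx(b_offdiag, abs=1e-12)


def test_vector_coupling_table_structure():
    vct = vector_coupling_coefficients(parse_pattern("++-+-"))
    n = vct.n_shells
    assert np.allclose(vct.a, np.ones((n, n)))
    assert np.allclose(vct.b, vct.b.T)
    assert np.allclose(np.diag(vct.b), 2.0)  # parallel-pair value
    # alpha/beta consistency with a/b and occupations (closed index 0)
    assert np.allclose(vct.alpha[:, 0], 2.0)
    assert np.allclose(vct.beta[1:, 0], 1.0)
    assert np.allclose(vct.alpha[1:, 1:], vct.a)
    assert np.allclose(vct.beta[1:, 1:], 0.5 * vct.b)
    assert vct.occupations == (2,) + (1,) * n
    # b derived from the coupling elements
    assert np.allclose(vct.b, 2.0 - 2.0 * vct.elements)


def test_high_spin_patterns_single_shell_b_two():
    for n in (2, 3, 5, 7):
        vct = vector_coupling_coefficients(parse_pattern("+" * n))
        assert vct.n_shells == 1
        assert vct.b[0, 0] == pytest.approx(2.0, abs=1e-12)


def test_closed_shell_table_degenerate():
    t = closed_shell_table()
    assert t.n_shells == 0
    assert t.alpha.tolist() == [[2.0]]
    assert t.beta.tolist() == [[1.0]]
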