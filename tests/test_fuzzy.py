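"""Algebra of interval-valued orthopair fuzzy numbers."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import ivffmcdm as m
from ivffmcdm.fuzzy import TOL

from conftest import random_valid_ivofn

CBRT = lambda x: x ** (1.0 / 3.0)

FULL = m.IVOFN(1, 1, 0, 0)     # complete membership
EMPTY = m.IVOFN(0, 0, 1, 1)    # complete non-membership
BLANK = m.IVOFN(0, 0, 0, 0)    # total hesitation


# -- strategies -------------------------------------------------------------

@st.composite
def valid_ivofns(draw, q=None):
    if q is None:
        q = draw(st.sampled_from([1, 2, 3]))
    mu_high = draw(st.floats(0, 1, allow_nan=False))
    nu_cap = (1.0 - mu_high**q) ** (1.0 / q)
    nu_high = draw(st.floats(0, 0.999)) * nu_cap
    mu_low = draw(st.floats(0, 1)) * mu_high
    nu_low = draw(st.floats(0, 1)) * nu_high
    return m.IVOFN(mu_low, mu_high, nu_low, nu_high, q)


@st.composite
def valid_ivofn_pairs(draw):
    q = draw(st.sampled_from([1, 2, 3]))
    return draw(valid_ivofns(q=q)), draw(valid_ivofns(q=q))


# -- validation -------------------------------------------------------------

@pytest.mark.parametrize(
    "f, expected",
    [
        (m.IVOFN(0.6, 0.7, 0.5, 0.6), True),      # 0.343 + 0.216 <= 1
        (m.IVOFN(0.9, 0.95, 0.8, 0.9), False),    # 0.857 + 0.729 > 1
        (m.IVOFN(0.5, 0.4, 0.0, 0.0), False),     # interval order violated
        (m.IVOFN(0.0, 0.0, 0.6, 0.5), False),
        (m.IVOFN(0.9, 0.95, 0.8, 0.9, q=10), True),  # feasible at a high rung
        (m.IVOFN(0.6, 0.7, 0.5, 0.6, q=1), False),   # infeasible at q=1
    ],
)
def test_validate(f, expected):
    assert m.validate(f) is expected


def test_operations_reject_invalid_inputs():
    bad = m.IVOFN(0.9, 0.95, 0.8, 0.9)
    good = m.IVOFN(0.5, 0.6, 0.3, 0.4)
    for op in (lambda: m.add(bad, good), lambda: bad.score(),
               lambda: bad.hesitation(), lambda: m.power(bad, 2.0)):
        with pytest.raises(m.FuzzyValidationError):
            op()


def test_mixed_rungs_are_rejected():
    f1 = m.IVOFN(0.5, 0.6, 0.3, 0.4, q=3)
    f2 = m.IVOFN(0.5, 0.6, 0.3, 0.4, q=2)
    with pytest.raises(m.FuzzyValidationError):
        m.add(f1, f2)
    with pytest.raises(m.FuzzyValidationError):
        m.ivffwa([f1, f2], m.DMWeights.equal(2))


# -- hesitation and score ---------------------------------------------------

@pytest.mark.parametrize(
    "f, lo, hi",
    [
        (FULL, 0.0, 0.0),
        (BLANK, 1.0, 1.0),
        # direct numeric evaluation of the complement roots
        (m.IVOFN(0.6, 0.7, 0.5, 0.6),
         CBRT(1 - 0.7**3 - 0.6**3), CBRT(1 - 0.6**3 - 0.5**3)),
    ],
)
def test_hesitation_examples(f, lo, hi):
    h = f.hesitation()
    assert h.pi_low == pytest.approx(lo, abs=1e-12)
    assert h.pi_high == pytest.approx(hi, abs=1e-12)


@pytest.mark.parametrize(
    "f, expected",
    [
        (FULL, 1.0),
        (EMPTY, -1.0),
        (m.IVOFN(0.3, 0.3, 0.3, 0.3), 0.0),   # symmetric number scores zero
        (m.IVOFN(0.7, 0.7, 0.7, 0.7, q=5), 0.0),
    ],
)
def test_score_examples(f, expected):
    assert f.score() == pytest.approx(expected, abs=1e-12)


@given(valid_ivofns())
def test_score_antisymmetric_under_membership_swap(f):
    swapped = m.IVOFN(f.nu_low, f.nu_high, f.mu_low, f.mu_high, f.q)
    if swapped.is_valid():
        assert swapped.score() == pytest.approx(-f.score(), abs=1e-9)


@given(valid_ivofns())
def test_hesitation_partition_identity(f):
    """mu^q + nu^q + pi^q = 1 at matched (upper/lower, lower/upper) bounds."""
    h = f.hesitation()
    q = f.q
    assert f.mu_high**q + f.nu_high**q + h.pi_low**q == pytest.approx(1.0, abs=1e-9)
    assert f.mu_low**q + f.nu_low**q + h.pi_high**q == pytest.approx(1.0, abs=1e-9)


# -- arithmetic -------------------------------------------------------------

def approx_equal(f1, f2, tol=1e-9):
    return (
        f1.q == f2.q
        and math.isclose(f1.mu_low, f2.mu_low, abs_tol=tol)
        and math.isclose(f1.mu_high, f2.mu_high, abs_tol=tol)
        and math.isclose(f1.nu_low, f2.nu_low, abs_tol=tol)
        and math.isclose(f1.nu_high, f2.nu_high, abs_tol=tol)
    )


def test_additive_and_multiplicative_identities():
    f = m.IVOFN(0.5, 0.6, 0.4, 0.5)
    assert approx_equal(m.add(f, EMPTY), f)
    assert approx_equal(m.multiply(f, FULL), f)
    assert approx_equal(m.scalar_multiply(1.0, f), f)
    assert approx_equal(m.power(f, 1.0), f)


def test_add_numeric_case_matches_formula():
    """Frozen spelled-out evaluation of the q-root sum formula."""
    f = m.IVOFN(0.5, 0.6, 0.4, 0.5)
    out = m.add(f, f)
    assert out.mu_low == pytest.approx(CBRT(0.125 + 0.125 - 0.125 * 0.125))
    assert out.mu_high == pytest.approx(CBRT(0.216 + 0.216 - 0.216 * 0.216))
    assert out.nu_low == pytest.approx(0.16)
    assert out.nu_high == pytest.approx(0.25)


def test_multiply_numeric_case_matches_formula():
    f1 = m.IVOFN(0.5, 0.6, 0.4, 0.5)
    f2 = m.IVOFN(0.3, 0.4, 0.6, 0.7)
    out = m.multiply(f1, f2)
    assert out.mu_low == pytest.approx(0.15)
    assert out.mu_high == pytest.approx(0.24)
    assert out.nu_low == pytest.approx(CBRT(0.4**3 + 0.6**3 - 0.4**3 * 0.6**3))
    assert out.nu_high == pytest.approx(CBRT(0.5**3 + 0.7**3 - 0.5**3 * 0.7**3))


def test_scalar_half_numeric_case():
    f = m.IVOFN(0.5, 0.6, 0.4, 0.5)
    out = m.scalar_multiply(0.5, f)
    assert out.mu_low == pytest.approx(CBRT(1 - (1 - 0.125) ** 0.5))
    assert out.nu_low == pytest.approx(0.4**0.5)


@given(valid_ivofn_pairs())
def test_add_multiply_commute(pair):
    f1, f2 = pair
    assert approx_equal(m.add(f1, f2), m.add(f2, f1))
    assert approx_equal(m.multiply(f1, f2), m.multiply(f2, f1))


@given(valid_ivofns())
def test_scalar_two_equals_self_sum_and_square_equals_self_product(f):
    # 1e-6 absolute: near-zero endpoints lose precision in (1-(1-x^q)^2)^(1/q)
    assert approx_equal(m.scalar_multiply(2.0, f), m.add(f, f), tol=1e-6)
    assert approx_equal(m.power(f, 2.0), m.multiply(f, f), tol=1e-6)


@given(valid_ivofn_pairs(), st.floats(0.1, 5.0))
def test_closure(pair, lam):
    f1, f2 = pair
    for out in (m.add(f1, f2), m.multiply(f1, f2),
                m.scalar_multiply(lam, f1), m.power(f1, lam)):
        assert out.is_valid()


# -- aggregation ------------------------------------------------------------

def test_ivffwa_idempotent_and_selective(rng):
    f = random_valid_ivofn(rng)
    w = m.DMWeights([0.2, 0.5, 0.3])
    assert approx_equal(m.ivffwa([f, f, f], w), f)
    g = random_valid_ivofn(rng)
    sel = m.DMWeights([1.0, 0.0])
    assert approx_equal(m.ivffwa([f, g], sel), f)
    # canonical form shares both properties
    assert approx_equal(m.ivffwa([f, f, f], w, form="canonical"), f, tol=1e-8)
    assert approx_equal(m.ivffwa([f, g], sel, form="canonical"), f, tol=1e-8)


def test_ivffwa_equal_weights_are_endpoint_means():
    fs = [m.IVOFN(0.1, 0.2, 0.6, 0.7), m.IVOFN(0.4, 0.5, 0.3, 0.4),
          m.IVOFN(0.7, 0.8, 0.1, 0.2)]
    out = m.ivffwa(fs, m.DMWeights.equal(3))
    assert out.mu_low == pytest.approx((0.1 + 0.4 + 0.7) / 3)
    assert out.mu_high == pytest.approx((0.2 + 0.5 + 0.8) / 3)
    assert out.nu_low == pytest.approx((0.6 + 0.3 + 0.1) / 3)
    assert out.nu_high == pytest.approx((0.7 + 0.4 + 0.2) / 3)


def test_ivffwa_output_within_input_envelope(rng):
    for q in (1, 2, 3):
        fs = [random_valid_ivofn(rng, q) for _ in range(4)]
        raw = rng.uniform(0.05, 1.0, size=4)
        w = m.DMWeights(raw / raw.sum())
        out = m.ivffwa(fs, w)
        for attr in ("mu_low", "mu_high", "nu_low", "nu_high"):
            vals = [getattr(f, attr) for f in fs]
            assert min(vals) - TOL <= getattr(out, attr) <= max(vals) + TOL
        assert out.is_valid()


def test_ivffwa_contract_errors():
    f = m.IVOFN(0.5, 0.6, 0.3, 0.4)
    with pytest.raises(m.FuzzyValidationError):
        m.ivffwa([f, f], m.DMWeights.equal(3))
    with pytest.raises(m.FuzzyValidationError):
        m.DMWeights([0.5, 0.6])
    with pytest.raises(m.FuzzyValidationError):
        m.DMWeights([1.2, -0.2])


def test_json_round_trip():
    f = m.IVOFN(0.123456, 0.2, 0.3, 0.654321)
    assert m.IVOFN.from_json(f.to_json()) == f
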