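"""Interval-valued orthopair fuzzy number algebra.

An interval-valued orthopair fuzzy number (IVOFN) carries a membership
interval ``[mu_low, mu_high]`` and a non-membership interval
``[nu_low, nu_high]``, both inside ``[0, 1]``, subject to the rung
constraint ``mu_high**q + nu_high**q <= 1``.  The rung exponent ``q``
selects the family: ``q=1`` intuitionistic, ``q=2`` Pythagorean and
``q=3`` Fermatean, which is the default used throughout this package.

The residual indeterminacy (hesitation) of an IVOFN is itself an
interval, obtained from the complement of the rung powers, and the score
function ``SF(f) = (mu_low**q + mu_high**q - nu_low**q - nu_high**q)/2``
defuzzifies a number to a crisp value in ``[-1, 1]``.

Arithmetic (``add``/``multiply``/``scalar_multiply``/``power``) follows
the standard algebraic t-norm/t-conorm operations of the q-rung orthopair
calculus.  Group aggregation uses :func:`ivffwa`; its default form is an
endpoint-wise weighted arithmetic mean (the form used by the decision
pipeline in this package), with the canonical power-mean form available
behind ``form="canonical"`` for cross-checking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Absolute tolerance used by every invariant check in the package.
TOL = 1e-9


class FuzzyValidationError(ValueError):
    """Raised when a fuzzy number or weight vector violates an invariant."""


def _qroot(x: float, q: int) -> float:
    """Sign-safe q-th root: arguments are clamped to [0, 1] before rooting."""
    if x < 0.0:
        x = 0.0
    elif x > 1.0:
        x = 1.0
    return x ** (1.0 / q)


@dataclass(frozen=True)
class HesitationInterval:
    """Hesitation (indeterminacy) interval ``[pi_low, pi_high]``."""

    pi_low: float
    pi_high: float

    def __post_init__(self) -> None:
        if self.pi_low > self.pi_high + TOL:
            raise FuzzyValidationError(
                f"hesitation interval order violated: {self.pi_low} > {self.pi_high}"
            )


@dataclass(frozen=True)
class IVOFN:
    """Interval-valued q-rung orthopair fuzzy number.

    Parameters
    ----------
    mu_low, mu_high
        Endpoints of the membership interval.
    nu_low, nu_high
        Endpoints of the non-membership interval.
    q
        Rung exponent (>= 1). ``q=3`` is the Fermatean case.
    """

    mu_low: float
    mu_high: float
    nu_low: float
    nu_high: float
    q: int = 3

    # -- predicates ---------------------------------------------------------

    def is_valid(self) -> bool:
        """True iff all structural invariants hold for this number's own q."""
        if self.q < 1 or int(self.q) != self.q:
            return False
        ok_range = all(
            -TOL <= v <= 1.0 + TOL
            for v in (self.mu_low, self.mu_high, self.nu_low, self.nu_high)
        )
        ok_order = (
            self.mu_low <= self.mu_high + TOL and self.nu_low <= self.nu_high + TOL
        )
        ok_rung = self.mu_high**self.q + self.nu_high**self.q <= 1.0 + TOL
        return ok_range and ok_order and ok_rung

    def _require_valid(self) -> None:
        if not self.is_valid():
            raise FuzzyValidationError(f"invalid IVOFN: {self}")

    # -- derived quantities -------------------------------------------------

    def hesitation(self) -> HesitationInterval:
        """Residual indeterminacy interval.

        ``pi_low`` pairs with the upper membership/non-membership bounds
        and ``pi_high`` with the lower ones, so that
        ``mu**q + nu**q + pi**q = 1`` at matched bounds.
        """
        self._require_valid()
        q = self.q
        lo = _qroot(1.0 - self.mu_high**q - self.nu_high**q, q)
        hi = _qroot(1.0 - self.mu_low**q - self.nu_low**q, q)
        return HesitationInterval(lo, hi)

    def score(self) -> float:
        """Score-function defuzzification, in ``[-1, 1]``."""
        self._require_valid()
        q = self.q
        return 0.5 * (
            self.mu_low**q + self.mu_high**q - self.nu_low**q - self.nu_high**q
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu": [self.mu_low, self.mu_high],
            "nu": [self.nu_low, self.nu_high],
            "q": self.q,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IVOFN":
        mu = d["mu"]
        nu = d["nu"]
        return cls(mu[0], mu[1], nu[0], nu[1], int(d.get("q", 3)))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "IVOFN":
        return cls.from_dict(json.loads(s))

    # operator sugar (delegates to the module-level functions)
    def __add__(self, other: "IVOFN") -> "IVOFN":
        return add(self, other)

    def __mul__(self, other):
        if isinstance(other, IVOFN):
            return multiply(self, other)
        return scalar_multiply(float(other), self)

    def __rmul__(self, other):
        return scalar_multiply(float(other), self)

    def __pow__(self, lam: float) -> "IVOFN":
        return power(self, lam)


def validate(f: IVOFN) -> bool:
    """Predicate form of :meth:`IVOFN.is_valid`."""
    return f.is_valid()


def _check_pair(f1: IVOFN, f2: IVOFN) -> None:
    if f1.q != f2.q:
        raise FuzzyValidationError(f"rung mismatch: q={f1.q} vs q={f2.q}")
    f1._require_valid()
    f2._require_valid()


def add(f1: IVOFN, f2: IVOFN) -> IVOFN:
    """Algebraic sum (probabilistic t-conorm on membership)."""
    _check_pair(f1, f2)
    q = f1.q

    def conorm(a: float, b: float) -> float:
        return _qroot(a**q + b**q - (a**q) * (b**q), q)

    return IVOFN(
        conorm(f1.mu_low, f2.mu_low),
        conorm(f1.mu_high, f2.mu_high),
        f1.nu_low * f2.nu_low,
        f1.nu_high * f2.nu_high,
        q,
    )


def multiply(f1: IVOFN, f2: IVOFN) -> IVOFN:
    """Algebraic product (dual of :func:`add`)."""
    _check_pair(f1, f2)
    q = f1.q

    def conorm(a: float, b: float) -> float:
        return _qroot(a**q + b**q - (a**q) * (b**q), q)

    return IVOFN(
        f1.mu_low * f2.mu_low,
        f1.mu_high * f2.mu_high,
        conorm(f1.nu_low, f2.nu_low),
        conorm(f1.nu_high, f2.nu_high),
        q,
    )


def scalar_multiply(lam: float, f: IVOFN) -> IVOFN:
    """Scalar multiple ``lam * f`` for positive real ``lam``."""
    if lam <= 0:
        raise FuzzyValidationError(f"scalar must be positive, got {lam}")
    f._require_valid()
    q = f.q
    return IVOFN(
        _qroot(1.0 - (1.0 - f.mu_low**q) ** lam, q),
        _qroot(1.0 - (1.0 - f.mu_high**q) ** lam, q),
        f.nu_low**lam,
        f.nu_high**lam,
        q,
    )


def power(f: IVOFN, lam: float) -> IVOFN:
    """Power ``f ** lam`` for positive real ``lam`` (dual of scalar multiply)."""
    if lam <= 0:
        raise FuzzyValidationError(f"exponent must be positive, got {lam}")
    f._require_valid()
    q = f.q
    return IVOFN(
        f.mu_low**lam,
        f.mu_high**lam,
        _qroot(1.0 - (1.0 - f.nu_low**q) ** lam, q),
        _qroot(1.0 - (1.0 - f.nu_high**q) ** lam, q),
        q,
    )


@dataclass(frozen=True)
class DMWeights:
    """Decision-maker weight vector: entries in [0, 1] summing to 1."""

    weights: tuple

    def __init__(self, weights: Iterable[float]):
        object.__setattr__(self, "weights", tuple(float(w) for w in weights))
        if not self.weights:
            raise FuzzyValidationError("empty weight vector")
        if any(w < -TOL or w > 1.0 + TOL for w in self.weights):
            raise FuzzyValidationError(f"weights outside [0,1]: {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise FuzzyValidationError(
                f"weights must sum to 1, got {sum(self.weights)}"
            )

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def equal(cls, n: int) -> "DMWeights":
        return cls([1.0 / n] * n)


def ivffwa(
    values: Sequence[IVOFN], w: DMWeights, form: str = "linear"
) -> IVOFN:
    """Weighted average of a collection of IVOFNs.

    ``form="linear"`` (default) averages the four interval endpoints
    arithmetically with the given weights.  ``form="canonical"`` uses the
    power-mean aggregation
    ``mu = (1 - prod (1-mu_i**q)**w_i)**(1/q)``, ``nu = prod nu_i**w_i``,
    which is the textbook weighted-average operator of the q-rung
    orthopair calculus; it is exposed for sensitivity checking.
    """
    values = list(values)
    if len(values) != len(w):
        raise FuzzyValidationError(
            f"{len(values)} values but {len(w)} weights"
        )
    q = values[0].q
    for f in values:
        if f.q != q:
            raise FuzzyValidationError("all aggregated numbers must share q")
        f._require_valid()
    ws = w.weights
    if form == "linear":
        return IVOFN(
            sum(wi * f.mu_low for wi, f in zip(ws, values)),
            sum(wi * f.mu_high for wi, f in zip(ws, values)),
            sum(wi * f.nu_low for wi, f in zip(ws, values)),
            sum(wi * f.nu_high for wi, f in zip(ws, values)),
            q,
        )
    if form == "canonical":
        def agg_mu(endpoint: str) -> float:
            prod = 1.0
            for wi, f in zip(ws, values):
                prod *= (1.0 - getattr(f, endpoint) ** q) ** wi
            return _qroot(1.0 - prod, q)

        def agg_nu(endpoint: str) -> float:
            prod = 1.0
            for wi, f in zip(ws, values):
                prod *= getattr(f, endpoint) ** wi
            return prod

        return IVOFN(
            agg_mu("mu_low"), agg_mu("mu_high"),
            agg_nu("nu_low"), agg_nu("nu_high"), q,
        )
    raise ValueError(f"unknown aggregation form: {form!r}")
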