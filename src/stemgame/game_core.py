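"""Core types for the two-strategy game between cancerous and healthy cells.

The competition between cancerous (C) and healthy (H) cells is modelled as a
2x2 evolutionary game with payoff matrix ``[[a, b], [c, d]]``: ``a`` is the
payoff of C meeting C, ``b`` of C meeting H, ``c`` of H meeting C and ``d``
of H meeting H.  On the simplex ``x + y = 1`` the replicator dynamics depend
on the payoffs only through the reduced parameters ``t1 = c - a`` and
``t2 = b - d``; the interior fixed point of the untreated system sits at
``x3 = t2 / (t1 + t2)``.

The sign of ``t1 + t2`` together with the location of ``x3`` relative to the
unit interval partitions parameter space into six hyperbolic regimes:
A1/A2/A3 (``t1 + t2 > 0``, ``x3`` above one / below zero / interior) and
B1/B2/B3 (``t1 + t2 < 0``, ``x3`` below zero / above one / interior).  The
boundary set (``t1 + t2 = 0``, or ``x3`` exactly 0 or 1) is non-hyperbolic
and labelled DEGENERATE rather than forced into a sub-case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)

__all__ = [
    "Case",
    "CaseLabel",
    "DegenerateCaseError",
    "InvalidInputError",
    "PayoffMatrix",
    "TParams",
    "X3Location",
    "classify_case",
    "derive_t_parameters",
    "interior_equilibrium",
]


class InvalidInputError(ValueError):
    """A user-supplied parameter is outside the model's domain."""


class DegenerateCaseError(ValueError):
    """Requested quantity is undefined on the degenerate boundary t1 + t2 = 0."""


class Case(str, Enum):
    """Dynamical regime of the untreated replicator system."""

    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    B1 = "B1"
    B2 = "B2"
    B3 = "B3"
    DEGENERATE = "DEGENERATE"


class X3Location(str, Enum):
    """Location of the interior fixed point x3 relative to [0, 1]."""

    BELOW_ZERO = "below_zero"
    INTERIOR = "interior"
    ABOVE_ONE = "above_one"
    UNDEFINED = "undefined"


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be a finite real number, got {value!r}")
    return value


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 payoff matrix of the cancerous-vs-healthy cell game.

    Parameters
    ----------
    a : float
        Payoff of a cancerous cell interacting with a cancerous cell.
    b : float
        Payoff of a cancerous cell interacting with a healthy cell.
    c : float
        Payoff of a healthy cell interacting with a cancerous cell.
    d : float
        Payoff of a healthy cell interacting with a healthy cell.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    @classmethod
    def from_t_params(cls, t1: float, t2: float) -> "PayoffMatrix":
        """A canonical payoff matrix realizing the reduced parameters.

        Any matrix with ``c - a = t1`` and ``b - d = t2`` generates identical
        dynamics; this picks ``a = d = 0``, ``b = t2``, ``c = t1``.
        """
        return cls(a=0.0, b=float(t2), c=float(t1), d=0.0)


@dataclass(frozen=True)
class TParams:
    """Reduced game parameters t1 = c − a and t2 = b − d.

    These two differences fully determine the replicator dynamics on the
    simplex; they carry no biological meaning of their own.
    """

    t1: float
    t2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t1", _require_finite("t1", self.t1))
        object.__setattr__(self, "t2", _require_finite("t2", self.t2))

    @property
    def sum(self) -> float:
        """t1 + t2, the leading coefficient of the equilibrium polynomial."""
        return self.t1 + self.t2

    @classmethod
    def from_payoff(cls, payoff: PayoffMatrix) -> "TParams":
        return cls(t1=payoff.c - payoff.a, t2=payoff.b - payoff.d)


@dataclass(frozen=True)
class CaseLabel:
    """Regime classification of a parameter pair.

    ``t_sign_pattern`` records the signs of (t1, t2) actually implied by the
    parameters, since published sub-case sign tables for this taxonomy are
    not always consistent with the x3-location definition used here.
    """

    label: Case
    x3_location: X3Location
    t_sign_pattern: str


def derive_t_parameters(payoff: PayoffMatrix) -> TParams:
    """Map a payoff matrix to the reduced parameters (t1, t2) = (c−a, b−d)."""
    return TParams.from_payoff(payoff)


def interior_equilibrium(t: TParams) -> float:
    """Interior fixed point x3 = t2 / (t1 + t2) of the untreated system.

    The value may lie outside [0, 1]; tracking it there still explains the
    trajectories inside the unit interval.

    Raises
    ------
    DegenerateCaseError
        If t1 + t2 = 0, where the cubic degenerates and x3 is undefined.
    """
    if t.sum == 0.0:
        raise DegenerateCaseError(
            "interior equilibrium x3 = t2/(t1+t2) is undefined for t1 + t2 = 0"
        )
    return t.t2 / t.sum


def _sign_pattern(t: TParams) -> str:
    def s(v: float) -> str:
        return "<0" if v < 0 else (">0" if v > 0 else "=0")

    return f"t1{s(t.t1)}, t2{s(t.t2)}"


def _x3_location(t: TParams) -> X3Location:
    # Exact sign tests on numerator/denominator: inputs are user-supplied
    # parameters, so no floating tolerance is applied.
    s = t.sum
    if s > 0.0:
        if t.t2 < 0.0:
            return X3Location.BELOW_ZERO
        if t.t2 > s:
            return X3Location.ABOVE_ONE
        if 0.0 < t.t2 < s:
            return X3Location.INTERIOR
    elif s < 0.0:
        if t.t2 > 0.0:
            return X3Location.BELOW_ZERO
        if t.t2 < s:
            return X3Location.ABOVE_ONE
        if s < t.t2 < 0.0:
            return X3Location.INTERIOR
    return X3Location.UNDEFINED


def classify_case(t: TParams) -> CaseLabel:
    """Assign the dynamical regime (A1..B3, or DEGENERATE) of (t1, t2).

    The family is the sign of t1 + t2 (A: positive, B: negative); the
    sub-case index follows the location of x3 = t2/(t1+t2): above one (A1,
    B2), below zero (A2, B1), or interior (A3, B3).  Parameter pairs on the
    non-hyperbolic boundaries — t1 + t2 = 0, or x3 exactly at 0 or 1 (i.e.
    t2 = 0 or t1 = 0) — are labelled DEGENERATE.
    """
    pattern = _sign_pattern(t)
    s = t.sum
    if s == 0.0 or t.t1 == 0.0 or t.t2 == 0.0:
        label = CaseLabel(Case.DEGENERATE, X3Location.UNDEFINED, pattern)
        logger.info("classify_case t1=%g t2=%g -> %s (%s)", t.t1, t.t2, label.label.value, pattern)
        return label
    loc = _x3_location(t)
    if s > 0.0:
        mapping = {
            X3Location.ABOVE_ONE: Case.A1,
            X3Location.BELOW_ZERO: Case.A2,
            X3Location.INTERIOR: Case.A3,
        }
    else:
        mapping = {
            X3Location.BELOW_ZERO: Case.B1,
            X3Location.ABOVE_ONE: Case.B2,
            X3Location.INTERIOR: Case.B3,
        }
    label = CaseLabel(mapping[loc], loc, pattern)
    logger.info(
        "classify_case t1=%g t2=%g -> %s (x3 %s; %s)",
        t.t1, t.t2, label.label.value, loc.value, pattern,
    )
    return label
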