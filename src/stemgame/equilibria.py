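"""Closed-form equilibria and stability of the game, with and without therapy.

Setting dx/dt = 0 on the simplex gives the untreated equilibrium cubic::

    (t1 + t2) x^3 − (t1 + 2 t2) x^2 + t2 x = 0
    ⇒ x = 0,  x = 1,  x3 = t2 / (t1 + t2)

Under stem-cell injection the nonzero equilibria solve the quadratic::

    (t1 + t2) x^2 − (t1 + 2 t2 + e) x + t2 = 0,      e = w j / l

with companion stem-cell level z_eq = (j/l) x_eq.  By Vieta the product of
the two nonzero roots, t2/(t1+t2), is independent of e — only their sum
moves — which is the lever the therapy design exploits.  A sufficient
condition for the quadratic to have no root in (0, 1) (used in the bistable
regime B3 to make the cancer-free state globally attracting) is::

    e > −2 sqrt(t2 (t1 + t2)) − (t1 + 2 t2)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import TherapyParams
from .game_core import DegenerateCaseError, TParams

logger = logging.getLogger(__name__)

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "Stability",
    "baseline_equilibria",
    "equilibrium_quadratic_roots",
    "equilibrium_report",
    "interior_exclusion_threshold",
    "no_interior_root_condition",
    "origin_stability",
    "therapy_equilibria",
    "vieta_diagnostics",
]

STABLE = "stable"
UNSTABLE = "unstable"
SADDLE = "saddle"
MARGINAL = "marginal"

#: Accepted stability labels.
Stability = str

#: Relative eigenvalue threshold below which a point is reported marginal.
_HYPERBOLICITY_RTOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the (reduced) dynamics.

    ``x`` may lie outside [0, 1]; such roots are reported because they shape
    the flow inside the unit interval.  ``z`` is the companion stem-cell
    level (j/l)·x under therapy and 0 otherwise.
    """

    x: float
    z: float
    stability: Stability
    source: str  # origin | baseline_cubic | therapy_quadratic


@dataclass
class EquilibriumSet:
    """All equilibria of one system, with Vieta diagnostics.

    ``product_check`` / ``sum_check`` are the absolute deviations of the two
    nonzero roots' product/sum from their closed-form values; both are None
    when fewer than two nonzero roots exist.
    """

    equilibria: list[Equilibrium]
    t: TParams
    e: float
    product_check: Optional[float] = None
    sum_check: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    def nonzero_roots(self) -> list[float]:
        """x-locations of the non-origin equilibria, ascending."""
        return sorted(eq.x for eq in self.equilibria if eq.source != "origin")

    def find(self, x: float, atol: float = 1e-9) -> Optional[Equilibrium]:
        """The equilibrium closest to x, if within atol."""
        best = None
        for eq in self.equilibria:
            if abs(eq.x - x) <= atol and (best is None or abs(eq.x - x) < abs(best.x - x)):
                best = eq
        return best

    def to_dict(self) -> dict:
        vieta = None
        if self.t.sum != 0.0:
            P, S = vieta_diagnostics(self.t, self.e)
            vieta = {"P": P, "S": S}
        try:
            cond = no_interior_root_condition(self.t, self.e)
        except DegenerateCaseError:
            cond = None
        return {
            "t1": self.t.t1,
            "t2": self.t.t2,
            "e": self.e,
            "equilibria": [
                {"x": eq.x, "z": eq.z, "stability": eq.stability, "source": eq.source}
                for eq in self.equilibria
            ],
            "vieta": vieta,
            "no_interior_root_in_unit_interval": cond,
            "flags": list(self.flags),
        }


def _stable_quadratic_roots(a: float, b: float, c: float) -> tuple[float, ...]:
    """Real roots of a x² + b x + c, ascending, cancellation-safe.

    Uses the sign-matched numerator q = −(b + sign(b)·√disc)/2 and returns
    (q/a, c/q) so that a root near zero is not lost to cancellation.  A
    linear fallback handles a = 0; complex pairs yield an empty tuple.
    """
    if a == 0.0:
        if b == 0.0:
            return ()
        return (-c / b,)
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return ()
    sq = math.sqrt(disc)
    if b == 0.0:
        r = sq / (2.0 * a)
        return tuple(sorted((-abs(r), abs(r))))
    q = -0.5 * (b + math.copysign(sq, b))
    return tuple(sorted((q / a, c / q)))


def equilibrium_quadratic_roots(t: TParams, e: float) -> tuple[float, ...]:
    """Real roots of (t1+t2)x² − (t1+2t2+e)x + t2 = 0, ascending."""
    return _stable_quadratic_roots(t.sum, -(t.t1 + 2.0 * t.t2 + e), t.t2)


def _cubic_derivative(t: TParams, x: float) -> float:
    """d/dx of the untreated reduced RHS x(1−x)(t2 − (t1+t2)x)."""
    return t.t2 - 2.0 * (t.t1 + 2.0 * t.t2) * x + 3.0 * t.sum * x * x


def _sign_stability(derivative: float) -> Stability:
    if derivative < 0.0:
        return STABLE
    if derivative > 0.0:
        return UNSTABLE
    return MARGINAL


def origin_stability(t: TParams) -> Stability:
    """Stability of the cancer-free state x = 0 (same with/without therapy).

    The linearization coefficient of the reduced dynamics at the origin is
    t2, and the therapy terms vanish there to first order (z_eq = 0), so the
    classification is governed by the sign of t2 alone.
    """
    return _sign_stability(t.t2)


def baseline_equilibria(t: TParams) -> EquilibriumSet:
    """Equilibria {0, 1, x3} of the untreated system with stability labels.

    Stability follows the sign of the reduced RHS derivative at each root:
    x=0 stable iff t2 < 0, x=1 stable iff t1 < 0, and the interior root
    (when it exists and is distinct) stable iff t1 + t2 > 0.  On the
    degenerate boundary t1 + t2 = 0 only {0, 1} are returned, flagged.
    """
    flags: list[str] = []
    eqs = [Equilibrium(0.0, 0.0, origin_stability(t), "origin")]
    # g'(1) = t1, so fixation of cancerous cells is stable iff t1 < 0
    eqs.append(Equilibrium(1.0, 0.0, _sign_stability(t.t1), "baseline_cubic"))
    if t.sum == 0.0:
        flags.append("degenerate_sum: cubic loses its interior root (t1 + t2 = 0)")
    else:
        x3 = t.t2 / t.sum
        if x3 == 0.0 or x3 == 1.0:
            flags.append(f"interior root coincides with boundary equilibrium at x={x3:g}")
        else:
            # g'(x3) = −(t1+t2)·x3·(1−x3); sign evaluated on the product
            eqs.append(
                Equilibrium(
                    x3,
                    0.0,
                    _sign_stability(-t.sum * x3 * (1.0 - x3)),
                    "baseline_cubic",
                )
            )
    es = EquilibriumSet(eqs, t, 0.0, flags=flags)
    _attach_vieta(es)
    return es


def _therapy_jacobian(t: TParams, therapy: TherapyParams, x: float) -> np.ndarray:
    """Jacobian of the reduced (x, z) system at (x, z=(j/l)x)."""
    z = therapy.j / therapy.l * x
    return np.array(
        [
            [_cubic_derivative(t, x) - therapy.w * z, -therapy.w * x],
            [therapy.j, -therapy.l],
        ]
    )


def _classify_eigenvalues(eigs: np.ndarray) -> Stability:
    re = np.real(eigs)
    scale = max(1.0, float(np.max(np.abs(eigs))))
    if np.any(np.abs(re) <= _HYPERBOLICITY_RTOL * scale):
        return MARGINAL
    if np.all(re < 0.0):
        return STABLE
    if np.all(re > 0.0):
        return UNSTABLE
    # real eigenvalues of opposite sign
    return SADDLE


def therapy_equilibria(t: TParams, therapy: TherapyParams) -> EquilibriumSet:
    """Equilibria of the therapy system: origin plus real quadratic roots.

    Each nonzero root carries z = (j/l)·x and a stability label from the
    eigenvalues of the 2-D (x, z) Jacobian (y eliminated via x + y = 1).
    The origin keeps its tumor-direction classification (sign of t2), which
    therapy cannot change; its z-direction always decays since l > 0.
    A complex root pair yields the origin alone, flagged.
    """
    e = therapy.e
    flags: list[str] = []
    eqs = [Equilibrium(0.0, 0.0, origin_stability(t), "origin")]
    if t.sum == 0.0:
        flags.append("degenerate_sum: nonzero-equilibrium equation is linear (t1 + t2 = 0)")
    roots = equilibrium_quadratic_roots(t, e)
    if not roots:
        flags.append("no nonzero equilibria: quadratic roots are complex")
    if len(roots) == 2 and roots[0] == roots[1]:
        roots = roots[:1]
        flags.append("double root: non-hyperbolic nonzero equilibrium")
    ratio = therapy.j / therapy.l
    for x in roots:
        if x == 0.0:
            # coincides with the origin (t2 = 0); keep the origin label only
            flags.append("quadratic root coincides with the origin")
            continue
        eigs = np.linalg.eigvals(_therapy_jacobian(t, therapy, x))
        eqs.append(Equilibrium(x, ratio * x, _classify_eigenvalues(eigs), "therapy_quadratic"))
    es = EquilibriumSet(eqs, t, e, flags=flags)
    _attach_vieta(es)
    logger.info(
        "therapy_equilibria t1=%g t2=%g e=%g -> %s",
        t.t1, t.t2, e,
        [(round(q.x, 6), q.stability) for q in es.equilibria],
    )
    return es


def _attach_vieta(es: EquilibriumSet) -> None:
    roots = es.nonzero_roots()
    if len(roots) == 2 and es.t.sum != 0.0:
        P, S = vieta_diagnostics(es.t, es.e)
        es.product_check = abs(roots[0] * roots[1] - P)
        es.sum_check = abs(roots[0] + roots[1] - S)


def vieta_diagnostics(t: TParams, e: float) -> tuple[float, float]:
    """Closed-form product and sum of the nonzero-equilibrium quadratic roots.

    P = t2/(t1+t2) does not depend on e; S = (t1 + 2 t2 + e)/(t1 + t2).

    Raises
    ------
    DegenerateCaseError
        If t1 + t2 = 0 (the quadratic degenerates to a linear equation).
    """
    if t.sum == 0.0:
        raise DegenerateCaseError("Vieta diagnostics undefined for t1 + t2 = 0")
    return t.t2 / t.sum, (t.t1 + 2.0 * t.t2 + e) / t.sum


def interior_exclusion_threshold(t: TParams) -> float:
    """Lower bound on e above which no nonzero equilibrium lies in (0, 1).

    Defined as −2·√(t2(t1+t2)) − (t1 + 2 t2).  The radicand t2(t1+t2) must
    be non-negative; that holds in the bistable regime B3 (t1 < 0, t2 < 0),
    the regime the condition is designed for.
    """
    rad = t.t2 * t.sum
    if rad < 0.0:
        raise DegenerateCaseError(
            "interior-exclusion threshold needs t2(t1+t2) >= 0, i.e. t2 and "
            f"t1+t2 of equal sign (case B3: t1<0, t2<0); got t1={t.t1}, t2={t.t2}"
        )
    return -2.0 * math.sqrt(rad) - (t.t1 + 2.0 * t.t2)


def no_interior_root_condition(t: TParams, e: float) -> bool:
    """Whether e strictly exceeds the interior-exclusion threshold.

    When true and (t1, t2) lies in the B3 region, the nonzero-equilibrium
    quadratic has no root in (0, 1), so the whole interval is attracted to
    the cancer-free state.
    """
    return e > interior_exclusion_threshold(t)


def equilibrium_report(t: TParams, therapy: Optional[TherapyParams] = None) -> dict:
    """JSON-ready equilibrium report for one parameter set."""
    es = therapy_equilibria(t, therapy) if therapy is not None else baseline_equilibria(t)
    return es.to_dict()
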