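"""Replicator dynamics of the cancer/healthy game, with and without therapy.

Untreated system (x = fraction of cancerous cells, y = 1 − x healthy)::

    dx/dt = x (fC − fCH)        fC  = a x + b y
    dy/dt = y (fH − fCH)        fH  = c x + d y
                                fCH = x fC + y fH

Stem-cell injection adds a third state z (stem-cell level) and three control
parameters: w (per-unit-z suppression of cancerous growth), j (drive of z by
the cancer fraction) and l (decay of z)::

    dx/dt = x (fC − fCH − z w)
    dy/dt = y (fH − fCH) + (1 − y) z w
    dz/dt = x j − z l

At equilibria only the composite e = w j / l matters for the cancer
fraction; the stem-cell level settles at z_eq = (j/l) x_eq.

On the simplex the cancer fraction obeys the scalar reduced equation
``dx/dt = x[(1 − x)(t2 − (t1 + t2) x) − w z]``, which at the quasi-steady
state z = (j/l) x becomes ``x[(1 − x)(t2 − (t1 + t2) x) − e x]``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .game_core import InvalidInputError, PayoffMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IntegrationError",
    "IntegrationSettings",
    "InvalidTherapyError",
    "NotConvergedError",
    "SystemState",
    "TherapyParams",
    "Trajectory",
    "baseline_rhs",
    "fitnesses",
    "simulate",
    "steady_state_value",
    "therapy_rhs",
]

#: |x + y − 1| allowed in an initial condition.
SIMPLEX_ATOL = 1e-9
#: Negative excursion that triggers a warning (round-off scale).
NEGATIVE_WARN = -1e-10
#: Negative excursion treated as genuine model escape.
NEGATIVE_ERROR = -1e-6


class InvalidTherapyError(ValueError):
    """Therapy parameters outside the admissible domain (l must be > 0)."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or the trajectory escaped the feasible region."""


class NotConvergedError(RuntimeError):
    """A steady state was requested from a trajectory that has not settled."""


@dataclass(frozen=True)
class TherapyParams:
    """Stem-cell injection parameters.

    Parameters
    ----------
    w : float
        Strength with which stem cells suppress the cancerous fraction (and
        boost the healthy one), per unit of z.
    j : float
        Feedback gain from the cancer fraction x onto stem-cell production.
    l : float
        Stem-cell decay rate; must be positive for z to admit a finite
        quasi-steady state.
    """

    w: float
    j: float
    l: float

    def __post_init__(self) -> None:
        for name in ("w", "j", "l"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise InvalidTherapyError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)
        if self.l <= 0.0:
            raise InvalidTherapyError(f"l must be > 0 for a finite stem-cell steady state, got {self.l}")

    @property
    def e(self) -> float:
        """Composite control parameter e = w j / l."""
        return self.w * self.j / self.l

    @classmethod
    def from_e(cls, e: float, j: float = 1.0, l: float = 1.0) -> "TherapyParams":
        """Expand a composite e into (w, j, l), default j = l = 1 so w = e."""
        j = float(j)
        if j == 0.0:
            raise InvalidTherapyError("cannot expand e into (w, j, l) with j = 0")
        return cls(w=float(e) * float(l) / j, j=j, l=float(l))


@dataclass(frozen=True)
class SystemState:
    """Population state (x, y, z) at time t."""

    x: float
    y: float
    z: float = 0.0
    t: float = 0.0

    @classmethod
    def from_x(cls, x: float, z: float = 0.0, t: float = 0.0) -> "SystemState":
        """State on the simplex with cancer fraction x (y = 1 − x)."""
        return cls(x=float(x), y=1.0 - float(x), z=float(z), t=float(t))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class IntegrationSettings:
    """Numerical integration configuration.

    An adaptive stiff-capable solver with tight tolerances keeps simulated
    steady states comparable to the closed-form equilibria.  A run is
    declared converged once the max-norm of the right-hand side falls below
    ``convergence_tol``; if the horizon is exhausted first it is doubled up
    to ``max_doublings`` times.
    """

    method: str = "LSODA"
    rtol: float = 1e-9
    atol: float = 1e-11
    convergence_tol: float = 1e-8
    horizon: float = 500.0
    max_doublings: int = 4


@dataclass
class Trajectory:
    """Time-ordered solution of a simulation run."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3): columns x, y, z
    converged: bool
    steady_state: Optional[SystemState]
    metadata: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "x": self.x, "y": self.y, "z": self.z}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def metadata_json(self, path=None) -> str:
        payload = dict(self.metadata, converged=bool(self.converged))
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def fitnesses(x: float, y: float, payoff: PayoffMatrix) -> tuple[float, float, float]:
    """Average fitnesses (fC, fH, fCH) at frequencies (x, y).

    fC = a x + b y and fH = c x + d y are the frequency-weighted payoffs of
    the cancerous and healthy strategies; fCH = x fC + y fH is the
    population average.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise InvalidInputError(f"frequencies must be finite, got x={x!r}, y={y!r}")
    fC = x * payoff.a + y * payoff.b
    fH = x * payoff.c + y * payoff.d
    fCH = x * fC + y * fH
    return fC, fH, fCH


def baseline_rhs(x: float, y: float, payoff: PayoffMatrix) -> tuple[float, float]:
    """Replicator right-hand side (dx/dt, dy/dt) without therapy."""
    fC, fH, fCH = fitnesses(x, y, payoff)
    return x * (fC - fCH), y * (fH - fCH)


def therapy_rhs(
    state, payoff: PayoffMatrix, therapy: TherapyParams
) -> tuple[float, float, float]:
    """Right-hand side (dx/dt, dy/dt, dz/dt) of the therapy-augmented system.

    ``state`` may be a :class:`SystemState` or any (x, y, z) triple.
    """
    if isinstance(state, SystemState):
        x, y, z = state.x, state.y, state.z
    else:
        x, y, z = state
    fC, fH, fCH = fitnesses(x, y, payoff)
    zw = z * therapy.w
    dx = x * (fC - fCH - zw)
    dy = y * (fH - fCH) + (1.0 - y) * zw
    dz = x * therapy.j - z * therapy.l
    return dx, dy, dz


def _validate_initial(initial: SystemState) -> None:
    if initial.x < 0.0 or initial.y < 0.0:
        raise InvalidInputError(f"initial frequencies must be non-negative: x={initial.x}, y={initial.y}")
    if abs(initial.x + initial.y - 1.0) > SIMPLEX_ATOL:
        raise InvalidInputError(
            f"initial condition off the simplex: x + y = {initial.x + initial.y!r} (must be 1)"
        )
    if initial.z < 0.0:
        raise InvalidInputError(f"initial stem-cell level must be non-negative, got z={initial.z}")


def _check_excursions(states: np.ndarray) -> None:
    low = float(states.min())
    if low < NEGATIVE_ERROR:
        raise IntegrationError(
            f"trajectory escaped the feasible region (min component {low:.3e}); "
            "this indicates genuine model escape, not round-off"
        )
    if low < NEGATIVE_WARN:
        warnings.warn(
            f"small negative excursion ({low:.3e}) along the trajectory; round-off scale",
            RuntimeWarning,
            stacklevel=3,
        )
    zmax = float(states[:, 2].max())
    if zmax > 1.0 + 1e-9:
        warnings.warn(
            f"stem-cell level exceeded 1 (max z = {zmax:.6g}); z is not bounded by the simplex",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate(
    initial: SystemState,
    payoff: PayoffMatrix,
    therapy: Optional[TherapyParams] = None,
    horizon: Optional[float] = None,
    settings: Optional[IntegrationSettings] = None,
) -> Trajectory:
    """Integrate the (therapy-augmented) replicator system to steady state.

    Integration stops early once the max-norm of the right-hand side drops
    below the convergence tolerance; otherwise the horizon is doubled up to
    ``settings.max_doublings`` times.  States are never clipped: small
    negative excursions are reported as warnings, large ones as errors.

    Raises
    ------
    InvalidInputError
        If the initial condition is off the simplex or negative.
    IntegrationError
        On solver failure or escape from the feasible region.
    """
    settings = settings or IntegrationSettings()
    span = float(horizon) if horizon is not None else settings.horizon
    if span <= 0.0:
        raise InvalidInputError(f"horizon must be positive, got {span}")
    _validate_initial(initial)

    if therapy is None:

        def rhs(tt, s):
            dx, dy = baseline_rhs(s[0], s[1], payoff)
            return (dx, dy, 0.0)

    else:

        def rhs(tt, s):
            return therapy_rhs((s[0], s[1], s[2]), payoff, therapy)

    ctol = settings.convergence_tol

    def rhs_norm(s) -> float:
        return max(abs(v) for v in rhs(0.0, s))

    def settled(tt, s):
        return rhs_norm(s) - ctol

    settled.terminal = True
    settled.direction = -1

    t_cur = initial.t
    s_cur = initial.as_array()
    times = [t_cur]
    states = [s_cur.copy()]
    converged = rhs_norm(s_cur) < ctol
    attempts = 0
    while not converged and attempts <= settings.max_doublings:
        sol = solve_ivp(
            rhs,
            (t_cur, t_cur + span),
            s_cur,
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
            events=[settled],
            dense_output=False,
        )
        if sol.status == -1:
            raise IntegrationError(
                f"ODE solver failed at t={sol.t[-1]:.6g}: {sol.message} "
                f"(method={settings.method}, rtol={settings.rtol}, atol={settings.atol})"
            )
        times.extend(sol.t[1:].tolist())
        states.extend(sol.y[:, 1:].T)
        t_cur = float(sol.t[-1])
        s_cur = sol.y[:, -1]
        converged = sol.status == 1 or rhs_norm(s_cur) < ctol
        span *= 2.0
        attempts += 1

    times_arr = np.asarray(times, dtype=float)
    states_arr = np.asarray(states, dtype=float)
    _check_excursions(states_arr)

    steady = (
        SystemState(x=float(s_cur[0]), y=float(s_cur[1]), z=float(s_cur[2]), t=t_cur)
        if converged
        else None
    )
    metadata = {
        "payoff": {"a": payoff.a, "b": payoff.b, "c": payoff.c, "d": payoff.d},
        "therapy": None
        if therapy is None
        else {"w": therapy.w, "j": therapy.j, "l": therapy.l, "e": therapy.e},
        "initial": {"x": initial.x, "y": initial.y, "z": initial.z, "t": initial.t},
        "settings": {
            "method": settings.method,
            "rtol": settings.rtol,
            "atol": settings.atol,
            "convergence_tol": settings.convergence_tol,
            "horizon": settings.horizon,
            "max_doublings": settings.max_doublings,
        },
        "t_final": t_cur,
        "n_points": int(times_arr.size),
    }
    logger.info(
        "simulate x0=%g e=%s converged=%s t_final=%g x_final=%g",
        initial.x,
        "none" if therapy is None else f"{therapy.e:g}",
        converged,
        t_cur,
        float(s_cur[0]),
    )
    return Trajectory(times_arr, states_arr, converged, steady, metadata)


def steady_state_value(traj: Trajectory) -> SystemState:
    """Final state of a converged trajectory.

    Raises
    ------
    NotConvergedError
        If the run never settled; integrate with a longer horizon (or more
        horizon doublings) and try again.
    """
    if not traj.converged or traj.steady_state is None:
        raise NotConvergedError(
            "trajectory has not converged; re-run simulate() with a longer "
            "horizon or a larger max_doublings"
        )
    return traj.steady_state
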