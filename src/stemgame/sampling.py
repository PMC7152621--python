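"""Seeded samplers over the case regions of (t1, t2) parameter space.

Used by property tests and scripted experiments to draw parameter sets that
provably belong to one dynamical regime, away from the non-hyperbolic
boundaries where trajectories stall.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .game_core import Case, TParams, classify_case

__all__ = ["sample_case_parameters"]

#: Bounding box for sampled (t1, t2).
_BOX = 10.0
#: Exclusion half-width around the degenerate line t1 + t2 = 0.
_SUM_MARGIN = 0.05
#: Margin keeping |t1|, |t2| away from the sub-case boundaries.
_T_MARGIN = 0.1
#: Minimum distance of an interior x3 from the boundary roots 0 and 1.
_X3_MARGIN = 0.05


def sample_case_parameters(
    label: Union[Case, str], n: int, seed: int
) -> list[TParams]:
    """Draw n parameter pairs uniformly from one case region.

    Rejection sampling from the box [−10, 10]², excluding |t1 + t2| < 0.05
    (near-degenerate stiffness), |t1| or |t2| < 0.1, and interior roots
    within 0.05 of the boundary equilibria.  Deterministic given the seed;
    every returned pair classifies back to the requested label.
    """
    label = Case(label)
    if label is Case.DEGENERATE:
        raise ValueError("the DEGENERATE boundary set has measure zero and cannot be sampled")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out: list[TParams] = []
    while len(out) < n:
        t1, t2 = rng.uniform(-_BOX, _BOX, size=2)
        if abs(t1 + t2) < _SUM_MARGIN or abs(t1) < _T_MARGIN or abs(t2) < _T_MARGIN:
            continue
        t = TParams(float(t1), float(t2))
        if classify_case(t).label is not label:
            continue
        x3 = t.t2 / t.sum
        if min(abs(x3), abs(x3 - 1.0)) < _X3_MARGIN:
            continue
        out.append(t)
    return out
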