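"""Closed-form equilibria, stability labels, Vieta and root-exclusion."""

import numpy as np
import pytest
from scipy.optimize import brentq

from stemgame.dynamics import TherapyParams
from stemgame.equilibria import (
    MARGINAL,
    SADDLE,
    STABLE,
    UNSTABLE,
    _cubic_derivative,
    baseline_equilibria,
    equilibrium_quadratic_roots,
    equilibrium_report,
    interior_exclusion_threshold,
    no_interior_root_condition,
    origin_stability,
    therapy_equilibria,
    vieta_diagnostics,
)
from stemgame.game_core import DegenerateCaseError, TParams


def _by_x(es):
    return {round(eq.x, 9): eq.stability for eq in es.equilibria}


@pytest.mark.parametrize(
    "t1, t2, expected",
    [
        (-1, 2, {0.0: UNSTABLE, 1.0: STABLE, 2.0: UNSTABLE}),
        (1, 2, {0.0: UNSTABLE, 1.0: UNSTABLE, round(2 / 3, 9): STABLE}),
        (-3, -1, {0.0: STABLE, 1.0: STABLE, 0.25: UNSTABLE}),
    ],
)
def test_baseline_equilibria(t1, t2, expected):
    es = baseline_equilibria(TParams(t1, t2))
    assert _by_x(es) == expected


def test_baseline_degenerate_sum_drops_interior_root():
    es = baseline_equilibria(TParams(1, -1))
    assert sorted(eq.x for eq in es.equilibria) == [0.0, 1.0]
    assert any("degenerate" in f for f in es.flags)


def test_therapy_equilibria_match_published_rows():
    es = therapy_equilibria(TParams(-1, 2), TherapyParams.from_e(18))
    roots = es.nonzero_roots()
    assert roots[0] == pytest.approx(0.0957, abs=1e-4)
    assert roots[1] == pytest.approx(20.904, abs=1e-3)
    es = therapy_equilibria(TParams(1, 2), TherapyParams.from_e(16))
    roots = es.nonzero_roots()
    assert roots[0] == pytest.approx(0.0966, abs=1e-4)
    assert roots[1] == pytest.approx(6.9034, abs=1e-4)


def test_therapy_at_e_zero_reduces_to_baseline_roots():
    es = therapy_equilibria(TParams(-1, 2), TherapyParams(w=0.0, j=1.0, l=1.0))
    assert es.nonzero_roots() == pytest.approx([1.0, 2.0], abs=1e-12)


def test_therapy_complex_pair_flagged():
    # B3 parameters above the exclusion threshold but below the upper
    # discriminant branch: no real nonzero roots at all.
    es = therapy_equilibria(TParams(-3, -1), TherapyParams.from_e(2))
    assert es.nonzero_roots() == []
    assert any("complex" in f for f in es.flags)
    assert es.equilibria[0].x == 0.0


def test_therapy_z_companion_is_scaled_root():
    therapy = TherapyParams(w=6.0, j=2.0, l=0.5)  # e = 24
    es = therapy_equilibria(TParams(-1, 2), therapy)
    for eq in es.equilibria:
        assert eq.z == pytest.approx(eq.x * therapy.j / therapy.l, abs=1e-12)


@pytest.mark.parametrize(
    "t2, expected", [(-1.0, STABLE), (2.0, UNSTABLE), (0.0, MARGINAL)]
)
def test_origin_stability(t2, expected):
    assert origin_stability(TParams(1.0, t2)) == expected


def test_origin_stability_unchanged_by_therapy(rng):
    """The linearization coefficient at x=0 is t2 with or without stem cells."""
    for _ in range(100):
        t1, t2 = rng.uniform(-10, 10, 2)
        t = TParams(t1, t2)
        base = baseline_equilibria(t).equilibria[0]
        ther = therapy_equilibria(t, TherapyParams.from_e(rng.uniform(-20, 20))).equilibria[0]
        assert base.x == ther.x == 0.0
        assert base.stability == ther.stability == origin_stability(t)
        assert _cubic_derivative(t, 0.0) == t2


@pytest.mark.parametrize(
    "t1, t2, e, expected",
    [
        (-1, 2, 0, (2.0, 3.0)),
        (-1, 2, 18, (2.0, 21.0)),
        (-4, 1, 0, (-1 / 3, 2 / 3)),
        (-4, 1, 7, (-1 / 3, -5 / 3)),
    ],
)
def test_vieta_diagnostics(t1, t2, e, expected):
    P, S = vieta_diagnostics(TParams(t1, t2), e)
    assert P == pytest.approx(expected[0], abs=1e-12)
    assert S == pytest.approx(expected[1], abs=1e-12)


def test_vieta_degenerate_sum_raises():
    with pytest.raises(DegenerateCaseError):
        vieta_diagnostics(TParams(1, -1), 5.0)


def test_root_product_invariant_in_e(rng):
    """Vieta: the product of the nonzero roots never moves with e."""
    for _ in range(20):
        t1, t2 = rng.uniform(-10, 10, 2)
        if abs(t1 + t2) < 0.05:
            continue
        t = TParams(t1, t2)
        P = t2 / (t1 + t2)
        products = []
        for e in np.linspace(-25, 25, 50):
            roots = equilibrium_quadratic_roots(t, float(e))
            if len(roots) == 2:
                products.append(roots[0] * roots[1])
        assert products, "expected some real-root e values"
        assert np.ptp(products) < 1e-9
        assert np.allclose(products, P, atol=1e-9)


def test_computed_roots_satisfy_vieta(rng):
    for _ in range(200):
        t1, t2 = rng.uniform(-10, 10, 2)
        e = rng.uniform(-20, 20)
        if abs(t1 + t2) < 0.05:
            continue
        t = TParams(t1, t2)
        roots = equilibrium_quadratic_roots(t, e)
        if len(roots) != 2:
            continue
        P, S = vieta_diagnostics(t, e)
        assert abs(roots[0] * roots[1] - P) < 1e-9 * max(1.0, abs(P))
        assert abs(roots[0] + roots[1] - S) < 1e-9 * max(1.0, abs(S))


def _grid_scan_roots(a, b, c, lo=-50.0, hi=50.0, step=1e-4):
    """Independent root bracketing: sign scan on a uniform grid + brentq."""
    xs = np.arange(lo, hi + step, step)
    vals = a * xs * xs + b * xs + c
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = [brentq(lambda x: a * x * x + b * x + c, xs[i], xs[i + 1], xtol=1e-13) for i in idx]
    roots.extend(float(x) for x in xs[vals == 0.0])
    return sorted(roots)


def test_quadratic_solver_agrees_with_grid_scan_oracle(rng):
    checked = 0
    while checked < 100:
        t1, t2 = rng.uniform(-10, 10, 2)
        e = rng.uniform(-20, 20)
        if abs(t1 + t2) < 0.05:
            continue
        t = TParams(t1, t2)
        analytic = [r for r in equilibrium_quadratic_roots(t, e) if -50 < r < 50]
        a, b, c = t1 + t2, -(t1 + 2 * t2 + e), t2
        scanned = _grid_scan_roots(a, b, c)
        assert len(scanned) == len(analytic)
        for r_scan, r_exact in zip(scanned, analytic):
            assert abs(r_scan - r_exact) < 1e-8
        checked += 1


def test_small_root_is_cancellation_safe():
    """For large e one root approaches 0; the sign-matched formulation must
    keep full relative accuracy there."""
    t = TParams(-1, 2)
    e = 1e8
    small = min(equilibrium_quadratic_roots(t, e))
    # exact small root from the convergent series t2/(t1+2t2+e) * (1 + ...)
    approx = 2.0 / (3.0 + e)
    assert small == pytest.approx(approx, rel=1e-6)
    assert small > 0


@pytest.mark.parametrize(
    "e, expected", [(2.0, True), (0.5, False), (10.0, True)]
)
def test_no_interior_root_condition(e, expected):
    t = TParams(-3, -1)  # threshold = -2*sqrt(4) - (-5) = 1
    assert interior_exclusion_threshold(t) == pytest.approx(1.0, abs=1e-12)
    assert no_interior_root_condition(t, e) is expected
    if expected:
        assert not any(0 < r < 1 for r in equilibrium_quadratic_roots(t, e))
    else:
        assert any(0 < r < 1 for r in equilibrium_quadratic_roots(t, e))


def test_exclusion_threshold_domain_error_names_required_case():
    with pytest.raises(DegenerateCaseError, match="B3"):
        interior_exclusion_threshold(TParams(-4, 1))


def test_jacobian_classification_consistent_with_reduced_map(rng):
    """The 2-D (x, z) Jacobian at a nonzero root has det = −l·φ'(x) and
    trace = φ'(x) + e·x − l, where φ is the reduced scalar map
    x[(1−x)(t2−(t1+t2)x) − ex].  Hence saddle ⇔ φ' > 0, and stability
    under φ' < 0 additionally needs a negative trace; any 1-D/2-D label
    disagreement must be of that oscillatory (positive-trace) type."""
    checked = 0
    hopf_disagreements = 0
    while checked < 500:
        t1, t2 = rng.uniform(-10, 10, 2)
        e = rng.uniform(-20, 20)
        if abs(t1 + t2) < 0.05:
            continue
        t = TParams(t1, t2)
        therapy = TherapyParams.from_e(e)
        es = therapy_equilibria(t, therapy)
        for eq in es.equilibria:
            if eq.source != "therapy_quadratic":
                continue
            phi_prime = _cubic_derivative(t, eq.x) - 2 * e * eq.x
            if abs(phi_prime) < 1e-3:  # skip near-marginal points
                continue
            trace = phi_prime + e * eq.x - therapy.l
            if phi_prime > 0:
                assert eq.stability == SADDLE
            elif trace < 0:
                assert eq.stability == STABLE
            else:
                assert eq.stability in (UNSTABLE, MARGINAL)
                hopf_disagreements += 1
            checked += 1
    # the oscillatory exception exists but stays rare
    assert hopf_disagreements < 0.05 * checked


def test_report_is_json_ready():
    report = equilibrium_report(TParams(-1, 2), TherapyParams.from_e(18))
    assert report["t1"] == -1 and report["e"] == 18
    assert {e["source"] for e in report["equilibria"]} == {"origin", "therapy_quadratic"}
    assert report["vieta"]["P"] == pytest.approx(2.0)
    import json

    json.dumps(report)
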