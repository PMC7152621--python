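# Methods

## Model

The package analyzes a two-strategy evolutionary game between cancerous (C)
and healthy (H) cells under replicator dynamics, and a feedback therapy in
which stem cells are injected at a rate driven by the tumor fraction. All
quantities are dimensionless frequencies/rates; time has arbitrary units
(the equations are autonomous, so only ratios of rates matter).

Untreated, the cancer fraction x obeys the scalar reduced equation on the
simplex x + y = 1:

    dx/dt = x (1 − x) (t2 − (t1 + t2) x),   t1 = c − a,  t2 = b − d.

Its fixed points are x = 0, x = 1 and x3 = t2/(t1 + t2), with stability read
from the derivative: x = 0 is stable iff t2 < 0, x = 1 iff t1 < 0, and x3
(when it lies between them) iff t1 + t2 > 0.

Therapy adds the stem-cell level z with parameters w, j, l (see README) and
the model is treated as a three-state ODE system; z is *not* a simplex
coordinate and is not bounded above by 1 (its quasi-steady state (j/l)·x can
exceed 1 for j > l; a runtime warning notes when it does). The third line of
the model is a differential equation, dz/dt = xj − zl: the equilibrium
relation z_eq = (j/l)x_eq only follows from setting ż = 0, which fixes the
interpretation. Nonzero equilibria solve
(t1+t2)x² − (t1+2t2+e)x + t2 = 0 with e = wj/l.

## Case taxonomy

Classification is by the sign of t1 + t2 (family A/B) and the location of x3
relative to [0, 1] (sub-case). Published sign-pattern tables for this
taxonomy are not internally consistent with the x3-location definition; the
classifier therefore uses the x3 location as the defining feature and
reports the actual sign pattern of (t1, t2) alongside the label. Parameter
pairs on the non-hyperbolic boundaries — t1 + t2 = 0, or t1 = 0 or t2 = 0
(x3 exactly at a boundary root) — are labelled DEGENERATE and never forced
into a sub-case; non-hyperbolic equilibria are reported as "marginal".
Classification uses exact sign tests, not floating tolerances, because the
inputs are user-supplied parameters, not computed quantities.

## Numerical choices

* **Quadratic roots** use the sign-matched formulation q = −(b + sign(b)√Δ)/2,
  roots q/a and c/q, because the regime of interest places one root near
  zero where the textbook formula loses precision to cancellation. a = 0
  falls back to the linear root; complex pairs are reported as "no nonzero
  equilibria", never silently dropped.
* **Integration**: LSODA (adaptive, stiff-capable), rtol 1e−9, atol 1e−11.
  Convergence is declared when the max-norm of the right-hand side falls
  below 1e−8; the default horizon of 500 time units doubles automatically up
  to 4 times if the run has not settled. Tight tolerances keep simulated
  steady states comparable to the closed-form equilibria at 1e−4 or better.
* **States are not clipped.** Negative excursions beyond −1e−10 raise a
  warning, beyond −1e−6 an error: the first scale is round-off, the second
  indicates genuine escape from the feasible region.
* **Root ordering** is ascending in x throughout; tables list the smaller
  nonzero root first.
* **Ties/degeneracies**: double roots and zero eigenvalues are labelled
  "marginal"; the degenerate t1 + t2 = 0 boundary returns the reduced
  equilibrium set with an explanatory flag instead of raising, except for
  quantities (x3, Vieta) that are genuinely undefined there, which raise a
  degenerate-case error.

## Stability classification under therapy

Nonzero equilibria are classified from the eigenvalues of the 2-D (x, z)
Jacobian (y eliminated by the simplex constraint); the origin keeps its
tumor-direction label (sign of t2), which therapy cannot alter and whose z
direction always decays for l > 0. Writing φ(x) for the reduced scalar map
x[(1−x)(t2−(t1+t2)x) − ex], the Jacobian at a nonzero root satisfies
det = −l·φ′(x) and trace = φ′(x) + e·x − l. Hence φ′ > 0 always means a
saddle, but φ′ < 0 guarantees stability only when the trace is also
negative: for large e·x relative to l the equilibrium loses stability in an
oscillatory (Hopf-type) manner that the scalar reduced map cannot see. This
is rare in the sampled parameter ranges and essentially confined to roots
outside [0, 1], but it is a genuine 2-D effect; the property tests assert
the exact det/trace relations rather than blind 1-D/2-D agreement. It also
means that triples (w, j, l) sharing the same composite e have identical
equilibrium *locations* (and z_eq scaled by j/l) but not identical Jacobians,
so stability margins — and near the Hopf boundary even labels — can depend on
j and l individually.

## Therapy design

* A2/B2 (and the degenerate ridge t1 + t2 = 0 with t2 < 0): the cancer-free
  state already attracts the interval; recommendation is "none needed".
* A1/A3/B1: the asymptotic prescription e → ±∞ is replaced by a finite,
  target-driven value: e(x*) = [(t1+t2)x*² − (t1+2t2)x* + t2]/x* places an
  equilibrium exactly at the requested residual fraction x*, and the design
  is accepted only after the 2-D Jacobian verifies it stable. Moderate
  finite e already achieves low residual tumor fractions, which is the
  practically relevant regime. For B1 the *positive* sign of e is what
  produces the stable small-positive equilibrium (and what reproduces the
  published numeric example); the tension with the e → −∞ prescription is
  surfaced as a discrepancy flag on the recommendation, never hidden.
* B3 (bistable): e is set 10 % above the interior-exclusion threshold
  −2√(t2(t1+t2)) − (t1+2t2). The threshold is strictly positive throughout
  the B3 region (at e = 0 an interior root always exists there), so a
  multiplicative margin is well defined; the strict inequality needs
  headroom both for floating point and for a usable convergence rate, since
  the passage time through the near-root bottleneck diverges as e approaches
  the threshold.

The threshold is exposed as printed — a lower bound only. Whether an upper
bound was ever intended cannot be settled from the available derivations;
the analyzer therefore also reports where real roots lie, so a user sees
the full picture (large e pushes the real roots outside (0, 1) rather than
keeping them complex).

## Parameter-space sampling for tests

Property tests draw (t1, t2) uniformly from [−10, 10]² with rejection,
excluding |t1 + t2| < 0.05, |t1| or |t2| < 0.1, and interior roots within
0.05 of a boundary root. The exclusions keep the sampled dynamics
hyperbolic: near the degenerate set trajectories stall and closed-form/
simulation comparisons become ill-conditioned without informing about the
model. Samplers are seeded and deterministic.

What the synthetic parameter draws emulate — and what they do not: they
cover the six qualitative regimes of the deterministic mean-field model, so
passing tests show the analysis (classification, equilibria, stability,
design rules) is internally correct across regimes. They do not emulate
measured payoffs, finite-population noise, spatial structure, or
patient-specific time scales, so they say nothing about fit to clinical
data — the model is a qualitative framework whose payoffs would have to be
estimated per patient before any quantitative claim.

## Problem sizes

The property suites use 500 random instances for the root-solver/oracle and
inverse-design checks, 200 sampled B3 parameter sets for the exclusion
condition (20 of which are additionally integrated from five interior
starts), and 1000 draws for the classifier totality check; these sizes make
the suite exhaustive over regimes while completing in well under a minute.

## Known limitations

* Deterministic, well-mixed, two-strategy model; no finite-population
  stochasticity, spatial structure, or time-varying payoffs.
* z is an abstract "stem-cell level" with linear production/decay; no
  toxicity, cost, or dosing-schedule structure.
* The design returns open-loop constants (w, j, l); it does not re-plan as
  the state evolves.
* Stability analysis is local; basin statements rest on the 1-D structure of
  the reduced map plus simulation, not on a global Lyapunov argument.
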