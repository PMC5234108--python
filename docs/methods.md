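# Methods

## Scope and model

`stentopt` optimizes two decoupled stent design problems with one adaptive
surrogate loop: (1) stent geometry (strut widths, thickness, chamfer
radius) for fatigue safety, and (2) balloon length for uniform expansion.
The structural solver is treated as a black box throughout; the package
ships closed-form toy evaluators so every stage can run and be verified
without one.

## Sampling: modified rectangular grid

The initial design is a full-factorial grid with the smallest symmetric
per-axis level count m such that m^d ≥ n, thinned to n points by greedy
maximin selection (seeded farthest-pair start, ties broken by index).
With `shrink` > 0, every coordinate lying on a bound is moved into the
interior by `shrink`×range plus a seeded inward jitter uniform on
[0, 1%]×range. The jitter breaks replicated coordinate values; the inward
move gives the surrogate interior information that pure corner/edge points
would not. `shrink` defaults to 0.1 — it must be < 0.5 to preserve the
ordering of moved coordinates, and 0.1 moves boundary points far enough to
matter without distorting the grid's spread. With `shrink` = 0 the design
is the raw grid subset (useful for reproducing factorial designs exactly).
Grids above 10^6 candidate points are refused with the achievable factorial
sizes listed; at that size a factorial initial design is the wrong tool.

A statistical property (checked in the test suite) quantifies the intent:
the minimum pairwise distance of an MRG design beats that of a
uniform-random design of the same size in ≥ 90% of seeded trials.

## Surrogate: ordinary Kriging

* Correlation: anisotropic squared-exponential on unit-cube-scaled
  coordinates. Scaling keeps hyperparameter estimation independent of each
  variable's physical units (mm of strut width vs mm of balloon length
  spans very different ranges).
* Trend: constant (ordinary Kriging); the predictor is the classic BLUP
  with generalized-least-squares mean μ̂ = (1ᵀR⁻¹y)/(1ᵀR⁻¹1).
* Hyperparameters θ ∈ [10⁻³, 10³]^d, estimated by maximising the
  concentrated log-likelihood −(n ln σ̂² + ln det R)/2 with L-BFGS-B in log θ
  from 10 seeded starts (one fixed at θ = 10, the rest uniform in the log
  box). Ten restarts is a standard budget for d ≤ 3 likelihood surfaces;
  the fit cost is negligible next to any real solver call.
* Conditioning: a relative nugget of 10⁻¹⁰ on the correlation diagonal,
  escalated tenfold (to at most 10⁻⁶) if the Cholesky factorisation fails.
  Within this nugget the model still interpolates to ≈ 10⁻⁶ of the response
  span, which the tests assert.
* Degenerate data: for constant responses the variance MLE is 0; the
  process variance is floored at 10⁻¹² so predictive spread — and hence the
  acquisition — remains defined. Coincident training points (distance
  < 10⁻¹⁰ in scaled coordinates) with conflicting responses are rejected
  with the offending row pair named; interpolation conditions would
  contradict each other.

## Acquisition and loop

Expected Improvement is used in its minimisation form; maximisation
problems (the fatigue margin) are negated on entry, so one code path
serves both. EI maximisation runs a seeded 1024-point uniform scan, keeps
the best 8 scan points plus 56 fresh uniform starts, and polishes each
with bounded L-BFGS-B — cheap insurance against missing the EI peak, which
is sharply multimodal once the surrogate interpolates.

The loop starts from the best initial sample (so f₀ is the initial-design
minimum, the predecessor used by the third stopping inequality at k = 1),
adds exactly one evaluation per iteration, and refits the surrogate —
including hyperparameters — every iteration; at these training-set sizes a
full refit costs milliseconds and avoids stale correlation lengths. A
newly proposed point that coincides with an existing training point is
evaluated and recorded but not added to the training set (it would make
the correlation matrix singular); the EI at such a point is ~0, so the
first stopping inequality is already closing.

Stopping tolerances default to ε₁ = 10⁻³ (dimensionless EI ratio) and
ε₂ = ε₃ = 10⁻³ in objective units, with `max_iterations` = 50; all three
are problem-scale-dependent knobs the caller should set deliberately —
the bundled analyses tighten them to 10⁻⁴–10⁻⁵ where the objective is
known to be smooth and cheap.

Constraint handling (fatigue): the Goodman constraint enters through a
penalty — an infeasible design (any node above the failure line) receives
the worst feasible objective seen so far plus `penalty` (default 10) times
the constraint violation in MPa. This keeps the surrogate single-output
and orders every infeasible design behind every feasible one. The penalty
is order-dependent by construction (it references the running worst
feasible value); runs remain reproducible because the evaluation order is
seed-determined.

## Fatigue margin

The margin of a stress point is the signed Euclidean distance in raw
(σ_m, σ_a) MPa coordinates to the Goodman line, positive below the line:

    d = (1 − σ_m/σ_UTS − σ_a/σ_N) / √(1/σ_UTS² + 1/σ_N²).

Raw-MPa coordinates are the default because the diagram is conventionally
drawn in stress units; a normalized variant (coordinates σ_m/σ_UTS,
σ_a/σ_N, line x + y = 1) is available via `normalized=True` since the axis
scaling of a published diagram is not always stated. Compressive mean
stress (σ_m < 0) is handled by the same formula. The set-level
D_shortest is the minimum margin over nodes with the worst node reported;
tests verify it against brute force and the per-point margin against a
numeric point-to-line minimisation to 10⁻⁶.

## Expansion metrics

Radial displacements are r(t) − r0. Dogboning is evaluated at 32 ms (peak
inflation, the design objective) and 42 ms (after deflation, reported
only). Recoil and foreshortening are absolute differences in mm — recoil
r(32) − r(42) per end, foreshortening L0 − L(42) — matching the mm units
of the benchmark performance table; relative variants are a one-line
division the caller can apply. Percent improvement between an original and
an optimized deployment is 100·(1 − optimal/original).

Pressure calibration is plain bisection on the monotone pressure→radius
map, with an up-front straddle check and endpoint short-circuit; it needs
⌈log₂(bracket/resolution)⌉ evaluations, ≈ 23 for the bundled example.

## Toy models (what they emulate, what they don't)

The toy fatigue model emulates the monotone stiffness trade-off of strut
sizing: along an effective stiffness coordinate t(x) = w·u (u the
normalized deviation from the designated optimum x*, w = 1/√d), mean
stress rises as σ_m* e^{a t} while the cyclic amplitude falls as
σ_a* e^{−b t + c|u|²}. The balance a·σ_m*/σ_UTS = b·σ_a*/σ_N makes x* the
unique stationary point of the margin, and the quadratic term c|u|²
(c = 0.5) makes it a strict interior maximum — verified by a dense 30³
grid scan in the tests. Defaults σ_m* = 304.6 MPa, σ_a* = 22.02 MPa place
the optimum's stress state at a realistic operating point of a deployed
stainless-steel stent (margin 31.96 MPa). The gains (b = 0.4, c = 0.5)
are sized so the whole design box stays below the failure line: the
bundled fatigue problem then exercises the smooth-landscape path of the
optimizer, while the penalty path is exercised separately with synthetic
unsafe evaluators in the tests. Nodes beyond the governing node are
scaled-down stress copies (factors 0.70–0.95, fixed seed), so the minimum
over nodes never switches node and the closed-form optimum survives.

The toy balloon model gives both stent ends a displacement following the
pressure pulse — quadratic in normalized pressure while loading (expansion
accelerates), flat on the hold, then shedding a 5% elastic recoil during
unloading — with a distal gain linear in balloon length that crosses unity
exactly at L* (default: interval midpoint). Dogboning at 32 ms is then
strictly increasing in L, negative at the lower bound (spindle), positive
at the upper (dogbone), zero at L*. Radius after deflation is strictly
increasing in peak pressure, which the calibration search requires.

Neither model captures contact mechanics, plasticity, balloon folding or
vessel interaction; passing tests demonstrate the optimization machinery
recovers known optima of landscapes with the stated structure, not
anything about a particular physical stent.

## Problem sizes

The bundled analyses use 18 initial + ≤ 42 adaptive evaluations for the
3-D fatigue problem, 12 + ≤ 28 for Branin, 10 + ≤ 30 for the 1-D balloon
problem, and 10⁶ Monte-Carlo draws for the EI check — comparable to the
evaluation budgets a practitioner would grant a solver-backed study at
desk scale.

## Known limitations

* EI is single-point and noise-free; batch proposals and noisy responses
  (stochastic Kriging) are out of scope.
* The constraint penalty requires at least one feasible evaluation to be
  informative; a fully infeasible initial design degrades to pure
  violation minimisation.
* Table-backed evaluators cannot extrapolate: querying a design absent
  from the table is an error, so they suit surrogate fitting and replay,
  not adaptive search.
* The convergence test compares single iterations; on noisy or deceptive
  landscapes the triple criterion can fire early — tighten ε₁ first, it is
  the scale-free one.
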