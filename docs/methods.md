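# Methods

## Model

Bimanual coordination is described by a single collective variable, the
relative phase φ between the two effectors, evolving as an overdamped
gradient system on the circle, φ̇ = −dV/dφ.  The potential

V(φ) = −Σₙ₌₁ᴺ aₙ cos(nφ) − c/(2π I₀(κ)) [e^{κ cos(φ−ψ)} + e^{κ cos(φ+ψ)}]

has two parts with distinct time scales:

* **Skeleton** — the cosine Fourier series.  Cosine terms only, so that
  V(φ) = V(−φ): swapping the left and right effector must leave the
  dynamics invariant.  The coefficients aₙ encode the long-lived repertoire;
  they change during practice and then stay frozen.
* **Learning term** — a symmetric ±ψ pair of von Mises wells (circular
  Gaussians with mean ±ψ and width ≈ 1/κ, normalized by 2π I₀(κ) with I₀
  the modified Bessel function of order zero).  Its amplitude c is the
  transient practice force: zero before practice, growing during practice,
  decaying as c(t) = c_end · e^{−t/τ_c} afterwards.  The pair is symmetric
  because learning ψ entails learning −ψ.

With only a₁, a₂ present the flow reduces to the classic bistable HKB form
φ̇ = −a sin φ − 2b sin 2φ (a = a₁, b = a₂), with attractors at 0° and 180°
and the in-phase pattern the more stable of the two (V″(0) = a₁ + 4a₂ = 13
versus V″(180°) = −a₁ + 4a₂ = 11 at the default coefficients).

Two practice schedules tie all learning-phase parameters to one control
parameter λ ∈ [0, 5], a temporal measure of how much practice has occurred
(the mapping of λ onto trial number need not be linear; the default ramp is
linear but any saturating ramp can be supplied):

| profile     | skeleton                    | learning term                  | target |
|-------------|-----------------------------|--------------------------------|--------|
| bistable    | a₁=1, a₂=3, a₄=0.6λ         | c=0.5λ, κ=1.75λ                | ψ=90°  |
| multistable | a₁=1, a₂=3, a₄=3, a₃=0.6λ   | c=0.9λ, κ=1.75λ                | ψ=135° |

The bistable schedule undergoes a saddle-node bifurcation at λ_c ≈ 1.716
(computed by λ-bisection on the fixed-point count; the stated vicinity of
this transition is λ ≈ 2), creating an attractor–repellor pair near the
practiced 90°.  The multistable schedule creates no new fixed points: its
mid-range attractor drifts monotonically from ≈88.4° at λ=0 to ≈131.4° at
λ=5.  After practice, with c decayed and skeletons frozen, the bistable
learner's new mid-range attractor persists near 88° while the multistable
learner's attractor relaxes back to ≈102° — the mechanism behind the recall
dichotomy.

### Two flow variants

The default flow is the exact analytic gradient of V.  A second variant
(`form="as_printed"`) replaces the von Mises gradient factors
κ sin(φ∓ψ) e^{κ cos(φ∓ψ)} by a common factor κ sin φ multiplying the sum of
the two exponentials.  That expression is *not* the derivative of any
potential of the above form and, notably, produces **no** saddle-node
bifurcation anywhere on λ ∈ [0, 5] for the bistable schedule (the
open-half-circle fixed-point count stays 1).  It is retained behind an
explicit flag for sensitivity/reproduction studies only; everything else in
the package uses the gradient form, since φ̇ = −dV/dφ is the defining
relation of the model.

## Numerics

* **Angles** — degrees at every public interface, radians internally;
  wrapping onto (−180°, 180°].  V, flow and curvature are dimensionless
  with derivatives taken with respect to φ in radians.
* **Bessel evaluation** — the von Mises prefactor is computed through the
  exponentially scaled I₀ (`i0e`), with well contributions written as
  e^{κ(cos·−1)}, so κ of any size cannot overflow.
* **Fixed points** — dense grid scan (default 0.1°, capped at 0.5°) for
  sign changes of the flow, refined by Brent bisection to 10⁻⁸ rad.
  Floating-point dust at the symmetry-pinned roots 0° and 180° (sin nπ ≈
  10⁻¹⁶) is snapped to exact zeros so those roots are never lost between
  two same-sign grid samples.  Stability comes from the sign of the flow
  slope (−V″ for the gradient form); |slope| < 10⁻⁶ is classified marginal
  (needed exactly at a bifurcation).  An all-zero parameter set returns a
  dedicated `MarginalCircle` result — the whole circle is marginal.
* **Bifurcation sweeps** — per-λ fixed points linked into branches by
  nearest location within a 5° jump per λ step (default Δλ = 0.05);
  unlinked points start new branches, ambiguous linking is recorded as a
  diagram warning.  Events are logged where the open-half-circle (0°, 180°)
  fixed-point count changes, at the midpoint of the bracketing λ interval,
  with the mean location of the new/vanished pair attached.
  `detect_saddle_node` bisects λ against that count to a default tolerance
  of 10⁻⁴ and raises when no count change is bracketed.
* **Langevin integration** — fixed-step Euler–Maruyama,
  φ ← φ + flow·dt + √(Q dt)·ξ, dt = 0.001 by default, with a warning when
  dt·max|flow| > 0.5 rad.  Noise is drawn once from a seeded numpy
  `Generator`, so every stochastic operation is bit-reproducible given
  (seed, dt, duration); the inner loop is numba-compiled.  The stationary
  density of this 1-D overdamped system is Boltzmann, p ∝ e^{−2V/Q}, which
  the test suite verifies to total-variation distance ≤ 0.05 at duration
  5000 (and ≤ 0.08 at duration 1000 in the quicker module test).
* **Circular statistics** — CE is the circular mean direction of the
  wrapped error φ − ψ_req; SD is the angular deviation √(2(1−R)) in
  degrees, chosen because it is bounded and has an exact closed form for
  test oracles; AE = |CE| and RMSE = √(CE² + SD²).  RMSE is a composite
  accuracy-plus-stability score; the decomposition into CE and SD is the
  informative pair.

## Behavioral protocol emulation

The synthetic protocol emulates a scanning-probe methodology: required
phases 0°–180° in 15° steps, three repetitions per phase, trial duration 30
time units, the first 20 % of each trial discarded as transient.

* **Environmental coupling** — the required phase enters only through the
  trial's initial condition (φ₀ = ψ_req) plus noise; there is no forcing
  term in the flow.  This is the minimal emulation consistent with the
  model: a trial simply relaxes into whichever basin the required phase
  falls in.  Consequences worth knowing: (i) a probe started near a
  repellor splits between basins across repetitions; (ii) during
  multistable practice, trials at intermediate λ fall into the 180° basin
  until the migrating repellor crosses 135° (near λ ≈ 4.2), so the
  practice-block error curve is step-like rather than gradual, and SD is
  transiently inflated in the λ ≈ 4.4–4.8 window where the freshly passed
  repellor sits within noise reach of the start.  Real learners track the
  drifting attractor continuously; this emulation does not.
* **Repetition pooling** — per-phase summaries pool the post-burn-in
  samples of all repetitions before computing CE/SD.  Averaging per-rep
  summaries instead would let repetitions that settled into different
  attractors cancel into a spuriously tight CE; pooling makes basin
  splitting visible as large SD, which the stability rule then rejects.
* **Stability rule and classification** — a probe phase is stable when
  AE < 20° and SD < 20°.  A repertoire is *bistable* when its stable set is
  within {0°, 15°, 165°, 180°} and contains both ends, *multistable* when it
  additionally contains a stable phase strictly inside (30°, 150°), and
  *other* otherwise — including the degenerate everything-stable case,
  which is flagged rather than classified.
* **Task assignment** — bistable → learn 90°, multistable → learn 135°; in
  both cases a phase in-between the patterns already in the repertoire.
* **Noise level** — Q = 0.3 by default.  At the λ=0 bistable in-phase
  attractor (V″ = 13) this gives a stationary SD of √(Q/2V″) ≈ 6°, i.e.
  clearly stable patterns, while mid-range probes fail the 20° rule —
  the regime the classification logic is built for.
* **Practice block** — 50 trials, λ ramped linearly 0 → 5, one trial per λ
  from φ₀ = ψ_target.  End-of-learning parameters are the λ = 5 set.
* **Post-practice decay** — τ_c = 5 trial-equivalents by default ("fast"
  relative to the frozen skeleton, which does not decay at all); exposed as
  a parameter since only its separation of scales matters.
* **Recall** — the relaxed landscape is re-scanned; recall succeeds when
  some probe passes the stability rule *and* the pattern actually produced
  there (probe + CE, i.e. the attractor the trial settles into) lies within
  20° of the practiced target.  Judging by the probe phase alone would
  accept a stable attractor that has migrated ~33° away merely because a
  nearby probe still lands on it; the produced-phase criterion reproduces
  the intended dichotomy (bifurcation route: recall true; shift route:
  recall false) robustly across seeds.

## What the synthetic data do and do not show

The generator reproduces the model's phenomenology under idealized
conditions: stationary white noise, no frequency/amplitude dynamics, no
attentional or fatigue effects, no inter-trial carry-over, and a learner
that is exactly the model.  Passing tests therefore validate the
implementation and the internal consistency of the two learning routes —
not the fit of the model to any human data set.  Empirical scan profiles,
learning curves and recall rates of human participants are qualitatively
mirrored (RMSE minima at repertoire attractors, accuracy gain on both
routes, stability gain only on the bifurcation route, the recall
dichotomy), but no quantitative comparison to behavioral measurements is
made or implied.

## Problem sizes and runtimes

Defaults were chosen so the whole suite runs in well under a minute on one
CPU aside from the long Boltzmann check: fixed-point grids of 3600 points,
bifurcation sweeps of 101 λ values, 30-time-unit trials at dt = 0.001
(30 001 steps), 50-trial practice blocks, and a single 5×10⁶-step
trajectory for the stationary-density validation.

## Known limitations

* One-dimensional phase dynamics only; no oscillator-level (two coupled
  limb oscillators) model, hence no movement-frequency control parameter.
* The λ ramp is imposed, not learned; no closed-loop error-driven update of
  the skeleton coefficients.
* Branch linking is nearest-neighbor continuation, adequate for the 1-D
  sweeps here but not a general continuation method.
* The scanning emulation cannot reproduce attraction effects *between*
  successive probe trials (each trial is independent).
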