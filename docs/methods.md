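# Methods

## The spheroid model of software partial gravity

The quantity an RPM controls is the unit direction **u**(t) of Earth's
gravity expressed in the sample frame. Simulated microgravity corresponds to
**u** visiting the unit sphere uniformly in residence time, so the running
time average of **u** tends to zero. Partial gravity is obtained by shaping
the residence distribution instead: `rpmsim` targets the law of the unit
direction from the *focus* of a prolate spheroid to a point distributed
uniformly over the spheroid's surface, with one focus placed at the rotation
center.

With the semi-major axis normalized to 1 and eccentricity e ∈ [0, 1), the
semi-minor axis is b = √(1 − e²) and the focus sits at distance e from the
center. Parametrizing the surface by the axial coordinate z ∈ [−1, 1]:

* focal distance d(z) = 1 − e z (the ellipse's focal-radius identity);
* surface-area element dA ∝ √(1 − e² z²) dz (so z is *not* uniform);
* unit focus→surface direction: axial component a(z) = (e − z)/(1 − e z),
  transverse component √(1 − e²)·√(1 − z²)/(1 − e z), with
  a² + t² = 1 identically.

Uniform residence over the surface therefore delivers the mean gravity
factor

    p(e) = | ∫₋₁¹ (e − z) √((1 + e z)/(1 − e z)) dz | / ∫₋₁¹ √(1 − e² z²) dz .

p is strictly increasing, p(0) = 0 (sphere → microgravity) and p(e) → 1 as
e → 1 (the spheroid degenerates to a segment seen end-on). The far side of
the spheroid subtends directions near the symmetry axis for a
disproportionate share of the surface, which is the entire mechanism: no
hardware is added, only residence time is redistributed.

Numerics: both integrals are evaluated with adaptive Gauss–Kronrod
quadrature at absolute tolerance 1e-8 (the integrands are finite on the
closed interval, including the endpoints); the inverse map p ↦ e uses
bracketed Brent root finding on [0, 1 − 1e-9] at tolerance 1e-6, unique by
monotonicity. The identity a² + t² = 1 and the geometric meaning of d(z)
and dA are property-tested against brute-force 3D geometry, and p(e) is
cross-checked against an importance-weighted surface Monte Carlo oracle
(uniform z, weight √(1 − e²z²), axial component taken from raw coordinates)
at 10⁷ points per eccentricity.

## Direction sampler

`sample_spheroid_directions` draws the axial coordinate by rejection from
the density ∝ √(1 − e² z²) (uniform envelope; worst-case acceptance π/4),
the azimuth uniformly, and maps through the components above, expressed
about the spheroid's symmetry axis. The axis is fixed in the *sample* frame
(default (0, 0, −1), i.e. the specimen's "down"), so the delivered mean
gravity vector has a defined direction relative to the specimen — what a
biology experiment requires.

## Trajectory driver

The physical machine can only turn its two gimbal axes at bounded rates
(60°/s per axis on the standard hardware; the conventional "maximum
acceleration 60°/s" is dimensionally an angular speed and is interpreted as
such). The driver must produce a *continuous* gimbal trajectory whose
gravity-direction residence converges to the spheroid law.

Convention: lab gravity along −Z; outer gimbal angle α about lab X; inner
gimbal angle β about the rotated Y. Then
u(α, β) = (cos α sin β, −sin α, −cos α cos β), and the angles→direction map
has Jacobian |cos α|, vanishing on the lines α = ±π/2 where u = ∓ŷ and the
inner axis loses all authority over u (the gimbal singularity).

Two natural driver designs fail measurably and were rejected:

* *i.i.d. waypoints joined by great-circle arcs at constant speed*: the
  residence density of the connecting arcs is not the waypoint density
  (rotational symmetry rescues only the uniform case), and 4 h runs at
  e = 0.53 averaged ≈0.33 g against the 0.383 g target;
* any controller that commands isotropic headings for u: the inner axis
  moves u at speed ≤ max_rate·|cos α|, so u crawls and over-dwells near
  ±ŷ; measured residence maps showed 3× density in the singular cells, the
  known pole artifact of naive RPM drivers.

The implemented driver is a **kinetic (bouncy-particle) random walk in
gimbal-angle space**. The state (α, β) moves at axis rates
max_rate·(cos φ, sin φ) for a heading φ — each axis always within its rate
limit, speed constant in the angle metric — and the heading is

* *refreshed* to a uniform random angle at Poisson times (default rate
  0.3 s⁻¹, i.e. a random new direction roughly every 3 s: the machine's
  "random direction, random interval" operating mode), and
* *bounced* (reflected off the gradient of the log target density) at the
  Poisson rate max(0, −v·∇ log π), the canonical rate that makes π the
  stationary law of such a walk.

The angle-space target is π(α, β) ∝ f(u(α, β))·|cos α|, the spheroid
direction law times the Jacobian; its push-forward onto the sphere is then
*exactly* the spheroid law, and the |cos α| factor automatically repels the
walk from the singular lines, eliminating the pole artifact instead of
patching it. For e = 0 the target reduces to |cos α| alone and the
residence converges to the uniform sphere. The direction density per solid
angle used in the gradient is f(a) ∝ √(1 − e² z(a)²)·(1 − e²)/(1 − a e)²
with z(a) = (e − a)/(1 − a e) (the self-inverse Möbius relation between
axial direction component and surface coordinate).

Measured behaviour at the default settings (dt = 0.1 s, 60°/s): e = 0.53
runs of 4 h reach a time-averaged |g| within 0.02 of p(0.53) across seeds;
e = 0 runs of 2 h average below 0.02 g, and their 100-cell residence-density
coefficient of variation falls from ≈0.2 at 15 min to ≈0.04 at 8 h
(density range 0.91–1.08, i.e. essentially uniform). The running
mean-gravity error after 1 h is of order 10⁻², a few percent of the target
level; exact convergence constants depend on the heading-refresh rate and
are not tuned to any reference trajectory.

Discretization: rates are piecewise-constant over each step, so the angle
advance is exact per segment (default dt = 0.1 s; the event rates are
evaluated at the step start, an O(dt) approximation). Angles are kept
unwrapped internally for continuity and wrapped to [0, 2π) only in reports.

## Two-state baseline

`two_state_trajectory` points the sample down for a fraction q = (p + 1)/2
of the run and up for the remaining 1 − q, giving a mean gravity factor of
exactly |1 − 2q| = p up to the dt discretization of the switch time
(error ≤ dt/duration). It is the simplest scheme achieving a given p and
serves as an analytic fixture for the averaging and convergence machinery;
its orientation distribution (two atoms) is of course maximally non-uniform.

## Time averaging and convergence reporting

`time_averaged_gravity` integrates m·u over the trace with trapezoidal
weights and reports the Euclidean norm of the mean vector — the *actual*
simulated gravity factor. `convergence_report` evaluates the running
|‖mean up to t‖ − p| at every sample. Trapezoidal weighting makes the
average exact for piecewise-linear u and additive over trace
concatenation (property-tested to 1e-12).

## Centrifuge planning

All hardware-paradigm quantities are elementary rotational mechanics with
g₀ = 9.81 m/s² exactly (the constant the planning tables round against,
not the 9.80665 standard-gravity value):

* g level: ω²r/g₀, with mandatory unit tags ('rpm' or 'deg/s') on angular
  speeds;
* integer rpm solver: round((60/2π)·√(g·g₀/r)), ties to even;
* residual g: the same formula applied to the RPM frame rate at the platter
  radius — 60°/s at 0.20 m gives 0.0224 g, reported as 0.02 at two
  decimals, 5.3–5.9% of a 0.38 g simulation depending on rounding;
* combined level: the residual's direction relative to the centrifuge
  vector is time-varying and uncharacterized, so three conventions are
  offered — interval [g − res, g + res] (default, honest bracket), scalar
  sum g + res (conservative), and root-sum-square (uncorrelated
  components);
* g gradient: at fixed ω the level is linear in r, so Δg/g = extent/r;
* equi-gravity placement: n positions at the midpoints of equal sub-arcs of
  the constant-radius arc clipped to the dish interior (law-of-cosines
  half-angle), all at identical g by construction, with an explicit
  feasible-radius range in the error when the arc misses the dish.

Report rounding is half-up at two decimals, matching how such planning
tables are printed; raw values are always retained. One rounding quirk of the standard settings is reproduced honestly: 75 rpm at 16 cm computes to 1.006 g
(1.01 at two decimals), marginally above its nominal "1 g control" label.

## Density diagnostics

The sphere is partitioned into equal-area cells: polar bands equally spaced
in cos θ, each cut into equal azimuthal sectors (default 10 × 10 = 100
cells of solid angle 4π/100 exactly). Residence maps weight each trace
sample by half its adjacent time intervals, so cell times sum exactly to
the trace duration and non-uniform steps are handled; densities are
normalized so the area-weighted mean is 1 (1 everywhere = uniform).

The analytic expected map integrates the same axial density the sampler
draws from, through the closed-form antiderivative of √(1 − e² z²), mapped
to direction space by the Möbius relation above; it requires the symmetry
axis aligned with ±z because the partition is polar about z. Uniformity
metrics are the density CV (equal cells → plain standard deviation), the
extremes, and the Pearson chi-square of residence against equal
expectation. Observed-vs-expected comparisons between i.i.d. sampler draws
and the analytic map use the standard chi-square goodness of fit;
trajectory samples are strongly autocorrelated, so chi-square p-values for
*trajectory* maps are descriptive only.

## Synthetic data and what the tests show

All inputs are generated in-code (the package simulates a physical
apparatus; there is no external data). The simulated runs use the study
conditions of the planning table: 60°/s rate limit, dt = 0.1 s, durations
of 1–4 h, eccentricities {0.25, 0.53, 0.66, 0.87}, centrifuge radii 12 and
16 cm, a 20 cm platter, 9 cm dishes, 25 specimens. The simulator idealizes
the machine: no motor dynamics (torque, inertia, backlash), no fluid shear
inside culture vessels, no Coriolis terms, and instantaneous heading
changes at event times. Passing tests therefore demonstrate the kinematic
and statistical correctness of the paradigms, not the mechanical fidelity
of any particular machine.

## Open choices made

* Which frame carries the samples is not standardized across machines; the
  package fixes the convention above (outer about lab X, inner about
  rotated Y, sample frame = inner frame) and documents it once. Any fixed
  perpendicular pair is equivalent up to relabeling.
* The mean gravity "p" is reported as the magnitude of the mean vector;
  the delivered direction is the spheroid's symmetry axis in the sample
  frame.
* Reference mean-convergence figures quoted for real machines may be
  single-run or averaged values; the tests check decay and order of
  magnitude, never specific convergence constants.
* The trajectory driver is one admissible traversal of the target
  distribution, chosen for provable stationarity under the rate limits;
  real machines run proprietary drivers whose transients will differ.
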