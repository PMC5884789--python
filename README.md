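# rpmsim

Planning and simulation toolkit for **partial-gravity experiments on random
positioning machines (RPMs)**, for gravitational and space biologists who
need reduced-gravity levels — Moon (0.17 g), Mars (0.38 g), or anything in
between — on the ground.

A classic RPM rotates a specimen inside two independently driven
perpendicular frames so that the direction of Earth's gravity, expressed in
the sample frame, is randomized over the unit sphere; the time-averaged
gravity converges to zero (simulated microgravity). `rpmsim` implements the
two established ways to turn the same machine into a *partial*-gravity
simulator:

* **Software paradigm (RPM^SW).** The residence-time distribution of the
  gravity direction is biased from the uniform sphere to a uniform law over
  the surface of a **prolate spheroid with a focal point at the rotation
  center**. For a spheroid with semi-major axis 1 and eccentricity *e*, a
  surface point at axial coordinate *z* sits at focal distance 1 − *ez* and
  carries area element ∝ √(1 − *e*²*z*²) dz, so the mean gravity factor is

      p(e) = | ∫₋₁¹ (e − z) √((1 + ez)/(1 − ez)) dz | / ∫₋₁¹ √(1 − e²z²) dz ,

  a strictly increasing map from *e* ∈ [0, 1) onto [0, 1): *e* = 0 is
  microgravity, *e* = 0.53 delivers Mars's 0.38 g. The package evaluates
  p(e) by adaptive quadrature, inverts it by bracketed root finding, samples
  the target direction law, and simulates gimbal-level trajectories whose
  residence converges to it under the 60°/s axis-rate limit.

* **Hardware paradigm (RPM^HW).** A centrifuge mounted on the RPM adds a
  controlled centripetal acceleration ω²r/g₀ on top of the simulated
  weightlessness. The planner solves integer-rpm settings for a target g at
  a given radius, quantifies the parasitic residual g from the RPM frame
  rotation (≈0.02 g at 60°/s on a 20 cm platter, ~5% of a Mars
  simulation), the g gradient across a specimen's radial extent, and places
  specimens along **equi-gravity arcs** of constant radius.

There is also the trivial **two-state baseline** (pointing the sample down a
fraction *q* = (*p* + 1)/2 of the time and up otherwise) and a
**diagnostics** layer that bins gravity traces into an equal-area partition
of the sphere and reports normalized residence densities (1 = uniform),
uniformity metrics, and observed-vs-expected comparisons against the
analytic spheroid law.

## Worked example

Reproduce the five-condition planning table from first principles:

```text
$ rpmsim table1
Condition        g level   rpm  radius cm  eccentricity
Moon                0.17    36         12          0.25
Mars                0.38    53         12          0.53
1/2 g-Earth         0.50    53         16          0.66
3/4 g-Earth         0.75    75         12          0.87
1 g HW control      1.01    75         16             —
```

Each row shows the integer rpm/radius pair whose centripetal acceleration
delivers the target g on the hardware paradigm, and the spheroid
eccentricity delivering the same mean g on the software paradigm. (The 1 g
control row computes to 1.006 g at its printed setting, hence 1.01.)

Plan a Mars run on the centrifuge:

```text
$ rpmsim plan-hw --target-g 0.38 --radius-cm 12
Hardware partial-g plan
  target g            : 0.38 g
  radius              : 12.0 cm
  angular speed       : 53 rpm
  achieved g          : 0.3768 g (0.38)
  residual g (frame)  : 0.0224 g (0.02)
  relative error      : 5.9 %
  g gradient          : 0.345–0.408 g over 2.0 cm (Δg/g = 16.7 %)
```

53 rpm at 12 cm gives 0.377 g; the frame rotation superimposes up to
0.022 g (5.9% of the target), and a specimen spanning 2 cm radially sees a
17% g spread — the reason specimens are placed along an equi-gravity arc
(`rpmsim.equigravity_positions`).

Simulate four hours of the software paradigm at the Mars eccentricity and
check convergence:

```text
$ rpmsim simulate --mode sw --eccentricity 0.53 --hours 4 --seed 1 --out-trace mars.csv
mode=sw duration=14400s seed=1
desired mean g      : 0.3831
achieved mean g     : 0.3828
final convergence   : 0.0002753
trace written to mars.csv
```

The time-averaged gravity magnitude of the simulated trajectory (0.3828 g)
matches the quadrature target p(0.53) = 0.3831 to three decimals after 4 h.
`rpmsim diagnose --trace mars.csv` then maps the orientation residence
density over a 100-cell equal-area partition of the sphere.

The same is available as a library:

```python
from rpmsim import eccentricity_for_mean_g, plan_hw, generate_sw_trajectory

e = eccentricity_for_mean_g(0.38)      # 0.5264
plan = plan_hw(target_g=0.38, radius=0.12)   # rpm 53, residual 0.0224 g, ...
```

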