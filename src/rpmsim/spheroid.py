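"""Software partial gravity on an RPM: the prolate-spheroid orientation distribution.

A regular RPM randomizes the sample-frame gravity direction uniformly over the
unit sphere, so the time-averaged gravity vector converges to zero (simulated
microgravity). The software partial-g paradigm biases the residence-time
distribution instead of adding hardware: the gravity direction is made to
dwell uniformly over the surface of a prolate spheroid, with one *focal point*
of the spheroid at the rotation center. Viewed from that focus, surface points
on the far side of the spheroid subtend directions near the symmetry axis for
a disproportionate share of the time, so the mean gravity direction is no
longer zero but a net vector of magnitude ``p`` along the axis. The spheroid's
eccentricity ``e`` is the single tuning knob: ``e = 0`` is the sphere
(microgravity, ``p = 0``) and ``p`` grows monotonically toward 1 as
``e`` approaches 1.

Geometry (semi-major axis normalized to 1, focus at the origin):

* a surface point at axial coordinate ``z ∈ [-1, 1]`` has focal distance
  ``d(z) = 1 - e z`` and surface-area element ``dA ∝ sqrt(1 - e² z²) dz``;
* the unit direction from the focus to that point has axial component
  ``(e - z)/(1 - e z)`` (measured along the delivered mean-gravity axis) and
  transverse component ``sqrt(1-e²) sqrt(1-z²)/(1 - e z)``;
* uniform residence over the surface then gives the mean gravity factor

  ``p(e) = |∫ (e - z) sqrt((1+e z)/(1-e z)) dz| / ∫ sqrt(1 - e² z²) dz``

  with both integrals over ``[-1, 1]``, evaluated here by adaptive quadrature.

The module provides the forward map ``p(e)``, its monotone inverse, an i.i.d.
sampler of the target direction distribution, a gimbal-level trajectory driver
that chases sampled waypoints along great circles, the trivial two-state
baseline (down a fraction ``q = (p+1)/2`` of the time, up otherwise), and
running-convergence reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .exceptions import EmptyTraceError, InvalidArgumentError
from .kinematics import (
    GravityTrace,
    gimbal_gravity_direction,
    running_time_averaged_gravity,
    wrap_angle,
)

__all__ = [
    "SpheroidSpec",
    "PartialGTarget",
    "ConvergenceReport",
    "mean_g_from_eccentricity",
    "eccentricity_for_mean_g",
    "axial_component",
    "transverse_component",
    "focal_distance",
    "band_weight",
    "sample_spheroid_directions",
    "generate_sw_trajectory",
    "two_state_trajectory",
    "convergence_report",
]

_DOWN = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class SpheroidSpec:
    """Prolate spheroid defining the target orientation distribution.

    Semi-major axis is normalized to 1, so the semi-minor axis is
    ``sqrt(1 - e²)`` and the focal distance from the center is ``e`` itself.
    ``symmetry_axis`` is the direction (in the sample frame) along which the
    net mean gravity is delivered; by default the sample's "down".
    """

    eccentricity: float
    symmetry_axis: np.ndarray = field(default_factory=lambda: _DOWN.copy())

    def __post_init__(self) -> None:
        e = float(self.eccentricity)
        if not (0.0 <= e < 1.0) or not math.isfinite(e):
            raise InvalidArgumentError(f"eccentricity must be in [0, 1), got {e!r}")
        object.__setattr__(self, "eccentricity", e)
        axis = np.asarray(self.symmetry_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if axis.shape != (3,) or not math.isfinite(norm) or abs(norm - 1.0) > 1e-9:
            raise InvalidArgumentError("symmetry_axis must be a unit 3-vector")
        object.__setattr__(self, "symmetry_axis", axis)

    @property
    def semi_major(self) -> float:
        return 1.0

    @property
    def semi_minor(self) -> float:
        return math.sqrt(1.0 - self.eccentricity**2)

    @property
    def focal_distance(self) -> float:
        return self.eccentricity


@dataclass(frozen=True)
class PartialGTarget:
    """Target mean gravity factor ``p`` and the derived two-state fraction ``q``.

    The simplest scheme achieving a mean factor ``p`` points the sample in
    the gravity direction a fraction ``q = (p + 1)/2`` of the time and in the
    antigravity direction the remaining ``1 - q``.
    """

    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise InvalidArgumentError(f"target gravity factor must be in [0, 1], got {self.p!r}")

    @property
    def q(self) -> float:
        return (self.p + 1.0) / 2.0


@dataclass
class ConvergenceReport:
    """Running error between achieved and desired mean gravity factor."""

    times: np.ndarray
    errors: np.ndarray
    desired_p: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.times.size != self.errors.size or self.times.size == 0:
            raise InvalidArgumentError("times and errors must be equal-length, non-empty")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(self.errors < 0):
            raise InvalidArgumentError("errors are absolute values, must be >= 0")

    @property
    def final_error(self) -> float:
        return float(self.errors[-1])

    def to_dict(self) -> dict:
        return {
            "desired_p": self.desired_p,
            "final_error": self.final_error,
            "times": self.times.tolist(),
            "errors": self.errors.tolist(),
        }


# --- geometry of the focus-centered prolate spheroid -------------------------


def focal_distance(e: float, z: np.ndarray | float) -> np.ndarray | float:
    """Distance from the focus (at the origin) to the surface point at axial z."""
    return 1.0 - e * np.asarray(z, dtype=float)


def axial_component(e: float, z: np.ndarray | float) -> np.ndarray | float:
    """Axial component of the unit focus→surface direction, along the mean-g axis."""
    z = np.asarray(z, dtype=float)
    return (e - z) / (1.0 - e * z)


def transverse_component(e: float, z: np.ndarray | float) -> np.ndarray | float:
    """Transverse component of the unit focus→surface direction."""
    z = np.asarray(z, dtype=float)
    return math.sqrt(1.0 - e * e) * np.sqrt(1.0 - z * z) / (1.0 - e * z)


def band_weight(e: float, z: np.ndarray | float) -> np.ndarray | float:
    """Unnormalized surface-area density of the axial coordinate, ∝ sqrt(1-e²z²)."""
    z = np.asarray(z, dtype=float)
    return np.sqrt(1.0 - (e * z) ** 2)


def _check_eccentricity(e: float) -> float:
    e = float(e)
    if not math.isfinite(e) or not (0.0 <= e < 1.0):
        raise InvalidArgumentError(f"eccentricity must be in [0, 1), got {e!r}")
    return e


def mean_g_from_eccentricity(e: float, _full_output: bool = False):
    """Mean gravity factor p of uniform residence over a spheroid of eccentricity e.

    Evaluates the two quadratures of the module docstring to absolute
    tolerance 1e-8 each. Strictly increasing in e; 0 at e = 0; → 1 as e → 1.
    """
    e = _check_eccentricity(e)
    if e == 0.0:
        return (0.0, 0) if _full_output else 0.0
    num, _, info_n = quad(
        lambda z: (e - z) * math.sqrt((1.0 + e * z) / (1.0 - e * z)),
        -1.0,
        1.0,
        epsabs=1e-8,
        limit=200,
        full_output=True,
    )[:3]
    den, _, info_d = quad(
        lambda z: math.sqrt(1.0 - (e * z) ** 2),
        -1.0,
        1.0,
        epsabs=1e-8,
        limit=200,
        full_output=True,
    )[:3]
    p = abs(num) / den
    if _full_output:
        return p, int(info_n["neval"]) + int(info_d["neval"])
    return p


def eccentricity_for_mean_g(p: float) -> float:
    """Inverse of :func:`mean_g_from_eccentricity` by bracketed root finding.

    Monotonicity of p(e) guarantees a unique root in [0, 1).
    """
    p = float(p)
    if not math.isfinite(p) or p < 0.0 or p >= 1.0:
        raise InvalidArgumentError(f"target mean g must be in [0, 1), got {p!r}")
    if p == 0.0:
        return 0.0
    hi = 1.0 - 1e-9
    return float(brentq(lambda e: mean_g_from_eccentricity(e) - p, 0.0, hi, xtol=1e-6))


# --- sampling the target direction distribution ------------------------------


def _sample_axial_z(e: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw z on [-1, 1] with density ∝ sqrt(1 - e² z²) by rejection.

    The envelope is uniform with acceptance probability sqrt(1-e²z²) ≤ 1;
    worst-case efficiency is π/4 even as e → 1.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        k = max(int((n - filled) * 1.6) + 16, 32)
        z = rng.uniform(-1.0, 1.0, size=k)
        keep = z[rng.uniform(0.0, 1.0, size=k) < np.sqrt(1.0 - (e * z) ** 2)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _axis_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed orthonormal triad."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def sample_spheroid_directions(
    spec: SpheroidSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """i.i.d. draws of the focus→surface unit direction under uniform residence.

    The axial coordinate z is drawn with density ∝ sqrt(1 - e² z²), the
    azimuth uniformly; each draw is the unit direction from the focus to the
    surface point, expressed about ``spec.symmetry_axis`` so that the sample
    mean converges to ``p(e) * symmetry_axis``.
    """
    if n < 1:
        raise InvalidArgumentError("need at least one sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e = spec.eccentricity
    z = _sample_axial_z(e, n, rng)
    a = axial_component(e, z)
    tr = transverse_component(e, z)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    e1, e2 = _axis_basis(spec.symmetry_axis)
    dirs = (
        a[:, None] * spec.symmetry_axis[None, :]
        + (tr * np.cos(phi))[:, None] * e1[None, :]
        + (tr * np.sin(phi))[:, None] * e2[None, :]
    )
    # kill last-bit drift so downstream unit-norm invariants hold exactly
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


# --- trajectory drivers -------------------------------------------------------


def _dlogf_da(e: float, a: float) -> float:
    """d/da of log target density per solid angle, at axial component a.

    The direction density of the spheroid law depends only on the axial
    component a = u·axis; with z(a) = (e - a)/(1 - a e) it is
    f(a) ∝ sqrt(1 - e² z²) · (1 - e²)/(1 - a e)².
    """
    z = (e - a) / (1.0 - a * e)
    dz = (e * e - 1.0) / (1.0 - a * e) ** 2
    return -e * e * z * dz / (1.0 - (e * z) ** 2) + 2.0 * e / (1.0 - a * e)


def generate_sw_trajectory(
    spec: SpheroidSpec,
    duration: float,
    dt: float = 0.1,
    max_rate: float = math.radians(60.0),
    seed: int | None = None,
    initial_angles: tuple[float, float] = (0.0, 0.0),
    heading_refresh_rate: float = 0.3,
) -> GravityTrace:
    """Simulate the software partial-g driver through the two-gimbal model.

    The driver is a kinetic (bouncy-particle) random walk in *gimbal-angle
    space*. The pair (α, β) of outer/inner angles moves at constant axis
    rates ``max_rate·(cos φ, sin φ)`` for a random heading φ — so both axes
    always respect the rate limit — with the heading refreshed at Poisson
    times (mean interval ``1/heading_refresh_rate``) and *bounced* off the
    gradient of the log target density at the Poisson rate that makes that
    density the stationary law of the walk. The angle-space target is the
    spheroid direction law times the Jacobian |cos α| of the angles→sphere
    map, so the push-forward of the walk's residence onto the gravity
    direction is exactly the spheroid law; the Jacobian factor also repels
    the walk from the gimbal singularity at α = ±π/2, where naive drivers
    pile up density on the u = ±y poles. For e = 0 the target reduces to
    |cos α| alone and the residence converges to the uniform sphere.

    Long-run properties: the empirical residence density converges to the
    spheroid law and the time-averaged gravity magnitude to p(e).
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    if max_rate <= 0:
        raise InvalidArgumentError("max_rate must be positive")
    rng = np.random.default_rng(seed)

    n_steps = math.ceil(duration / dt)
    t = np.arange(n_steps + 1, dtype=float) * dt
    t[-1] = duration
    alpha = np.empty(n_steps + 1)
    beta = np.empty(n_steps + 1)
    a, b = float(initial_angles[0]), float(initial_angles[1])
    alpha[0], beta[0] = a, b

    e = spec.eccentricity
    kx, ky, kz = (float(c) for c in spec.symmetry_axis)
    s = max_rate
    p_refresh = 1.0 - math.exp(-heading_refresh_rate * dt)
    uni_b = rng.random(n_steps)  # bounce draws
    uni_r = rng.random(n_steps)  # refresh draws
    sin, cos = math.sin, math.cos
    phi = rng.uniform(0.0, 2.0 * math.pi)
    va, vb = cos(phi), sin(phi)
    bounce_count = 0
    refresh_count = 0

    for i in range(n_steps):
        sa, ca = sin(a), cos(a)
        sb, cb = sin(b), cos(b)
        # gradient of log[target] in angle space; target = f(u·axis)·|cos α|
        if e > 0.0:
            ax_c = kx * ca * sb - ky * sa - kz * ca * cb  # u·axis
            g = _dlogf_da(e, ax_c)
            ga = g * (kx * (-sa * sb) - ky * ca + kz * (sa * cb))
            gb = g * (kx * (ca * cb) + kz * (ca * sb))
        else:
            ga = gb = 0.0
        ca_safe = ca if abs(ca) > 1e-12 else (1e-12 if ca >= 0.0 else -1e-12)
        ga += -sa / ca_safe  # d log|cos α| / dα
        drift = s * (va * ga + vb * gb)
        if drift < 0.0 and uni_b[i] < 1.0 - math.exp(drift * dt):
            # bounce: reflect the heading off the density gradient
            gn = math.hypot(ga, gb)
            if gn > 1e-12:
                na, nb = ga / gn, gb / gn
                d2 = 2.0 * (va * na + vb * nb)
                va, vb = va - d2 * na, vb - d2 * nb
                bounce_count += 1
        if uni_r[i] < p_refresh:
            phi = rng.uniform(0.0, 2.0 * math.pi)
            va, vb = cos(phi), sin(phi)
            refresh_count += 1
        step = t[i + 1] - t[i]
        a += s * va * step
        b += s * vb * step
        alpha[i + 1] = a
        beta[i + 1] = b

    u = gimbal_gravity_direction(alpha, beta)
    meta = {
        "driver": "gimbal_bounce_walk",
        "eccentricity": spec.eccentricity,
        "seed": seed,
        "dt": dt,
        "max_rate": max_rate,
        "heading_refresh_rate": heading_refresh_rate,
        "bounce_count": bounce_count,
        "refresh_count": refresh_count,
        "rates_clipped": False,  # axis rates are max_rate·(cos φ, sin φ) by design
        "final_angles_wrapped": [float(wrap_angle(alpha[-1])), float(wrap_angle(beta[-1]))],
    }
    return GravityTrace(t=t, u=u, metadata=meta)


def two_state_trajectory(
    target: PartialGTarget, duration: float, dt: float = 0.1
) -> GravityTrace:
    """Deterministic two-state baseline: down for q·duration, then up.

    The time-averaged gravity magnitude equals ``p`` up to the dt
    discretization of the switch time (error ≤ dt/duration).
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    n_steps = math.ceil(duration / dt)
    t = np.arange(n_steps + 1, dtype=float) * dt
    t[-1] = duration
    switch = target.q * duration
    u = np.where((t <= switch)[:, None], _DOWN[None, :], -_DOWN[None, :])
    meta = {"driver": "two_state", "p": target.p, "q": target.q, "dt": dt}
    return GravityTrace(t=t, u=u, metadata=meta)


def convergence_report(trace: GravityTrace, desired_p: float) -> ConvergenceReport:
    """Running |achieved − desired| mean-gravity-factor error at each sample time."""
    if len(trace) == 0:
        raise EmptyTraceError("cannot report convergence of an empty trace")
    times, mags = running_time_averaged_gravity(trace)
    return ConvergenceReport(times=times, errors=np.abs(mags - desired_p), desired_p=desired_p)
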