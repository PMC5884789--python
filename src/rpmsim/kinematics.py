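"""Rigid-body kinematics of a two-gimbal random positioning machine (RPM).

An RPM carries a sample inside two independently driven perpendicular frames.
The quantity of biological interest is not the machine's attitude itself but
the direction of Earth's gravity *as seen by the sample*: rotating the sample
frame redistributes that direction over the unit sphere, and its time average
sets the net simulated gravity level.

Conventions (fixed once, used throughout the package):

* lab gravity points along ``-Z`` of the lab frame;
* the outer gimbal rotates about the lab ``X`` axis by angle ``alpha``;
* the inner gimbal rotates about the outer frame's (rotated) ``Y`` axis by
  angle ``beta``;
* an :class:`Orientation` is the attitude of the sample, i.e. the rotation
  taking sample-frame vectors to lab-frame vectors; its inverse therefore
  expresses lab vectors (gravity) in the sample frame.

With these conventions the gravity direction in the sample frame has the
closed form ``u = (cos(alpha) sin(beta), -sin(alpha), -cos(alpha) cos(beta))``,
which the trajectory integrators exploit for speed; the quaternion-based
:class:`Orientation` path is retained as the general-purpose representation
and is cross-checked against the closed form in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .exceptions import EmptyTraceError, InvalidArgumentError

__all__ = [
    "Orientation",
    "GimbalState",
    "GravityTrace",
    "LAB_GRAVITY_DIRECTION",
    "orientation_from_gimbal",
    "gravity_in_sample_frame",
    "gimbal_gravity_direction",
    "integrate_gimbal_trajectory",
    "time_averaged_gravity",
    "running_time_averaged_gravity",
    "wrap_angle",
]

#: Direction of Earth's gravity in the lab frame (unit vector).
LAB_GRAVITY_DIRECTION = np.array([0.0, 0.0, -1.0])

_UNIT_TOL = 1e-9


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (radians) to ``[0, 2*pi)`` for reporting.

    Internal integrations keep angles unwrapped to preserve continuity;
    wrapping is applied only when angles are displayed or serialized.
    """
    return np.mod(angle, 2.0 * np.pi)


@dataclass(frozen=True)
class Orientation:
    """Attitude of the sample: rotation mapping sample-frame to lab-frame vectors.

    Stored as a unit quaternion (scalar-last, scipy convention). The inverse
    maps lab-frame vectors into the sample frame, which is how the gravity
    direction experienced by the specimen is obtained.
    """

    quat: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quat, dtype=float)
        if q.shape != (4,) or not np.all(np.isfinite(q)):
            raise InvalidArgumentError("orientation quaternion must be 4 finite numbers")
        norm = float(np.linalg.norm(q))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise InvalidArgumentError(f"orientation quaternion norm {norm!r} != 1")
        object.__setattr__(self, "quat", q)

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]))

    @classmethod
    def from_rotation(cls, rotation: Rotation) -> "Orientation":
        q = rotation.as_quat()
        return cls(q / np.linalg.norm(q))

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def as_matrix(self) -> np.ndarray:
        return self.as_rotation().as_matrix()

    def inverse(self) -> "Orientation":
        return Orientation.from_rotation(self.as_rotation().inv())

    def compose(self, other: "Orientation") -> "Orientation":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return Orientation.from_rotation(self.as_rotation() * other.as_rotation())

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        return self.as_rotation().apply(vectors)


@dataclass
class GimbalState:
    """Instantaneous state of the two gimbal axes.

    Angles are stored unwrapped (radians); rates in rad/s. ``max_rate`` is the
    per-axis angular speed limit — 60 deg/s on the standard machines.
    """

    outer_angle: float
    inner_angle: float
    outer_rate: float = 0.0
    inner_rate: float = 0.0
    max_rate: float = math.radians(60.0)

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise InvalidArgumentError("max_rate must be positive")
        if abs(self.outer_rate) > self.max_rate + 1e-12:
            raise InvalidArgumentError("outer_rate exceeds max_rate")
        if abs(self.inner_rate) > self.max_rate + 1e-12:
            raise InvalidArgumentError("inner_rate exceeds max_rate")

    @property
    def wrapped_angles(self) -> tuple[float, float]:
        """Angles wrapped to [0, 2*pi) for reporting."""
        return (float(wrap_angle(self.outer_angle)), float(wrap_angle(self.inner_angle)))


@dataclass
class GravityTrace:
    """Time series of the gravity direction expressed in the sample frame.

    Attributes
    ----------
    t : (n,) array
        Sample times in seconds, strictly increasing.
    u : (n, 3) array
        Unit direction of lab gravity in the sample frame at each time.
    m : (n,) array
        Gravity magnitude in g units at each time (1 for a static lab;
        centrifuge paradigms may carry other magnitudes).
    metadata : dict
        Provenance: seed, driver name, clipping flags, waypoint counts, …
    """

    t: np.ndarray
    u: np.ndarray
    m: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.t.ndim != 1 or self.u.shape != (self.t.size, 3):
            raise InvalidArgumentError("trace needs t of shape (n,) and u of shape (n, 3)")
        if self.t.size == 0:
            raise EmptyTraceError("gravity trace must contain at least one sample")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise InvalidArgumentError("trace times must be strictly increasing")
        norms = np.linalg.norm(self.u, axis=1)
        if not np.allclose(norms, 1.0, atol=_UNIT_TOL, rtol=0):
            raise InvalidArgumentError("every gravity direction must be unit-norm")
        if self.m is None:
            self.m = np.ones_like(self.t)
        else:
            self.m = np.asarray(self.m, dtype=float)
            if self.m.shape != self.t.shape:
                raise InvalidArgumentError("m must have the same shape as t")
            if np.any(self.m < 0):
                raise InvalidArgumentError("gravity magnitudes must be non-negative")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "ux": self.u[:, 0],
                "uy": self.u[:, 1],
                "uz": self.u[:, 2],
                "m": self.m,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trace as UTF-8 CSV with header ``t,ux,uy,uz,m``."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GravityTrace":
        df = pd.read_csv(path)
        u = df[["ux", "uy", "uz"]].to_numpy()
        # re-normalize against round-tripping noise from decimal serialization
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        return cls(t=df["t"].to_numpy(), u=u, m=df["m"].to_numpy())

    @classmethod
    def concatenate(cls, traces: Sequence["GravityTrace"]) -> "GravityTrace":
        """Join traces end-to-end, shifting times so segments abut."""
        if not traces:
            raise EmptyTraceError("nothing to concatenate")
        ts, us, ms = [traces[0].t], [traces[0].u], [traces[0].m]
        offset = float(traces[0].t[-1])
        for tr in traces[1:]:
            shifted = tr.t - tr.t[0] + offset
            ts.append(shifted[1:] if shifted.size > 1 else shifted[:0])
            us.append(tr.u[1:] if shifted.size > 1 else tr.u[:0])
            ms.append(tr.m[1:] if shifted.size > 1 else tr.m[:0])
            offset = float(shifted[-1])
        return cls(t=np.concatenate(ts), u=np.vstack(us), m=np.concatenate(ms))


def orientation_from_gimbal(outer_angle: float, inner_angle: float) -> Orientation:
    """Attitude produced by outer rotation about lab X, then inner about the rotated Y.

    The composition is intrinsic: the inner gimbal axis is the outer frame's
    Y axis *after* the outer rotation has been applied.
    """
    if not (math.isfinite(outer_angle) and math.isfinite(inner_angle)):
        raise InvalidArgumentError("gimbal angles must be finite")
    rot = Rotation.from_euler("XY", [outer_angle, inner_angle])
    return Orientation.from_rotation(rot)


def gravity_in_sample_frame(orientation: Orientation) -> np.ndarray:
    """Unit direction of lab gravity expressed in the sample frame."""
    return orientation.inverse().apply(LAB_GRAVITY_DIRECTION)


def gimbal_gravity_direction(
    outer_angle: float | np.ndarray, inner_angle: float | np.ndarray
) -> np.ndarray:
    """Closed-form sample-frame gravity direction for gimbal angles.

    Vectorized; equals ``gravity_in_sample_frame(orientation_from_gimbal(a, b))``
    and is what the trajectory integrators use internally.
    """
    a = np.asarray(outer_angle, dtype=float)
    b = np.asarray(inner_angle, dtype=float)
    u = np.stack(
        [np.cos(a) * np.sin(b), -np.sin(a), -np.cos(a) * np.cos(b)],
        axis=-1,
    )
    return u


def _sample_times(duration: float, dt: float) -> np.ndarray:
    """Grid 0, dt, 2 dt, …, ending exactly at ``duration`` (last step may be short)."""
    n = math.ceil(duration / dt)
    t = np.arange(n + 1, dtype=float) * dt
    t[-1] = duration
    return t


def integrate_gimbal_trajectory(
    rate_profile: Callable[[float], tuple[float, float]],
    duration: float,
    dt: float = 0.1,
    max_rate: float = math.radians(60.0),
    initial_angles: tuple[float, float] = (0.0, 0.0),
) -> GravityTrace:
    """Integrate a gimbal rate profile into a sample-frame gravity trace.

    ``rate_profile(t)`` returns (outer_rate, inner_rate) in rad/s at time t;
    rates are held constant over each step (exact for the piecewise-constant
    drivers used in this package) and clipped to ``±max_rate``. Clipping, if
    it occurred, is recorded in the trace metadata.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    if dt > duration:
        dt = duration
    if max_rate <= 0:
        raise InvalidArgumentError("max_rate must be positive")

    t = _sample_times(duration, dt)
    n = t.size
    alpha = np.empty(n)
    beta = np.empty(n)
    alpha[0], beta[0] = initial_angles
    clipped = False
    for i in range(n - 1):
        wa, wb = rate_profile(float(t[i]))
        if abs(wa) > max_rate or abs(wb) > max_rate:
            clipped = True
            wa = min(max(wa, -max_rate), max_rate)
            wb = min(max(wb, -max_rate), max_rate)
        step = t[i + 1] - t[i]
        alpha[i + 1] = alpha[i] + wa * step
        beta[i + 1] = beta[i] + wb * step

    u = gimbal_gravity_direction(alpha, beta)
    meta = {
        "driver": "rate_profile",
        "dt": dt,
        "max_rate": max_rate,
        "rates_clipped": clipped,
        "final_angles_wrapped": [float(wrap_angle(alpha[-1])), float(wrap_angle(beta[-1]))],
    }
    return GravityTrace(t=t, u=u, metadata=meta)


def time_averaged_gravity(trace: GravityTrace) -> tuple[np.ndarray, float]:
    """Time-weighted mean gravity vector and its magnitude (g units).

    The mean of ``m * u`` over the trace with trapezoidal weighting in time;
    the returned magnitude — the Euclidean norm of the mean vector — is the
    *actual* net simulated gravity factor of the run.
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot average an empty trace")
    g = trace.u * trace.m[:, None]
    if len(trace) == 1 or trace.duration == 0:
        mean = g[0]
    else:
        mean = np.trapezoid(g, trace.t, axis=0) / trace.duration
    return mean, float(np.linalg.norm(mean))


def running_time_averaged_gravity(trace: GravityTrace) -> tuple[np.ndarray, np.ndarray]:
    """Running mean-gravity magnitude up to each sample time.

    Returns ``(t, magnitudes)`` where ``magnitudes[k]`` is the norm of the
    trapezoidal time average of ``m*u`` over ``[t[0], t[k]]``. The first
    entry is the instantaneous magnitude (the average over a zero-length
    window).
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot average an empty trace")
    g = trace.u * trace.m[:, None]
    if len(trace) == 1:
        return trace.t.copy(), np.array([float(np.linalg.norm(g[0]))])
    cum = cumulative_trapezoid(g, trace.t, axis=0, initial=0.0)
    elapsed = trace.t - trace.t[0]
    mags = np.empty(len(trace))
    mags[0] = np.linalg.norm(g[0])
    mags[1:] = np.linalg.norm(cum[1:] / elapsed[1:, None], axis=1)
    return trace.t.copy(), mags
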