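"""Hardware partial gravity: a centrifuge mounted on a random positioning machine.

The hardware paradigm takes the RPM's simulated weightlessness as the base
level and superimposes a controlled centripetal acceleration from a built-on
centrifuge platter. The planning quantities are all elementary rotational
mechanics — g level ω²r/g0, the integer-rpm setting that realizes a target
level at a given radius, the parasitic residual g contributed by the RPM
frame rotation itself, the g gradient across a sample of finite radial
extent, and the equi-gravity arc along which specimens are placed so that
every individual sees the same g.

Unit discipline: angular speeds must carry an explicit unit tag (``"rpm"`` or
``"deg/s"``); radii are in meters; g levels in units of g0 = 9.81 m/s².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import GeometryError, InvalidArgumentError, UnitError

__all__ = [
    "G0",
    "SpeedUnit",
    "CentrifugeSetting",
    "ResidualRule",
    "ResidualContext",
    "DishPlacement",
    "centripetal_g",
    "solve_rpm",
    "residual_g",
    "relative_residual_error",
    "combined_g",
    "g_gradient",
    "GradientReport",
    "equigravity_positions",
]

#: Reference gravity, m/s². 9.81 exactly (not the standard 9.80665): this is
#: the constant the planning tables are built on.
G0 = 9.81


class SpeedUnit(str, Enum):
    RPM = "rpm"
    DEG_S = "deg/s"


_UNIT_ALIASES = {
    "rpm": SpeedUnit.RPM,
    "deg/s": SpeedUnit.DEG_S,
    "deg_s": SpeedUnit.DEG_S,
    "deg per s": SpeedUnit.DEG_S,
}


def _to_rad_s(speed: float, unit: str | SpeedUnit) -> float:
    try:
        unit = _UNIT_ALIASES[unit.value if isinstance(unit, SpeedUnit) else str(unit).lower()]
    except KeyError:
        raise UnitError(
            f"unknown angular speed unit {unit!r}; use 'rpm' or 'deg/s'"
        ) from None
    if unit is SpeedUnit.RPM:
        return speed * 2.0 * math.pi / 60.0
    return math.radians(speed)


def centripetal_g(angular_speed: float, radius: float, unit: str | SpeedUnit) -> float:
    """Centripetal acceleration ω²r as a fraction of g0.

    ``angular_speed`` must carry a unit tag ('rpm' or 'deg/s'); ``radius``
    is in meters.
    """
    if radius <= 0:
        raise InvalidArgumentError(f"radius must be positive, got {radius!r}")
    if angular_speed < 0:
        raise InvalidArgumentError("angular speed must be non-negative")
    omega = _to_rad_s(angular_speed, unit)
    return omega * omega * radius / G0


def solve_rpm(target_g: float, radius: float) -> int:
    """Integer rpm realizing ``target_g`` at ``radius`` (nearest, ties to even)."""
    if radius <= 0:
        raise InvalidArgumentError(f"radius must be positive, got {radius!r}")
    if target_g < 0:
        raise InvalidArgumentError("target g must be non-negative")
    omega = math.sqrt(target_g * G0 / radius)  # rad/s
    return int(round(omega * 60.0 / (2.0 * math.pi)))


@dataclass(frozen=True)
class CentrifugeSetting:
    """An angular speed / radius pair and its derived g level."""

    angular_speed: float
    radius: float
    unit: str | SpeedUnit = SpeedUnit.RPM

    def __post_init__(self) -> None:
        # validates radius, speed and unit tag
        centripetal_g(self.angular_speed, self.radius, self.unit)

    @property
    def g_level(self) -> float:
        return centripetal_g(self.angular_speed, self.radius, self.unit)


def residual_g(frame_rate: float, platter_radius: float) -> float:
    """Worst-case parasitic g at the platter edge from the RPM frame rotation.

    ``frame_rate`` in deg/s (the RPM axis speed), ``platter_radius`` in m.
    At the standard 60 deg/s and a 0.20 m platter this is ≈ 0.022 g,
    conventionally reported as 0.02 g.
    """
    if frame_rate < 0:
        raise InvalidArgumentError("frame rate must be non-negative")
    return centripetal_g(frame_rate, platter_radius, SpeedUnit.DEG_S)


def relative_residual_error(residual: float, target: float) -> float:
    """Residual g as a percentage of the target partial-g level."""
    if target <= 0:
        raise InvalidArgumentError("target g must be positive for a relative error")
    if residual < 0:
        raise InvalidArgumentError("residual g must be non-negative")
    return 100.0 * residual / target


class ResidualRule(str, Enum):
    """How the frame-rotation residual is combined with the centrifuge g.

    The residual's direction relative to the centrifuge vector varies in
    time and is not characterized, so three conventions are offered:
    ``interval`` (default) brackets the level as [g−res, g+res];
    ``scalar_add`` takes the conservative scalar sum g+res;
    ``rss`` the root-sum-square for uncorrelated components.
    """

    INTERVAL = "interval"
    SCALAR_ADD = "scalar_add"
    RSS = "rss"


@dataclass(frozen=True)
class ResidualContext:
    """RPM frame rotation context generating the parasitic residual g.

    The residual is derived from the frame rate and platter radius;
    ``residual_override`` substitutes a stated rounded value (e.g. the
    conventional 0.02 g) for the derived one.
    """

    frame_rate: float = 60.0  # deg/s
    platter_radius: float = 0.20  # m
    rule: ResidualRule = ResidualRule.INTERVAL
    residual_override: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule", ResidualRule(self.rule))
        if self.residual < 0:
            raise InvalidArgumentError("residual g must be non-negative")

    @property
    def residual(self) -> float:
        if self.residual_override is not None:
            return float(self.residual_override)
        return residual_g(self.frame_rate, self.platter_radius)


def combined_g(
    setting: CentrifugeSetting, ctx: ResidualContext
) -> tuple[float, tuple[float, float]]:
    """Nominal g level and the residual-adjusted interval under ``ctx.rule``.

    Returns ``(nominal, (low, high))``. Under ``rss`` and ``scalar_add`` the
    interval degenerates to a single combined value.
    """
    g = setting.g_level
    res = ctx.residual
    if ctx.rule is ResidualRule.INTERVAL:
        lo, hi = max(g - res, 0.0), g + res
    elif ctx.rule is ResidualRule.SCALAR_ADD:
        lo = hi = g + res
    else:  # RSS
        lo = hi = math.sqrt(g * g + res * res)
    return g, (lo, hi)


@dataclass(frozen=True)
class GradientReport:
    """g gradient across a sample's radial extent at fixed angular speed."""

    g_min: float
    g_max: float
    delta_g: float
    relative: float  # delta_g / g at the center radius


def g_gradient(angular_speed_rpm: float, r_center: float, sample_extent: float) -> GradientReport:
    """g spread across a sample spanning ``r_center ± extent/2`` on the platter.

    At fixed ω the g level is linear in r, so Δg/g_center = extent/r_center.
    """
    if sample_extent < 0:
        raise InvalidArgumentError("sample extent must be non-negative")
    r_in = r_center - sample_extent / 2.0
    r_out = r_center + sample_extent / 2.0
    if r_in <= 0:
        raise InvalidArgumentError(
            f"inner radius {r_in!r} must be positive (extent too large for r_center)"
        )
    if angular_speed_rpm == 0:
        return GradientReport(0.0, 0.0, 0.0, 0.0)
    g_in = centripetal_g(angular_speed_rpm, r_in, SpeedUnit.RPM)
    g_out = centripetal_g(angular_speed_rpm, r_out, SpeedUnit.RPM)
    g_c = centripetal_g(angular_speed_rpm, r_center, SpeedUnit.RPM)
    return GradientReport(g_in, g_out, g_out - g_in, (g_out - g_in) / g_c)


@dataclass(frozen=True)
class DishPlacement:
    """Specimen positions along an equi-gravity arc on the centrifuge platter.

    Coordinates are platter-frame meters with the rotation axis at the
    origin and the dish center on the +x axis.
    """

    dish_center_radius: float
    dish_diameter: float
    target_radius: float
    positions: np.ndarray  # (n, 2)

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)


def equigravity_positions(
    dish_center_radius: float,
    dish_diameter: float,
    target_radius: float,
    n: int,
) -> DishPlacement:
    """Place ``n`` specimens evenly along the constant-radius arc inside a dish.

    All positions lie at exactly ``target_radius`` from the rotation axis —
    hence at identical centrifugal g — and strictly inside the dish. Raises
    :class:`GeometryError` (naming the feasible radius range) when the
    target-radius circle does not traverse the dish.
    """
    if n < 1:
        raise InvalidArgumentError("need at least one position")
    if dish_diameter <= 0 or dish_center_radius <= 0 or target_radius <= 0:
        raise InvalidArgumentError("radii and diameter must be positive")
    r_dish = dish_diameter / 2.0
    lo, hi = dish_center_radius - r_dish, dish_center_radius + r_dish
    # half-angle of the target arc inside the dish, from the law of cosines
    cos_lim = (target_radius**2 + dish_center_radius**2 - r_dish**2) / (
        2.0 * target_radius * dish_center_radius
    )
    if cos_lim >= 1.0:
        raise GeometryError(
            f"circle of radius {target_radius} m does not cross the dish; "
            f"feasible target radii are in ({max(lo, 0.0):.4g}, {hi:.4g}) m"
        )
    half_angle = math.pi if cos_lim <= -1.0 else math.acos(cos_lim)
    # midpoints of n equal sub-arcs: evenly spaced and strictly inside the dish
    k = np.arange(n)
    phi = -half_angle + (k + 0.5) * (2.0 * half_angle / n)
    pos = np.column_stack([target_radius * np.cos(phi), target_radius * np.sin(phi)])
    return DishPlacement(
        dish_center_radius=dish_center_radius,
        dish_diameter=dish_diameter,
        target_radius=target_radius,
        positions=pos,
    )
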