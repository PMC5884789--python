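"""Experiment planning: settings blocks for both partial-gravity paradigms.

Produces the numbers an experimenter needs before a run: for the software
paradigm the spheroid eccentricity realizing a target mean g (or vice
versa); for the hardware paradigm the integer rpm at a chosen radius plus
the residual-g, relative-error and g-gradient diagnostics; and the standard
five-condition planning table (Moon, Mars, 1/2 g, 3/4 g, 1 g control)
recomputed from first principles.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

from .centrifuge import (
    CentrifugeSetting,
    ResidualContext,
    centripetal_g,
    g_gradient,
    relative_residual_error,
    residual_g,
    solve_rpm,
)
from .exceptions import InvalidArgumentError
from .spheroid import eccentricity_for_mean_g, mean_g_from_eccentricity

__all__ = ["round_half_up", "plan_sw", "plan_hw", "standard_conditions"]

#: The five standard planning conditions: (name, target g, HW radius in cm).
_STANDARD = [
    ("Moon", 0.17, 12.0),
    ("Mars", 0.38, 12.0),
    ("1/2 g-Earth", 0.50, 16.0),
    ("3/4 g-Earth", 0.75, 12.0),
    ("1 g HW control", 1.00, 16.0),
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def plan_sw(
    target_g: float | None = None,
    eccentricity: float | None = None,
    max_rate_deg_s: float = 60.0,
) -> dict:
    """Settings block for a software partial-g run.

    Give exactly one of ``target_g`` (the desired mean gravity factor) or
    ``eccentricity``; the other is resolved through the spheroid quadrature.
    """
    if (target_g is None) == (eccentricity is None):
        raise InvalidArgumentError("give exactly one of target_g or eccentricity")
    if target_g is not None:
        eccentricity = eccentricity_for_mean_g(target_g)
    expected = mean_g_from_eccentricity(eccentricity)
    return {
        "paradigm": "sw",
        "eccentricity": float(eccentricity),
        "expected_mean_g": expected,
        "target_g": float(target_g) if target_g is not None else expected,
        "max_rate_deg_s": max_rate_deg_s,
        "settings": {
            "mode": "spheroid random",
            "max_rate_deg_s": max_rate_deg_s,
            "eccentricity_2dp": round_half_up(eccentricity, 2),
        },
    }


def plan_hw(
    target_g: float,
    radius: float,
    frame_rate_deg_s: float = 60.0,
    platter_radius: float = 0.20,
    sample_extent: float = 0.02,
) -> dict:
    """Settings block for a hardware (centrifuge-on-RPM) partial-g run.

    ``radius`` and ``platter_radius`` in meters. Reports the integer rpm,
    the g actually achieved at that rpm, the frame-rotation residual g and
    its relative error versus the target, and the g gradient across a
    sample of the stated radial extent.
    """
    rpm = solve_rpm(target_g, radius)
    achieved = centripetal_g(rpm, radius, "rpm") if rpm > 0 else 0.0
    res = residual_g(frame_rate_deg_s, platter_radius)
    grad = g_gradient(rpm, radius, sample_extent) if rpm > 0 else None
    out = {
        "paradigm": "hw",
        "target_g": float(target_g),
        "radius_m": float(radius),
        "rpm": rpm,
        "achieved_g": achieved,
        "achieved_g_2dp": round_half_up(achieved, 2),
        "residual_g": res,
        "residual_g_2dp": round_half_up(res, 2),
        "frame_rate_deg_s": frame_rate_deg_s,
        "platter_radius_m": platter_radius,
        "relative_error_pct": relative_residual_error(res, target_g) if target_g > 0 else 0.0,
        "sample_extent_m": sample_extent,
    }
    if grad is not None:
        out["gradient"] = {
            "g_min": grad.g_min,
            "g_max": grad.g_max,
            "delta_g": grad.delta_g,
            "relative": grad.relative,
        }
    return out


def standard_conditions() -> list[dict]:
    """The five-condition planning table, computed from first principles.

    For each condition: the integer rpm at the stated radius and the g that
    rpm actually delivers (hardware paradigm), and the spheroid eccentricity
    delivering the same mean g (software paradigm; undefined for 1 g).
    """
    rows = []
    for name, g, radius_cm in _STANDARD:
        radius = radius_cm / 100.0
        rpm = solve_rpm(g, radius)
        setting = CentrifugeSetting(rpm, radius)
        ecc = eccentricity_for_mean_g(g) if g < 1.0 else None
        rows.append(
            {
                "condition": name,
                "target_g": g,
                "rpm": rpm,
                "radius_cm": radius_cm,
                "achieved_g": setting.g_level,
                "achieved_g_2dp": round_half_up(setting.g_level, 2),
                "eccentricity": ecc,
                "eccentricity_2dp": round_half_up(ecc, 2) if ecc is not None else None,
            }
        )
    return rows
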