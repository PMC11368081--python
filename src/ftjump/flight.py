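"""Closed-form ballistic flight computations for vertical jump testing.

The flight-time (FT) method estimates jump height as ``h = g·FT²/8``,
which is exact only when the CoM height at landing equals its height at
takeoff.  A flatter landing (CoM lower by ``|h_diff|``) lengthens the
airborne phase and inflates the estimate.  This module provides the
forward pipeline (true flight quantities → measured FT → estimated height
→ percentage error), its exact inversion, and the anthropometric
correction that recovers true height from measured FT plus an estimate of
the CoM drop.

Two sign orientations appear (see :mod:`ftjump.kinematics`): the
canonical ``h_diff`` is landing-minus-takeoff (negative for a flatter
landing); correction entry points take the anthropometric estimate in its
natural takeoff-minus-landing orientation (positive for a flatter
landing) and convert internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anthropometry import PhysicsConfig

__all__ = [
    "FlightSolution",
    "CorrectionResult",
    "ascending_time",
    "true_flight_time",
    "takeoff_velocity",
    "measured_flight_time",
    "estimated_height",
    "height_error",
    "estimated_height_closed_form",
    "true_height_from_flight",
    "corrected_height",
    "solve_flight",
]

_DEFAULT_PHYSICS = PhysicsConfig()


@dataclass(frozen=True)
class FlightSolution:
    """All flight quantities for one jump condition.

    ``h_diff`` is in the landing-minus-takeoff orientation.  ``t_diff``
    (a.k.a. the flight-time difference ``FT_diff``) is the extra airborne
    time caused by the posture change, ``FT − FT_true``.
    """

    h: float
    t_a: float
    FT_true: float
    V_to: float
    h_diff: float
    FT: float
    t_diff: float
    h_est: float
    h_error: float


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected jump height from measured FT and an anthropometric CoM drop."""

    FT: float
    hdiff_hat: float
    h_corrected: float


def _check_physics(physics: PhysicsConfig | None) -> PhysicsConfig:
    return _DEFAULT_PHYSICS if physics is None else physics


def ascending_time(h: float, physics: PhysicsConfig | None = None) -> float:
    """Time (s) to rise ballistically through height ``h`` (m): sqrt(2h/g)."""
    if h < 0:
        raise ValueError(f"jump height must be non-negative, got h={h}")
    g = _check_physics(physics).g
    return math.sqrt(2.0 * h / g)


def true_flight_time(h: float, physics: PhysicsConfig | None = None) -> float:
    """Flight time (s) with identical takeoff and landing CoM heights: 2·t_a."""
    return 2.0 * ascending_time(h, physics)


def takeoff_velocity(h: float, physics: PhysicsConfig | None = None) -> float:
    """Vertical takeoff velocity (m·s⁻¹) for jump height ``h``: g·t_a."""
    g = _check_physics(physics).g
    return g * ascending_time(h, physics)


def measured_flight_time(
    V_to: float, h_diff: float, physics: PhysicsConfig | None = None
) -> float:
    """Measured flight time (s) when the CoM lands ``h_diff`` above takeoff.

    ``FT = (V_to + sqrt(V_to² − 2·g·h_diff)) / g`` with ``h_diff`` in the
    landing-minus-takeoff orientation; reduces to ``2·V_to/g`` at
    ``h_diff = 0``.
    """
    if V_to < 0:
        raise ValueError(f"takeoff velocity must be non-negative, got {V_to}")
    g = _check_physics(physics).g
    radicand = V_to * V_to - 2.0 * g * h_diff
    if radicand < 0:
        raise ValueError(
            f"unreachable landing height: h_diff={h_diff} m exceeds the apex "
            f"of a jump with V_to={V_to} m/s"
        )
    return (V_to + math.sqrt(radicand)) / g


def estimated_height(FT: float, physics: PhysicsConfig | None = None) -> float:
    """FT-method jump-height estimate (m): g·FT²/8."""
    if FT < 0:
        raise ValueError(f"flight time must be non-negative, got {FT}")
    g = _check_physics(physics).g
    return g * FT * FT / 8.0


def height_error(h_est: float, h: float) -> float:
    """Signed percentage error of the estimate relative to true height."""
    if h <= 0:
        raise ValueError(f"percentage error undefined for true height h={h}")
    return (h_est - h) / h * 100.0


def estimated_height_closed_form(h: float, h_diff: float) -> float:
    """FT-method estimate (m) directly from (h, h_diff); g cancels.

    Composing the forward pipeline algebraically gives
    ``ĥ = (√h + √(h − h_diff))² / 4`` — the gravitational acceleration
    drops out, which is why the percentage error is g-invariant.
    """
    if h < 0:
        raise ValueError(f"jump height must be non-negative, got h={h}")
    if h - h_diff < 0:
        raise ValueError(f"unreachable landing height: h_diff={h_diff} > h={h}")
    return (math.sqrt(h) + math.sqrt(h - h_diff)) ** 2 / 4.0


def true_height_from_flight(
    FT: float, h_diff: float, physics: PhysicsConfig | None = None
) -> tuple[float, float, float]:
    """Invert the measured flight time back to true jump height.

    With ``h_diff`` in the landing-minus-takeoff orientation the takeoff
    velocity is ``V_to = g·FT/2 + h_diff/FT``, so a flatter landing
    (negative ``h_diff``) recovers a smaller height than ``g·FT²/8``.

    Returns
    -------
    (h, FT_true, t_diff) : tuple of float
        True height (m), true flight time ``2·V_to/g`` (s), and the
        flight-time difference ``FT − FT_true`` (s).
    """
    if FT <= 0:
        raise ValueError(f"flight time must be positive, got FT={FT}")
    g = _check_physics(physics).g
    V_to = g * FT / 2.0 + h_diff / FT
    if V_to < 0:
        raise ValueError(
            f"h_diff={h_diff} m inconsistent with FT={FT} s: implied takeoff velocity negative"
        )
    FT_true = 2.0 * V_to / g
    h = V_to * V_to / (2.0 * g)
    return h, FT_true, FT - FT_true


def corrected_height(
    FT: float, hdiff_hat: float, physics: PhysicsConfig | None = None
) -> CorrectionResult:
    """Anthropometrically corrected jump height ``ĥ_c`` (m).

    ``hdiff_hat`` is the takeoff-minus-landing CoM-drop estimate (positive
    for a flatter landing), so
    ``ĥ_c = (g·FT/2 − hdiff_hat/FT)² / (2g) ≤ g·FT²/8`` when
    ``hdiff_hat ≥ 0``.
    """
    h, _, _ = true_height_from_flight(FT, -hdiff_hat, physics)
    return CorrectionResult(FT=FT, hdiff_hat=hdiff_hat, h_corrected=h)


def solve_flight(
    h: float, h_diff: float, physics: PhysicsConfig | None = None
) -> FlightSolution:
    """Run the full forward pipeline for one (true height, CoM difference)."""
    physics = _check_physics(physics)
    t_a = ascending_time(h, physics)
    V_to = physics.g * t_a
    FT_true = 2.0 * t_a
    FT = measured_flight_time(V_to, h_diff, physics)
    h_est = estimated_height(FT, physics)
    return FlightSolution(
        h=h,
        t_a=t_a,
        FT_true=FT_true,
        V_to=V_to,
        h_diff=h_diff,
        FT=FT,
        t_diff=FT - FT_true,
        h_est=h_est,
        h_error=height_error(h_est, h) if h > 0 else 0.0,
    )
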