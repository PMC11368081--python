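"""Planar kinematic chain about the tiptoe pivot.

At takeoff and landing the body is fully extended except for ankle
plantarflexion ``alpha`` (degrees; 0° = foot flat on the floor).  The chain
origin is the tiptoes: plantarflexing the ankle rotates the tiptoe-to-ankle
line from its natural standing inclination ``beta`` up to ``alpha + beta``,
raising the ankle by ``l_at·(sin(alpha + beta) − sin(beta))``.  Every
segment above the foot translates rigidly upward by that amount, while the
foot's own CoM rotates about the toes; the whole-body CoM is the
mass-weighted sum.

Sign conventions
----------------
``h_diff = h_landing − h_takeoff`` (negative for a flatter, more
dorsiflexed landing) is the canonical signed quantity consumed by the
flight equations.  The anthropometric estimator returns the opposite
orientation, ``l_at·(sin(alpha_to + beta) − sin(alpha_land + beta))``,
positive in the flatter-landing scenario; correction entry points in
:mod:`ftjump.flight` expect that orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anthropometry import BodyModel

__all__ = [
    "Posture",
    "ComState",
    "HdiffEstimate",
    "ankle_raise",
    "foot_com_raise",
    "standing_com_height",
    "com_height",
    "com_difference",
    "estimate_hdiff_anthro",
    "hdiff_anthro",
]


@dataclass(frozen=True)
class Posture:
    """Extended-body posture parameterised by ankle plantarflexion only.

    ``alpha`` is in degrees from the flat-foot standing orientation; knee,
    hip and torso are frozen in the extended configuration.
    """

    alpha: float

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 90):
            raise ValueError(f"ankle plantarflexion alpha={self.alpha}° outside [0, 90]")


@dataclass(frozen=True)
class ComState:
    """Whole-body CoM heights at takeoff and landing and their difference."""

    h_to: float
    h_l: float
    h_diff: float


@dataclass(frozen=True)
class HdiffEstimate:
    """Anthropometric estimate of the takeoff-minus-landing CoM drop (m).

    Positive when takeoff is more plantarflexed than landing — the
    opposite orientation to :class:`ComState.h_diff`.
    """

    hdiff_hat: float


def ankle_raise(model: BodyModel, alpha: float) -> float:
    """Vertical rise of the ankle above its standing height (m).

    ``l_at·(sin(alpha + beta) − sin(beta))``; zero at ``alpha = 0`` and
    strictly increasing until the toe-ankle line is vertical at
    ``alpha = 90° − beta``.
    """
    Posture(alpha)
    a = math.radians(alpha)
    b = model.beta_rad
    return model.l_at * (math.sin(a + b) - math.sin(b))


def foot_com_raise(model: BodyModel, alpha: float) -> float:
    """Vertical rise of the foot CoM (m) when the foot pivots at the toes.

    The foot CoM sits at ``com_fraction`` along the tiptoe-to-ankle line,
    so its rise is that fraction of :func:`ankle_raise`.
    """
    return model.segment("foot").com_fraction * ankle_raise(model, alpha)


def standing_com_height(model: BodyModel) -> float:
    """Whole-body CoM height (m) in the flat-foot standing posture."""
    foot = model.segment("foot")
    shank = model.segment("shank")
    thigh = model.segment("thigh")
    hat = model.segment("HAT")
    knee_height = model.ankle_height + shank.length
    hip_height = knee_height + thigh.length
    heights = {
        # foot CoM on the tiptoe-to-ankle line (toe at floor level)
        "foot": foot.com_fraction * model.ankle_height,
        "shank": model.ankle_height + shank.com_fraction * shank.length,
        "thigh": knee_height + thigh.com_fraction * thigh.length,
        "HAT": hip_height + hat.com_fraction * hat.length,
    }
    return sum(seg.mass_fraction * heights[seg.name] for seg in model.segments)


def com_height(model: BodyModel, posture: Posture) -> float:
    """Whole-body CoM height above the floor (m) for a given posture.

    All segments above the foot translate rigidly with the ankle; only the
    foot CoM follows the toe-pivot rotation.
    """
    m_foot = model.foot_mass_fraction
    rise = (1.0 - m_foot) * ankle_raise(model, posture.alpha) + m_foot * foot_com_raise(
        model, posture.alpha
    )
    return standing_com_height(model) + rise


def com_difference(model: BodyModel, alpha_to: float, alpha_land: float) -> ComState:
    """Signed landing-minus-takeoff CoM difference ``h_diff`` (m).

    Negative when the landing posture is flatter (more dorsiflexed) than
    takeoff, which lengthens the measured flight time.
    """
    h_to = com_height(model, Posture(alpha_to))
    h_l = com_height(model, Posture(alpha_land))
    return ComState(h_to=h_to, h_l=h_l, h_diff=h_l - h_to)


def hdiff_anthro(l_at: float, beta_deg: float, alpha_to: float, alpha_land: float) -> float:
    """Anthropometric CoM-drop estimate from raw toe-ankle geometry (m)."""
    Posture(alpha_to)
    Posture(alpha_land)
    b = math.radians(beta_deg)
    return l_at * (math.sin(math.radians(alpha_to) + b) - math.sin(math.radians(alpha_land) + b))


def estimate_hdiff_anthro(model: BodyModel, alpha_to: float, alpha_land: float) -> HdiffEstimate:
    """Anthropometric estimate of the takeoff-minus-landing CoM drop.

    Equals the pure ankle-raise difference; it omits the foot-mass
    correction, so ``|h_diff| ≤ hdiff_hat`` whenever takeoff is more
    plantarflexed, and it carries the opposite sign orientation to
    :func:`com_difference`.
    """
    return HdiffEstimate(hdiff_hat=hdiff_anthro(model.l_at, model.beta, alpha_to, alpha_land))
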