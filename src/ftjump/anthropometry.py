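"""Stature-scaled planar four-segment body model.

The jumper is modelled in the sagittal plane as a chain of four rigid
segments — foot, shank, thigh, and HAT (head-arms-trunk) — standing on a
single leg whose segment masses are doubled so the one modelled leg carries
the mass of both.  Every geometric quantity scales linearly with stature
``H``; segment masses enter only as fractions of total body mass, so the
absolute mass cancels from every centre-of-mass (CoM) position.

Foot geometry: foot length is 0.152·H, the lateral-malleolus (ankle)
standing height is 0.039·H, and the tiptoe-to-ankle horizontal distance is
78.7 % of foot length.  The straight tiptoe-to-ankle line therefore has
length ``l_at = sqrt((0.039·H)² + (0.152·0.787·H)²) ≈ 0.126·H`` and makes a
constant natural inclination angle ``beta ≈ 18.06°`` with the floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicsConfig",
    "SegmentSpec",
    "Segment",
    "BodyModel",
    "default_segment_table",
    "build_body_model",
    "l_at_from_stature",
    "l_at_from_foot_length",
    "FOOT_LENGTH_FRACTION",
    "ANKLE_HEIGHT_FRACTION",
    "TOE_ANKLE_FRACTION",
]

#: Foot length as a fraction of stature.
FOOT_LENGTH_FRACTION = 0.152
#: Standing lateral-malleolus height as a fraction of stature.
ANKLE_HEIGHT_FRACTION = 0.039
#: Tiptoe-to-ankle horizontal distance as a fraction of foot length.
TOE_ANKLE_FRACTION = 0.787

_SEGMENT_NAMES = ("foot", "shank", "thigh", "HAT")
_MASS_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PhysicsConfig:
    """Physical constants of the simulation.

    Parameters
    ----------
    g : float
        Gravitational acceleration in m·s⁻².  The percentage jump-height
        error is provably independent of ``g``; it only rescales absolute
        times and velocities.
    """

    g: float = 9.81

    def __post_init__(self) -> None:
        if not (self.g > 0):
            raise ValueError(f"gravitational acceleration must be positive, got g={self.g}")


@dataclass(frozen=True)
class SegmentSpec:
    """Dimensionless description of one body segment.

    ``length_fraction`` is the segment length as a fraction of stature,
    ``mass_fraction`` the fraction of total body mass (already doubled for
    the single-leg construction), and ``com_fraction`` the CoM location
    along the segment measured from its distal joint (toe for the foot,
    ankle for the shank, knee for the thigh, hip for the HAT).
    """

    name: str
    length_fraction: float
    mass_fraction: float
    com_fraction: float

    def __post_init__(self) -> None:
        if self.name not in _SEGMENT_NAMES:
            raise ValueError(f"unknown segment name {self.name!r}; expected one of {_SEGMENT_NAMES}")
        for field_name in ("length_fraction", "mass_fraction", "com_fraction"):
            value = getattr(self, field_name)
            if not (0 < value <= 1):
                raise ValueError(f"segment {self.name!r}: {field_name}={value} outside (0, 1]")


@dataclass(frozen=True)
class Segment:
    """A segment scaled to absolute length (m) for a given stature."""

    name: str
    length: float
    mass_fraction: float
    com_fraction: float


def default_segment_table() -> list[SegmentSpec]:
    """Return the default four-segment anthropometric table.

    Mass fractions follow standard cadaver-based segmental tables with the
    leg segments doubled for the single-leg model: foot 2×0.0145 = 0.029,
    shank 2×0.0465 = 0.093, thigh 2×0.100 = 0.200, and HAT the remaining
    0.678.  They sum to exactly 1.  Length fractions for shank (0.246) and
    thigh (0.245) come from the same tables; the HAT length is the
    remainder up to full stature.  The foot CoM sits at the midpoint of
    the tiptoe-to-ankle line; shank and thigh CoMs sit 0.433 of segment
    length from their proximal joint (0.567 from the distal joint used
    here), the HAT CoM 0.626 from the hip.

    Only the foot mass fraction and foot CoM location affect the
    takeoff-landing CoM difference — every above-foot segment translates
    rigidly when the ankle plantarflexes — so the remaining entries matter
    only for absolute standing CoM height.
    """
    hat_length = 1.0 - ANKLE_HEIGHT_FRACTION - 0.246 - 0.245
    return [
        SegmentSpec("foot", FOOT_LENGTH_FRACTION, 0.029, 0.5),
        SegmentSpec("shank", 0.246, 0.093, 0.567),
        SegmentSpec("thigh", 0.245, 0.200, 0.567),
        SegmentSpec("HAT", hat_length, 0.678, 0.626),
    ]


def _validate_table(table: list[SegmentSpec]) -> None:
    names = [s.name for s in table]
    if sorted(names) != sorted(_SEGMENT_NAMES):
        raise ValueError(f"segment table must contain exactly {_SEGMENT_NAMES}, got {names}")
    total = sum(s.mass_fraction for s in table)
    if abs(total - 1.0) > _MASS_SUM_TOL:
        raise ValueError(f"segment mass fractions must sum to 1.0, got {total!r}")


@dataclass(frozen=True)
class BodyModel:
    """A four-segment body scaled to one stature.

    All lengths in metres; ``beta`` in degrees.  ``l_at`` is computed from
    the exact component expression, never from the display-rounded 0.126
    coefficient.
    """

    H: float
    segments: tuple[Segment, ...]
    foot_length: float
    ankle_height: float
    toe_ankle_horizontal: float
    l_at: float
    beta: float
    physics: PhysicsConfig

    @property
    def beta_rad(self) -> float:
        return math.radians(self.beta)

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    @property
    def foot_mass_fraction(self) -> float:
        return self.segment("foot").mass_fraction


def build_body_model(
    H: float,
    table: list[SegmentSpec] | None = None,
    physics: PhysicsConfig | None = None,
) -> BodyModel:
    """Scale the segment table to stature ``H`` (m).

    Raises
    ------
    ValueError
        If ``H`` is outside the (0.5, 3.0) m sanity bounds or the table is
        inconsistent.
    """
    if not (0.5 < H < 3.0):
        raise ValueError(f"stature H={H} m outside sanity bounds (0.5, 3.0)")
    if table is None:
        table = default_segment_table()
    _validate_table(table)
    if physics is None:
        physics = PhysicsConfig()

    segments = tuple(
        Segment(s.name, s.length_fraction * H, s.mass_fraction, s.com_fraction) for s in table
    )
    foot_length = FOOT_LENGTH_FRACTION * H
    ankle_height = ANKLE_HEIGHT_FRACTION * H
    toe_ankle_horizontal = TOE_ANKLE_FRACTION * foot_length
    # computed from the stature-free fractions so l_at scales exactly
    # linearly with H and beta is bit-identical across statures
    l_at = l_at_from_stature(1.0) * H
    beta = natural_foot_angle()
    return BodyModel(
        H=H,
        segments=segments,
        foot_length=foot_length,
        ankle_height=ankle_height,
        toe_ankle_horizontal=toe_ankle_horizontal,
        l_at=l_at,
        beta=beta,
        physics=physics,
    )


def l_at_from_stature(H: float) -> float:
    """Tiptoe-to-ankle straight-line distance (m) from stature (m)."""
    if H <= 0:
        raise ValueError(f"stature must be positive, got {H}")
    return math.hypot(ANKLE_HEIGHT_FRACTION * H, TOE_ANKLE_FRACTION * FOOT_LENGTH_FRACTION * H)


def l_at_from_foot_length(foot_length: float) -> float:
    """Tiptoe-to-ankle straight-line distance (m) from foot length (m).

    Stature is recovered as ``foot_length / 0.152`` before applying the
    standing-foot geometry.
    """
    if foot_length <= 0:
        raise ValueError(f"foot length must be positive, got {foot_length}")
    return l_at_from_stature(foot_length / FOOT_LENGTH_FRACTION)


def natural_foot_angle() -> float:
    """Natural standing foot inclination beta in degrees (stature-free)."""
    return math.degrees(
        math.atan2(ANKLE_HEIGHT_FRACTION, TOE_ANKLE_FRACTION * FOOT_LENGTH_FRACTION)
    )
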