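"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ftjump import GridSpec, build_body_model, run_grid
from ftjump.anthropometry import BodyModel
from ftjump.kinematics import Posture


@pytest.fixture(scope="session")
def default_grid():
    """The full 16,400-condition factorial grid, simulated once per session."""
    return run_grid(GridSpec())


@pytest.fixture
def small_spec():
    """A small grid spec for fast structural and determinism tests."""
    return GridSpec(
        stature_min=1.5,
        stature_max=1.9,
        stature_count=5,
        takeoff_angle=40.0,
        ankle_changes=(0.0, 10.0, 20.0, 40.0),
        jump_heights=(0.10, 0.20, 0.30),
    )


def com_height_oracle(model: BodyModel, alpha: float) -> float:
    """Brute-force whole-body CoM height via explicit planar coordinates.

    Every segment CoM is a 2D point with the toe at the origin.  The foot
    points are rotated about the toes with a 2x2 rotation matrix by the
    plantarflexion angle; every above-foot point is translated by the
    displacement of the ankle point.  Independent of the analytic
    ankle-raise decomposition used by the implementation.
    """
    Posture(alpha)
    foot = model.segment("foot")
    shank = model.segment("shank")
    thigh = model.segment("thigh")
    hat = model.segment("HAT")

    ankle0 = np.array([-model.toe_ankle_horizontal, model.ankle_height])
    foot_com0 = foot.com_fraction * ankle0  # on the toe-ankle line from the toe
    knee_y = model.ankle_height + shank.length
    hip_y = knee_y + thigh.length
    above0 = {
        "shank": np.array([ankle0[0], model.ankle_height + shank.com_fraction * shank.length]),
        "thigh": np.array([ankle0[0], knee_y + thigh.com_fraction * thigh.length]),
        "HAT": np.array([ankle0[0], hip_y + hat.com_fraction * hat.length]),
    }

    # plantarflexion rotates the foot about the toe origin, lifting the heel
    a = math.radians(alpha)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    # choose the rotation sense that raises the ankle
    ankle1 = rot @ ankle0
    if ankle1[1] < ankle0[1]:
        ankle1 = rot.T @ ankle0
        foot_com1 = rot.T @ foot_com0
    else:
        foot_com1 = rot @ foot_com0
    shift = ankle1 - ankle0

    total = foot.mass_fraction * foot_com1[1]
    for name in ("shank", "thigh", "HAT"):
        total += model.segment(name).mass_fraction * (above0[name] + shift)[1]
    return float(total)


def projectile_flight_time(V_to: float, h_diff: float, g: float, dt: float = 1e-6) -> float:
    """Time-stepped projectile oracle for the measured flight time.

    Samples the ballistic trajectory y(t) = V·t − g·t²/2 on a fine grid and
    locates the descending crossing of the landing height ``h_diff`` by
    linear interpolation.  Independent of the closed-form quadratic root.
    """
    t_max = (V_to + math.sqrt(V_to * V_to + 2 * g * (abs(h_diff) + 0.01))) / g
    t = np.arange(0.0, t_max, dt)
    y = V_to * t - 0.5 * g * t * t
    descending = t > V_to / g
    below = descending & (y <= h_diff)
    i = int(np.argmax(below))
    assert below[i], "trajectory never crossed the landing height"
    # linear interpolation between the bracketing samples
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (h_diff - y0) * (t1 - t0) / (y1 - y0))
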