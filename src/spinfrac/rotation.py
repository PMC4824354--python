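"""Rotational-speed conversions (RCF, RPM, rad/s, rev/s).

Relative centrifugal force (RCF) expresses centrifugal acceleration in
multiples of standard gravity: RCF = r * omega**2 / g, with omega in rad/s
and r the radius at which the acceleration is evaluated.  Spin protocols
are quoted in RCF while valve physics and Stokes timing need angular
velocity, so every conversion is anchored at an explicit radius.
"""

from __future__ import annotations

import math

#: Standard gravity, m/s^2 (exact by convention).
G = 9.80665

_TWO_PI = 2.0 * math.pi


def rpm_to_rad(rpm: float) -> float:
    """Revolutions per minute to rad/s."""
    return rpm * _TWO_PI / 60.0


def rad_to_rpm(omega_rad: float) -> float:
    """rad/s to revolutions per minute."""
    return omega_rad * 60.0 / _TWO_PI


def rad_to_rev_s(omega_rad: float) -> float:
    """rad/s to revolutions per second."""
    return omega_rad / _TWO_PI


def rcf_to_omega_rad(rcf: float, radius: float) -> float:
    """Angular velocity (rad/s) producing `rcf` g-multiples at `radius` (m)."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if rcf < 0:
        raise ValueError(f"RCF must be non-negative, got {rcf}")
    return math.sqrt(rcf * G / radius)


def omega_rad_to_rcf(omega_rad: float, radius: float) -> float:
    """g-multiples produced at `radius` (m) by angular velocity `omega_rad`."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return radius * omega_rad**2 / G


def rcf_to_rpm(rcf: float, radius: float) -> float:
    return rad_to_rpm(rcf_to_omega_rad(rcf, radius))


def rpm_to_rcf(rpm: float, radius: float) -> float:
    if rpm < 0:
        raise ValueError(f"RPM must be non-negative, got {rpm}")
    return omega_rad_to_rcf(rpm_to_rad(rpm), radius)


def speed_convert(value: float, radius: float, direction: str) -> float:
    """Convert between RCF and RPM at a given anchoring radius.

    Parameters
    ----------
    value
        The speed to convert (RCF for ``to_rpm``, RPM for ``to_rcf``).
    radius
        Radius in meters at which the RCF is evaluated.
    direction
        Either ``"to_rpm"`` or ``"to_rcf"``.  The two directions are exact
        inverses of each other.
    """
    if value < 0:
        raise ValueError(f"speed value must be non-negative, got {value}")
    if direction == "to_rpm":
        return rcf_to_rpm(value, radius)
    if direction == "to_rcf":
        return rpm_to_rcf(value, radius)
    raise ValueError(f"direction must be 'to_rpm' or 'to_rcf', got {direction!r}")
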