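"""Capillary burst-valve physics.

A burst valve is an abrupt expansion of a rectangular channel of height h
and width w.  A non-wetting meniscus (advancing contact angle theta_A >
90 deg) pins at the expansion with a Young-Laplace holding pressure

    P_h = -2 sigma cos(theta_A) (1/h + 1/w),

and releases when the centrifugal pressure of the liquid column behind it,

    P_A = 1/2 rho omega^2 |r_d^2 - r_p^2|,

exceeds that threshold.  The burst speed is the rotation rate at which
the two are equal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from . import rotation
from .device import FluidSample, ValveGeometry
from .rotation import speed_convert  # re-exported convenience

__all__ = [
    "PressureValue",
    "LiquidColumn",
    "DegenerateValveWarning",
    "burst_pressure",
    "column_pressure",
    "burst_speed",
    "speed_convert",
]


class DegenerateValveWarning(UserWarning):
    """The valve cannot pin the fluid (wetting contact angle): zero threshold."""


@dataclass(frozen=True)
class PressureValue:
    """A pressure with its physical role attached.

    kind is ``"burst_threshold"`` (meniscus holding pressure P_h) or
    ``"centrifugal"`` (driving pressure P_A of a spinning liquid column).
    """

    value: float  # Pa
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("burst_threshold", "centrifugal"):
            raise ValueError(f"unknown pressure kind {self.kind!r}")
        if self.kind == "burst_threshold" and self.value < 0:
            raise ValueError(f"burst threshold cannot be negative, got {self.value}")


@dataclass(frozen=True)
class LiquidColumn:
    """A contiguous liquid column in the lane, from r_proximal to r_distal."""

    density: float  # kg/m^3
    r_proximal: float  # m
    r_distal: float  # m

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.r_distal <= self.r_proximal:
            raise ValueError(
                f"r_distal ({self.r_distal}) must exceed r_proximal ({self.r_proximal})"
            )


def burst_pressure(valve: ValveGeometry, fluid: FluidSample) -> PressureValue:
    """Young-Laplace holding pressure of a pinned meniscus.

    Returns P_h = -2 sigma cos(theta_A) (1/h + 1/w); positive for a
    non-wetting fluid (theta_A > 90 deg).  A wetting fluid cannot be
    pinned: the threshold is reported as 0 Pa with a
    :class:`DegenerateValveWarning`.
    """
    cos_theta = math.cos(fluid.contact_angle_rad)
    if cos_theta >= 0:
        warnings.warn(
            f"contact angle {fluid.contact_angle_adv} deg <= 90 deg: the valve cannot "
            "pin a wetting fluid; burst threshold is 0",
            DegenerateValveWarning,
            stacklevel=2,
        )
        return PressureValue(0.0, "burst_threshold")
    p = -2.0 * fluid.surface_tension * cos_theta * (1.0 / valve.height + 1.0 / valve.width)
    return PressureValue(p, "burst_threshold")


def column_pressure(column: LiquidColumn, omega_rad: float) -> PressureValue:
    """Centrifugal pressure P_A = 1/2 rho omega^2 |r_d^2 - r_p^2| of a
    liquid column spun at `omega_rad` rad/s (magnitude of the radial
    pressure difference across the column)."""
    if omega_rad < 0:
        raise ValueError(f"angular velocity must be >= 0, got {omega_rad}")
    p = 0.5 * column.density * omega_rad**2 * abs(column.r_distal**2 - column.r_proximal**2)
    return PressureValue(p, "centrifugal")


def burst_speed(valve: ValveGeometry, fluid: FluidSample, column: LiquidColumn) -> float:
    """Rotation rate (RPM) at which the column's centrifugal pressure
    equals the valve's holding pressure.

    Closed form: omega = sqrt(2 P_h / (rho (r_d^2 - r_p^2))).  A
    degenerate valve (P_h = 0) bursts at any speed and returns 0 RPM with
    a warning.
    """
    p_h = burst_pressure(valve, fluid).value
    if p_h == 0.0:
        warnings.warn(
            "degenerate valve (zero burst threshold): bursts at any rotation speed",
            DegenerateValveWarning,
            stacklevel=2,
        )
        return 0.0
    omega = math.sqrt(
        2.0 * p_h / (column.density * abs(column.r_distal**2 - column.r_proximal**2))
    )
    return rotation.rad_to_rpm(omega)
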