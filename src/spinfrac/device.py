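"""Domain types for the centrifugal fractionation disk.

A disk lane is an ordered radial stack of density-gradient sections
(proximal sample chamber out to the distal rim), separated by capillary
burst valves.  All stored quantities are SI (m, kg/m^3, Pa.s, N/m,
degrees only at construction time for contact angles); convenience
constructors and properties expose the bench units used at the interface
(mm, g/mL, mPa.s, um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from . import rotation

__all__ = [
    "FluidSample",
    "ValveGeometry",
    "CellSpecies",
    "MediumSection",
    "LaneDesign",
    "SpinProtocol",
    "reference_lane",
    "reference_cell_panel",
    "reference_protocol",
    "default_blood",
    "CHANNEL_HEIGHT_M",
]

#: Default channel height: sum of the bonded adhesive-stack layers
#: (0.05 mm carrier + 0.28 mm + 0.34 mm adhesive), in meters.
CHANNEL_HEIGHT_M = 0.67e-3


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class FluidSample:
    """The liquid phase driven through the valves (typically diluted blood).

    Parameters
    ----------
    surface_tension
        Liquid surface tension sigma, N/m.
    contact_angle_adv
        Advancing contact angle theta_A on the channel material, degrees.
        Only a non-wetting fluid (theta_A > 90 deg) can be pinned by an
        expansion valve.
    density
        Liquid density rho, kg/m^3.
    viscosity
        Dynamic viscosity, Pa.s.  Used only when a lane section holds the
        sample itself rather than a separation medium.
    """

    surface_tension: float
    contact_angle_adv: float
    density: float
    viscosity: float = 4.0e-3

    def __post_init__(self) -> None:
        _require(self.surface_tension > 0, f"surface_tension must be > 0, got {self.surface_tension}")
        _require(
            0 < self.contact_angle_adv < 180,
            f"contact_angle_adv must lie in (0, 180) degrees, got {self.contact_angle_adv}",
        )
        _require(self.density > 0, f"density must be > 0, got {self.density}")
        _require(self.viscosity > 0, f"viscosity must be > 0, got {self.viscosity}")

    @property
    def contact_angle_rad(self) -> float:
        return math.radians(self.contact_angle_adv)


@dataclass(frozen=True)
class ValveGeometry:
    """Capillary burst valve: an abrupt expansion of a h x w channel."""

    height: float  # m
    width: float  # m
    radial_position: float  # m from rotation axis

    def __post_init__(self) -> None:
        _require(self.height > 0, f"valve height must be > 0, got {self.height}")
        _require(self.width > 0, f"valve width must be > 0, got {self.width}")
        _require(self.radial_position >= 0, f"radial_position must be >= 0, got {self.radial_position}")


@dataclass(frozen=True)
class CellSpecies:
    """A sedimenting blood particle.

    `agglutination_factor` multiplies the effective radius to model
    aggregates (e.g. rouleaux-forming red cells); sedimentation time
    scales as 1/R^2, so a factor of 3 is a 9x speed-up.
    """

    name: str
    density: float  # kg/m^3
    radius: float  # m
    agglutination_factor: float = 1.0

    def __post_init__(self) -> None:
        _require(self.density > 0, f"density must be > 0, got {self.density}")
        _require(self.radius > 0, f"radius must be > 0, got {self.radius}")
        _require(
            self.agglutination_factor >= 1,
            f"agglutination_factor must be >= 1, got {self.agglutination_factor}",
        )

    @classmethod
    def from_lab(
        cls,
        name: str,
        density_g_ml: float,
        radius_um: float,
        agglutination_factor: float = 1.0,
    ) -> "CellSpecies":
        """Construct from bench units (g/mL, um)."""
        return cls(name, density_g_ml * 1000.0, radius_um * 1e-6, agglutination_factor)

    @property
    def density_g_ml(self) -> float:
        return self.density / 1000.0

    @property
    def radius_um(self) -> float:
        return self.radius / 1e-6

    @property
    def effective_radius(self) -> float:
        """Radius x agglutination factor, m."""
        return self.radius * self.agglutination_factor

    def with_agglutination(self, factor: float) -> "CellSpecies":
        return replace(self, agglutination_factor=factor)


@dataclass(frozen=True)
class MediumSection:
    """One density-gradient compartment of a lane.

    The section occupies the half-open radial interval [r_proximal,
    r_distal).  `volume_ul` is informational only (loading volume); it is
    not used by any computation.
    """

    label: str
    medium_density: float  # kg/m^3
    medium_viscosity: float  # Pa.s
    r_proximal: float  # m
    r_distal: float  # m
    volume_ul: float | None = None

    def __post_init__(self) -> None:
        _require(self.medium_density > 0, f"medium_density must be > 0, got {self.medium_density}")
        _require(self.medium_viscosity > 0, f"medium_viscosity must be > 0, got {self.medium_viscosity}")
        _require(
            self.r_distal > self.r_proximal,
            f"section {self.label!r}: r_distal ({self.r_distal}) must exceed r_proximal ({self.r_proximal})",
        )

    @property
    def medium_density_g_ml(self) -> float:
        return self.medium_density / 1000.0

    def contains(self, r: float) -> bool:
        return self.r_proximal <= r < self.r_distal


_CONTIG_TOL = 1e-9  # m; adjacency check tolerance


@dataclass(frozen=True)
class LaneDesign:
    """One lane: contiguous sections ordered proximal (sample) to distal,
    with a capillary valve between each adjacent pair."""

    sections: tuple[MediumSection, ...]
    valves: tuple[ValveGeometry, ...]
    disk_radius: float  # m

    def __init__(
        self,
        sections: Sequence[MediumSection],
        valves: Sequence[ValveGeometry],
        disk_radius: float,
    ) -> None:
        object.__setattr__(self, "sections", tuple(sections))
        object.__setattr__(self, "valves", tuple(valves))
        object.__setattr__(self, "disk_radius", float(disk_radius))
        self._validate()

    def _validate(self) -> None:
        _require(len(self.sections) >= 1, "a lane needs at least one section")
        for a, b in zip(self.sections, self.sections[1:]):
            if abs(a.r_distal - b.r_proximal) > _CONTIG_TOL:
                kind = "gap" if b.r_proximal > a.r_distal else "overlap"
                raise ValueError(
                    f"radial {kind} between sections {a.label!r} (r_distal={a.r_distal}) "
                    f"and {b.label!r} (r_proximal={b.r_proximal}); sections must tile contiguously"
                )
        _require(
            len(self.valves) == len(self.sections) - 1,
            f"expected {len(self.sections) - 1} valves for {len(self.sections)} sections, "
            f"got {len(self.valves)}",
        )
        _require(
            self.sections[-1].r_distal <= self.disk_radius + _CONTIG_TOL,
            f"lane extends to {self.sections[-1].r_distal} m, beyond disk radius {self.disk_radius} m",
        )

    @property
    def r_proximal(self) -> float:
        """Proximal edge of the lane (sample introduction point), m."""
        return self.sections[0].r_proximal

    @property
    def r_distal(self) -> float:
        """Distal wall of the lane, m."""
        return self.sections[-1].r_distal

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sections)

    def section_at(self, r: float) -> MediumSection:
        """Section containing radius `r` under the [r_p, r_d) convention.

        The distal wall itself is assigned to the distal-most section.
        """
        for s in self.sections:
            if s.contains(r):
                return s
        if math.isclose(r, self.r_distal, rel_tol=0, abs_tol=_CONTIG_TOL) or r >= self.r_distal:
            return self.sections[-1]
        raise ValueError(f"radius {r} m lies outside the lane [{self.r_proximal}, {self.r_distal}]")

    def with_sections(self, sections: Sequence[MediumSection]) -> "LaneDesign":
        """New lane with the same valves/radius but replaced sections
        (valve count must still match)."""
        return LaneDesign(sections, self.valves, self.disk_radius)


@dataclass(frozen=True)
class SpinProtocol:
    """Trapezoidal spin protocol quoted in RCF.

    The disk accelerates at `accel_rcf_per_min` to `plateau_rcf`, holds
    for `plateau_duration` seconds, then decelerates at
    `decel_rcf_per_min`.  RCF <-> angular velocity conversion is anchored
    at `reference_radius` (default: the lane's outer rim).
    """

    plateau_rcf: float
    accel_rcf_per_min: float
    decel_rcf_per_min: float
    plateau_duration: float  # s
    reference_radius: float  # m

    def __post_init__(self) -> None:
        for name in ("plateau_rcf", "accel_rcf_per_min", "decel_rcf_per_min", "plateau_duration", "reference_radius"):
            _require(getattr(self, name) > 0, f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def t_accel(self) -> float:
        """Acceleration ramp time t_a, s."""
        return self.plateau_rcf / self.accel_rcf_per_min * 60.0

    @property
    def t_decel(self) -> float:
        """Deceleration ramp time t_d, s."""
        return self.plateau_rcf / self.decel_rcf_per_min * 60.0

    @property
    def total_duration(self) -> float:
        """Wall-clock protocol length t_a + plateau + t_d, s."""
        return self.t_accel + self.plateau_duration + self.t_decel

    @property
    def plateau_omega_rad(self) -> float:
        """Plateau angular velocity, rad/s, from RCF at the reference radius."""
        return rotation.rcf_to_omega_rad(self.plateau_rcf, self.reference_radius)

    @property
    def plateau_rev_s(self) -> float:
        """Plateau angular velocity, rev/s (the unit of the timing formula)."""
        return rotation.rad_to_rev_s(self.plateau_omega_rad)

    @property
    def plateau_rpm(self) -> float:
        return rotation.rad_to_rpm(self.plateau_omega_rad)


# ---------------------------------------------------------------------------
# Built-in reference hardware and reagents
# ---------------------------------------------------------------------------

#: Histopaque-1077 separation medium density, kg/m^3.
HISTOPAQUE_1077_DENSITY = 1077.0
#: Histopaque-1077 dynamic viscosity, Pa.s (vendor-typical value; not a
#: device-specific measurement — override in configs when known).
HISTOPAQUE_1077_VISCOSITY = 1.5e-3


def reference_lane(
    *,
    channel_height: float = CHANNEL_HEIGHT_M,
    medium_density: float = HISTOPAQUE_1077_DENSITY,
    medium_viscosity: float = HISTOPAQUE_1077_VISCOSITY,
) -> LaneDesign:
    """The built-in disk lane: 60 mm disk radius, five 7 mm gradient
    sections (A distal ... E proximal) plus the 7 mm sample section F,
    separated by 1 mm x 7 mm capillary valves whose footprint lies within
    the section boundaries.

    All sections are filled with the same medium (Histopaque-1077 by
    default); replace the sections to model a loaded sample or a stepped
    gradient.
    """
    labels = ["F", "E", "D", "C", "B", "A"]  # proximal -> distal
    outer_mm, step_mm = 60.0, 7.0
    inner_mm = outer_mm - step_mm * len(labels)
    sections = []
    for i, label in enumerate(labels):
        # mm arithmetic first so radii match bench-unit configs bit-for-bit
        r_p_mm = inner_mm + i * step_mm
        sections.append(
            MediumSection(
                label=label,
                medium_density=medium_density,
                medium_viscosity=medium_viscosity,
                r_proximal=r_p_mm * 1e-3,
                r_distal=(r_p_mm + step_mm) * 1e-3,
                volume_ul=12.0,
            )
        )
    outer = outer_mm * 1e-3
    valves = [
        ValveGeometry(height=channel_height, width=7e-3, radial_position=s.r_distal)
        for s in sections[:-1]
    ]
    return LaneDesign(sections, valves, disk_radius=outer)


def reference_cell_panel(rbc_agglutination: float = 1.0) -> list[CellSpecies]:
    """The six common blood components with representative densities and
    effective radii (midpoints of the literature ranges; single reported
    value for the red cell).

    Red cells frequently agglutinate into rouleaux; pass
    `rbc_agglutination` > 1 to model the resulting larger effective
    particle.
    """
    return [
        CellSpecies.from_lab("Monocyte", 1.072, 6.75),
        CellSpecies.from_lab("Lymphocyte", 1.075, 4.5),
        CellSpecies.from_lab("Basophil", 1.075, 4.75),
        CellSpecies.from_lab("Neutrophil", 1.085, 6.75),
        CellSpecies.from_lab("Eosinophil", 1.095, 6.75),
        CellSpecies.from_lab("RBC", 1.098, 2.63, agglutination_factor=rbc_agglutination),
    ]


def reference_protocol(reference_radius: float = 60e-3) -> SpinProtocol:
    """The stock separation protocol: ramp at 500 RCF/min to a 500 RCF
    plateau held 4 minutes, then decelerate at 322 RCF/min."""
    return SpinProtocol(
        plateau_rcf=500.0,
        accel_rcf_per_min=500.0,
        decel_rcf_per_min=322.0,
        plateau_duration=240.0,
        reference_radius=reference_radius,
    )


def default_blood() -> FluidSample:
    """Representative whole-blood fluid parameters (literature-typical,
    not device-specific): sigma = 58 mN/m, theta_A = 110 deg on acrylic,
    rho = 1060 kg/m^3, eta = 4 mPa.s.  Override in configs when measured
    values are available."""
    return FluidSample(
        surface_tension=0.058,
        contact_angle_adv=110.0,
        density=1060.0,
        viscosity=4.0e-3,
    )
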