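"""Closed-form sedimentation timing through discrete density sections.

A spherical particle of effective radius R and density rho sedimenting
radially through a medium of density rho0 and viscosity eta at constant
angular velocity omega (rev/s) obeys Stokes drag, giving an exponential
radial trajectory and a section transit time

    t = 9 eta ln(r_d / r_p) / (8 pi^2 omega^2 R^2 (rho - rho0)).

Transit times are summed over the sections of a lane, and a single ramp
correction 2 (t_a + t_d) / 3 accounts for the reduced sedimentation
during spin-up and spin-down (the ramps deliver 1/3 of the
plateau-equivalent exposure per unit time for a linear-in-RPM ramp; see
:mod:`spinfrac.trajectory` for the numerical demonstration).

A particle cannot sediment into a medium at least as dense as itself
(isopycnic trapping): it comes to rest at the blocking interface, which
is how a density-gradient lane banks each species into a retrievable
section.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .device import CellSpecies, LaneDesign, MediumSection, SpinProtocol

__all__ = [
    "NON_TRAVERSABLE",
    "MigrationResult",
    "PartitionMap",
    "section_transit_time",
    "ramp_correction",
    "migration_schedule",
    "predict_partitions",
    "stokes_rate_constant",
]

logger = logging.getLogger(__name__)

#: Marker returned by :func:`section_transit_time` when the cell cannot
#: sediment through the section (medium at least as dense as the cell).
NON_TRAVERSABLE = math.inf

_8PI2 = 8.0 * math.pi**2


def stokes_rate_constant(cell: CellSpecies, section: MediumSection, speed_rev_s: float) -> float:
    """Exponential growth rate k (1/s) of the radial position, dr/dt = k r.

    k = 8 pi^2 omega^2 R^2 (rho - rho0) / (9 eta) with omega in rev/s.
    Returns 0 when the medium is at least as dense as the cell.
    """
    if speed_rev_s <= 0:
        raise ValueError(f"speed_rev_s must be > 0, got {speed_rev_s}")
    delta_rho = cell.density - section.medium_density
    if delta_rho <= 0:
        return 0.0
    r_eff = cell.effective_radius
    return _8PI2 * speed_rev_s**2 * r_eff**2 * delta_rho / (9.0 * section.medium_viscosity)


def section_transit_time(
    cell: CellSpecies, section: MediumSection, speed_rev_s: float
) -> float:
    """Time (s) for the cell to cross the section at constant speed, or
    :data:`NON_TRAVERSABLE` (inf) when the medium blocks it.

    Raises ``ValueError`` for a section touching the rotation axis
    (r_proximal = 0), where the logarithmic form is undefined.
    """
    if section.r_proximal <= 0:
        raise ValueError(
            f"section {section.label!r} has r_proximal = {section.r_proximal}; "
            "transit time is undefined at the rotation axis"
        )
    k = stokes_rate_constant(cell, section, speed_rev_s)
    if k == 0.0:
        return NON_TRAVERSABLE
    return math.log(section.r_distal / section.r_proximal) / k


def ramp_correction(protocol: SpinProtocol) -> float:
    """Extra wall-clock time 2 (t_a + t_d) / 3 added to a lane total to
    compensate for reduced sedimentation during the speed ramps."""
    return 2.0 * (protocol.t_accel + protocol.t_decel) / 3.0


@dataclass(frozen=True)
class MigrationResult:
    """Outcome of walking one species through a lane.

    boundary_arrivals lists, for every section the cell fully traverses,
    the cumulative wall-clock time (including the one-time ramp
    correction) at which it reaches that section's distal boundary.
    terminal_section is the section in which the cell comes to rest: the
    distal-most section if it clears the lane, otherwise the first
    blocking section (whose proximal interface carries the banked cells,
    assigned under the half-open [r_p, r_d) convention).
    """

    species: str
    boundary_arrivals: tuple[tuple[str, float], ...]
    terminal_section: str
    trapped_at_interface: bool

    def __post_init__(self) -> None:
        times = [t for _, t in self.boundary_arrivals]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("cumulative arrival times must be strictly increasing")

    @property
    def total_time(self) -> float | None:
        """Wall-clock time to the last boundary crossed, or None if the
        cell never leaves the first section."""
        return self.boundary_arrivals[-1][1] if self.boundary_arrivals else None


@dataclass(frozen=True)
class PartitionMap:
    """Predicted resting section per species at protocol end."""

    assignments: Mapping[str, str] = field(default_factory=dict)
    end_time: float = 0.0

    def __getitem__(self, species: str) -> str:
        return self.assignments[species]

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def items(self):
        return self.assignments.items()


def migration_schedule(
    cell: CellSpecies, lane: LaneDesign, protocol: SpinProtocol
) -> MigrationResult:
    """Cumulative traversal schedule of one species through the lane.

    Walks the sections proximal to distal from the sample section's
    proximal edge, accumulating per-section transit times at the plateau
    speed, with the ramp correction added once; stops at the first
    section whose medium is at least as dense as the cell.
    """
    f = protocol.plateau_rev_s
    corr = ramp_correction(protocol)
    logger.debug(
        "migration_schedule: species=%s f=%.4f rev/s t_a=%.2f s t_d=%.2f s ramp_corr=%.2f s",
        cell.name, f, protocol.t_accel, protocol.t_decel, corr,
    )
    arrivals: list[tuple[str, float]] = []
    cum = 0.0
    trapped = False
    terminal = lane.sections[0].label
    for sec in lane.sections:
        t = section_transit_time(cell, sec, f)
        logger.debug(
            "  section %s: delta_rho=%.1f kg/m^3 transit=%s",
            sec.label, cell.density - sec.medium_density,
            "non-traversable" if math.isinf(t) else f"{t:.2f} s",
        )
        if math.isinf(t):
            trapped = True
            terminal = sec.label  # rests at this section's proximal interface
            break
        cum += t
        arrivals.append((sec.label, corr + cum))
        terminal = sec.label
    return MigrationResult(
        species=cell.name,
        boundary_arrivals=tuple(arrivals),
        terminal_section=terminal,
        trapped_at_interface=trapped,
    )


def predict_partitions(
    panel: Sequence[CellSpecies], lane: LaneDesign, protocol: SpinProtocol
) -> PartitionMap:
    """Resting section of every species when the protocol ends.

    The protocol's wall-clock length t_a + plateau + t_d provides an
    effective plateau-equivalent sedimentation time of (total - ramp
    correction); each species is advanced through the sections by its
    closed-form exponential trajectory for that long.  A species blocked
    by a dense medium is assigned the blocking section (it bands at that
    section's proximal interface, which the [r_p, r_d) convention assigns
    to the distal side); a species reaching the lane end is assigned the
    distal-most section.
    """
    f = protocol.plateau_rev_s
    total = protocol.total_duration
    tau_available = max(total - ramp_correction(protocol), 0.0)
    assignments: dict[str, str] = {}
    for cell in panel:
        if cell.name in assignments:
            raise ValueError(f"duplicate species name {cell.name!r} in panel")
        tau = tau_available
        assigned = lane.sections[-1].label  # default: cleared the lane
        for sec in lane.sections:
            k = stokes_rate_constant(cell, sec, f)
            if k == 0.0:
                assigned = sec.label  # banked at this section's proximal interface
                break
            need = math.log(sec.r_distal / sec.r_proximal) / k
            if tau >= need:
                tau -= need
            else:
                # protocol ends mid-section
                r = sec.r_proximal * math.exp(k * tau)
                assigned = lane.section_at(r).label
                break
        assignments[cell.name] = assigned
        logger.debug("predict_partitions: %s -> %s", cell.name, assigned)
    return PartitionMap(assignments=assignments, end_time=total)
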