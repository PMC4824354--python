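"""Config and count-table file round-tripping.

Device configs are YAML (or JSON — any YAML-parsable) documents with a
``schema_version`` key, holding the fluid, lane, protocol and cell panel
of one experiment in bench units:

    lengths mm, densities g/mL, viscosities mPa.s, angles degrees,
    surface tension mN/m, radii um, durations s, ramp rates RCF/min.

Units are converted to SI at the boundary; values that look like the
wrong unit (a "g/mL" density above 100 is almost certainly kg/m^3) are a
hard error, never a silent conversion.  Unknown keys are rejected by
name so typos cannot silently drop a parameter.

Count tables are CSV with header ``disk,section,cell_class,count``; an
optional reader ingests XLSX workbooks of the same column layout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .device import (
    CellSpecies,
    FluidSample,
    LaneDesign,
    MediumSection,
    SpinProtocol,
    ValveGeometry,
)
from .metrics import CountTable

__all__ = [
    "SCHEMA_VERSION",
    "DesignBundle",
    "load_design",
    "save_design",
    "load_counts",
    "save_counts",
    "load_counts_xlsx",
    "reference_design_path",
]

SCHEMA_VERSION = 1

_COUNT_HEADER = ["disk", "section", "cell_class", "count"]


@dataclass(frozen=True)
class DesignBundle:
    """Everything one experiment config describes."""

    lane: LaneDesign
    protocol: SpinProtocol
    panel: tuple[CellSpecies, ...]
    fluid: FluidSample


class ConfigError(ValueError):
    """A config file failed validation."""


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"missing key(s) {sorted(missing)} in {where}")


def _number(mapping: Mapping[str, Any], key: str, where: str) -> float:
    v = mapping[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"{where}.{key} must be a number, got {v!r}")
    return float(v)


def _density_g_ml(mapping: Mapping[str, Any], key: str, where: str) -> float:
    v = _number(mapping, key, where)
    if v > 100:
        raise ConfigError(
            f"{where}.{key} = {v} looks like kg/m^3; this field is g/mL (e.g. 1.077)"
        )
    if v <= 0:
        raise ConfigError(f"{where}.{key} must be > 0, got {v}")
    return v


def _parse_fluid(node: Mapping[str, Any]) -> FluidSample:
    _check_keys(
        node,
        {"surface_tension_mn_per_m", "contact_angle_deg", "density_g_per_ml", "viscosity_mpa_s"},
        {"surface_tension_mn_per_m", "contact_angle_deg", "density_g_per_ml"},
        "fluid",
    )
    return FluidSample(
        surface_tension=_number(node, "surface_tension_mn_per_m", "fluid") * 1e-3,
        contact_angle_adv=_number(node, "contact_angle_deg", "fluid"),
        density=_density_g_ml(node, "density_g_per_ml", "fluid") * 1000.0,
        viscosity=_number(node, "viscosity_mpa_s", "fluid") * 1e-3
        if "viscosity_mpa_s" in node
        else 4.0e-3,
    )


def _parse_section(node: Mapping[str, Any], i: int) -> MediumSection:
    where = f"lane.sections[{i}]"
    _check_keys(
        node,
        {"label", "r_proximal_mm", "r_distal_mm", "medium_density_g_per_ml",
         "medium_viscosity_mpa_s", "volume_ul"},
        {"label", "r_proximal_mm", "r_distal_mm", "medium_density_g_per_ml",
         "medium_viscosity_mpa_s"},
        where,
    )
    return MediumSection(
        label=str(node["label"]),
        medium_density=_density_g_ml(node, "medium_density_g_per_ml", where) * 1000.0,
        medium_viscosity=_number(node, "medium_viscosity_mpa_s", where) * 1e-3,
        r_proximal=_number(node, "r_proximal_mm", where) * 1e-3,
        r_distal=_number(node, "r_distal_mm", where) * 1e-3,
        volume_ul=_number(node, "volume_ul", where) if "volume_ul" in node else None,
    )


def _parse_valve(node: Mapping[str, Any], i: int) -> ValveGeometry:
    where = f"lane.valves[{i}]"
    _check_keys(node, {"height_mm", "width_mm", "radial_position_mm"},
                {"height_mm", "width_mm", "radial_position_mm"}, where)
    return ValveGeometry(
        height=_number(node, "height_mm", where) * 1e-3,
        width=_number(node, "width_mm", where) * 1e-3,
        radial_position=_number(node, "radial_position_mm", where) * 1e-3,
    )


def _parse_lane(node: Mapping[str, Any]) -> LaneDesign:
    _check_keys(node, {"disk_radius_mm", "sections", "valves"},
                {"disk_radius_mm", "sections", "valves"}, "lane")
    sections = [_parse_section(s, i) for i, s in enumerate(node["sections"])]
    valves = [_parse_valve(v, i) for i, v in enumerate(node["valves"])]
    try:
        return LaneDesign(sections, valves, _number(node, "disk_radius_mm", "lane") * 1e-3)
    except ValueError as exc:
        raise ConfigError(f"lane: {exc}") from exc


def _parse_protocol(node: Mapping[str, Any]) -> SpinProtocol:
    _check_keys(
        node,
        {"plateau_rcf", "accel_rcf_per_min", "decel_rcf_per_min",
         "plateau_duration_s", "reference_radius_mm"},
        {"plateau_rcf", "accel_rcf_per_min", "decel_rcf_per_min",
         "plateau_duration_s", "reference_radius_mm"},
        "protocol",
    )
    return SpinProtocol(
        plateau_rcf=_number(node, "plateau_rcf", "protocol"),
        accel_rcf_per_min=_number(node, "accel_rcf_per_min", "protocol"),
        decel_rcf_per_min=_number(node, "decel_rcf_per_min", "protocol"),
        plateau_duration=_number(node, "plateau_duration_s", "protocol"),
        reference_radius=_number(node, "reference_radius_mm", "protocol") * 1e-3,
    )


def _parse_species(node: Mapping[str, Any], i: int) -> CellSpecies:
    where = f"panel[{i}]"
    _check_keys(node, {"name", "density_g_per_ml", "radius_um", "agglutination_factor"},
                {"name", "density_g_per_ml", "radius_um"}, where)
    return CellSpecies.from_lab(
        name=str(node["name"]),
        density_g_ml=_density_g_ml(node, "density_g_per_ml", where),
        radius_um=_number(node, "radius_um", where),
        agglutination_factor=_number(node, "agglutination_factor", where)
        if "agglutination_factor" in node
        else 1.0,
    )


def load_design(path: str | Path) -> DesignBundle:
    """Load a device config; every domain invariant is enforced at load."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    _check_keys(doc, {"schema_version", "fluid", "lane", "protocol", "panel"},
                {"schema_version", "fluid", "lane", "protocol", "panel"}, str(path))
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: unrecognized schema_version {doc['schema_version']!r} "
            f"(this reader understands {SCHEMA_VERSION})"
        )
    return DesignBundle(
        lane=_parse_lane(doc["lane"]),
        protocol=_parse_protocol(doc["protocol"]),
        panel=tuple(_parse_species(s, i) for i, s in enumerate(doc["panel"])),
        fluid=_parse_fluid(doc["fluid"]),
    )


def save_design(bundle: DesignBundle, path: str | Path) -> None:
    """Write a config that :func:`load_design` reads back value-identical."""
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "fluid": {
            "surface_tension_mn_per_m": bundle.fluid.surface_tension / 1e-3,
            "contact_angle_deg": bundle.fluid.contact_angle_adv,
            "density_g_per_ml": bundle.fluid.density / 1000.0,
            "viscosity_mpa_s": bundle.fluid.viscosity / 1e-3,
        },
        "lane": {
            "disk_radius_mm": bundle.lane.disk_radius / 1e-3,
            "sections": [
                {
                    "label": s.label,
                    "r_proximal_mm": s.r_proximal / 1e-3,
                    "r_distal_mm": s.r_distal / 1e-3,
                    "medium_density_g_per_ml": s.medium_density / 1000.0,
                    "medium_viscosity_mpa_s": s.medium_viscosity / 1e-3,
                    **({"volume_ul": s.volume_ul} if s.volume_ul is not None else {}),
                }
                for s in bundle.lane.sections
            ],
            "valves": [
                {
                    "height_mm": v.height / 1e-3,
                    "width_mm": v.width / 1e-3,
                    "radial_position_mm": v.radial_position / 1e-3,
                }
                for v in bundle.lane.valves
            ],
        },
        "protocol": {
            "plateau_rcf": bundle.protocol.plateau_rcf,
            "accel_rcf_per_min": bundle.protocol.accel_rcf_per_min,
            "decel_rcf_per_min": bundle.protocol.decel_rcf_per_min,
            "plateau_duration_s": bundle.protocol.plateau_duration,
            "reference_radius_mm": bundle.protocol.reference_radius / 1e-3,
        },
        "panel": [
            {
                "name": c.name,
                "density_g_per_ml": c.density / 1000.0,
                "radius_um": c.radius / 1e-6,
                "agglutination_factor": c.agglutination_factor,
            }
            for c in bundle.panel
        ],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def reference_design_path() -> Path:
    """Path of the shipped reference device config (the stock lane,
    protocol, blood fluid and cell panel)."""
    return Path(resources.files("spinfrac").joinpath("data/reference_design.yaml"))


def _rows_to_table(rows: Sequence[Sequence[Any]], source: str) -> CountTable:
    records = []
    for lineno, row in rows:
        if len(row) != 4:
            raise ConfigError(f"{source} row {lineno}: expected 4 fields, got {len(row)}")
        disk, section, cell_class, count = row
        try:
            fcount = float(count)
        except (TypeError, ValueError):
            raise ConfigError(f"{source} row {lineno}: count {count!r} is not a number") from None
        if fcount != int(fcount):
            raise ConfigError(f"{source} row {lineno}: count {count!r} is not an integer")
        if fcount < 0:
            raise ConfigError(f"{source} row {lineno}: count {count!r} is negative")
        records.append((str(disk), str(section), str(cell_class), int(fcount)))
    try:
        return CountTable.from_records(records)
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def load_counts(path: str | Path) -> CountTable:
    """Read a ``disk,section,cell_class,count`` CSV into a validated
    CountTable; malformed rows are reported with their line number."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigError(f"{path}: empty file") from None
        if [h.strip() for h in header] != _COUNT_HEADER:
            raise ConfigError(
                f"{path}: expected header {','.join(_COUNT_HEADER)!r}, got {','.join(header)!r}"
            )
        rows = [(i, row) for i, row in enumerate(reader, start=2) if row]
    return _rows_to_table(rows, str(path))


def save_counts(table: CountTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, columns=_COUNT_HEADER)


def load_counts_xlsx(
    path: str | Path,
    sheet: str | int = 0,
    column_map: Mapping[str, str] | None = None,
) -> CountTable:
    """Read an XLSX workbook whose first row is a header into a
    CountTable.

    `column_map` maps the canonical names (disk, section, cell_class,
    count) to the workbook's actual column headers; by default the
    canonical names themselves are expected.  Workbook columns are
    surfaced verbatim in error messages rather than guessed.
    """
    import openpyxl

    cmap = {k: k for k in _COUNT_HEADER}
    if column_map:
        cmap.update(column_map)
    wb = openpyxl.load_workbook(Path(path), read_only=True, data_only=True)
    ws = wb[sheet] if isinstance(sheet, str) else wb.worksheets[sheet]
    it = ws.iter_rows(values_only=True)
    try:
        header = [str(h).strip() if h is not None else "" for h in next(it)]
    except StopIteration:
        raise ConfigError(f"{path}: empty worksheet") from None
    try:
        idx = {k: header.index(cmap[k]) for k in _COUNT_HEADER}
    except ValueError:
        raise ConfigError(
            f"{path}: worksheet columns are {header}; expected "
            f"{[cmap[k] for k in _COUNT_HEADER]} (use column_map to map them)"
        ) from None
    rows = []
    for lineno, row in enumerate(it, start=2):
        if row is None or all(v is None for v in row):
            continue
        rows.append((lineno, [row[idx[k]] for k in _COUNT_HEADER]))
    return _rows_to_table(rows, str(path))
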