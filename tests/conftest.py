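from dataclasses import replace

import pytest

import spinfrac as sf


@pytest.fixture
def blood() -> sf.FluidSample:
    return sf.default_blood()


@pytest.fixture
def lane() -> sf.LaneDesign:
    """Stock lane, all six sections loaded with Histopaque-1077."""
    return sf.reference_lane()


@pytest.fixture
def loaded_lane(lane) -> sf.LaneDesign:
    """Stock lane as run: diluted-blood sample in section F, Histopaque-1077
    in the five gradient sections."""
    sections = list(lane.sections)
    sections[0] = replace(sections[0], medium_density=1030.0, medium_viscosity=1.6e-3)
    return lane.with_sections(sections)


@pytest.fixture
def protocol() -> sf.SpinProtocol:
    return sf.reference_protocol()


@pytest.fixture
def panel() -> list[sf.CellSpecies]:
    return sf.reference_cell_panel()
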