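"""Closed-form sedimentation timing, ramp correction, migration schedules
and partition prediction."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import spinfrac as sf
from spinfrac.sedimentation import (
    NON_TRAVERSABLE,
    ramp_correction,
    section_transit_time,
    stokes_rate_constant,
)


def section(rho=1077.0, eta=1.5e-3, rp=30e-3, rd=37e-3, label="X"):
    return sf.MediumSection(label, rho, eta, rp, rd)


class TestSectionTransitTime:
    def test_neutral_buoyancy_is_non_traversable(self):
        cell = sf.CellSpecies("c", 1077.0, 5e-6)
        assert section_transit_time(cell, section(rho=1077.0), 40.0) is NON_TRAVERSABLE

    def test_lighter_cell_is_non_traversable(self):
        cell = sf.CellSpecies.from_lab("Lymphocyte", 1.075, 4.5)
        assert math.isinf(section_transit_time(cell, section(), 40.0))

    def test_halving_radius_quadruples_time(self):
        big = sf.CellSpecies("c", 1098.0, 5e-6)
        small = sf.CellSpecies("c", 1098.0, 2.5e-6)
        t_big = section_transit_time(big, section(), 40.0)
        t_small = section_transit_time(small, section(), 40.0)
        assert t_small == pytest.approx(4 * t_big)

    def test_agglutination_enters_via_effective_radius(self):
        single = sf.CellSpecies.from_lab("RBC", 1.098, 2.63)
        rouleaux = single.with_agglutination(3.0)
        t1 = section_transit_time(single, section(), 40.0)
        t3 = section_transit_time(rouleaux, section(), 40.0)
        assert t3 == pytest.approx(t1 / 9)

    def test_section_at_axis_rejected(self):
        cell = sf.CellSpecies("c", 1098.0, 5e-6)
        with pytest.raises(ValueError, match="axis"):
            section_transit_time(cell, section(rp=0.0, rd=7e-3), 40.0)

    @given(
        drho=st.floats(5.0, 50.0),
        scale_w=st.floats(1.1, 3.0),
        scale_r=st.floats(1.1, 3.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_time_decreases_with_speed_radius_and_density_contrast(
        self, drho, scale_w, scale_r
    ):
        sec = section()
        cell = sf.CellSpecies("c", sec.medium_density + drho, 3e-6)
        t0 = section_transit_time(cell, sec, 40.0)
        assert section_transit_time(cell, sec, 40.0 * scale_w) < t0
        faster = sf.CellSpecies("c", cell.density, cell.radius * scale_r)
        assert section_transit_time(faster, sec, 40.0) < t0
        denser = sf.CellSpecies("c", cell.density + 10.0, cell.radius)
        assert section_transit_time(denser, sec, 40.0) < t0

    @given(split=st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_transit_time_additive_over_contiguous_subsections(self, split):
        sec = section()
        r_mid = sec.r_proximal + split * (sec.r_distal - sec.r_proximal)
        first = section(rp=sec.r_proximal, rd=r_mid)
        second = section(rp=r_mid, rd=sec.r_distal)
        cell = sf.CellSpecies("c", 1098.0, 3e-6)
        whole = section_transit_time(cell, sec, 40.0)
        parts = section_transit_time(cell, first, 40.0) + section_transit_time(cell, second, 40.0)
        assert parts == pytest.approx(whole, rel=1e-12)


class TestRampCorrection:
    def test_reference_protocol_values(self, protocol):
        """500 RCF plateau reached at 500 RCF/min and left at 322 RCF/min:
        t_a = 60 s, t_d = 93.2 s, correction = 2(t_a + t_d)/3 = 102.1 s."""
        assert protocol.t_accel == pytest.approx(60.0)
        assert protocol.t_decel == pytest.approx(93.17, abs=0.01)
        assert ramp_correction(protocol) == pytest.approx(102.11, abs=0.01)

    def test_linear_in_ramp_times(self):
        p1 = sf.SpinProtocol(500, 500, 322, 240, 0.06)
        p2 = sf.SpinProtocol(500, 250, 161, 240, 0.06)  # both ramps twice as long
        assert ramp_correction(p2) == pytest.approx(2 * ramp_correction(p1))


class TestMigrationSchedule:
    def test_mononuclear_cells_do_not_migrate_in_1077(self, lane, protocol, panel):
        """Lymphocytes and monocytes are lighter than the 1.077 g/mL medium:
        they never cross a boundary."""
        for name in ("Lymphocyte", "Monocyte"):
            cell = next(c for c in panel if c.name == name)
            res = sf.migration_schedule(cell, lane, protocol)
            assert res.trapped_at_interface
            assert res.boundary_arrivals == ()
            assert res.terminal_section == "F"

    def test_granulocytes_traverse_with_increasing_times(self, lane, protocol, panel):
        for name in ("Neutrophil", "Eosinophil"):
            cell = next(c for c in panel if c.name == name)
            res = sf.migration_schedule(cell, lane, protocol)
            assert not res.trapped_at_interface
            times = [t for _, t in res.boundary_arrivals]
            assert len(times) == 6  # clears every section
            assert all(b > a for a, b in zip(times, times[1:]))
            assert res.terminal_section == "A"

    def test_schedule_includes_ramp_correction_once(self, lane, protocol):
        cell = sf.CellSpecies.from_lab("RBC", 1.098, 2.63)
        res = sf.migration_schedule(cell, lane, protocol)
        f = protocol.plateau_rev_s
        expected_first = ramp_correction(protocol) + section_transit_time(
            cell, lane.sections[0], f
        )
        assert res.boundary_arrivals[0][1] == pytest.approx(expected_first)

    def test_rouleaux_overtake_single_red_cells(self, lane, protocol):
        single = sf.CellSpecies.from_lab("RBC", 1.098, 2.63)
        rouleaux = single.with_agglutination(3.0)
        t1 = sf.migration_schedule(single, lane, protocol).boundary_arrivals[0][1]
        t3 = sf.migration_schedule(rouleaux, lane, protocol).boundary_arrivals[0][1]
        assert t3 < t1
        # the pure transit part scales by 1/9
        corr = ramp_correction(protocol)
        assert (t3 - corr) == pytest.approx((t1 - corr) / 9)

    def test_trapped_mid_lane_rests_at_blocking_interface(self, loaded_lane, protocol):
        """A cell that clears the sample section but cannot enter the first
        gradient section bands at that interface (reported under the
        blocking section, where the band is physically retrieved)."""
        wbc = sf.CellSpecies.from_lab("Lymphocyte", 1.075, 4.5)
        res = sf.migration_schedule(wbc, loaded_lane, protocol)
        assert res.trapped_at_interface
        assert [lab for lab, _ in res.boundary_arrivals] == ["F"]
        assert res.terminal_section == "E"


class TestPredictPartitions:
    def test_every_species_assigned_exactly_once(self, lane, protocol, panel):
        pm = sf.predict_partitions(panel, lane, protocol)
        assert sorted(pm) == sorted(c.name for c in panel)

    def test_light_cells_stay_proximal_in_all_1077(self, lane, protocol, panel):
        pm = sf.predict_partitions(panel, lane, protocol)
        assert pm["Lymphocyte"] == "F"
        assert pm["Monocyte"] == "F"

    def test_very_dense_large_species_reaches_distal_end(self, lane, protocol):
        heavy = sf.CellSpecies("bead", 2000.0, 50e-6)
        pm = sf.predict_partitions([heavy], lane, protocol)
        assert pm["bead"] == "A"

    def test_loaded_lane_banks_wbc_in_E_and_rouleaux_rbc_in_A(self, loaded_lane, protocol):
        panel = [
            sf.CellSpecies.from_lab("WBC", 1.075, 4.5),
            sf.CellSpecies.from_lab("RBC", 1.098, 2.63, agglutination_factor=3.0),
        ]
        pm = sf.predict_partitions(panel, loaded_lane, protocol)
        assert pm["WBC"] == "E"
        assert pm["RBC"] == "A"

    def test_single_red_cells_stall_before_the_distal_end(self, loaded_lane, protocol):
        """Without agglutination the model leaves single red cells mid-lane —
        rouleaux formation is what clears them to the rim."""
        single = sf.CellSpecies.from_lab("RBC", 1.098, 2.63)
        pm = sf.predict_partitions([single], loaded_lane, protocol)
        assert pm["RBC"] != "A"

    def test_duplicate_species_names_rejected(self, lane, protocol):
        cell = sf.CellSpecies("c", 1098.0, 3e-6)
        with pytest.raises(ValueError, match="duplicate"):
            sf.predict_partitions([cell, cell], lane, protocol)


class TestTrappedIff:
    @given(density_g_ml=st.floats(1.02, 1.12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_trapped_iff_some_section_at_least_as_dense(self, density_g_ml):
        lane = sf.reference_lane()
        protocol = sf.reference_protocol()
        cell = sf.CellSpecies.from_lab("c", density_g_ml, 5.0)
        res = sf.migration_schedule(cell, lane, protocol)
        blocked = any(s.medium_density >= cell.density for s in lane.sections)
        assert res.trapped_at_interface == blocked

    def test_rate_constant_zero_only_when_blocked(self, lane):
        sec = lane.sections[0]
        light = sf.CellSpecies("c", sec.medium_density - 1, 5e-6)
        heavy = sf.CellSpecies("c", sec.medium_density + 1, 5e-6)
        assert stokes_rate_constant(light, sec, 40.0) == 0.0
        assert stokes_rate_constant(heavy, sec, 40.0) > 0.0
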