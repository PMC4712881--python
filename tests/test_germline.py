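"""Germ-cell chart behavior: thresholds, phase sampling, fate logic,
growth and apoptosis."""

import numpy as np
import pytest

from germsim.germline import (CellCycleParams, FateParams, SignalingParams,
                              apoptosis_draw, apoptosis_step_probability,
                              build_germline_chart, contact_inhibition_guard,
                              decide_sex_fate, grow_cell,
                              sample_phase_duration)
from germsim.statechart import CellContext, step_statechart


@pytest.fixture
def chart():
    return build_germline_chart(CellCycleParams(), SignalingParams(),
                                FateParams())


def ctx(**kw):
    defaults = dict(time_hph=50.0, dtc_distance_um=10.0, volume_fraction=1.0,
                    radius_um=2.7, life_stage="adult",
                    rng=np.random.default_rng(0), dt_h=0.02)
    defaults.update(kw)
    return CellContext(**defaults)


def fresh(chart, cycle="G1", **durations):
    inst = chart.initial_instance()
    inst.active["CellCycle"] = cycle
    inst.sampled_durations.update(
        {"G1": 0.4, "S": 4.0, "G2": 2.8, "M": 0.8})
    inst.sampled_durations.update(durations)
    return inst


# ---------------------------------------------------------------- sampling
class TestPhaseSampling:
    def test_zero_cv_returns_exact_mean(self):
        assert sample_phase_duration(2.0, 0.0, np.random.default_rng(0)) == 2.0

    def test_large_sample_statistics(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_phase_duration(1.0, 0.1, rng)
                          for _ in range(100_000)])
        assert abs(draws.mean() - 1.0) < 0.01
        assert abs(draws.std() - 0.1) < 0.005

    def test_negative_draw_clamped(self):
        class NegativeRng:
            def normal(self, mean, sd):
                return -5.0
        assert sample_phase_duration(2.0, 0.1, NegativeRng()) == \
            pytest.approx(0.02)


# ----------------------------------------------------------- simple guards
class TestContactInhibition:
    def test_adult_below_threshold_arrests(self):
        cc = CellCycleParams()
        assert contact_inhibition_guard(ctx(volume_fraction=0.69), cc)

    def test_adult_above_threshold_free(self):
        cc = CellCycleParams()
        assert not contact_inhibition_guard(ctx(volume_fraction=0.71), cc)

    def test_larval_cells_never_arrest(self):
        cc = CellCycleParams()
        assert not contact_inhibition_guard(
            ctx(volume_fraction=0.5, life_stage="larval"), cc)


class TestSexFate:
    @pytest.mark.parametrize("t,expected", [
        (32.4, "sperm_fated"),
        (32.6, "oocyte_fated"),
        (32.5, "oocyte_fated"),  # tie goes to oocyte (strict "before")
    ])
    def test_time_boundary(self, t, expected):
        c = ctx(time_hph=t, dtc_distance_um=200.0)
        assert decide_sex_fate(c, FateParams()) == expected

    def test_error_before_decision_distance(self):
        with pytest.raises(ValueError):
            decide_sex_fate(ctx(dtc_distance_um=150.0), FateParams())


class TestGrowth:
    def test_meiotic_cap_at_4um(self):
        fate = FateParams()
        assert grow_cell(4.0, "MeioticProphase", "Precursor", fate, 10.0) == 4.0

    def test_oocyte_saturates_at_10um(self):
        fate = FateParams()
        r = grow_cell(9.99, "MeioticProphase", "OocyteFated", fate, 1.0)
        assert r == 10.0

    def test_mitotic_cells_do_not_grow(self):
        fate = FateParams()
        assert grow_cell(2.7, "S", "Precursor", fate, 5.0) == 2.7


class TestApoptosis:
    def test_zero_probability_never_dies(self):
        fate = FateParams(apoptosis_prob_per_h=0.0)
        c = ctx(dtc_distance_um=220.0)
        assert not any(apoptosis_draw(c, fate, 1.0, np.random.default_rng(i))
                       for i in range(100))

    def test_certain_death_in_one_hour(self):
        fate = FateParams(apoptosis_prob_per_h=1.0)
        assert apoptosis_draw(ctx(dtc_distance_um=220.0), fate, 1.0,
                              np.random.default_rng(0))

    def test_proximal_gonad_is_protected(self):
        """Cells that reach the proximal gonad (>= 250 um from the DTC)
        are committed to becoming mature gametes and never die."""
        fate = FateParams(apoptosis_prob_per_h=1.0)
        assert not apoptosis_draw(ctx(dtc_distance_um=250.0), fate, 1.0,
                                  np.random.default_rng(0))

    def test_larval_cells_do_not_die(self):
        fate = FateParams(apoptosis_prob_per_h=1.0)
        assert not apoptosis_draw(ctx(dtc_distance_um=220.0,
                                      life_stage="larval"),
                                  fate, 1.0, np.random.default_rng(0))

    def test_hazard_conversion_statistics(self):
        """Per-step probability follows the geometric hazard
        1-(1-P)^dt, checked against the closed form at P=0.1, dt=0.5."""
        expected = 1.0 - 0.9 ** 0.5
        assert apoptosis_step_probability(0.1, 0.5) == pytest.approx(expected)
        fate = FateParams(apoptosis_prob_per_h=0.1)
        rng = np.random.default_rng(3)
        c = ctx(dtc_distance_um=220.0)
        n = 100_000
        deaths = sum(apoptosis_draw(c, fate, 0.5, rng) for _ in range(n))
        assert deaths / n == pytest.approx(expected, rel=0.05)


# ----------------------------------------------------- chart-level behavior
class TestChartBehavior:
    def test_receptor_hysteresis_between_35_and_70(self, chart):
        inst = fresh(chart)
        c = ctx(dtc_distance_um=50.0, life_stage="larval")
        for _ in range(10):
            step_statechart(inst, chart, c, dt=0.02)
        assert inst.active["GLP1Receptor"] == "Bound"

    def test_signal_loss_cascade_beyond_70(self, chart):
        inst = fresh(chart, cycle="G1")
        c = ctx(dtc_distance_um=80.0, life_stage="larval")
        events = []
        for _ in range(5):
            events += step_statechart(inst, chart, c, dt=0.02)
        assert inst.active["GLP1Receptor"] == "Absent"
        assert inst.active["LAG1"] == "Inactive"
        assert inst.active["GLD"] == "Active"
        assert inst.active["CellCycle"] == "NonProliferative"
        assert ("meiotic_entry",) in events

    def test_g1_cell_in_active_gld_region_exits_without_division(self, chart):
        inst = fresh(chart, cycle="G1")
        inst.active["GLD"] = "Active"
        inst.active["LAG1"] = "Inactive"
        inst.active["GLP1Receptor"] = "Absent"
        events = step_statechart(inst, chart,
                                 ctx(dtc_distance_um=90.0), dt=0.02)
        assert inst.active["CellCycle"] == "NonProliferative"
        assert ("division",) not in events

    def test_s_phase_cell_divides_once_then_daughters_exit(self, chart):
        """A cell past G1 when the GLD region activates completes S, G2,
        divides on M entry, and exits mitosis at its next G1."""
        inst = fresh(chart, cycle="S", S=0.1, G2=0.1, M=0.1)
        inst.timers["CellCycle"] = 0.09
        c = ctx(dtc_distance_um=90.0, life_stage="larval")
        divisions = 0
        for _ in range(400):
            events = step_statechart(inst, chart, c, dt=0.02)
            divisions += sum(e[0] == "division" for e in events)
            if inst.active["CellCycle"] == "NonProliferative":
                break
        assert divisions == 1
        assert inst.active["CellCycle"] == "NonProliferative"

    def test_meiotic_entry_blocked_inside_70um(self, chart):
        """Even with GLD active (inherited), a cell within 70 um of the
        DTC does not leave the mitotic cycle."""
        inst = fresh(chart, cycle="G1")
        inst.active["GLD"] = "Active"
        step_statechart(inst, chart, ctx(dtc_distance_um=60.0), dt=0.02)
        assert inst.active["CellCycle"] != "NonProliferative"

    def test_g2_timer_frozen_under_compression_in_adult(self, chart):
        inst = fresh(chart, cycle="G2")
        c_squeezed = ctx(volume_fraction=0.6)
        step_statechart(inst, chart, c_squeezed, dt=0.02)
        assert inst.timers["CellCycle"] == 0.0
        c_free = ctx(volume_fraction=0.9)
        step_statechart(inst, chart, c_free, dt=0.02)
        assert inst.timers["CellCycle"] == pytest.approx(0.02)

    def test_oocyte_maturity_event_at_10um(self, chart):
        inst = fresh(chart)
        inst.active["SexDetermination"] = "OocyteFated"
        events = step_statechart(
            inst, chart, ctx(dtc_distance_um=260.0, radius_um=10.0), dt=0.02)
        assert inst.active["SexDetermination"] == "MatureOocyte"
        assert ("mature_oocyte",) in events

    def test_realized_cycle_length_matches_stage_total(self, chart):
        """Uncompressed larval cells complete the cycle in ~3 h on
        average (division-to-division interval)."""
        rng = np.random.default_rng(11)
        c = CellContext(time_hph=20.0, dtc_distance_um=10.0,
                        volume_fraction=1.0, radius_um=2.7,
                        life_stage="larval", rng=rng, dt_h=0.02)
        inst = fresh(chart, cycle="G1")
        inst.sampled_durations.update(
            {"G1": 0.15, "S": 1.5, "G2": 1.05, "M": 0.3})
        times = []
        t = 0.0
        for _ in range(60_000):
            events = step_statechart(inst, chart, c, dt=0.02)
            t += 0.02
            if ("division",) in events:
                times.append(t)
            if len(times) >= 120:
                break
        intervals = np.diff(times)
        assert abs(intervals.mean() - 3.0) / 3.0 < 0.03
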