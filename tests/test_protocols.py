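"""Protocol builders: schedule tiling, the five study scenarios."""

import numpy as np
import pytest

from circapain.protocols import (
    MIN_PER_DAY,
    DailyCycle,
    LightSchedule,
    Protocol,
    baseline_protocol,
    chronic_restriction_protocol,
    clock_to_sim,
    daguet_cr_protocol,
    deprivation_sweep_protocol,
    jet_lag_protocol,
    sim_to_clock,
)


def at_clock(day: int, hhmm: float) -> float:
    """Simulation time of clock time ``hhmm`` (minutes after midnight) on a day."""
    return (day - 1) * MIN_PER_DAY + clock_to_sim(hhmm)


class TestDailyCycle:
    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            DailyCycle(((0.0, 700.0, 100.0), (720.0, 1440.0, 0.0)))

    def test_negative_lux_rejected(self):
        with pytest.raises(ValueError):
            DailyCycle(((0.0, 1440.0, -1.0),))

    def test_wrapping_light_interval(self):
        # lights on 03:00-15:00 clock = sim-clock 1140 wrapping to 420
        c = DailyCycle.on_off(1140.0, 12.0, 600.0, 0.0)
        assert c.lux_at(0.0) == 600.0
        assert c.lux_at(419.0) == 600.0
        assert c.lux_at(421.0) == 0.0
        assert c.lux_at(1141.0) == 600.0


def test_every_protocol_tiles_time_without_gaps():
    protocols = [
        baseline_protocol(),
        daguet_cr_protocol(),
        deprivation_sweep_protocol(34.0),
        jet_lag_protocol("east"),
        jet_lag_protocol("west", with_flight_deprivation=True),
        chronic_restriction_protocol(),
    ]
    for prot in protocols:
        ts = np.linspace(-2 * MIN_PER_DAY, prot.duration - 1e-6, 977)
        lux = [prot.lux_at(t) for t in ts]  # raises if any gap existed
        assert min(lux) >= 0.0


class TestBaselineProtocol:
    def test_reference_day_lux_pattern(self):
        prot = baseline_protocol((14.0, 10.0), 600.0, 0.0, 10.0)
        assert prot.lux_at(at_clock(3, 9 * 60)) == 600.0  # 09:00, lit
        assert prot.lux_at(at_clock(3, 21 * 60 + 59)) == 600.0  # 21:59
        assert prot.lux_at(at_clock(3, 22 * 60 + 1)) == 0.0  # 22:01, dark
        assert prot.lux_at(at_clock(4, 7 * 60)) == 0.0  # 07:00, dark
        assert prot.forced_wake_intervals == ()

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            baseline_protocol((14.0, 11.0))


class TestDaguetCR:
    def test_deprivation_window_is_34h_ending_1800_day3(self):
        prot = daguet_cr_protocol()
        (start, end), = prot.forced_wake_intervals
        assert end - start == 34.0 * 60.0
        assert start == at_clock(2, 8 * 60)  # 08:00 day 2
        assert end == at_clock(3, 18 * 60)  # 18:00 day 3

    def test_low_light_during_deprivation_dark_baseline_night(self):
        prot = daguet_cr_protocol()
        # 03:00 in the deprivation night falls in sim-day 2 (days run 08:00-08:00)
        assert prot.lux_at(at_clock(2, 3 * 60)) == 0.5  # 03:00 during CR
        assert prot.lux_at(at_clock(1, 3 * 60)) == 0.0  # 03:00 baseline night
        assert prot.lux_at(at_clock(1, 15 * 60)) == 0.5  # day-1 laboratory light

    def test_recovery_tail_is_12_12(self):
        prot = daguet_cr_protocol(recovery_days=4.5)
        assert prot.lux_at(at_clock(4, 12 * 60)) == 0.5
        assert prot.lux_at(at_clock(4, 23 * 60)) == 0.0


class TestDeprivationSweep:
    def test_twelve_hours_or_less_means_no_forcing(self):
        assert deprivation_sweep_protocol(12.0).forced_wake_intervals == ()
        assert deprivation_sweep_protocol(5.0).forced_wake_intervals == ()

    def test_total_34_extends_22h_past_window_start(self):
        prot = deprivation_sweep_protocol(34.0, wake_onset_min=0.0)
        (start, end), = prot.forced_wake_intervals
        assert end - start == 34.0 * 60.0
        # 12 h of habitual wake + 22 h of enforced wakefulness
        assert end - (start + 12.0 * 60.0) == 22.0 * 60.0

    def test_release_phase_spacing_between_cases(self):
        p36 = deprivation_sweep_protocol(36.0)
        p38 = deprivation_sweep_protocol(38.0)
        assert p38.forced_wake_intervals[0][1] - p36.forced_wake_intervals[0][1] == 120.0

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            deprivation_sweep_protocol(-1.0)


class TestJetLag:
    def test_origin_schedule_until_switch(self):
        for direction in ("east", "west"):
            prot = jet_lag_protocol(direction)
            base = baseline_protocol((12.0, 12.0), 600.0, 0.0, 3.0)
            for t in np.linspace(0.0, 2 * MIN_PER_DAY - 1.0, 101):
                assert prot.lux_at(t) == base.lux_at(t)

    def test_eastward_arrival_is_daytime_in_destination(self):
        # arrival 08:00 origin = 13:00 destination: lights already on
        prot = jet_lag_protocol("east")
        t_switch = 2 * MIN_PER_DAY
        assert prot.lux_at(t_switch + 1.0) == 600.0
        # destination night: 20:00-08:00 local = 15:00-03:00 origin
        assert prot.lux_at(t_switch + clock_to_sim(16 * 60)) == 0.0

    def test_westward_arrival_is_night_in_destination(self):
        # arrival 08:00 origin = 03:00 destination: dark until 08:00 local
        prot = jet_lag_protocol("west")
        t_switch = 2 * MIN_PER_DAY
        assert prot.lux_at(t_switch + 1.0) == 0.0
        assert prot.lux_at(t_switch + clock_to_sim(14 * 60)) == 600.0

    @pytest.mark.parametrize("direction, hours", [("east", 8.0), ("west", 11.0)])
    def test_flight_deprivation_ends_at_arrival(self, direction, hours):
        prot = jet_lag_protocol(direction, with_flight_deprivation=True)
        (start, end), = prot.forced_wake_intervals
        assert end == 2 * MIN_PER_DAY
        assert end - start == hours * 60.0

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            jet_lag_protocol("north")


class TestChronicRestriction:
    def test_four_hour_nightly_sleep_opportunity(self):
        prot = chronic_restriction_protocol()
        forced_per_day = [e - s for s, e in prot.forced_wake_intervals]
        assert all(f == 20.0 * 60.0 for f in forced_per_day)
        assert len(forced_per_day) == 7

    def test_forcing_by_clock_time(self):
        prot = chronic_restriction_protocol()
        assert prot.forced_at(at_clock(2, 2 * 60))  # 02:00: kept awake
        assert not prot.forced_at(at_clock(2, 5 * 60))  # 05:00: may sleep

    def test_light_indoor_during_wake_dark_in_window(self):
        prot = chronic_restriction_protocol()
        assert prot.lux_at(at_clock(2, 2 * 60)) == 600.0
        assert prot.lux_at(at_clock(2, 5 * 60)) == 0.0


def test_clock_time_conversions_roundtrip():
    assert clock_to_sim(480.0) == 0.0  # 08:00 is the origin
    assert sim_to_clock(1140.0) == 180.0  # sim-clock 1140 is 03:00
    for m in (0.0, 123.0, 480.0, 1439.0):
        assert clock_to_sim(sim_to_clock(m)) == m % MIN_PER_DAY


def test_control_has_identical_light_but_no_forcing():
    prot = daguet_cr_protocol()
    ctrl = prot.without_forcing()
    assert ctrl.forced_wake_intervals == ()
    for t in np.linspace(-3 * MIN_PER_DAY, prot.duration - 1.0, 301):
        assert ctrl.lux_at(t) == prot.lux_at(t)
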