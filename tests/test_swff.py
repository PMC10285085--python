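"""Sleep-wake flip-flop: response functions, homeostat, transitions, bouts."""

import math

import numpy as np
import pytest

import circapain as ca
from circapain.swff import (
    SWFFParams,
    SWFFState,
    beta_S_of_Hs,
    detect_transitions,
    sigmoid_response,
    swff_rhs,
)

SP = SWFFParams()


class TestSigmoidResponse:
    def test_half_activation_at_threshold(self):
        assert sigmoid_response(-0.4, 6.0, -0.4, 0.4) == pytest.approx(3.0)

    def test_saturation(self):
        assert sigmoid_response(100.0, 6.0, -0.4, 0.4) == pytest.approx(6.0)

    def test_one_slope_above_threshold(self):
        # x - beta = alpha gives max/2 * (1 + tanh 1)
        expected = 6.0 * 0.5 * (1.0 + math.tanh(1.0))
        assert sigmoid_response(0.0, 6.0, -0.4, 0.4) == pytest.approx(expected)

    def test_monotone_increasing(self):
        xs = np.linspace(-3, 3, 50)
        ys = [sigmoid_response(x, 6.0, -0.4, 0.4) for x in xs]
        assert np.all(np.diff(ys) > 0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_response(0.0, 6.0, -0.4, 0.0)


@pytest.mark.parametrize(
    "Hs, expected",
    [(0.0, -0.0118), (100.0, -0.5118), (323.88, -1.63120)],
)
def test_beta_s_tracks_sleep_pressure(Hs, expected):
    assert beta_S_of_Hs(Hs, SP) == pytest.approx(expected, abs=1e-5)


class TestSwffRhs:
    def test_homeostat_wake_rise_rate_from_floor(self):
        st = SWFFState(fW=6.0, fS=0.0, fSCN=3.0, Hs=0.0, behavioral_state="wake")
        dHs = swff_rhs(st, 0.0, SP)[3]
        assert dHs == pytest.approx(323.88 / 946.8)

    def test_homeostat_sleep_branch_at_floor(self):
        st = SWFFState(fW=1.0, fS=5.0, fSCN=3.0, Hs=0.0, behavioral_state="sleep")
        assert swff_rhs(st, 0.0, SP)[3] == pytest.approx(0.0)

    def test_scn_relaxes_to_sigmoid_of_cs(self):
        # equilibrium of the SCN population at constant Cs = 1
        eq = sigmoid_response(1.0, 7.0, -0.1, 0.7)
        st = SWFFState(fW=6.0, fS=0.0, fSCN=eq, Hs=50.0)
        assert swff_rhs(st, 1.0, SP)[2] == pytest.approx(0.0, abs=1e-12)

    def test_forced_wake_input_keeps_wake_drive_high(self):
        # even with the sleep population saturated, the forcing offsets it
        st = SWFFState(fW=4.0, fS=6.0, fSCN=1.0, Hs=300.0, behavioral_state="wake")
        dfW_forced = swff_rhs(st, 0.0, SP, forced_wake=True)[0]
        dfW_free = swff_rhs(st, 0.0, SP, forced_wake=False)[0]
        assert dfW_forced > dfW_free
        assert dfW_forced > 0  # pulled up toward a rate above threshold


class TestDetectTransitions:
    def test_constant_trajectory_has_no_events(self):
        assert detect_transitions(np.arange(5.0), np.full(5, 5.0)) == []

    def test_down_then_up_crossing(self):
        ev = detect_transitions(np.array([0.0, 10.0, 20.0]), np.array([5.0, 3.0, 5.0]))
        assert [e.kind for e in ev] == ["sleep_onset", "wake_onset"]
        assert ev[0].time == pytest.approx(5.0)
        assert ev[1].time == pytest.approx(15.0)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            detect_transitions(np.array([0.0, 2.0, 1.0]), np.array([5.0, 3.0, 5.0]))


class TestEntrainedSolution:
    def test_events_alternate(self, baseline_exp):
        kinds = [e.kind for e in baseline_exp.events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_24h_periodic_sleep_onsets(self, baseline_exp):
        onsets = [e.time for e in baseline_exp.events if e.kind == "sleep_onset"]
        spacing = np.diff(onsets)
        assert np.all(np.abs(spacing[-3:] - 1440.0) < 1.0)

    def test_detector_agrees_with_integrator_events(self, baseline_exp):
        redetected = detect_transitions(baseline_exp.t, baseline_exp.fW, SP.theta_W)
        assert len(redetected) == len(baseline_exp.events)
        for a, b in zip(redetected, baseline_exp.events):
            assert a.kind == b.kind
            assert abs(a.time - b.time) < 0.1

    def test_firing_rates_within_population_bounds(self, baseline_exp):
        for arr, mx in ((baseline_exp.fW, 6.0), (baseline_exp.fS, 6.0), (baseline_exp.fSCN, 7.0)):
            assert arr.min() >= -1e-6
            assert arr.max() <= mx + 1e-6

    def test_mutual_inhibition_no_high_high_state(self, baseline_exp):
        # away from the brief switching transients, the populations are
        # exclusive: never both above half-max; and even mid-switch the
        # crossover stays well below the active population's level
        near_switch = np.zeros(len(baseline_exp.t), dtype=bool)
        for e in baseline_exp.events:
            near_switch |= np.abs(baseline_exp.t - e.time) < 30.0
        both_high = (baseline_exp.fW > 3.0) & (baseline_exp.fS > 3.0)
        assert not (both_high & ~near_switch).any()
        assert np.minimum(baseline_exp.fW, baseline_exp.fS).max() < 3.5

    def test_homeostat_monotone_within_bouts_and_bounded(self, baseline_exp):
        t, Hs = baseline_exp.t, baseline_exp.Hs
        assert Hs.min() >= 0.0 and Hs.max() <= 323.88
        bounds = [t[0]] + [e.time for e in baseline_exp.events] + [t[-1]]
        awake = baseline_exp.awake
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sel = (t > lo + 1e-6) & (t < hi - 1e-6)
            if sel.sum() < 3:
                continue
            seg = Hs[sel]
            if awake[sel][0]:
                assert np.all(np.diff(seg) > 0)
            else:
                assert np.all(np.diff(seg) < 0)


def test_spinup_erases_initial_state():
    """Two different initial states converge to the same entrained cycle."""
    prot = ca.baseline_protocol((14.0, 10.0), 600.0, 0.0, 5.0)
    durations = []
    for init in (None, np.array([-0.8, 0.3, 0.2, 5.5, 0.5, 2.0, 150.0])):
        res = ca.simulate(prot, initial_state=init).experiment()
        so = [e.time for e in res.events if e.kind == "sleep_onset"]
        wo = [e.time for e in res.events if e.kind == "wake_onset"]
        w = [x for x in wo if so[-2] < x < so[-1]][0]
        durations.append(((so[-1] - w) / 60.0, (w - so[-2]) / 60.0))
    assert durations[0][0] == pytest.approx(durations[1][0], abs=0.02)
    assert durations[0][1] == pytest.approx(durations[1][1], abs=0.02)


class TestForcedWakefulness:
    def test_state_clamped_wake_and_homeostat_rises(self, cr_exp):
        sel = cr_exp.forced
        assert cr_exp.awake[sel].all()
        Hs = cr_exp.Hs[sel]
        assert np.all(np.diff(Hs) > 0)

    def test_deprivation_peak_exceeds_baseline_day(self, cr_exp):
        dep_end = 3480.0
        i_end = np.searchsorted(cr_exp.t, dep_end)
        baseline_day = cr_exp.Hs[cr_exp.t < 1440.0]
        assert cr_exp.Hs[i_end - 1] > baseline_day.max()
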