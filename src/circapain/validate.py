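"""End-to-end analyses of the built-in study scenarios.

Each function runs the relevant protocol(s) from scratch and reduces the
simulation to the headline quantities of that scenario: entrained wake and
sleep durations, the constant-routine sinusoid calibration, jet-lag
sleep-bout and entrainment measures, recovery sleep, and the
chronic-restriction pain-peak drift.  They are shared by the command-line
``validate`` report, the acceptance script and the test suite, so every
number is produced by one code path.
"""

from __future__ import annotations

import numpy as np

from . import metrics as m
from .clock import ClockParams
from .pain import PainParams, SineFit, derive_mapping, fit_sine_24h
from .protocols import (
    MIN_PER_DAY,
    baseline_protocol,
    chronic_restriction_protocol,
    daguet_cr_protocol,
    deprivation_sweep_protocol,
    jet_lag_protocol,
)
from .swff import SWFFParams, simulate

__all__ = [
    "baseline_durations",
    "cr_calibration",
    "mapping_from_published_fits",
    "cr_recovery",
    "jetlag_summary",
    "chronic_summary",
    "sweep_summary",
    "validate_suite",
]

#: Published sinusoid fits of the circadian pain component and of the
#: simulated circadian drive over the constant-routine protocol
#: (amplitude, phase min, midline; period 1440 min).  Used as *inputs* to
#: the mapping derivation, which the pipeline must reproduce.
PUBLISHED_CP_FIT = SineFit(0.34, 780.0, 0.038)
PUBLISHED_CS_FIT = SineFit(0.9968, 56.0, 0.0235)


def _last_cycle_durations(events) -> tuple[float, float]:
    """(wake_h, sleep_h) of the final complete wake+sleep cycle."""
    so = [e.time for e in events if e.kind == "sleep_onset"]
    wo = [e.time for e in events if e.kind == "wake_onset"]
    if len(so) < 2:
        raise ValueError("need at least two sleep onsets for a full cycle")
    w_between = [t for t in wo if so[-2] < t < so[-1]]
    if not w_between:
        raise ValueError("no wake onset between the last two sleep onsets")
    w = w_between[0]
    return (so[-1] - w) / 60.0, (w - so[-2]) / 60.0


def baseline_durations(
    days: float = 15.0,
    clock_params: ClockParams | None = None,
    swff_params: SWFFParams | None = None,
) -> dict:
    """Entrained wake/sleep durations under the 14:10, 600:0 lux day."""
    res = simulate(
        baseline_protocol((14.0, 10.0), 600.0, 0.0, days),
        clock_params,
        swff_params,
    ).experiment()
    wake_h, sleep_h = _last_cycle_durations(res.events)
    onsets = [e.time for e in res.events if e.kind == "sleep_onset"]
    return {
        "wake_h": wake_h,
        "sleep_h": sleep_h,
        "sleep_onset_spacing_min": list(np.diff(onsets)),
        "cs_range": (float(res.Cs.min()), float(res.Cs.max())),
    }


def cr_calibration(pain_params: PainParams | None = None) -> dict:
    """Constant-routine run: sinusoid fit of Cs and the derived Cs->Cp map.

    The fit covers the experimental window (baseline day plus the 34 h of
    forced wakefulness, 58 h in total).
    """
    res = simulate(daguet_cr_protocol(), pain_params=pain_params).experiment()
    sel = res.t <= 3480.0
    cs_fit = fit_sine_24h(res.t[sel], res.Cs[sel])
    gain, offset, delay = derive_mapping(cs_fit, PUBLISHED_CP_FIT)
    return {
        "cs_fit_amplitude": cs_fit.amplitude,
        "cs_fit_phase_min": cs_fit.phase,
        "cs_fit_midline": cs_fit.offset,
        "derived_gain": gain,
        "derived_offset": offset,
        "derived_delay_min": delay,
    }


def mapping_from_published_fits() -> dict:
    """Cs->Cp affine map recovered from the published fit coefficients."""
    gain, offset, delay = derive_mapping(PUBLISHED_CS_FIT, PUBLISHED_CP_FIT)
    return {"gain": gain, "offset": offset, "delay_min": delay}


def cr_recovery() -> dict:
    """Deprivation + recovery: sleep rebound and daily pain differences."""
    prot = daguet_cr_protocol()
    dep = simulate(prot).experiment()
    ctrl = simulate(prot.without_forcing()).experiment()
    bouts = m.sleep_bouts(dep.events, dep.t[-1])
    bouts_c = m.sleep_bouts(ctrl.events, ctrl.t[-1])
    day3 = bouts[bouts["day"] == 3]["duration_h"]
    day3_c = bouts_c[bouts_c["day"] == 3]["duration_h"]
    daily_diff = m.daily_pain_difference(dep.t, dep.P, ctrl.P)
    return {
        "recovery_sleep_h": float(day3.sum()),
        "control_sleep_h": float(day3_c.sum()),
        "daily_pain_diff": list(daily_diff),
        "peak_diff_day": int(np.argmax(daily_diff)) + 1,
        "pain_peak_clock_h": list(
            m.pain_peak_times(ctrl.t, ctrl.P, as_clock=True) / 60.0
        ),
    }


def jetlag_summary(
    direction: str, with_flight_deprivation: bool = False, total_days: float = 18.0
) -> dict:
    """Sleep-bout changes and circadian re-entrainment for a 5-zone shift."""
    prot = jet_lag_protocol(
        direction, with_flight_deprivation=with_flight_deprivation, total_days=total_days
    )
    run = simulate(prot).experiment()
    ctrl = simulate(baseline_protocol((12.0, 12.0), 600.0, 0.0, total_days)).experiment()
    n_days = int(total_days)
    sleep_run = m.daily_sleep_hours(m.sleep_bouts(run.events, run.t[-1]), n_days)
    sleep_ctrl = m.daily_sleep_hours(m.sleep_bouts(ctrl.events, ctrl.t[-1]), n_days)
    diff_min = (sleep_run - sleep_ctrl) * 60.0
    peaks = m.circadian_peak_times(run.t, run.Cs)
    peaks_c = m.circadian_peak_times(ctrl.t, ctrl.Cs)
    dpk = np.abs(peaks - peaks_c) / 60.0
    e_day = m.entrainment_day(dpk, target_shift_h=5.0)
    # post-travel days while still entraining (travel day is day 3);
    # the last simulated day is dropped: its bout may still be open
    last = (e_day if e_day is not None else n_days) - 1
    during = diff_min[2:last]
    return {
        "sleep_diff_min": list(diff_min),
        "peak_diff_h": list(dpk),
        "entrainment_day": e_day,
        "max_sleep_reduction_min": float(-during.min()) if during.size else 0.0,
        "median_sleep_change_min": float(np.median(during)) if during.size else 0.0,
        "daily_pain_diff": list(m.daily_pain_difference(run.t, run.P, ctrl.P)),
    }


def chronic_summary(days: int = 7) -> dict:
    """A week of 04:00-08:00 sleep windows vs the unrestricted control."""
    run = simulate(chronic_restriction_protocol(days)).experiment()
    ctrl = simulate(baseline_protocol((12.0, 12.0), 600.0, 0.0, days)).experiment()
    peaks_clock_h = m.pain_peak_times(run.t, run.P, as_clock=True) / 60.0
    daily_diff = m.daily_pain_difference(run.t, run.P, ctrl.P)
    return {
        "pain_peak_clock_h": list(peaks_clock_h),
        "peak_shift_h": float(peaks_clock_h[-1] - peaks_clock_h[0]),
        "daily_pain_diff": list(daily_diff),
        "cs_peak_shift_h": list(
            (m.circadian_peak_times(run.t, run.Cs) - m.circadian_peak_times(ctrl.t, ctrl.Cs))
            / 60.0
        ),
    }


def sweep_summary(totals=(24.0, 30.0, 40.0, 48.0)) -> dict:
    """Deprivation-duration sweep on the 12:12 600:0 lux baseline.

    For each total time awake: the pain-difference area over the 7-day
    horizon, the clock phase at release, the sleep latency after release,
    and the SCN firing rate at release.
    """
    ctrl = simulate(baseline_protocol((12.0, 12.0), 600.0, 0.0, 7.0)).experiment()
    wake_onset = next(
        e.time for e in ctrl.events if e.kind == "wake_onset" and e.time >= 0
    )
    out = {"wake_onset_min": float(wake_onset), "cases": {}}
    for T in totals:
        run = simulate(
            deprivation_sweep_protocol(T, wake_onset_min=wake_onset)
        ).experiment()
        release = wake_onset + T * 60.0
        later_onsets = [
            e.time
            for e in run.events
            if e.kind == "sleep_onset" and e.time >= release - 1.0
        ]
        latency_h = (later_onsets[0] - release) / 60.0 if later_onsets else np.nan
        i = int(np.searchsorted(run.t, release))
        out["cases"][f"{T:g}"] = {
            "area_zh": m.total_pain_area(run.t, run.P, ctrl.P),
            "release_fSCN_hz": float(run.fSCN[min(i, len(run.t) - 1)]),
            "sleep_latency_h": float(latency_h),
        }
    return out


def validate_suite() -> dict:
    """Run every built-in check and report computed vs expected values.

    Failures are reported, never raised; the report is JSON-serializable.
    """
    checks: list[dict] = []

    def add(name, value, expected, tol, cmp="abs"):
        if cmp == "abs":
            ok = abs(value - expected) <= tol
        elif cmp == "le":
            ok = value <= expected + tol
        else:
            raise ValueError(cmp)
        checks.append(
            {
                "name": name,
                "computed": value,
                "expected": expected,
                "tolerance": tol,
                "cmp": cmp,
                "passed": bool(ok),
            }
        )

    base = baseline_durations()
    add("baseline_wake_duration_h", base["wake_h"], 16.74, 0.05)
    add("baseline_sleep_duration_h", base["sleep_h"], 7.26, 0.05)
    cal = cr_calibration()
    add("cr_cs_fit_amplitude", cal["cs_fit_amplitude"], 0.9968, 0.01)
    add("cr_cs_fit_phase_min", cal["cs_fit_phase_min"], 56.0, 10.0)
    mapping = mapping_from_published_fits()
    add("mapping_gain", mapping["gain"], 0.3411, 0.0005)
    rec = cr_recovery()
    add("recovery_sleep_h", rec["recovery_sleep_h"], 10.0, 0.0, cmp="le")
    east = jetlag_summary("east")
    add("east_max_sleep_reduction_min", east["max_sleep_reduction_min"], 40.0, 0.0, cmp="le")
    west = jetlag_summary("west")
    add("west_median_sleep_increase_min", west["median_sleep_change_min"], 10.0, 10.0)
    chronic = chronic_summary()
    add("chronic_pain_peak_shift_h", chronic["peak_shift_h"], 1.5, 0.5)
    return {
        "n_checks": len(checks),
        "n_passed": sum(c["passed"] for c in checks),
        "checks": checks,
    }
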