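"""Unit, oracle-equivalence, and property tests for the longitudinal classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_mrd import (
    ImagingAssessment,
    call_molecular_progression,
    classify_clearance,
    classify_molecular_response,
    compute_lead_time,
    match_timepoints,
)
from ctdna_mrd.types import parse_timepoint

from conftest import make_call

# schedule used for randomly generated series (label, day)
SCHEDULE = [("C1D1", 0), ("C1D8", 7), ("C2D1", 28), ("C4D1", 70), ("C7D1", 133), ("C10D1", 196)]
PPM_GRID = [0.0, 2.0, 5.0, 50.0, 60.0, 100.0, 1000.0]


def series(ppms, labels=None):
    labels = labels or [lab for lab, _ in SCHEDULE[: len(ppms)]]
    days = dict(SCHEDULE)
    return [make_call("P1", lab, days[lab], ppm) for lab, ppm in zip(labels, ppms)]


# ---------------------------------------------------------------------------
# independent brute-force oracles: a direct transliteration of the written
# rules via exhaustive enumeration over timepoints, with no shared state
# with the implementation


def oracle_response(calls):
    by = {c.timepoint_label: c for c in calls}
    base = by.get("C1D1")
    if base is None or not base.detected:
        return "not-evaluable", None
    ev = by.get("C2D1") or by.get("C4D1")
    if ev is None:
        return "not-evaluable", None
    b = base.ppm if base.detected else 0.0
    e = ev.ppm if ev.detected else 0.0
    r = e / b
    return ("mR" if r < 0.5 else "mNR"), r


def oracle_clearance(calls):
    in_window = [
        c for c in calls if (1, 8) <= parse_timepoint(c.timepoint_label) <= (7, 1)
    ]
    if not in_window:
        return "not-evaluable"
    return "cleared" if any(not c.detected for c in in_window) else "persistent"


def oracle_progression(calls):
    calls = sorted(calls, key=lambda c: c.day)
    eff = [c.ppm if c.detected else 0.0 for c in calls]
    for t in range(1, len(calls)):
        nadir = min(eff[:t])
        if calls[t].detected and eff[t] > 0 and (nadir == 0 or eff[t] >= 1.2 * nadir):
            return calls[t].day
    return None


class TestMolecularResponse:
    def test_deep_responder(self):
        label, ratio, _ = classify_molecular_response(series([1000.0, 1100.0, 15.0]))
        assert label == "mR" and ratio == pytest.approx(0.015)

    def test_exact_half_decrease_is_non_response(self):
        label, ratio, _ = classify_molecular_response(series([100.0, 90.0, 50.0]))
        assert label == "mNR" and ratio == pytest.approx(0.5)

    def test_c4d1_fallback_when_c2d1_missing(self):
        calls = series([100.0, 20.0], labels=["C1D1", "C4D1"])
        label, ratio, _ = classify_molecular_response(calls)
        assert label == "mR" and ratio == pytest.approx(0.2)

    def test_undetected_evaluation_timepoint_is_full_response(self):
        label, ratio, _ = classify_molecular_response(series([100.0, 80.0, 0.0]))
        assert label == "mR" and ratio == 0.0

    def test_missing_baseline_not_evaluable(self):
        calls = series([50.0, 20.0], labels=["C2D1", "C4D1"])
        label, ratio, reason = classify_molecular_response(calls)
        assert label == "not-evaluable" and reason == "baseline-missing"

    def test_undetected_baseline_not_evaluable(self):
        label, _, reason = classify_molecular_response(series([0.0, 50.0, 20.0]))
        assert label == "not-evaluable" and reason == "baseline-undetected"


class TestClearance:
    def test_cleared_on_any_window_negative(self):
        assert classify_clearance(series([500.0, 400.0, 300.0, 0.0])) == "cleared"

    def test_persistent_when_all_window_positive(self):
        assert classify_clearance(series([500.0, 400.0, 300.0, 10.0, 5.0])) == "persistent"

    def test_baseline_only_not_evaluable(self):
        assert classify_clearance(series([500.0])) == "not-evaluable"

    def test_window_excludes_baseline_and_post_c7d1(self):
        # negative baseline or negative C10D1 alone never count as clearance
        calls = [
            make_call("P1", "C1D1", 0, 100.0),
            make_call("P1", "C2D1", 28, 50.0),
            make_call("P1", "C10D1", 196, 0.0),
        ]
        assert classify_clearance(calls) == "persistent"


class TestMolecularProgression:
    def test_twenty_percent_rise_above_nadir(self):
        calls = series([100.0, 50.0, 70.0], labels=["C1D1", "C2D1", "C4D1"])
        assert call_molecular_progression(calls) == 70

    def test_strictly_decreasing_never_progresses(self):
        assert call_molecular_progression(series([100.0, 80.0, 50.0, 10.0])) is None

    def test_reappearance_after_clearance_progresses(self):
        calls = series([100.0, 0.0, 5.0], labels=["C1D1", "C2D1", "C4D1"])
        assert call_molecular_progression(calls) == 70

    def test_rise_below_threshold_ignored(self):
        calls = series([100.0, 50.0, 59.0], labels=["C1D1", "C2D1", "C4D1"])
        assert call_molecular_progression(calls) is None

    @given(
        ppms=st.lists(st.sampled_from(PPM_GRID), min_size=1, max_size=6),
        extra=st.sampled_from(PPM_GRID),
    )
    @settings(max_examples=200, deadline=None)
    def test_appending_never_delays_progression(self, ppms, extra):
        labels = [lab for lab, _ in SCHEDULE]
        before = call_molecular_progression(series(ppms, labels[: len(ppms)]))
        after = call_molecular_progression(series(ppms + [extra], labels[: len(ppms) + 1]))
        if before is not None:
            assert after == before


class TestOracleEquivalence:
    """Each classifier must equal exhaustive enumeration of the written rule."""

    @given(ppms=st.lists(st.sampled_from(PPM_GRID), min_size=1, max_size=6))
    @settings(max_examples=500, deadline=None)
    def test_random_series_equivalence(self, ppms):
        calls = series(ppms)
        label, ratio, _ = classify_molecular_response(calls)
        o_label, o_ratio = oracle_response(calls)
        assert label == o_label
        if o_ratio is None:
            assert ratio is None
        else:
            assert ratio == pytest.approx(o_ratio)
        assert classify_clearance(calls) == oracle_clearance(calls)
        assert call_molecular_progression(calls) == oracle_progression(calls)


def imaging(pid="P1", pd_day=None, days=(0, 70, 133, 196)):
    out = []
    for d in days:
        cat = "SD" if d != pd_day else "PD"
        out.append(ImagingAssessment(pid, d, 50.0, cat))
    return out


class TestLeadTime:
    def test_molecular_before_imaging(self):
        calls = series([100.0, 50.0, 70.0, 90.0, 110.0, 150.0])
        lead, reason = compute_lead_time(115, imaging(pd_day=196), calls)
        assert reason is None and lead == 115 - 196 == -81

    def test_example_sixty_five_day_advantage(self):
        calls = [make_call("P1", lab, d, 100.0) for lab, d in
                 [("C1D1", 0), ("C2D1", 28), ("C4D1", 70), ("C6D1", 115), ("C9D1", 178)]]
        lead, reason = compute_lead_time(115, imaging(pd_day=196, days=(0, 70, 133, 196)), calls)
        # gap between day-178 draw and day-196 imaging is 18 d (within 30)
        assert reason is None and lead == -81

    def test_same_day_progression(self):
        calls = series([100.0, 50.0, 70.0, 90.0, 110.0, 150.0])
        lead, reason = compute_lead_time(196, imaging(pd_day=196), calls)
        assert lead == 0 and reason is None

    def test_no_imaging_progression(self):
        lead, reason = compute_lead_time(70, imaging(pd_day=None), series([100.0, 50.0]))
        assert lead is None and reason == "no-imaging-progression"

    def test_no_post_progression_samples(self):
        calls = series([100.0, 80.0])  # days 0, 7 only; imaging PD at 196
        lead, reason = compute_lead_time(None, imaging(pd_day=196), calls)
        assert lead is None and reason == "no-molecular-progression-samples"

    def test_sampling_gap_excluded(self):
        calls = series([100.0, 50.0, 70.0])  # last draw day 28; PD at 70? gap 42
        im = imaging(pd_day=70, days=(0, 70))
        calls = calls[:2]  # draws at days 0 and 7 -> gap 63 > 30
        lead, reason = compute_lead_time(7, im, calls)
        assert lead is None and reason == "sampling-gap"


class TestMatchTimepoints:
    def test_nearest_within_window(self):
        calls = [make_call("P1", "C1D1", 0, 100.0),
                 make_call("P1", "C3D1", 63, 50.0),
                 make_call("P1", "C5D1", 95, 25.0)]
        im = [ImagingAssessment("P1", 0, 80.0, "SD"), ImagingAssessment("P1", 70, 40.0, "SD")]
        pairs = match_timepoints(calls, im)
        assert len(pairs) == 1
        day, ppm_ratio, size_ratio = pairs[0]
        assert day == 70 and ppm_ratio == pytest.approx(0.5) and size_ratio == pytest.approx(0.5)

    def test_window_exceeded_drops_pair(self):
        calls = [make_call("P1", "C1D1", 0, 100.0), make_call("P1", "C6D1", 105, 50.0)]
        im = [ImagingAssessment("P1", 0, 80.0, "SD"), ImagingAssessment("P1", 70, 40.0, "SD")]
        assert match_timepoints(calls, im) == []

    def test_perfect_concordance_gives_rho_one(self):
        from ctdna_mrd import correlate_dynamics

        calls = [make_call("P1", lab, d, ppm) for (lab, d), ppm in
                 zip(SCHEDULE, [100.0, 50.0, 25.0, 12.5, 6.25, 3.125])]
        im = [ImagingAssessment("P1", d, 80.0 * (0.5 ** i), "SD")
              for i, d in enumerate([0, 7, 28, 70, 133, 196])]
        pairs = match_timepoints(calls, im)
        assert all(p == pytest.approx(s) for _, p, s in pairs)
        rho, _ = correlate_dynamics([(p, s) for _, p, s in pairs])
        assert rho == pytest.approx(1.0)

    def test_zero_baseline_sod_rejected(self):
        calls = [make_call("P1", "C1D1", 0, 100.0)]
        im = [ImagingAssessment("P1", 0, 0.0, "SD")]
        with pytest.raises(ValueError, match="baseline sum"):
            match_timepoints(calls, im)
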