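"""Longitudinal molecular classification from detection-call time series.

Derives, per patient: molecular response (mR/mNR) from the early ctDNA
ratio to baseline, ctDNA clearance in the C1D8..C7D1 window, molecular
progression (earliest >=20% rise above the running ctDNA nadir), lead
time of molecular versus imaging progression, and matched ctDNA/imaging
fold-change pairs for correlation analysis.

Conventions (applied consistently with the rules' wording):

* a non-detected timepoint contributes PPM = 0 to ratios and to the nadir;
* a rise from a zero nadir to any detected value counts as progression
  (ctDNA reappearance after clearance);
* the progressing timepoint itself must be detected;
* exactly a 50% decrease (ratio 0.5) is mNR — mR requires a *greater
  than* 50% decrease;
* lead time is molecular minus imaging progression day, so negative
  values mean ctDNA anticipated imaging.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .types import DetectionCall, ImagingAssessment, MolecularClassification, parse_timepoint

__all__ = [
    "effective_ppm",
    "classify_molecular_response",
    "classify_clearance",
    "call_molecular_progression",
    "imaging_progression_day",
    "compute_lead_time",
    "match_timepoints",
    "classify_patient",
]

#: clearance window bounds as (cycle, day) tuples, inclusive
_CLEARANCE_LO = (1, 8)
_CLEARANCE_HI = (7, 1)


def effective_ppm(call: DetectionCall) -> float:
    """PPM as used downstream: the estimate if detected, else 0."""
    return call.ppm if call.detected else 0.0


def _sorted_calls(calls: Sequence[DetectionCall]) -> list[DetectionCall]:
    days = [c.day for c in calls]
    if any(b <= a for a, b in zip(days, days[1:])):
        ordered = sorted(calls, key=lambda c: c.day)
        if any(b.day <= a.day for a, b in zip(ordered, ordered[1:])):
            raise ValueError("detection calls contain duplicate days")
        return ordered
    return list(calls)


def classify_molecular_response(
    calls: Sequence[DetectionCall],
) -> tuple[str, Optional[float], Optional[str]]:
    """Early molecular response from the ctDNA ratio to baseline.

    The evaluation timepoint is C2D1, falling back to C4D1 when C2D1 was
    not drawn. mR requires ratio < 0.5 strictly; a non-detected evaluation
    timepoint gives ratio 0 and hence mR.

    Returns ``(label, ratio, reason)`` with label in
    {"mR", "mNR", "not-evaluable"}.
    """
    by_label = {c.timepoint_label: c for c in calls}
    baseline = by_label.get("C1D1")
    if baseline is None:
        return "not-evaluable", None, "baseline-missing"
    if not baseline.detected:
        return "not-evaluable", None, "baseline-undetected"
    eval_call = by_label.get("C2D1", by_label.get("C4D1"))
    if eval_call is None:
        return "not-evaluable", None, "no-evaluation-timepoint"
    ratio = effective_ppm(eval_call) / effective_ppm(baseline)
    return ("mR" if ratio < 0.5 else "mNR"), ratio, None


def classify_clearance(calls: Sequence[DetectionCall]) -> str:
    """ctDNA clearance: any non-detected timepoint in C1D8..C7D1.

    Returns "cleared", "persistent", or "not-evaluable" when the patient
    has no draws inside the window.
    """
    window = [
        c
        for c in calls
        if _CLEARANCE_LO <= parse_timepoint(c.timepoint_label) <= _CLEARANCE_HI
    ]
    if not window:
        return "not-evaluable"
    return "cleared" if any(not c.detected for c in window) else "persistent"


def call_molecular_progression(calls: Sequence[DetectionCall]) -> Optional[int]:
    """Earliest ctDNA rise of >=20% above the running nadir.

    Scans in day order keeping the minimum effective PPM seen so far
    (baseline included; non-detected = 0). Progression is the first later,
    *detected* timepoint whose PPM is >= 1.2x the nadir — or, when the
    nadir is 0, any detected timepoint (reappearance). Returns the day,
    or None.
    """
    ordered = _sorted_calls(calls)
    if len(ordered) < 2:
        return None
    nadir = effective_ppm(ordered[0])
    for call in ordered[1:]:
        ppm = effective_ppm(call)
        if call.detected and ppm > 0 and (nadir == 0.0 or ppm >= 1.2 * nadir):
            return call.day
        nadir = min(nadir, ppm)
    return None


def imaging_progression_day(imaging: Sequence[ImagingAssessment]) -> Optional[int]:
    """Earliest RECIST PD assessment day, or None."""
    pd_days = [im.day for im in imaging if im.recist_category == "PD"]
    return min(pd_days) if pd_days else None


def compute_lead_time(
    molecular_day: Optional[int],
    imaging: Sequence[ImagingAssessment],
    calls: Sequence[DetectionCall],
    max_gap_days: int = 30,
) -> tuple[Optional[int], Optional[str]]:
    """Lead time of molecular over imaging progression.

    Returns ``(lead_time_days, exclusion_reason)``; exactly one is set.
    Lead time = molecular day - imaging PD day (negative: ctDNA earlier).
    Exclusions: no imaging progression; no plasma at/after imaging PD when
    molecular progression was never called before it; or a sampling gap
    larger than ``max_gap_days`` between the last plasma draw preceding
    imaging PD and the imaging PD date.
    """
    img_day = imaging_progression_day(imaging)
    if img_day is None:
        return None, "no-imaging-progression"
    call_days = sorted(c.day for c in calls)
    if molecular_day is None:
        if not any(d >= img_day for d in call_days):
            return None, "no-molecular-progression-samples"
        return None, "no-molecular-progression"
    prior = [d for d in call_days if d <= img_day]
    if prior and img_day - prior[-1] > max_gap_days:
        return None, "sampling-gap"
    return molecular_day - img_day, None


def match_timepoints(
    calls: Sequence[DetectionCall],
    imaging: Sequence[ImagingAssessment],
    window: int = 30,
) -> list[tuple[int, float, float]]:
    """Pair imaging assessments with the nearest ctDNA call within a window.

    For each post-baseline imaging assessment, finds the nearest call
    within ±``window`` days (ties broken toward the earlier call) and
    emits ``(imaging_day, ppm_ratio, size_ratio)`` — both ratios relative
    to baseline (C1D1 PPM, day-0 sum of diameters).

    Raises ``ValueError`` when the baseline PPM or baseline sum of
    diameters is missing or non-positive (such a patient is excluded
    upstream).
    """
    baseline_call = next((c for c in calls if c.timepoint_label == "C1D1"), None)
    if baseline_call is None or effective_ppm(baseline_call) <= 0:
        raise ValueError("baseline ctDNA PPM missing or non-positive")
    baseline_im = next((im for im in imaging if im.day == 0), None)
    if baseline_im is None or baseline_im.sum_of_diameters <= 0:
        raise ValueError("baseline sum of diameters missing or zero")
    ppm0 = effective_ppm(baseline_call)
    sod0 = baseline_im.sum_of_diameters
    pairs: list[tuple[int, float, float]] = []
    for im in imaging:
        if im.day == 0:
            continue  # baseline-to-baseline pair carries no information
        best = min(
            (c for c in calls if abs(c.day - im.day) <= window),
            key=lambda c: (abs(c.day - im.day), c.day),
            default=None,
        )
        if best is None:
            continue
        pairs.append((im.day, effective_ppm(best) / ppm0, im.sum_of_diameters / sod0))
    return pairs


def classify_patient(
    calls: Sequence[DetectionCall],
    imaging: Sequence[ImagingAssessment],
    max_gap_days: int = 30,
) -> MolecularClassification:
    """Assemble the full per-patient molecular classification."""
    ordered = _sorted_calls(calls)
    label, ratio, reason = classify_molecular_response(ordered)
    clearance = classify_clearance(ordered)
    mol_day = call_molecular_progression(ordered)
    img_day = imaging_progression_day(imaging)
    lead, lead_reason = compute_lead_time(mol_day, imaging, ordered, max_gap_days)
    return MolecularClassification(
        patient_id=ordered[0].patient_id,
        molecular_response=label,
        response_ratio=ratio,
        clearance=clearance,
        molecular_progression_day=mol_day,
        imaging_progression_day=img_day,
        lead_time_days=lead,
        exclusion_reason=reason or lead_reason,
    )
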