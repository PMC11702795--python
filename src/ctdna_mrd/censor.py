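"""Assay-sensitivity degradation: censoring detections at a PPM threshold.

Simulates re-running the cohort through a less sensitive MRD assay
(first-generation tumor-informed tests have LODs near 100 PPM) by turning
every positive detection at or below the threshold into "not detected",
then quantifies what the loss of ultra-low-level detections costs:
progression calls lost, lead-time changes, and clearance-group switches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .types import DetectionCall, MolecularClassification

__all__ = ["CensorConfig", "censor_calls", "compare_sensitivity"]


@dataclass(frozen=True)
class CensorConfig:
    threshold_ppm: float = 100.0

    def __post_init__(self) -> None:
        if self.threshold_ppm <= 0:
            raise ValueError("censoring threshold must be > 0")


def censor_calls(
    calls: Sequence[DetectionCall], threshold_ppm: float = 100.0
) -> list[DetectionCall]:
    """Turn detections at <= threshold PPM into non-detections.

    The threshold is inclusive. Censored calls keep their original p-value
    (for audit) but report ppm = 0, matching "not detected" semantics
    downstream. Idempotent; calls above the threshold are unchanged.
    """
    if threshold_ppm <= 0:
        raise ValueError("censoring threshold must be > 0")
    out = []
    for c in calls:
        if c.detected and c.ppm <= threshold_ppm:
            out.append(replace(c, detected=False, ppm=0.0, censored=True))
        else:
            out.append(c)
    return out


def compare_sensitivity(
    original: Sequence[MolecularClassification],
    censored: Sequence[MolecularClassification],
) -> pd.DataFrame:
    """Per-patient impact of the sensitivity degradation.

    Returns a DataFrame with one row per patient recording progression
    calls lost, lead-time deltas, and clearance switches, plus aggregate
    counts in ``DataFrame.attrs["summary"]`` (set differences of
    patient-id sets).
    """
    orig = {c.patient_id: c for c in original}
    cens = {c.patient_id: c for c in censored}
    if set(orig) != set(cens):
        raise ValueError("original and censored classifications cover different patients")

    rows = []
    for pid in sorted(orig):
        a, b = orig[pid], cens[pid]
        lead_delta: Optional[float]
        if a.lead_time_days is not None and b.lead_time_days is not None:
            lead_delta = b.lead_time_days - a.lead_time_days
        else:
            lead_delta = None
        rows.append(
            {
                "patient_id": pid,
                "progression_original": a.molecular_progression_day is not None,
                "progression_censored": b.molecular_progression_day is not None,
                "progression_lost": (
                    a.molecular_progression_day is not None
                    and b.molecular_progression_day is None
                ),
                "lead_time_original": a.lead_time_days,
                "lead_time_censored": b.lead_time_days,
                "lead_time_delta": lead_delta,
                "clearance_original": a.clearance,
                "clearance_censored": b.clearance,
                "clearance_switched": a.clearance != b.clearance,
            }
        )
    df = pd.DataFrame(rows)
    progressors = {p for p, c in orig.items() if c.molecular_progression_day is not None}
    progressors_cens = {
        p for p, c in cens.items() if c.molecular_progression_day is not None
    }
    cleared = {p for p, c in orig.items() if c.clearance == "cleared"}
    cleared_cens = {p for p, c in cens.items() if c.clearance == "cleared"}
    df.attrs["summary"] = {
        "n_patients": len(orig),
        "n_progressors_original": len(progressors),
        "n_progressors_censored": len(progressors_cens),
        "n_progressions_lost": len(progressors - progressors_cens),
        "n_cleared_original": len(cleared),
        "n_cleared_censored": len(cleared_cens),
        "n_newly_cleared": len(cleared_cens - cleared),
    }
    return df
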