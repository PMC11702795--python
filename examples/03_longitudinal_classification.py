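"""Classify one simulated patient's longitudinal ctDNA series.

Derives molecular response (>50% drop by C2D1), clearance (any negative
draw in C1D8..C7D1), molecular progression (>=20% rise above the running
nadir), and the lead time of molecular over imaging progression.
"""

from ctdna_mrd import CohortConfig, classify_patient, simulate_cohort
from ctdna_mrd.pipeline import detect_cohort

cohort = simulate_cohort(CohortConfig(seed=7))
# pick a relapsing partial responder
patient = next(
    p for p in cohort
    if p.response_class == "PR"
    and any(im.recist_category == "PD" for im in p.imaging_series)
)
calls = detect_cohort(patient.plasma_samples, {patient.patient_id: patient.panel})

print(f"patient {patient.patient_id} (best response {patient.response_class})")
for c in calls:
    status = f"{c.ppm:10.1f} PPM" if c.detected else "not detected"
    print(f"  {c.timepoint_label:>6}  day {c.day:3d}  {status}")

cls = classify_patient(calls, patient.imaging_series)
print()
print(f"molecular response   : {cls.molecular_response} (ratio {cls.response_ratio:.3f})")
print(f"ctDNA clearance      : {cls.clearance}")
print(f"molecular progression: day {cls.molecular_progression_day}")
print(f"imaging progression  : day {cls.imaging_progression_day}")
print(f"lead time            : {cls.lead_time_days} days")
print()
print("A negative lead time means the ctDNA rise anticipated the RECIST")
print("progression call by that many days.")
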