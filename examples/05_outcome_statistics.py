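"""Outcome statistics: ratio comparisons, correlation, and survival.

Runs the full pipeline on one synthetic cohort and computes the endpoint
statistics: exact Wilcoxon rank-sum on early ctDNA ratios (responders vs
non-responders), Spearman correlation of ctDNA vs tumor-size fold
changes, and Kaplan-Meier / Cox analysis of PFS by molecular response.
"""

import numpy as np

from ctdna_mrd import CohortConfig, simulate_cohort, survival_by_group
from ctdna_mrd.pipeline import (
    _outcome_stats,
    _survival_records,
    classify_cohort,
    cohort_tables,
    detect_cohort,
)

cohort = simulate_cohort(CohortConfig(seed=7))
panels = {p.patient_id: p.panel for p in cohort}
calls = detect_cohort([s for p in cohort for s in p.plasma_samples], panels)
imaging = [im for p in cohort for im in p.imaging_series]
classifications, pairs = classify_cohort(calls, imaging)
patients = cohort_tables(cohort)["patients"]

stats = _outcome_stats(classifications, pairs, patients)

w = stats["c2d1_ratio_wilcoxon"]
print(f"C2D1/baseline ratio, CR/PR vs SD/PD: medians "
      f"{w['median_ratio_cr_pr']:.3f} vs {w['median_ratio_sd_pd']:.3f}, "
      f"exact rank-sum p = {w['p_value']:.4f}")
corr = stats["ctdna_imaging_correlation"]
print(f"ctDNA vs tumor-size fold changes   : rho = {corr['rho']:.2f} "
      f"(p = {corr['p_value']:.2e}, {corr['n_pairs']} pairs)")
pfs = stats["mr_pfs"]
print(f"PFS, mNR vs mR                     : HR = {pfs['hazard_ratio']:.1f} "
      f"(log-rank p = {pfs['logrank_p']:.4f})")
leads = stats["lead_time"]
print(f"lead time                          : median {leads['median_days']} days "
      f"({leads['n']} evaluable patients)")
print()
print("Responders' ctDNA collapses by C2D1 while non-responders' barely")
print("moves; molecular non-response carries a large PFS hazard; and the")
print("negative median lead time is the days by which ctDNA anticipated")
print("radiographic progression.")
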