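"""Outcome statistics on pipeline outputs.

Group comparison of ctDNA ratios (exact Wilcoxon rank-sum), correlation
of ctDNA and imaging fold changes (Spearman), and survival analysis by
molecular grouping (Kaplan-Meier, log-rank, univariable Cox with Efron
tie handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import exceptions
from lifelines.statistics import logrank_test
from scipy.stats import mannwhitneyu, spearmanr

__all__ = [
    "SurvivalRecord",
    "compare_ratio_groups",
    "correlate_dynamics",
    "survival_by_group",
    "SurvivalComparison",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's endpoint: time-to-event, event flag, molecular group."""

    patient_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if not self.group:
            raise ValueError("group label must be non-empty")


def compare_ratio_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Exact Wilcoxon rank-sum test between two groups of ctDNA ratios.

    Uses the exact null distribution (full enumeration) — appropriate for
    the small per-group sizes of an MRD cohort. Returns (U statistic,
    p-value).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(group_a, group_b, alternative=alternative, method="exact")
    return float(res.statistic), float(res.pvalue)


def correlate_dynamics(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Spearman rank correlation between ctDNA and tumor-size fold changes.

    ``pairs`` are (ppm_ratio, size_ratio) tuples from matched timepoints.
    Returns (rho, p) with tie-corrected p-value.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs")
    x, y = zip(*pairs)
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class SurvivalComparison:
    """Two-group survival comparison result."""

    reference_group: str
    comparison_group: str
    n_reference: int
    n_comparison: int
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    hr_p: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference_group": self.reference_group,
            "comparison_group": self.comparison_group,
            "n_reference": self.n_reference,
            "n_comparison": self.n_comparison,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci_low": self.hr_ci_low,
            "hr_ci_high": self.hr_ci_high,
            "hr_p": self.hr_p,
        }


def survival_by_group(
    records: Sequence[SurvivalRecord],
    reference: Optional[str] = None,
    penalizer: float = 0.0,
) -> SurvivalComparison:
    """KM curves, log-rank test, and univariable Cox HR for two groups.

    The hazard ratio is for the non-reference group relative to
    ``reference`` (pass the favorable group — mR or cleared — so HR > 1
    means the unfavorable group does worse). Cox fitting uses Efron tie
    handling, the accepted default with heavily tied event times.
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if not any(r.event for r in records):
        raise ValueError("need at least one event")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")
    other = next(g for g in groups if g != reference)

    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "exposed": [int(r.group == other) for r in records],
        }
    )
    ref_mask = df["exposed"] == 0
    lr = logrank_test(
        df.loc[ref_mask, "time"],
        df.loc[~ref_mask, "time"],
        event_observed_A=df.loc[ref_mask, "event"],
        event_observed_B=df.loc[~ref_mask, "event"],
    )

    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except exceptions.ConvergenceError:
        # complete separation between small groups: refit with light ridge
        # shrinkage so the HR stays finite (its direction is unaffected)
        cph = CoxPHFitter(penalizer=max(penalizer, 0.1))
        cph.fit(df, duration_col="time", event_col="event")
    with np.errstate(over="ignore"):
        hr = float(np.exp(cph.params_["exposed"]))
        ci = cph.confidence_intervals_
        ci_low = float(np.exp(ci.loc["exposed"].iloc[0]))
        ci_high = float(np.exp(ci.loc["exposed"].iloc[1]))
    hr_p = float(cph.summary.loc["exposed", "p"])

    curves: dict[str, pd.DataFrame] = {}
    for g, mask in ((reference, ref_mask), (other, ~ref_mask)):
        km = KaplanMeierFitter()
        km.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=g)
        curves[g] = km.survival_function_

    return SurvivalComparison(
        reference_group=reference,
        comparison_group=other,
        n_reference=int(ref_mask.sum()),
        n_comparison=int((~ref_mask).sum()),
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci_low=ci_low,
        hr_ci_high=ci_high,
        hr_p=hr_p,
        km_curves=curves,
    )
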