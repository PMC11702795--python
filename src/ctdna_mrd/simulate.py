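"""Synthetic cohort generator.

Emulates the data structure of a 25-patient metastatic esophagogastric
cancer trial cohort profiled with bespoke tumor-informed MRD panels:
per-patient panels of 506-1,875 variants with an LOD near 2 PPM, a best
overall response mixture of 2 CR / 14 PR / 2 SD / 5 PD, 100% baseline
ctDNA positivity, longitudinal plasma draws at C1D1, C1D8, C2D1 and then
every third cycle, imaging every three cycles from C4D1, and PFS/OS
endpoints driven by the simulated tumor trajectory.

The generative model, per patient:

1. draw a best-overall-response class from the mixture;
2. simulate a relative tumor-burden trajectory r(t) for that class
   (CR: exponential decay to eradication; PR: decay to a plateau with a
   possible later relapse; SD: flat with a possible relapse; PD: growth
   from the start);
3. map burden to ctDNA tumor fraction via a power law
   f(t) = f0 * r(t)**gamma with multiplicative lognormal shedding noise
   and a transient multiplicative bump at C1D8 (responders shed more
   immediately after the immunotherapy lead-in);
4. draw pooled molecule counts from the same Poisson forward model the
   detection stage assumes;
5. derive imaging sums-of-diameters from r(t) with RECIST 1.1
   categorisation, and PFS/OS from the imaging progression day plus a
   class-specific exponential post-progression survival.

ctDNA falling orders of magnitude faster than tumor diameters (gamma > 1)
reflects that responders' ctDNA ratios reach ~0.01-0.05 of baseline by
C2D1 while RECIST sums shrink only 30-70%; burden is closer to volume
than to diameter, and shedding tracks viable burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import ConfigurationError, PanelDesign, PlasmaSample, ImagingAssessment, SimPatient

__all__ = [
    "CohortConfig",
    "default_schedule",
    "simulate_cohort",
    "generate_counts",
    "qc_tumor_purity",
]

RESPONSE_CLASSES = ("CR", "PR", "SD", "PD")


def default_schedule(max_followup_days: int = 550) -> list[tuple[str, int]]:
    """Plasma-draw schedule: C1D1, C1D8, C2D1, then every third cycle.

    Day mapping uses the trial's 7-day pembrolizumab lead-in followed by
    21-day cycles: C1D1 = day 0, C1D8 = day 7, CnD1 = 7 + 21*(n-1) for
    n >= 2 (so C2D1 = 28, C4D1 = 70, C7D1 = 133, ...).
    """
    schedule = [("C1D1", 0), ("C1D8", 7), ("C2D1", 28)]
    cycle = 4
    while True:
        day = 7 + 21 * (cycle - 1)
        if day > max_followup_days:
            break
        schedule.append((f"C{cycle}D1", day))
        cycle += 3
    return schedule


@dataclass
class CohortConfig:
    """Full generative specification of a synthetic cohort.

    Defaults reproduce the emulated trial's structure; see the package
    methods note for the calibration rationale behind depth, error rate
    and the kinetic parameters.
    """

    n_patients: int = 25
    # BOR counts of the emulated cohort (2 CR / 14 PR / 2 SD / 5 PD among
    # 23 response-evaluable of 25 patients), normalised to probabilities
    response_mixture: dict[str, float] = field(
        default_factory=lambda: {"CR": 2 / 23, "PR": 14 / 23, "SD": 2 / 23, "PD": 5 / 23}
    )
    # baseline tumor fraction: log-uniform; >=100x LOD so baselines are
    # always detectable, as observed in the cohort (100% C1D1 positivity)
    baseline_tumor_fraction_range: tuple[float, float] = (2.5e-4, 0.41)
    panel_size_range: tuple[int, int] = (506, 1875)
    mean_molecules_per_site: float = 4000.0
    per_site_error_rate: float = 5e-7
    # transient C1D8 shedding bump: responders (CR/PR) vs non-responders
    c1d8_response_bump: dict[str, float] = field(
        default_factory=lambda: {"responder": 1.26, "nonresponder": 0.88}
    )
    # per-day rates on relative tumor burden; decay begins after a short
    # treatment-response lag (responders' ctDNA transiently rises first)
    response_lag_days: float = 10.0
    decay_rate_cr: float = 0.12
    decay_rate_pr: float = 0.12
    growth_rate_pd: float = 0.008
    relapse_growth_rate: float = 0.015
    pr_plateau_range: tuple[float, float] = (0.08, 0.40)
    # burden -> ctDNA coupling exponent (power law on the linear scale)
    ctdna_size_exponent: float = 3.0
    # fraction of PR patients whose viable tumor is eradicated (ctDNA
    # decays to zero) even though imaging plateaus at a residual mass
    pr_deep_clearance_prob: float = 0.35
    deep_clearance_decay_range: tuple[float, float] = (0.10, 0.16)
    # deep responders relapse later (durable responses); multiplier on the
    # PR median relapse day
    deep_clearance_relapse_delay: float = 2.0
    # transient on-chemo ctDNA dip for SD/PD patients (depth, center
    # day, gaussian width): their shedding sags transiently around day 40
    # and recovers, without any durable response
    nonresponder_dip_depth: float = 0.7
    nonresponder_dip_center_day: float = 40.0
    nonresponder_dip_width_days: float = 22.0
    lognormal_noise_sd: float = 0.25
    schedule: list[tuple[str, int]] = field(default_factory=default_schedule)
    imaging_interval: int = 3  # cycles between imaging assessments
    max_followup_days: int = 550
    # median relapse day (lognormal) and post-progression survival means
    pr_relapse_median_day: float = 200.0
    sd_relapse_median_day: float = 130.0
    relapse_day_log_sd: float = 0.45
    post_progression_survival_mean: dict[str, float] = field(
        default_factory=lambda: {"PR": 280.0, "SD": 220.0, "PD": 130.0}
    )
    baseline_sod_range_mm: tuple[float, float] = (40.0, 150.0)
    tumor_purity_range: tuple[float, float] = (0.10, 0.70)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if set(self.response_mixture) != set(RESPONSE_CLASSES):
            raise ConfigurationError("response mixture must cover CR/PR/SD/PD")
        total = sum(self.response_mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"response mixture must sum to 1, got {total}")
        if any(w < 0 for w in self.response_mixture.values()):
            raise ConfigurationError("mixture weights must be non-negative")
        for name, (lo, hi) in (
            ("baseline_tumor_fraction_range", self.baseline_tumor_fraction_range),
            ("panel_size_range", self.panel_size_range),
        ):
            if not (0 < lo < hi):
                raise ConfigurationError(f"{name} must be positive and non-degenerate")
        if not self.schedule:
            raise ConfigurationError("schedule must not be empty")
        days = [d for _, d in self.schedule]
        if days != sorted(set(days)) or days[0] != 0:
            raise ConfigurationError("schedule days must be strictly increasing from day 0")
        if self.schedule[0][0] != "C1D1":
            raise ConfigurationError("schedule must start at C1D1")


def qc_tumor_purity(purity: float, threshold: float = 0.07) -> bool:
    """Tumor-content eligibility gate for panel design.

    Patients whose tumor specimen has purity below the threshold (default
    7%, the WGS-estimated tumor-content cutoff) are ineligible for
    bespoke-panel MRD profiling.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    return purity >= threshold


def generate_counts(
    tumor_fraction: float,
    panel: PanelDesign,
    rng: np.random.Generator,
) -> tuple[int, int, float]:
    """Forward model for one plasma draw's pooled molecule counts.

    The pooled informative depth M is Poisson around the panel's expected
    total; variant-supporting molecules are Poisson with mean
    M * tumor_fraction + lambda0 where lambda0 = M * per-site error rate —
    the same null the detection test assumes.

    Returns ``(variant_molecules, total_molecules, expected_noise)``.
    """
    if not 0.0 <= tumor_fraction < 1.0:
        raise ValueError(f"tumor fraction must be in [0, 1), got {tumor_fraction}")
    total = int(rng.poisson(panel.mean_total_molecules))
    total = max(total, 1)
    lam0 = total * panel.per_site_error_rate
    k = int(rng.poisson(total * tumor_fraction + lam0))
    return min(k, total), total, lam0


def _burden_trajectory(
    cls: str, cfg: CohortConfig, rng: np.random.Generator, deep: bool = False
) -> tuple["_Trajectory", Optional[float]]:
    """Draw class-specific trajectory parameters; returns (r(t), relapse day)."""
    if cls == "CR":
        return _Trajectory("CR", rate=cfg.decay_rate_cr, lag=cfg.response_lag_days), None
    if cls == "PD":
        return _Trajectory("PD", rate=cfg.growth_rate_pd), 0.0
    plateau = float(rng.uniform(*cfg.pr_plateau_range)) if cls == "PR" else 1.0
    median = cfg.pr_relapse_median_day if cls == "PR" else cfg.sd_relapse_median_day
    if deep:
        median *= cfg.deep_clearance_relapse_delay
    relapse_day = float(rng.lognormal(math.log(median), cfg.relapse_day_log_sd))
    return (
        _Trajectory(
            cls,
            rate=cfg.decay_rate_pr if cls == "PR" else 0.0,
            plateau=plateau,
            relapse_day=relapse_day,
            relapse_rate=cfg.relapse_growth_rate,
            lag=cfg.response_lag_days,
        ),
        relapse_day,
    )


@dataclass(frozen=True)
class _Trajectory:
    """Relative tumor burden r(t), r(0) = 1, piecewise by response class."""

    cls: str
    rate: float
    plateau: float = 0.0
    relapse_day: Optional[float] = None
    relapse_rate: float = 0.0
    lag: float = 0.0  # days before treatment effect kicks in
    eradication_threshold: float = 0.02  # CR burden below this is true zero

    def _decay_time(self, t: float) -> float:
        return max(0.0, t - self.lag)

    def __call__(self, t: float) -> float:
        if self.cls == "CR":
            r = math.exp(-self.rate * self._decay_time(t))
            return 0.0 if r < self.eradication_threshold else r
        if self.cls == "PD":
            return math.exp(self.rate * t)
        r = self.plateau + (1.0 - self.plateau) * math.exp(-self.rate * self._decay_time(t))
        if self.relapse_day is not None and t > self.relapse_day:
            base = self.plateau + (1.0 - self.plateau) * math.exp(
                -self.rate * self._decay_time(self.relapse_day)
            )
            r = base * math.exp(self.relapse_rate * (t - self.relapse_day))
        return r


def _recist_category(sod: float, baseline: float, nadir: float) -> str:
    """RECIST 1.1 category from sum of diameters (target lesions only)."""
    if sod < 5.0:
        return "CR"
    if sod >= 1.2 * nadir and sod - nadir >= 5.0:
        return "PD"
    if sod <= 0.7 * baseline:
        return "PR"
    return "SD"


def _draw_panel_size(cfg: CohortConfig, rng: np.random.Generator) -> int:
    """Panel sizes skew toward the ~1,800-variant design target."""
    lo, hi = cfg.panel_size_range
    if rng.uniform() < 0.7:
        return int(rng.integers(max(lo, int(0.93 * hi)), hi + 1))
    return int(rng.integers(lo, hi + 1))


def simulate_cohort(config: CohortConfig) -> list[SimPatient]:
    """Generate the full synthetic cohort; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    classes = list(RESPONSE_CLASSES)
    weights = np.array([config.response_mixture[c] for c in classes])
    bump = config.c1d8_response_bump
    f_lo, f_hi = config.baseline_tumor_fraction_range
    imaging_step = 21 * config.imaging_interval

    patients: list[SimPatient] = []
    for i in range(config.n_patients):
        pid = f"SIM{i + 1:03d}"
        cls = classes[int(rng.choice(len(classes), p=weights))]
        panel = PanelDesign(
            patient_id=pid,
            n_variants=_draw_panel_size(config, rng),
            mean_molecules_per_site=config.mean_molecules_per_site,
            per_site_error_rate=config.per_site_error_rate,
        )
        purity = float(rng.uniform(*config.tumor_purity_range))
        f0 = float(np.exp(rng.uniform(np.log(f_lo), np.log(f_hi))))
        deep = cls == "PR" and rng.uniform() < config.pr_deep_clearance_prob
        traj, _ = _burden_trajectory(cls, config, rng, deep=deep)
        baseline_sod = float(rng.uniform(*config.baseline_sod_range_mm))

        # --- imaging series: baseline, then every imaging_interval cycles
        # from C4D1, stopping at first PD ---
        imaging = [ImagingAssessment(pid, 0, round(baseline_sod, 1), "SD")]
        nadir = baseline_sod
        imaging_pd_day: Optional[int] = None
        day = 7 + 21 * 3  # C4D1
        while day <= config.max_followup_days:
            sod = baseline_sod * traj(day) * float(
                np.exp(rng.normal(0.0, 0.03))
            )
            sod = 0.0 if traj(day) == 0.0 else max(sod, 0.0)
            cat = _recist_category(sod, baseline_sod, nadir)
            imaging.append(ImagingAssessment(pid, day, round(sod, 1), cat))
            if cat == "PD":
                imaging_pd_day = day
                break
            nadir = min(nadir, sod) if sod >= 5.0 else min(nadir, 5.0)
            day += imaging_step

        # --- survival endpoints ---
        if imaging_pd_day is not None:
            mean_post = config.post_progression_survival_mean.get(cls, 200.0)
            os_days = imaging_pd_day + float(rng.exponential(mean_post))
            if os_days > config.max_followup_days:
                os_days, os_event = config.max_followup_days, False
            else:
                os_event = True
            pfs_days, pfs_event = imaging_pd_day, True
        else:
            os_days, os_event = config.max_followup_days, False
            pfs_days, pfs_event = config.max_followup_days, False
        os_days = int(round(os_days))
        pfs_days = int(round(min(pfs_days, os_days)))

        # --- ctDNA kinetics: coupled to burden via the power law, with a
        # deep-clearance path for a subset of PRs and a transient chemo
        # dip for non-responders ---
        gamma = config.ctdna_size_exponent
        deep_decay = float(rng.uniform(*config.deep_clearance_decay_range))

        def ct_relative(t: float) -> float:
            """Relative ctDNA level (1 at baseline, exact 0 when eradicated)."""
            if deep:
                rel = traj.relapse_day
                lagged = max(0.0, t - config.response_lag_days)
                if rel is None or t <= rel:
                    v = math.exp(-deep_decay * lagged)
                    return v if v >= 1e-6 else 0.0
                restart = max(math.exp(-deep_decay * max(0.0, rel - config.response_lag_days)), 1e-4)
                return min(restart * math.exp(gamma * config.relapse_growth_rate * (t - rel)), 1.0)
            r = traj(t)
            if r == 0.0:
                return 0.0
            v = r**gamma
            if cls in ("SD", "PD"):
                d = config.nonresponder_dip_depth
                v *= 1.0 - d * math.exp(
                    -((t - config.nonresponder_dip_center_day) ** 2)
                    / (2.0 * config.nonresponder_dip_width_days**2)
                )
            return v

        truth: dict[int, float] = {}
        samples: list[PlasmaSample] = []
        for label, t in config.schedule:
            if t > os_days:
                break
            rel_ct = ct_relative(t)
            if rel_ct == 0.0:
                f = 0.0
            else:
                f = f0 * rel_ct
                f *= float(np.exp(rng.normal(0.0, config.lognormal_noise_sd)))
                if label == "C1D8":
                    # configured bump = expected observed mean C1D8/baseline
                    # ratio; the baseline-normalised ratio of two lognormal
                    # noises has mean e^{sigma^2}, which is divided out here
                    f *= bump[
                        "responder" if cls in ("CR", "PR") else "nonresponder"
                    ] * math.exp(-config.lognormal_noise_sd**2)
                f = min(f, 0.95)
            truth[t] = f
            k, total, lam0 = generate_counts(f, panel, rng)
            samples.append(
                PlasmaSample(
                    patient_id=pid,
                    timepoint_label=label,
                    day=t,
                    variant_molecules=k,
                    total_molecules=total,
                    expected_noise=lam0,
                )
            )

        # imaging after death is not observable
        imaging = [im for im in imaging if im.day <= os_days]

        patients.append(
            SimPatient(
                patient_id=pid,
                response_class=cls,
                panel=panel,
                true_tumor_fraction_series=truth,
                plasma_samples=samples,
                imaging_series=imaging,
                pfs_days=max(pfs_days, 1),
                pfs_event=pfs_event,
                os_days=max(os_days, 1),
                os_event=os_event,
                tumor_purity=purity,
            )
        )
    return patients
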