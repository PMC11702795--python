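"""Unit and property tests for the synthetic cohort generator."""

import dataclasses

import numpy as np
import pytest

from ctdna_mrd import (
    CohortConfig,
    ConfigurationError,
    PanelDesign,
    compute_lod,
    default_schedule,
    generate_counts,
    qc_tumor_purity,
    simulate_cohort,
)
from ctdna_mrd.pipeline import cohort_tables


class TestConfig:
    def test_default_config_valid(self):
        cfg = CohortConfig()
        assert cfg.n_patients == 25
        assert sum(cfg.response_mixture.values()) == pytest.approx(1.0)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(response_mixture={"CR": 0.5, "PR": 0.2, "SD": 0.2, "PD": 0.2})

    def test_empty_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(schedule=[])

    def test_unordered_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(schedule=[("C1D1", 0), ("C2D1", 28), ("C1D8", 7)])

    def test_default_schedule_day_mapping(self):
        sched = dict(default_schedule())
        assert sched["C1D1"] == 0 and sched["C1D8"] == 7
        assert sched["C2D1"] == 28 and sched["C4D1"] == 70 and sched["C7D1"] == 133


class TestPurityGate:
    @pytest.mark.parametrize(
        "purity,eligible", [(0.07, True), (0.069, False), (1.0, True), (0.0, False)]
    )
    def test_threshold_boundary(self, purity, eligible):
        assert qc_tumor_purity(purity) is eligible

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qc_tumor_purity(1.2)


class TestGenerateCounts:
    def test_null_model_mean_equals_noise(self, cohort_panel, rng):
        lam_noise = cohort_panel.mean_total_molecules * cohort_panel.per_site_error_rate
        ks = [generate_counts(0.0, cohort_panel, rng)[0] for _ in range(4000)]
        se = np.sqrt(lam_noise / len(ks))
        assert np.mean(ks) == pytest.approx(lam_noise, abs=3 * se + 0.05)

    def test_mean_linear_in_fraction(self, rng):
        panel = PanelDesign("P1", 1000, 1000.0, 1e-6)  # M ~ 1e6
        draws = [generate_counts(0.4, panel, rng) for _ in range(300)]
        mean_k = np.mean([d[0] for d in draws])
        assert mean_k == pytest.approx(4e5, rel=0.01)

    def test_moments_match_poisson_oracle(self, rng):
        # k | M is Poisson(M*f + M*e); with M itself Poisson(N*d) the
        # marginal mean is N*d*(f+e) and the variance adds N*d*(f+e)^2
        panel = PanelDesign("P1", 100, 50.0, 1e-4)
        f, n = 0.02, 10_000
        rate = f + panel.per_site_error_rate
        ks = np.array([generate_counts(f, panel, rng)[0] for _ in range(n)])
        mean_o = panel.mean_total_molecules * rate
        var_o = mean_o + panel.mean_total_molecules * rate**2
        assert ks.mean() == pytest.approx(mean_o, abs=3 * np.sqrt(var_o / n))
        assert ks.var() == pytest.approx(var_o, rel=0.15)

    def test_invalid_fraction_rejected(self, cohort_panel, rng):
        with pytest.raises(ValueError):
            generate_counts(-0.1, cohort_panel, rng)
        with pytest.raises(ValueError):
            generate_counts(1.0, cohort_panel, rng)


class TestSimulateCohort:
    def test_deterministic_under_fixed_seed(self):
        cfg = CohortConfig(seed=42)
        t1 = cohort_tables(simulate_cohort(cfg))
        t2 = cohort_tables(simulate_cohort(CohortConfig(seed=42)))
        for name in t1:
            assert t1[name].to_csv() == t2[name].to_csv()

    def test_patient_count_and_ids(self, default_cohort):
        assert len(default_cohort) == 25
        assert len({p.patient_id for p in default_cohort}) == 25

    def test_structural_invariants(self, default_cohort):
        schedule_days = {d for _, d in CohortConfig().schedule}
        for p in default_cohort:
            assert p.pfs_days <= p.os_days
            assert all(s.day in schedule_days for s in p.plasma_samples)
            assert all(0.0 <= f < 1.0 for f in p.true_tumor_fraction_series.values())
            assert all(s.variant_molecules <= s.total_molecules for s in p.plasma_samples)
            if p.response_class == "CR":
                assert all(im.recist_category != "PD" for im in p.imaging_series)

    def test_response_frequencies_match_mixture(self):
        # binomial oracle: pooled class frequencies across many draws lie
        # within 3 standard errors of the configured mixture weights
        cfg0 = CohortConfig()
        counts = {c: 0 for c in cfg0.response_mixture}
        n_total = 0
        for seed in range(25):
            cohort = simulate_cohort(
                dataclasses.replace(CohortConfig(seed=seed), n_patients=200)
            )
            for p in cohort:
                counts[p.response_class] += 1
                n_total += 1
        for cls, w in cfg0.response_mixture.items():
            se = np.sqrt(w * (1 - w) / n_total)
            assert counts[cls] / n_total == pytest.approx(w, abs=3 * se)

    def test_baseline_detection_monotone_in_baseline_fraction(self):
        # lowering the baseline-fraction range toward the LOD can only
        # reduce the baseline detection rate
        from ctdna_mrd.pipeline import detect_cohort

        def baseline_rate(lo, hi, seed=3):
            cfg = CohortConfig(
                seed=seed, n_patients=40, baseline_tumor_fraction_range=(lo, hi)
            )
            pats = simulate_cohort(cfg)
            calls = detect_cohort(
                [s for p in pats for s in p.plasma_samples if s.timepoint_label == "C1D1"],
                {p.patient_id: p.panel for p in pats},
            )
            return np.mean([c.detected for c in calls])

        low = baseline_rate(5e-7, 5e-6)   # at/below LOD: partial detection
        high = baseline_rate(2e-4, 0.41)  # default: ~100x LOD
        assert low <= high
        assert high == 1.0

    def test_baseline_positivity_at_default_range(self, default_cohort, cohort_panel):
        # default baseline range starts >=100x LOD: every baseline detected
        lod_fraction = compute_lod(cohort_panel) / 1e6
        assert CohortConfig().baseline_tumor_fraction_range[0] >= 100 * lod_fraction
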