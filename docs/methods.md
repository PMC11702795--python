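# Methods

## Detection model

Each patient's bespoke panel targets *N* somatic variants (506–1,875 in
the emulated cohort). One plasma library yields, pooled across all sites,
*M* informative deduplicated molecules of which *k* support a tumor
variant. Background errors arrive at a per-molecule rate ε, so the
noise-only expectation is λ₀ = *M*·ε. Detection is a one-tailed Poisson
test, *p* = P(K ≥ k) with K ~ Poisson(λ₀); a sample is "detected" at
*p* ≤ α with α = 0.001. The inclusive tail (P(K ≥ k), not P(K > k)) is
the standard conservative convention for discrete upper-tail tests, and
the discreteness makes the realised type-I error fall below α (measured
≈ 8×10⁻⁴ at λ₀ ∈ {1, 3, 10}). λ₀ = 0 is handled as a limit (p = 1 for
k = 0, else 0).

Signal is pooled: molecules are summed across all panel sites into one
count tested against one pooled λ₀. Commercial implementations may weight
sites individually; the pooled statistic is the minimal model consistent
with a single Poisson test per sample, and the per-site structure is not
needed at molecule-count resolution.

**Quantification.** Tumor fraction is estimated by method of moments with
noise subtraction, floored at zero, and expressed in parts per million:
PPM = max(0, k − λ₀)/M × 10⁶. Above the LOD the median estimate is
unbiased (median recovery at a true 100 PPM is within 1%); at or below
the noise level it returns 0 rather than a negative fraction. Reported
PPM for non-detected samples is 0 downstream; the raw estimate is kept
for diagnostics.

**Limit of detection.** k\* is the smallest count significant at α under
the noise model; the LOD is the smallest tumor fraction *f* such that
P(K ≥ k\*) ≥ 0.95 with K ~ Poisson(λ₀ + f·M/10⁶). Because that tail
probability is continuous and strictly increasing in the Poisson mean,
*f* is found by root bracketing (Brent) to 10⁻¹⁰. The 95% power level is
the conventional LOD definition. k\* > λ₀ always holds at α = 0.001 and
is asserted, so a detected sample can never quantify at 0 PPM.

**Depth and error-rate defaults.** Per-site depth (4,000 molecules) and
error rate (ε = 5×10⁻⁷) are not published quantities; they were chosen
once so that a ~1,800-variant panel (M ≈ 7.2×10⁶, λ₀ ≈ 3.6) has an LOD of
2.03 PPM — the emulated cohort's median — with the full panel-size range
mapping to LODs of roughly 1.7–4.8 PPM, consistent with the advertised
1–3 PPM sensitivity scale for near-full panels.

## Longitudinal classification

All rules operate on effective PPM (0 for non-detected samples).

* **Molecular response**: ratio = PPM(C2D1)/PPM(C1D1), using C4D1 when
  C2D1 is absent. mR requires a *greater than* 50% decrease, so a ratio
  of exactly 0.5 is mNR. Undetected evaluation timepoints give ratio 0
  (mR). Missing or undetected baseline → not evaluable.
* **Clearance**: cleared iff ≥1 timepoint with label in C1D8..C7D1
  (compared as (cycle, day) tuples, inclusive) is not detected;
  persistent if all window draws are detected; not evaluable if the
  window is empty.
* **Molecular progression**: scanning in day order with a running nadir
  (baseline included), progression is the earliest *detected* timepoint
  with PPM ≥ 1.2× nadir; from a zero nadir any detected value qualifies
  (ctDNA reappearance after clearance is progression). Requiring the
  progressing timepoint to be detected prevents noise-level "increases"
  among negatives. The running-nadir reading means a transient early
  shedding spike (e.g. the C1D8 bump) can itself constitute progression;
  see Limitations.
* **Lead time**: molecular minus imaging progression day (imaging
  progression = earliest RECIST PD), negative when ctDNA is earlier; the
  reported "advantage" is its negation. Patients are excluded with a
  recorded reason when there is no imaging progression, no plasma at or
  after imaging progression (and none before it progressed molecularly),
  or when the gap between the last draw preceding imaging PD and the PD
  date exceeds 30 days. The gap rule is evaluated on that single
  interval — the written exclusion ("gaps larger than 30 days between
  imaging and ctDNA measurements") is ambiguous, and the progression
  window is where a gap distorts the lead time.
* **Matched pairs**: each post-baseline imaging assessment is paired with
  the nearest draw within ±30 days (ties to the earlier draw), emitting
  (PPM ratio to baseline, sum-of-diameters ratio to baseline). The
  baseline-to-baseline pair is excluded; patients without a positive
  baseline PPM or a positive baseline sum of diameters are excluded.

## Sensitivity censoring

A blunter assay is simulated by flipping every detection at ≤100 PPM
(inclusive) to "not detected" with PPM 0; p-values are retained for
audit via a `censored` flag. The operation is idempotent and can only
remove evidence, giving four monotonicity guarantees that are tested:
censored detections ⊆ original; censored progressors ⊆ original
progressors; censored cleared-set ⊇ original cleared-set; and per-patient
lead-time advantage never grows.

## Outcome statistics

Exact Wilcoxon rank-sum (full enumeration of the null, appropriate at
n ≤ 20 per group) compares early ctDNA ratios between response groups;
Spearman's ρ with tie correction measures ctDNA/imaging concordance over
matched pairs; survival comparisons report Kaplan–Meier curves, the
log-rank test, and a univariable Cox hazard ratio with Wald 95% CI,
Efron tie handling (event times are heavily tied to imaging visit days).
The favorable group (mR, cleared) is the reference, so HR > 1 means the
unfavorable group does worse. With complete separation between small
groups the partial likelihood is unbounded; the fit then retries with a
light ridge penalty (0.1) so the HR stays finite — its direction, which
is what the calibration checks use, is unaffected. Patients with
not-evaluable labels are excluded from the corresponding comparison.

## Synthetic cohort generator

The generator produces cohorts with the structure of the emulated trial:
25 patients; best-overall-response mixture 2 CR / 14 PR / 2 SD / 5 PD
over the 23 response-evaluable patients, normalised to probabilities;
plasma at C1D1 (day 0), C1D8 (day 7), C2D1 (day 28) and then day 1 of
every third cycle (C4D1 = 70, C7D1 = 133, …), using the trial's 7-day
immunotherapy lead-in plus 21-day cycles to map cycle labels to days;
imaging at baseline and every three cycles from C4D1.

Per patient: a response class is drawn from the mixture; relative tumor
burden r(t) follows the class (CR: exponential decay, rate 0.12/day, to
eradication below 2% of baseline; PR: decay to a plateau uniform on
0.08–0.40 with a lognormal relapse day, median 200 d; SD: flat with
relapse median 130 d; PD: growth at 0.008/day). Decay starts after a
10-day response lag, so day-7 levels are not yet suppressed. Baseline
tumor fraction is log-uniform on 2.5×10⁻⁴–0.41 (250–410,000 PPM): at
least ~100× the LOD, because the emulated cohort was 100% ctDNA-positive
at baseline — the 1.5 PPM floor of observed positives is reached by
on-treatment declines, not by baselines.

ctDNA couples to burden through a power law, f(t) = f₀·r(t)^γ with
γ = 3.0 (`ctdna_size_exponent`), multiplicative lognormal shedding
noise (σ = 0.25), and a
transient C1D8 bump whose configured values (1.26 responders / 0.88
non-responders) are the target *observed mean* ratios — the generator
divides out the e^σ² mean inflation of a baseline-normalised lognormal
ratio. The power law, rather than direct proportionality, reflects that
responders' ctDNA falls orders of magnitude (C2D1 ratios near 0.01–0.05)
while RECIST diameter sums shrink only 30–70%: shedding tracks viable
volume-like burden, not diameters, and rank correlations of fold changes
are preserved under any monotone coupling. Two further mechanisms round
out the kinetics: 35% of PR patients are "deep responders" whose ctDNA
decays to true zero (rate 0.10–0.16/day) despite a residual mass on
imaging — these supply the PR clearances observed in such cohorts and
reappear from zero at relapse — and SD/PD patients get a transient
on-chemo shedding dip (depth 0.7, Gaussian in time around day 40) so
their C2D1 ratios sit near, not above, 1.

Molecule counts come from the same forward model the detection stage
assumes: M ~ Poisson(N·depth), k ~ Poisson(M·f + M·ε). Imaging sums of
diameters are baseline·r(t) with 3% lognormal measurement noise,
categorised by RECIST 1.1 (PD at ≥20% over nadir plus 5 mm; PR at ≥30%
below baseline; CR below 5 mm); imaging stops at the first PD. PFS is
the first imaging PD day; OS adds class-specific exponential
post-progression survival (means 280/220/130 d for PR/SD/PD); both are
censored at 550 days of follow-up. Under these defaults, 20 pooled
cohorts give ~79% sample-level positivity, ~16% of positives below
100 PPM, a ~31% clearance rate, median panel LOD 2.04 PPM, and a median
lead-time advantage of 63 days — matching the scale of the emulated
cohort (75%, 20%, 29%, 2.03 PPM, 65 days).

### What the generator does and does not emulate

It reproduces molecule-count statistics, detection/LOD behaviour,
response-stratified kinetics, schedule structure, and outcome coupling.
It does not model clonal evolution, variant-specific dynamics,
site-level error heterogeneity, read-level artifacts, inter-visit
correlated shedding noise, non-target/new-lesion RECIST events, or
informative missingness of draws. Passing tests therefore demonstrate
correctness of the analysis rules and calibration of the statistical
machinery under a faithful count model — not robustness to every
real-data pathology.

## Numerical choices and degenerate inputs

* Poisson tails via the survival function at k−1; LOD root found with
  Brent to 10⁻¹⁰ on the power curve.
* Exact rank-sum p-values (no normal approximation) at cohort sizes.
* Ties in timepoint matching break toward the earlier draw.
* k is capped at M in the forward model (a once-in-astronomy event at
  realistic parameters).
* Zero baseline sum-of-diameters, empty groups, zero events, unordered
  or duplicated days, mixtures not summing to 1, and purity outside
  [0, 1] all raise typed errors rather than propagating nonsense.
* All simulation randomness flows through one `numpy` Generator seeded
  from the config, making cohorts byte-identical across reruns.

## Problem sizes

Test and reproduction runs use 25-patient cohorts aggregated over 20
seeds, 10⁵-draw noise-only calibration per background level, 10³–2×10⁴
replicate draws for recovery/power checks, and 10⁴ random series for
classifier-oracle equivalence — sizes at which every Monte-Carlo band in
the suite is 3 standard errors or wider.

## Limitations

* The running-nadir progression rule, taken literally, lets the C1D8
  shedding spike register as molecular progression in patients whose
  ctDNA later collapses; the median lead-time advantage is robust to
  this (63 vs 65 days) but the mean is inflated. A global-nadir variant
  would behave differently; the running-nadir form is kept because it is
  the stated rule and is what the append-monotonicity property and the
  enumeration oracle verify.
* The pooled Poisson test ignores site-level weighting a commercial
  pipeline may apply.
* Survival generation is calibrated only to cohort-scale medians
  (PFS ≈ 230 d, OS ≈ 490 d), not to individual histories.
* The exact Wilcoxon comparison of C1D8 ratios is reported descriptively
  alongside group means, mirroring how small non-significant early
  differences should be communicated.
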