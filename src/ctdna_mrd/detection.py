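"""Poisson detection model, PPM quantification, and limit of detection.

A plasma sample is called ctDNA-positive when its pooled count of
variant-supporting molecules k is significantly above the expected
background lambda0 under a one-tailed Poisson test (p <= alpha, default
alpha = 0.001). Tumor fraction is quantified in parts per million (PPM):
the noise-subtracted count divided by the pooled informative depth M,
scaled by 1e6. The limit of detection (LOD) is the smallest tumor
fraction detected with the configured power (default 95%) at that alpha.
"""

from __future__ import annotations

from scipy.optimize import brentq
from scipy.stats import poisson

from .types import DetectionCall, PanelDesign, PlasmaSample

__all__ = [
    "poisson_detect",
    "estimate_ppm",
    "ppm_to_fraction",
    "fraction_to_ppm",
    "detection_threshold",
    "compute_lod",
    "call_sample",
]


def poisson_detect(
    k: int, lam0: float, alpha: float = 0.001
) -> tuple[float, bool]:
    """One-tailed Poisson test of k observed molecules against noise lam0.

    Returns ``(p_value, detected)`` where ``p_value = P(K >= k)`` for
    K ~ Poisson(lam0) (upper tail, inclusive) and ``detected`` is
    ``p_value <= alpha``. The inclusive tail makes the test conservative.
    ``lam0 = 0`` is handled as a limit: p = 1 for k = 0, else p = 0.
    """
    if not float(k).is_integer() or k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    if lam0 < 0:
        raise ValueError("expected noise must be >= 0")
    k = int(k)
    if lam0 == 0:
        p = 1.0 if k == 0 else 0.0
    else:
        # sf(k-1) = P(K > k-1) = P(K >= k)
        p = float(poisson.sf(k - 1, lam0))
    return p, p <= alpha


def estimate_ppm(k: int, lam0: float, total_molecules: int) -> float:
    """Tumor fraction in PPM: max(0, k - lam0) / M x 1e6.

    Method-of-moments estimator with background subtraction, floored at
    zero so noise-only samples quantify as 0 rather than negative.
    """
    if total_molecules < 1:
        raise ValueError("total molecule count must be >= 1")
    if k > total_molecules:
        raise ValueError("k cannot exceed total molecules")
    return max(0.0, k - lam0) / total_molecules * 1e6


def ppm_to_fraction(ppm: float) -> float:
    """Convert parts per million to a unitless tumor fraction."""
    return ppm / 1e6


def fraction_to_ppm(fraction: float) -> float:
    """Convert a unitless tumor fraction to parts per million."""
    return fraction * 1e6


def detection_threshold(lam0: float, alpha: float = 0.001) -> int:
    """Smallest integer count k* whose upper-tail p-value is <= alpha.

    Any observed count >= k* is called detected. ``poisson.isf`` gives the
    largest k with P(K > k) > alpha, so k* + 1... we search explicitly from
    that anchor to stay correct at discrete boundaries.
    """
    if lam0 <= 0:
        return 1  # any signal molecule beats a zero-noise background
    k = int(poisson.isf(alpha, lam0))
    while float(poisson.sf(k - 1, lam0)) <= alpha:
        k -= 1
    while float(poisson.sf(k - 1, lam0)) > alpha:
        k += 1
    return k


def compute_lod(
    panel: PanelDesign,
    total_molecules: int | None = None,
    alpha: float = 0.001,
    power: float = 0.95,
) -> float:
    """Per-sample limit of detection in PPM.

    The LOD is the smallest tumor fraction f such that a sample with mean
    signal lam0 + f*M/1e6 reaches the detection threshold k* with the
    requested power, where k* is the smallest count significant at alpha
    under the noise-only model. P(K >= k*) is continuous and strictly
    increasing in the Poisson mean, so f is found by root bracketing.
    """
    if total_molecules is None:
        total_molecules = round(panel.mean_total_molecules)
    if total_molecules < 1:
        raise ValueError("total molecule count must be >= 1")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    lam0 = total_molecules * panel.per_site_error_rate
    kstar = detection_threshold(lam0, alpha)
    # assay coherence: the threshold count must exceed the noise mean,
    # otherwise a "detected" sample could quantify at 0 PPM
    assert kstar > lam0

    def tail_power(lam: float) -> float:
        return float(poisson.sf(kstar - 1, lam)) - power

    lo, hi = lam0, max(lam0 + 1.0, 2.0 * kstar)
    while tail_power(hi) < 0:
        hi *= 2.0
    lam_req = brentq(tail_power, lo, hi, xtol=1e-10)
    return (lam_req - lam0) / total_molecules * 1e6


def call_sample(
    sample: PlasmaSample,
    panel: PanelDesign,
    alpha: float = 0.001,
    power: float = 0.95,
) -> DetectionCall:
    """Assemble the detection call for one plasma sample.

    The reported ``ppm`` is 0 for non-detected samples (the raw
    noise-subtracted estimate is retained in ``ppm_raw``).
    """
    if sample.patient_id != panel.patient_id:
        raise ValueError(
            f"sample patient {sample.patient_id!r} does not match "
            f"panel patient {panel.patient_id!r}"
        )
    p, detected = poisson_detect(sample.variant_molecules, sample.expected_noise, alpha)
    ppm_raw = estimate_ppm(
        sample.variant_molecules, sample.expected_noise, sample.total_molecules
    )
    lod = compute_lod(panel, sample.total_molecules, alpha=alpha, power=power)
    return DetectionCall(
        patient_id=sample.patient_id,
        timepoint_label=sample.timepoint_label,
        day=sample.day,
        p_value=p,
        detected=detected,
        ppm=ppm_raw if detected else 0.0,
        lod_ppm=lod,
        alpha=alpha,
        ppm_raw=ppm_raw,
    )
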