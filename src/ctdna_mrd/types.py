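"""Domain types shared across the pipeline.

The objects here mirror the entities of a tumor-informed liquid-biopsy MRD
study: a patient-specific assay panel, one plasma draw's deduplicated
molecule counts, the detection call derived from it, a RECIST imaging
assessment, and the per-patient longitudinal molecular labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional


class ConfigurationError(ValueError):
    """Invalid configuration or domain-object construction."""


_CXDY = re.compile(r"^C(\d+)D(\d+)$")


def parse_timepoint(label: str) -> tuple[int, int]:
    """Parse a ``CxDy`` treatment-schedule label into ``(cycle, day)``.

    C1D1 is the baseline draw; C1D8 is one week after the pembrolizumab
    lead-in; C2D1 and later fall on day 1 of each 21-day cycle.
    """
    m = _CXDY.match(label)
    if m is None:
        raise ValueError(f"not a CxDy timepoint label: {label!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass(frozen=True)
class PanelDesign:
    """A patient's bespoke MRD assay.

    Parameters
    ----------
    patient_id
        Patient identifier shared with the plasma samples.
    n_variants
        Number of somatic variants targeted by the hybrid-capture panel
        (506-1,875 in the emulated cohort).
    mean_molecules_per_site
        Expected number of deduplicated cfDNA molecules observed per
        panel site in one plasma library.
    per_site_error_rate
        Probability that a background (non-tumor) molecule reads as
        variant-supporting at a panel site.
    """

    patient_id: str
    n_variants: int
    mean_molecules_per_site: float
    per_site_error_rate: float

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("panel must target at least one variant")
        if self.mean_molecules_per_site < 1:
            raise ConfigurationError("mean molecules per site must be >= 1")
        if not 0.0 < self.per_site_error_rate < 1.0:
            raise ConfigurationError("per-site error rate must be in (0, 1)")

    @property
    def mean_total_molecules(self) -> float:
        """Expected informative molecules pooled across all panel sites."""
        return self.n_variants * self.mean_molecules_per_site


@dataclass(frozen=True)
class PlasmaSample:
    """Deduplicated molecule counts for one blood draw.

    ``variant_molecules`` (k) is the pooled count of tumor-variant-supporting
    molecules across all panel sites; ``total_molecules`` (M) is the pooled
    informative depth; ``expected_noise`` is the background expectation
    lambda0 = M x per-site error rate.
    """

    patient_id: str
    timepoint_label: str
    day: int
    variant_molecules: int
    total_molecules: int
    expected_noise: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ConfigurationError("sample day must be >= 0")
        if self.variant_molecules < 0:
            raise ConfigurationError("variant molecule count must be >= 0")
        if self.variant_molecules > self.total_molecules:
            raise ConfigurationError("variant molecules cannot exceed total molecules")
        if self.expected_noise < 0:
            raise ConfigurationError("expected noise must be >= 0")


@dataclass(frozen=True)
class DetectionCall:
    """Detection status and quantification for one plasma sample.

    ``ppm`` is the noise-subtracted tumor-fraction estimate in parts per
    million; it is reported as 0 for non-detected samples (the raw estimate
    is kept in ``ppm_raw`` for diagnostics). ``lod_ppm`` is the per-sample
    limit of detection at the configured power.
    """

    patient_id: str
    timepoint_label: str
    day: int
    p_value: float
    detected: bool
    ppm: float
    lod_ppm: float
    alpha: float = 0.001
    ppm_raw: float = 0.0
    censored: bool = False  # detection suppressed by a sensitivity-degradation analysis

    def __post_init__(self) -> None:
        if self.censored:
            if self.detected:
                raise ConfigurationError("a censored call cannot be detected")
        elif self.detected != (self.p_value <= self.alpha):
            raise ConfigurationError("detected flag inconsistent with p-value and alpha")
        if self.ppm < 0 or self.lod_ppm <= 0:
            raise ConfigurationError("ppm must be >= 0 and lod_ppm > 0")


@dataclass(frozen=True)
class ImagingAssessment:
    """One RECIST 1.1 evaluation.

    ``sum_of_diameters`` is the sum of longest diameters of target lesions
    in millimetres. A day-0 row carries the baseline measurement (category
    ``SD`` by convention; it can never constitute progression).
    """

    patient_id: str
    day: int
    sum_of_diameters: float
    recist_category: str

    def __post_init__(self) -> None:
        if self.day < 0 or self.sum_of_diameters < 0:
            raise ConfigurationError("imaging day and sum of diameters must be >= 0")
        if self.recist_category not in {"CR", "PR", "SD", "PD"}:
            raise ConfigurationError(
                f"recist_category must be CR/PR/SD/PD, got {self.recist_category!r}"
            )


@dataclass(frozen=True)
class MolecularClassification:
    """Per-patient longitudinal molecular labels.

    ``molecular_response`` is mR for a >50% ctDNA decrease from baseline at
    C2D1 (or C4D1 when C2D1 is missing), mNR otherwise. ``clearance`` is
    cleared when at least one timepoint in the C1D8..C7D1 window is not
    detected. ``lead_time_days`` = molecular - imaging progression day
    (negative means ctDNA called progression earlier).
    """

    patient_id: str
    molecular_response: str  # mR | mNR | not-evaluable
    response_ratio: Optional[float]
    clearance: str  # cleared | persistent | not-evaluable
    molecular_progression_day: Optional[int]
    imaging_progression_day: Optional[int]
    lead_time_days: Optional[int]
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lead_time_days is not None:
            if self.molecular_progression_day is None or self.imaging_progression_day is None:
                raise ConfigurationError("lead time requires both progression days")
            if self.lead_time_days != (
                self.molecular_progression_day - self.imaging_progression_day
            ):
                raise ConfigurationError("lead time must equal molecular - imaging day")
        if self.response_ratio is not None and self.response_ratio < 0:
            raise ConfigurationError("response ratio must be >= 0")


@dataclass
class SimPatient:
    """A fully simulated patient: ground truth plus observable data."""

    patient_id: str
    response_class: str  # best overall response: CR | PR | SD | PD
    panel: PanelDesign
    true_tumor_fraction_series: dict[int, float] = field(default_factory=dict)
    plasma_samples: list[PlasmaSample] = field(default_factory=list)
    imaging_series: list[ImagingAssessment] = field(default_factory=list)
    pfs_days: int = 0
    pfs_event: bool = False
    os_days: int = 0
    os_event: bool = False
    tumor_purity: float = 0.0
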