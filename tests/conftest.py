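import numpy as np
import pytest

from ctdna_mrd import CohortConfig, DetectionCall, PanelDesign, simulate_cohort


@pytest.fixture(scope="session")
def cohort_panel() -> PanelDesign:
    """A cohort-typical bespoke panel (~1,800 variants, default depth/error)."""
    cfg = CohortConfig()
    return PanelDesign(
        patient_id="P1",
        n_variants=1800,
        mean_molecules_per_site=cfg.mean_molecules_per_site,
        per_site_error_rate=cfg.per_site_error_rate,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default 25-patient synthetic cohort, fixed seed."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_call(
    patient_id: str,
    label: str,
    day: int,
    ppm: float,
    detected: bool | None = None,
    lod: float = 2.0,
) -> DetectionCall:
    """Hand-built detection call for classifier tests.

    ``detected`` defaults to ``ppm > 0``; p-values are synthetic but
    consistent with the detected flag at alpha = 0.001.
    """
    if detected is None:
        detected = ppm > 0
    return DetectionCall(
        patient_id=patient_id,
        timepoint_label=label,
        day=day,
        p_value=1e-6 if detected else 1.0,
        detected=detected,
        ppm=ppm if detected else 0.0,
        lod_ppm=lod,
        ppm_raw=ppm,
    )


@pytest.fixture
def call_factory():
    return make_call
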