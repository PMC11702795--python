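"""End-to-end orchestration: simulate -> detect -> classify -> censor -> stats.

Each stage is also runnable standalone from files (see the CLI); the
pipeline is their composition and emits a reproducibility manifest with
the seed, parameter values, and per-table row counts and hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .censor import censor_calls, compare_sensitivity
from .classify import classify_patient, match_timepoints
from .detection import call_sample
from .io import (
    calls_to_frame,
    classifications_to_frame,
    frame_to_calls,
    frame_to_imaging,
    frame_to_samples,
    imaging_to_frame,
    samples_to_frame,
    write_table,
)
from .simulate import CohortConfig, simulate_cohort
from .stats import SurvivalRecord, compare_ratio_groups, correlate_dynamics, survival_by_group
from .types import DetectionCall, ImagingAssessment, MolecularClassification, PanelDesign, PlasmaSample, SimPatient

__all__ = ["RunConfig", "run_pipeline", "detect_cohort", "classify_cohort", "cohort_tables"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "ctdna_mrd_run"
    seed: int = 0
    alpha: float = 0.001
    power: float = 0.95
    censor_threshold_ppm: float = 100.0
    match_window_days: int = 30
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.power <= 0 or self.censor_threshold_ppm <= 0:
            raise ValueError("alpha, power and censor threshold must be positive")
        if self.match_window_days <= 0:
            raise ValueError("match window must be positive")


def cohort_tables(patients: Sequence[SimPatient]) -> dict[str, pd.DataFrame]:
    """Flatten a simulated cohort into the three cohort tables."""
    samples = samples_to_frame([s for p in patients for s in p.plasma_samples])
    imaging = imaging_to_frame([im for p in patients for im in p.imaging_series])
    rows = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "bor": [p.response_class for p in patients],
            "pfs_days": [p.pfs_days for p in patients],
            "pfs_event": [int(p.pfs_event) for p in patients],
            "os_days": [p.os_days for p in patients],
            "os_event": [int(p.os_event) for p in patients],
            "panel_n_variants": [p.panel.n_variants for p in patients],
            "tumor_purity": [p.tumor_purity for p in patients],
        }
    )
    return {"samples": samples, "imaging": imaging, "patients": rows}


def detect_cohort(
    samples: Sequence[PlasmaSample],
    panels: dict[str, PanelDesign],
    alpha: float = 0.001,
    power: float = 0.95,
) -> list[DetectionCall]:
    """Run the Poisson detection model over every sample."""
    calls = []
    for s in samples:
        if s.patient_id not in panels:
            raise KeyError(f"no panel for patient {s.patient_id!r}")
        calls.append(call_sample(s, panels[s.patient_id], alpha=alpha, power=power))
    return calls


def classify_cohort(
    calls: Sequence[DetectionCall],
    imaging: Sequence[ImagingAssessment],
    match_window_days: int = 30,
) -> tuple[list[MolecularClassification], pd.DataFrame]:
    """Classify every patient and collect matched ctDNA/imaging pairs."""
    calls_by_pid: dict[str, list[DetectionCall]] = {}
    for c in calls:
        calls_by_pid.setdefault(c.patient_id, []).append(c)
    imaging_by_pid: dict[str, list[ImagingAssessment]] = {}
    for im in imaging:
        imaging_by_pid.setdefault(im.patient_id, []).append(im)

    classifications = []
    pair_rows = []
    for pid in sorted(calls_by_pid):
        pcalls = sorted(calls_by_pid[pid], key=lambda c: c.day)
        pimaging = sorted(imaging_by_pid.get(pid, []), key=lambda im: im.day)
        classifications.append(classify_patient(pcalls, pimaging, match_window_days))
        try:
            pairs = match_timepoints(pcalls, pimaging, window=match_window_days)
        except ValueError:
            continue  # patient lacks a positive baseline pair; excluded
        for day, ppm_ratio, size_ratio in pairs:
            pair_rows.append(
                {"patient_id": pid, "day": day, "ppm_ratio": ppm_ratio, "size_ratio": size_ratio}
            )
    pairs_df = pd.DataFrame(pair_rows, columns=["patient_id", "day", "ppm_ratio", "size_ratio"])
    return classifications, pairs_df


def _survival_records(
    classifications: Sequence[MolecularClassification],
    patients: pd.DataFrame,
    endpoint: str,
    grouping: str,
) -> list[SurvivalRecord]:
    """Survival records for one endpoint (pfs|os) and grouping (mr|clearance)."""
    times = patients.set_index("patient_id")
    records = []
    for c in classifications:
        if grouping == "mr":
            group = c.molecular_response
            if group not in ("mR", "mNR"):
                continue
        else:
            group = c.clearance
            if group not in ("cleared", "persistent"):
                continue
        row = times.loc[c.patient_id]
        records.append(
            SurvivalRecord(
                patient_id=c.patient_id,
                time=float(row[f"{endpoint}_days"]),
                event=bool(row[f"{endpoint}_event"]),
                group=group,
            )
        )
    return records


def _outcome_stats(
    classifications: Sequence[MolecularClassification],
    pairs: pd.DataFrame,
    patients: pd.DataFrame,
) -> dict:
    """The standard endpoint statistics block for one classification set."""
    out: dict = {}
    ratios = {
        c.patient_id: c.response_ratio
        for c in classifications
        if c.response_ratio is not None
    }
    bor = patients.set_index("patient_id")["bor"]
    resp = [r for pid, r in ratios.items() if bor.get(pid) in ("CR", "PR")]
    nonresp = [r for pid, r in ratios.items() if bor.get(pid) in ("SD", "PD")]
    if resp and nonresp:
        stat, p = compare_ratio_groups(resp, nonresp)
        out["c2d1_ratio_wilcoxon"] = {
            "statistic": stat,
            "p_value": p,
            "median_ratio_cr_pr": float(np.median(resp)),
            "median_ratio_sd_pd": float(np.median(nonresp)),
        }
    if len(pairs) >= 3:
        rho, p = correlate_dynamics(list(zip(pairs["ppm_ratio"], pairs["size_ratio"])))
        out["ctdna_imaging_correlation"] = {"rho": rho, "p_value": p, "n_pairs": int(len(pairs))}
    reference = {"mr": "mR", "clearance": "cleared"}
    for grouping in ("mr", "clearance"):
        for endpoint in ("pfs", "os"):
            records = _survival_records(classifications, patients, endpoint, grouping)
            key = f"{grouping}_{endpoint}"
            try:
                res = survival_by_group(records, reference=reference[grouping])
                out[key] = res.to_dict()
            except ValueError as exc:
                out[key] = {"error": str(exc)}
    leads = [
        c.lead_time_days for c in classifications if c.lead_time_days is not None
    ]
    out["lead_time"] = {
        "n": len(leads),
        "median_days": float(np.median(leads)) if leads else None,
        "mean_days": float(np.mean(leads)) if leads else None,
    }
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write every table, and return the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    patients = simulate_cohort(cohort_cfg)
    tables = cohort_tables(patients)
    panels = {p.patient_id: p.panel for p in patients}

    all_samples = [s for p in patients for s in p.plasma_samples]
    calls = detect_cohort(all_samples, panels, alpha=config.alpha, power=config.power)
    imaging = [im for p in patients for im in p.imaging_series]

    classifications, pairs = classify_cohort(calls, imaging, config.match_window_days)
    censored = censor_calls(calls, config.censor_threshold_ppm)
    cens_classifications, cens_pairs = classify_cohort(
        censored, imaging, config.match_window_days
    )
    impact = compare_sensitivity(classifications, cens_classifications)

    stats = {
        "original": _outcome_stats(classifications, pairs, tables["patients"]),
        "censored": _outcome_stats(cens_classifications, cens_pairs, tables["patients"]),
        "censoring_impact": impact.attrs["summary"],
    }

    written: dict[str, Path] = {}
    for name, schema, df in [
        ("samples.tsv", "samples", tables["samples"]),
        ("imaging.tsv", "imaging", tables["imaging"]),
        ("patients.tsv", "patients", tables["patients"]),
        ("calls.tsv", "calls", calls_to_frame(calls)),
        ("calls_censored.tsv", "calls", calls_to_frame(censored)),
        ("classifications.tsv", "classifications", classifications_to_frame(classifications)),
        ("classifications_censored.tsv", "classifications", classifications_to_frame(cens_classifications)),
        ("matched_pairs.tsv", "matched_pairs", pairs),
    ]:
        path = out_dir / name
        write_table(df, path, schema)
        written[name] = path
    impact_path = out_dir / "impact.tsv"
    impact.to_csv(impact_path, sep="\t", index=False)
    written["impact.tsv"] = impact_path
    stats_path = out_dir / "stats.json"
    stats_path.write_text(json.dumps(stats, indent=2, default=str))
    written["stats.json"] = stats_path

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "power": config.power,
        "censor_threshold_ppm": config.censor_threshold_ppm,
        "match_window_days": config.match_window_days,
        "cohort_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort_cfg).items()
            if not isinstance(v, dict)
        },
        "tables": {
            name: {
                "rows": (
                    sum(1 for _ in open(path, encoding="utf-8")) - 1
                    if path.suffix == ".tsv"
                    else None
                ),
                "sha256": _sha256(path),
            }
            for name, path in written.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
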