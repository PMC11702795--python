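"""Tabular IO: fixed-schema TSV tables and optional VCF panel input.

All pipeline tables are UTF-8 TSV with a header row. Schemas:

* ``samples.tsv``  — patient_id, timepoint_label, day, variant_molecules,
  total_molecules, expected_noise
* ``imaging.tsv``  — patient_id, day, sum_of_diameters_mm, recist_category
* ``patients.tsv`` — patient_id, bor, pfs_days, pfs_event, os_days,
  os_event, panel_n_variants, tumor_purity
* ``calls.tsv``    — patient_id, timepoint_label, day, p_value, detected,
  ppm, lod_ppm
* ``classifications.tsv`` — one row per patient with every
  MolecularClassification field
* ``matched_pairs.tsv``   — patient_id, day, ppm_ratio, size_ratio

Validation errors name the file, column, and offending line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .types import (
    DetectionCall,
    ImagingAssessment,
    MolecularClassification,
    PlasmaSample,
)

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "samples_to_frame",
    "frame_to_samples",
    "imaging_to_frame",
    "frame_to_imaging",
    "calls_to_frame",
    "frame_to_calls",
    "classifications_to_frame",
    "panel_size_from_vcf",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: column name -> pandas dtype target ("Int64" = nullable integer)
SCHEMAS: dict[str, dict[str, str]] = {
    "samples": {
        "patient_id": "str",
        "timepoint_label": "str",
        "day": "int64",
        "variant_molecules": "int64",
        "total_molecules": "int64",
        "expected_noise": "float64",
    },
    "imaging": {
        "patient_id": "str",
        "day": "int64",
        "sum_of_diameters_mm": "float64",
        "recist_category": "str",
    },
    "patients": {
        "patient_id": "str",
        "bor": "str",
        "pfs_days": "int64",
        "pfs_event": "int64",
        "os_days": "int64",
        "os_event": "int64",
        "panel_n_variants": "int64",
        "tumor_purity": "float64",
    },
    "calls": {
        "patient_id": "str",
        "timepoint_label": "str",
        "day": "int64",
        "p_value": "float64",
        "detected": "int64",
        "ppm": "float64",
        "lod_ppm": "float64",
    },
    "classifications": {
        "patient_id": "str",
        "molecular_response": "str",
        "response_ratio": "float64?",
        "clearance": "str",
        "molecular_progression_day": "Int64",
        "imaging_progression_day": "Int64",
        "lead_time_days": "Int64",
        "exclusion_reason": "str?",
    },
    "matched_pairs": {
        "patient_id": "str",
        "day": "int64",
        "ppm_ratio": "float64",
        "size_ratio": "float64",
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one pipeline TSV against its schema."""
    path = Path(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in spec if not c.endswith("?") and c not in df.columns]
    # optional columns are marked with a trailing "?" on the dtype
    required = [c for c, t in spec.items() if not t.endswith("?")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    out = pd.DataFrame(index=df.index)
    for col, dtype in spec.items():
        optional = dtype.endswith("?")
        dtype = dtype.rstrip("?")
        if col not in df.columns:
            out[col] = pd.Series([pd.NA] * len(df), dtype="object")
            continue
        raw = df[col]
        if dtype == "str":
            out[col] = raw.replace("", pd.NA) if optional else raw
            continue
        cleaned = raw.replace("", pd.NA) if (optional or dtype == "Int64") else raw
        try:
            numeric = pd.to_numeric(cleaned, errors="raise")
            if dtype in ("int64", "Int64"):
                # reject fractional values masquerading as integers
                bad = (pd.Series(numeric, dtype="float64") % 1).fillna(0) != 0
                if bad.any():
                    line = int(bad.idxmax()) + 2
                    raise SchemaError(
                        f"{path.name}: column {col!r} line {line}: not an integer"
                    )
            out[col] = pd.Series(numeric).astype(dtype)
        except SchemaError:
            raise
        except (ValueError, TypeError):
            bad_line = None
            for i, v in cleaned.items():
                if pd.isna(v):
                    continue
                try:
                    float(v)
                except (ValueError, TypeError):
                    bad_line = int(i) + 2  # +1 header, +1 one-based
                    break
            raise SchemaError(
                f"{path.name}: column {col!r}"
                + (f" line {bad_line}" if bad_line else "")
                + f": cannot parse as {dtype}"
            ) from None
    return out


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a pipeline table as TSV in schema column order."""
    spec = SCHEMAS[schema]
    cols = [c for c in spec]
    missing = [c for c, t in spec.items() if not t.endswith("?") and c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema}: missing column(s) {', '.join(missing)}")
    out = df.reindex(columns=cols)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# record <-> DataFrame converters


def samples_to_frame(samples: Sequence[PlasmaSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "timepoint_label": [s.timepoint_label for s in samples],
            "day": [s.day for s in samples],
            "variant_molecules": [s.variant_molecules for s in samples],
            "total_molecules": [s.total_molecules for s in samples],
            "expected_noise": [s.expected_noise for s in samples],
        }
    )


def frame_to_samples(df: pd.DataFrame) -> list[PlasmaSample]:
    return [
        PlasmaSample(
            patient_id=r.patient_id,
            timepoint_label=r.timepoint_label,
            day=int(r.day),
            variant_molecules=int(r.variant_molecules),
            total_molecules=int(r.total_molecules),
            expected_noise=float(r.expected_noise),
        )
        for r in df.itertuples(index=False)
    ]


def imaging_to_frame(series: Sequence[ImagingAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [im.patient_id for im in series],
            "day": [im.day for im in series],
            "sum_of_diameters_mm": [im.sum_of_diameters for im in series],
            "recist_category": [im.recist_category for im in series],
        }
    )


def frame_to_imaging(df: pd.DataFrame) -> list[ImagingAssessment]:
    return [
        ImagingAssessment(
            patient_id=r.patient_id,
            day=int(r.day),
            sum_of_diameters=float(r.sum_of_diameters_mm),
            recist_category=r.recist_category,
        )
        for r in df.itertuples(index=False)
    ]


def calls_to_frame(calls: Sequence[DetectionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in calls],
            "timepoint_label": [c.timepoint_label for c in calls],
            "day": [c.day for c in calls],
            "p_value": [c.p_value for c in calls],
            "detected": [int(c.detected) for c in calls],
            "ppm": [c.ppm for c in calls],
            "lod_ppm": [c.lod_ppm for c in calls],
        }
    )


def frame_to_calls(df: pd.DataFrame, alpha: float = 0.001) -> list[DetectionCall]:
    calls = []
    for r in df.itertuples(index=False):
        detected = bool(r.detected)
        p = float(r.p_value)
        # a significant p-value with detected=0 marks a sensitivity-censored call
        censored = (not detected) and p <= alpha
        calls.append(
            DetectionCall(
                patient_id=r.patient_id,
                timepoint_label=r.timepoint_label,
                day=int(r.day),
                p_value=p,
                detected=detected,
                ppm=float(r.ppm),
                lod_ppm=float(r.lod_ppm),
                alpha=alpha,
                ppm_raw=float(r.ppm),
                censored=censored,
            )
        )
    return calls


def classifications_to_frame(
    classifications: Sequence[MolecularClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in classifications],
            "molecular_response": [c.molecular_response for c in classifications],
            "response_ratio": [c.response_ratio for c in classifications],
            "clearance": [c.clearance for c in classifications],
            "molecular_progression_day": pd.array(
                [c.molecular_progression_day for c in classifications], dtype="Int64"
            ),
            "imaging_progression_day": pd.array(
                [c.imaging_progression_day for c in classifications], dtype="Int64"
            ),
            "lead_time_days": pd.array(
                [c.lead_time_days for c in classifications], dtype="Int64"
            ),
            "exclusion_reason": [c.exclusion_reason for c in classifications],
        }
    )


def panel_size_from_vcf(path: str | Path) -> int:
    """Number of panel variants = record count of a VCF 4.x file."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        return sum(1 for _ in vf)
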