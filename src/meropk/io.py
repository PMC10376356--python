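"""CSV/JSON readers and writers for cohort tables and reports.

Dialect: comma-separated, UTF-8, header row required, '.' decimal
separator.  Validation errors carry 1-based data line numbers so clinical
exports can be fixed in place.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import PatientProfile
from .exposure import BandTally, ExposureBand
from .tdm import ConcentrationRecord

__all__ = [
    "CsvValidationError",
    "read_patients_csv",
    "write_patients_csv",
    "read_concentrations_csv",
    "write_concentrations_csv",
    "write_tally_csv",
    "write_stats_json",
]

PATIENT_COLUMNS = {
    "patient_id": str,
    "age": float,
    "sex": str,
    "weight_kg": float,
    "height_cm": float,
    "serum_creatinine_mg_dl": float,
    "on_crrt": bool,
}
OPTIONAL_PATIENT_COLUMNS = {"crrt_effluent_L_h": float, "sofa": float, "saps": float, "died_in_hospital": bool}

CONCENTRATION_COLUMNS = {
    "patient_id": str,
    "time_h": float,
    "daily_dose_mg": float,
    "conc_mg_L": float,
}


class CsvValidationError(ValueError):
    """A malformed input table; message names the offending data line."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvValidationError(f"{path}: missing required columns {missing}")


def read_patients_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient cohort table."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise CsvValidationError(f"{path}: empty data section")
    _require_columns(df, PATIENT_COLUMNS, path)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.age < 18:
            raise CsvValidationError(f"{path} line {i}: age must be >= 18, got {row.age}")
        if row.sex not in ("male", "female"):
            raise CsvValidationError(f"{path} line {i}: sex must be male/female, got {row.sex!r}")
        if row.weight_kg <= 0 or row.height_cm <= 0:
            raise CsvValidationError(f"{path} line {i}: non-positive weight/height")
        if row.serum_creatinine_mg_dl <= 0:
            raise CsvValidationError(f"{path} line {i}: serum creatinine must be positive")
    df["on_crrt"] = df["on_crrt"].astype(bool)
    return df


def write_patients_csv(patients: list[PatientProfile], path: str | Path) -> None:
    """Write a cohort CSV.  Latent fields (true clearance) are never written."""
    rows = [
        dict(
            patient_id=p.patient_id,
            age=round(p.age, 1),
            sex=p.sex,
            weight_kg=round(p.weight, 1),
            height_cm=round(p.height, 1),
            serum_creatinine_mg_dl=round(p.serum_creatinine, 3),
            on_crrt=p.on_crrt,
            crrt_effluent_L_h=(p.crrt.effluent_flow if p.on_crrt else ""),
            sofa=p.sofa,
            saps=p.saps,
            died_in_hospital=p.died_in_hospital,
        )
        for p in patients
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_concentrations_csv(path: str | Path) -> list[ConcentrationRecord]:
    """Read a concentration-measurement table into records (phase is derived)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise CsvValidationError(f"{path}: empty data section")
    _require_columns(df, CONCENTRATION_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.conc_mg_L <= 0:
            raise CsvValidationError(f"{path} line {i}: concentration must be positive, got {row.conc_mg_L}")
        if row.daily_dose_mg <= 0:
            raise CsvValidationError(f"{path} line {i}: daily dose must be positive")
        if row.time_h < 0:
            raise CsvValidationError(f"{path} line {i}: time must be non-negative")
        records.append(
            ConcentrationRecord(
                patient_id=str(row.patient_id),
                time_h=float(row.time_h),
                daily_dose_mg=float(row.daily_dose_mg),
                value=float(row.conc_mg_L),
            )
        )
    return records


def write_concentrations_csv(records: Iterable[ConcentrationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(patient_id=r.patient_id, time_h=round(r.time_h, 2),
                 daily_dose_mg=r.daily_dose_mg, conc_mg_L=round(r.value, 3))
            for r in records
        ]
    ).to_csv(path, index=False)


def write_tally_csv(tallies: dict[str, BandTally], path: str | Path) -> None:
    """Write band tallies as rows of (group, band, count, percent)."""
    rows = []
    for group, tally in tallies.items():
        for band in ExposureBand:
            rows.append(
                dict(group=group, band=band.label, count=tally.counts[band], percent=tally.percent(band))
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_stats_json(results: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(results, indent=2) + "\n")
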