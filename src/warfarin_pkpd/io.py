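"""Delimited-text table I/O for visit records and demographics.

Canonical on-disk formats (TSV by default, CSV accepted by extension):

* visit table — columns ``patient_id, t_days, inr, dose_mg, tau_h``;
  ``tau_h`` may be omitted (default 24, logged once). ``t_days`` may
  instead be an ISO-8601 ``date`` column, converted to days from each
  patient's first visit at ingestion.
* demographics table — columns ``patient_id, age_years, sex (M/F),
  body_weight_kg, interacting_drug (0/1)``; one row per patient, and
  ids must cover every id in the visit table.

Schema violations raise :class:`~warfarin_pkpd.errors.SchemaError` with
file and line context. Numbers are written with a fixed decimal format
so a written table round-trips byte-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .metrics import Patient, VisitRecord

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "patients_to_frames", "frames_to_patients"]

VISIT_COLUMNS = ["patient_id", "t_days", "inr", "dose_mg", "tau_h"]
DEMO_COLUMNS = ["patient_id", "age_years", "sex", "body_weight_kg", "interacting_drug"]

_FLOAT_FORMAT = "%.6f"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    return pd.read_csv(path, sep=_sep_for(path), dtype={"patient_id": str})


def _require_numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise SchemaError(
            f"{path}, line {line}, column {col!r}: "
            f"non-numeric value {df[col][bad.idxmax()]!r}"
        )
    if values.isna().any():
        line = int(values.isna().idxmax()) + 2
        raise SchemaError(f"{path}, line {line}, column {col!r}: missing value")
    return values.to_numpy(dtype=float)


def read_cohort(visits_path: str | Path, demographics_path: str | Path) -> list[Patient]:
    """Load and join the visit and demographics tables into Patients.

    Visits are sorted per patient by ``t_days`` on load. Raises
    :class:`SchemaError` with file/line context for malformed cells,
    missing columns, duplicate demographic rows, or visit ids missing
    from the demographics table.
    """
    visits_path, demographics_path = Path(visits_path), Path(demographics_path)
    vdf = _read_table(visits_path)
    ddf = _read_table(demographics_path)

    missing = {"patient_id", "inr", "dose_mg"} - set(vdf.columns)
    if missing:
        raise SchemaError(f"{visits_path}: missing columns {sorted(missing)}")
    if "t_days" not in vdf.columns:
        if "date" in vdf.columns:
            dates = pd.to_datetime(vdf["date"], format="ISO8601", errors="coerce")
            if dates.isna().any():
                line = int(dates.isna().idxmax()) + 2
                raise SchemaError(f"{visits_path}, line {line}: unparseable ISO date")
            first = dates.groupby(vdf["patient_id"]).transform("min")
            vdf["t_days"] = (dates - first).dt.total_seconds() / 86400.0
        else:
            raise SchemaError(f"{visits_path}: need a 't_days' or 'date' column")
    if "tau_h" not in vdf.columns:
        logger.info("%s: no tau_h column; defaulting to 24 h (once daily)", visits_path)
        vdf["tau_h"] = 24.0

    t = _require_numeric(vdf, "t_days", visits_path)
    inr = _require_numeric(vdf, "inr", visits_path)
    dose = _require_numeric(vdf, "dose_mg", visits_path)
    tau = _require_numeric(vdf, "tau_h", visits_path)

    missing_d = set(DEMO_COLUMNS) - set(ddf.columns)
    if missing_d:
        raise SchemaError(f"{demographics_path}: missing columns {sorted(missing_d)}")
    if ddf["patient_id"].duplicated().any():
        dup = ddf["patient_id"][ddf["patient_id"].duplicated()].iloc[0]
        raise SchemaError(f"{demographics_path}: duplicate patient_id {dup!r}")
    age = _require_numeric(ddf, "age_years", demographics_path)
    weight = _require_numeric(ddf, "body_weight_kg", demographics_path)
    inter = _require_numeric(ddf, "interacting_drug", demographics_path)

    orphans = sorted(set(vdf["patient_id"]) - set(ddf["patient_id"]))
    if orphans:
        raise SchemaError(
            f"{visits_path}: visit ids missing from demographics: {orphans[:10]}"
        )

    visits_by_pid: dict[str, list[VisitRecord]] = {}
    order = np.lexsort((t, vdf["patient_id"].to_numpy()))
    for i in order:
        pid = vdf["patient_id"].iloc[i]
        try:
            rec = VisitRecord(pid, float(t[i]), float(inr[i]), float(dose[i]), float(tau[i]))
        except ValueError as exc:
            raise SchemaError(f"{visits_path}, line {int(i) + 2}: {exc}") from exc
        visits_by_pid.setdefault(pid, []).append(rec)

    patients = []
    for j, row in ddf.iterrows():
        pid = row["patient_id"]
        sex = str(row["sex"]).strip().upper()
        if sex not in ("M", "F"):
            raise SchemaError(
                f"{demographics_path}, line {int(j) + 2}: sex must be M or F, got {row['sex']!r}"
            )
        try:
            patients.append(
                Patient(
                    patient_id=pid, age=float(age[j]), sex=sex,
                    body_weight=float(weight[j]),
                    visits=visits_by_pid.get(pid, []),
                    interacting_drug=bool(int(inter[j])),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{demographics_path}, line {int(j) + 2}: {exc}") from exc
    return patients


def patients_to_frames(patients: list[Patient]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten Patients into canonical (visits, demographics) DataFrames."""
    vrows = [
        {"patient_id": v.patient_id, "t_days": v.t, "inr": v.inr,
         "dose_mg": v.dose, "tau_h": v.tau}
        for p in patients for v in p.visits
    ]
    drows = [
        {"patient_id": p.patient_id, "age_years": p.age, "sex": p.sex,
         "body_weight_kg": p.body_weight, "interacting_drug": int(p.interacting_drug)}
        for p in patients
    ]
    return pd.DataFrame(vrows, columns=VISIT_COLUMNS), pd.DataFrame(drows, columns=DEMO_COLUMNS)


def frames_to_patients(visits: pd.DataFrame, demographics: pd.DataFrame) -> list[Patient]:
    """Inverse of :func:`patients_to_frames` for in-memory tables."""
    by_pid: dict[str, list[VisitRecord]] = {}
    for row in visits.sort_values(["patient_id", "t_days"]).itertuples(index=False):
        by_pid.setdefault(row.patient_id, []).append(
            VisitRecord(row.patient_id, row.t_days, row.inr, row.dose_mg, row.tau_h)
        )
    return [
        Patient(
            patient_id=row.patient_id, age=row.age_years, sex=row.sex,
            body_weight=row.body_weight_kg, visits=by_pid.get(row.patient_id, []),
            interacting_drug=bool(row.interacting_drug),
        )
        for row in demographics.itertuples(index=False)
    ]


def write_cohort(
    patients: list[Patient], visits_path: str | Path, demographics_path: str | Path
) -> None:
    """Write the canonical visit and demographics tables (fixed decimals)."""
    visits_path, demographics_path = Path(visits_path), Path(demographics_path)
    vdf, ddf = patients_to_frames(patients)
    vdf.to_csv(visits_path, sep=_sep_for(visits_path), index=False,
               float_format=_FLOAT_FORMAT)
    ddf.to_csv(demographics_path, sep=_sep_for(demographics_path), index=False,
               float_format=_FLOAT_FORMAT)
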