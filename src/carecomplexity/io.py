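"""CSV readers/writers for cohort data, report writing and run manifests.

Interchange format is plain CSV (UTF-8, comma-separated, ISO-8601 dates)
across four files per cohort directory:

* ``patients.csv`` -- one row per hospitalization (demographics, ward,
  dates, outcome, admission flags, DRG value);
* ``settings.csv`` -- care-setting intervals per patient;
* ``vitals.csv`` -- daily vital-sign observations (AVPU coded A/V/P/U,
  supplemental oxygen 0/1);
* ``assessments.csv`` -- mICD rubric assessments, one column per dimension.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .cohort import ConsistencyReport, CrossTab, PatientRecord
from .errors import ValidationError
from .micd import DIMENSIONS, MicdAssessment
from .news import VitalSigns

__all__ = [
    "COHORT_FILES",
    "RunManifest",
    "read_cohort",
    "write_cohort",
    "write_reports",
]

COHORT_FILES = ("patients.csv", "settings.csv", "vitals.csv", "assessments.csv")

_AVPU_CODE = {"Alert": "A", "Verbal": "V", "Pain": "P", "Unresponsive": "U"}
_AVPU_LABEL = {v: k for k, v in _AVPU_CODE.items()}

PATIENT_COLUMNS = (
    "patient_id",
    "ward",
    "age",
    "gender",
    "admission_date",
    "discharge_date",
    "outcome",
    "admission_source",
    "admission_type",
    "drg_value",
)
SETTING_COLUMNS = ("patient_id", "start_date", "end_date", "setting")
VITAL_COLUMNS = (
    "patient_id",
    "observed_at",
    "respiration_rate",
    "spo2",
    "supplemental_oxygen",
    "temperature",
    "systolic_bp",
    "heart_rate",
    "avpu",
)
ASSESSMENT_COLUMNS = ("patient_id", "assessed_at", "context") + DIMENSIONS


@dataclass
class RunManifest:
    """Provenance of one simulate/analyze run."""

    tool_version: str
    seed: int | None
    config_hashes: dict[str, str]
    inputs: dict[str, int]  # file path -> row count
    created_at: str

    @classmethod
    def create(
        cls,
        seed: int | None = None,
        config_hashes: Mapping[str, str] | None = None,
        inputs: Mapping[str, int] | None = None,
    ) -> "RunManifest":
        return cls(
            tool_version=__version__,
            seed=seed,
            config_hashes=dict(config_hashes or {}),
            inputs=dict(inputs or {}),
            created_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def config_hash(obj) -> str:
    """Platform-stable SHA-256 of a canonical JSON rendering of a config."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def _parse_date(value, *, where: str) -> date:
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"{where}: malformed date {value!r}") from exc


def _require_columns(df: pd.DataFrame, expected, name: str) -> None:
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValidationError(f"{name}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(expected)
    if unknown:
        raise ValidationError(f"{name}: unknown columns {sorted(unknown)}")


def read_cohort(directory) -> list[PatientRecord]:
    """Read and fully validate the four cohort CSVs from ``directory``.

    Row-level problems are collected and reported together in one
    :class:`ValidationError` listing the offending file and row.
    """
    directory = Path(directory)
    for fname in COHORT_FILES:
        if not (directory / fname).exists():
            raise ValidationError(f"missing cohort file: {directory / fname}")
    patients = pd.read_csv(directory / "patients.csv", dtype={"patient_id": str})
    settings = pd.read_csv(directory / "settings.csv", dtype={"patient_id": str})
    vitals = pd.read_csv(directory / "vitals.csv", dtype={"patient_id": str})
    assessments = pd.read_csv(directory / "assessments.csv", dtype={"patient_id": str})
    _require_columns(patients, PATIENT_COLUMNS, "patients.csv")
    _require_columns(settings, SETTING_COLUMNS, "settings.csv")
    _require_columns(vitals, VITAL_COLUMNS, "vitals.csv")
    _require_columns(assessments, ASSESSMENT_COLUMNS, "assessments.csv")

    errors: list[str] = []
    by_settings: dict[str, list] = {}
    for i, row in settings.iterrows():
        try:
            by_settings.setdefault(str(row["patient_id"]), []).append(
                (
                    _parse_date(row["start_date"], where=f"settings.csv row {i}"),
                    _parse_date(row["end_date"], where=f"settings.csv row {i}"),
                    str(row["setting"]),
                )
            )
        except ValidationError as exc:
            errors.append(str(exc))

    by_vitals: dict[str, list[VitalSigns]] = {}
    for i, row in vitals.iterrows():
        try:
            avpu_raw = str(row["avpu"]).strip()
            avpu = _AVPU_LABEL.get(avpu_raw, avpu_raw)
            v = VitalSigns(
                respiration_rate=int(row["respiration_rate"]),
                spo2=int(row["spo2"]),
                supplemental_oxygen=bool(int(row["supplemental_oxygen"])),
                temperature=float(row["temperature"]),
                systolic_bp=int(row["systolic_bp"]),
                heart_rate=int(row["heart_rate"]),
                avpu=avpu,
                observed_at=_parse_date(row["observed_at"], where=f"vitals.csv row {i}"),
            )
            v.validate()
            by_vitals.setdefault(str(row["patient_id"]), []).append(v)
        except (ValidationError, ValueError) as exc:
            errors.append(f"vitals.csv row {i}: {exc}")

    by_micd: dict[str, list[MicdAssessment]] = {}
    for i, row in assessments.iterrows():
        try:
            a = MicdAssessment(
                **{d: int(row[d]) for d in DIMENSIONS},
                assessed_at=_parse_date(
                    row["assessed_at"], where=f"assessments.csv row {i}"
                ),
                context=str(row["context"]),
            )
            a.validate()
            by_micd.setdefault(str(row["patient_id"]), []).append(a)
        except (ValidationError, ValueError) as exc:
            errors.append(f"assessments.csv row {i}: {exc}")

    records: list[PatientRecord] = []
    for i, row in patients.iterrows():
        pid = str(row["patient_id"])
        try:
            drg = row["drg_value"]
            rec = PatientRecord(
                patient_id=pid,
                ward=str(row["ward"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                admission_date=_parse_date(
                    row["admission_date"], where=f"patients.csv row {i}"
                ),
                discharge_date=_parse_date(
                    row["discharge_date"], where=f"patients.csv row {i}"
                ),
                outcome=str(row["outcome"]),
                setting_intervals=by_settings.get(pid, []),
                vitals_series=sorted(
                    by_vitals.get(pid, []), key=lambda v: v.observed_at
                ),
                micd_series=sorted(by_micd.get(pid, []), key=lambda a: a.assessed_at),
                admission_type=str(row["admission_type"]),
                admission_source=str(row["admission_source"]),
                drg_value=None if pd.isna(drg) else float(drg),
            )
            rec.validate()
            records.append(rec)
        except ValidationError as exc:
            errors.append(f"patients.csv row {i}: {exc}")
    if errors:
        raise ValidationError(
            f"cohort validation failed with {len(errors)} problem(s):\n"
            + "\n".join(f"  - {e}" for e in errors)
        )
    return records


def write_cohort(records: Iterable[PatientRecord], directory) -> dict[str, int]:
    """Write the four cohort CSVs; returns per-file row counts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p_rows, s_rows, v_rows, a_rows = [], [], [], []
    for rec in records:
        p_rows.append(
            {
                "patient_id": rec.patient_id,
                "ward": rec.ward,
                "age": rec.age,
                "gender": rec.gender,
                "admission_date": rec.admission_date.isoformat(),
                "discharge_date": rec.discharge_date.isoformat(),
                "outcome": rec.outcome,
                "admission_source": rec.admission_source,
                "admission_type": rec.admission_type,
                "drg_value": rec.drg_value,
            }
        )
        for start, end, setting in rec.setting_intervals:
            s_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "start_date": start.isoformat(),
                    "end_date": end.isoformat(),
                    "setting": setting,
                }
            )
        for v in rec.vitals_series:
            v_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "observed_at": v.observed_at.isoformat(),
                    "respiration_rate": v.respiration_rate,
                    "spo2": v.spo2,
                    "supplemental_oxygen": int(v.supplemental_oxygen),
                    "temperature": v.temperature,
                    "systolic_bp": v.systolic_bp,
                    "heart_rate": v.heart_rate,
                    "avpu": _AVPU_CODE[v.avpu],
                }
            )
        for a in rec.micd_series:
            a_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "assessed_at": a.assessed_at.isoformat(),
                    "context": a.context,
                    **{d: getattr(a, d) for d in DIMENSIONS},
                }
            )
    frames = {
        "patients.csv": pd.DataFrame(p_rows, columns=list(PATIENT_COLUMNS)),
        "settings.csv": pd.DataFrame(s_rows, columns=list(SETTING_COLUMNS)),
        "vitals.csv": pd.DataFrame(v_rows, columns=list(VITAL_COLUMNS)),
        "assessments.csv": pd.DataFrame(a_rows, columns=list(ASSESSMENT_COLUMNS)),
    }
    counts = {}
    for fname, df in frames.items():
        df.to_csv(directory / fname, index=False)
        counts[fname] = len(df)
    return counts


def _crosstab_frame(tab: CrossTab) -> pd.DataFrame:
    df = tab.to_frame().reset_index()
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    df[pct_cols] = df[pct_cols].map(lambda x: f"{x:.1f}")
    meta = pd.DataFrame(
        {
            df.columns[0]: ["chi2_stat", "chi2_dof", "chi2_p"],
            df.columns[1]: [f"{tab.chi2_stat:.6g}", tab.chi2_dof, f"{tab.chi2_p:.6g}"],
        }
    )
    return pd.concat([df, meta], ignore_index=True)


def write_reports(
    crosstabs: Mapping[str, CrossTab],
    consistency: ConsistencyReport | None,
    summaries: Mapping[str, pd.DataFrame] | None,
    out_dir,
    manifest: RunManifest | None = None,
) -> list[Path]:
    """Write tidy report CSVs plus the run manifest; returns written paths.

    Report files are byte-stable for identical inputs: fixed column order,
    percentages printed to one decimal, no timestamps outside the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, tab in crosstabs.items():
        path = out_dir / f"{name}.csv"
        _crosstab_frame(tab).to_csv(path, index=False)
        written.append(path)
    if consistency is not None:
        path = out_dir / "consistency.csv"
        frame = consistency.to_frame()
        frame["proportion"] = frame["proportion"].map(lambda x: f"{x:.4f}")
        frame.to_csv(path, index=False)
        written.append(path)
    for name, df in (summaries or {}).items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=True)
        written.append(path)
    if manifest is not None:
        path = out_dir / "manifest.json"
        manifest.write(path)
        written.append(path)
    return written
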