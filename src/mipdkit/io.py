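"""File formats: patient JSON, cohort JSON-lines, advice JSON, time-course CSV.

Timestamps are ISO-8601; naive timestamps are assumed UTC. Schema violations
raise :class:`SchemaError` with a message naming the offending field.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Union

from .advisor import DoseAdvice
from .models import CovariateSet, Sex
from .records import Observation, ObservationSet, PatientRecord
from .simulate import DoseEvent

__all__ = [
    "SchemaError",
    "parse_patient",
    "patient_to_dict",
    "load_patient",
    "save_patient",
    "load_cohort_jsonl",
    "save_cohort_jsonl",
    "advice_to_dict",
    "export_cohort_tables",
]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def _parse_time(value: object, where: str) -> datetime:
    if not isinstance(value, str):
        raise SchemaError(f"{where}: expected an ISO-8601 time string, got {value!r}")
    try:
        t = datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError as exc:
        raise SchemaError(f"{where}: invalid time {value!r} ({exc})") from None
    return t.replace(tzinfo=timezone.utc) if t.tzinfo is None else t


def _opt_float(value) -> float | None:
    return None if value is None else float(value)


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return d[key]


def parse_patient(doc: dict) -> PatientRecord:
    if not isinstance(doc, dict):
        raise SchemaError("patient document must be a JSON object")
    pid = str(_require(doc, "id", "patient"))
    covs = []
    for i, c in enumerate(_require(doc, "covariates", "patient")):
        where = f"covariates[{i}]"
        try:
            covs.append(
                CovariateSet(
                    time=_parse_time(_require(c, "time", where), where),
                    weight_kg=float(_require(c, "weight_kg", where)),
                    serum_creatinine_mg_dL=float(
                        _require(c, "serum_creatinine_mg_dL", where)
                    ),
                    age_years=float(_require(c, "age_years", where)),
                    sex=Sex(_require(c, "sex", where)),
                    clcr_ml_min=_opt_float(c.get("clcr_ml_min")),
                    albumin_g_L=_opt_float(c.get("albumin_g_L")),
                    sofa=int(c["sofa"]) if c.get("sofa") is not None else None,
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{where}: {exc}") from None
    doses = []
    for i, d in enumerate(doc.get("doses", [])):
        where = f"doses[{i}]"
        try:
            doses.append(
                DoseEvent(
                    drug=str(_require(d, "drug", where)),
                    amount_mg=float(_require(d, "amount_mg", where)),
                    start_time=_parse_time(_require(d, "start_time", where), where),
                    infusion_duration_min=float(d.get("infusion_duration_min", 60.0)),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{where}: {exc}") from None
    obs = []
    for i, o in enumerate(doc.get("observations", [])):
        where = f"observations[{i}]"
        try:
            obs.append(
                Observation(
                    time=_parse_time(_require(o, "time", where), where),
                    concentration_mg_L=float(_require(o, "concentration_mg_L", where)),
                    drug=str(o.get("drug", "")),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{where}: {exc}") from None
    try:
        return PatientRecord(
            id=pid, covariates=covs, doses=doses, observations=ObservationSet(tuple(obs))
        )
    except ValueError as exc:
        raise SchemaError(str(exc)) from None


def patient_to_dict(p: PatientRecord) -> dict:
    return {
        "id": p.id,
        "covariates": [
            {
                "time": c.time.isoformat(),
                "weight_kg": c.weight_kg,
                "serum_creatinine_mg_dL": c.serum_creatinine_mg_dL,
                "age_years": c.age_years,
                "sex": c.sex.value,
                "clcr_ml_min": c.clcr_ml_min,
                "albumin_g_L": c.albumin_g_L,
                "sofa": c.sofa,
            }
            for c in p.covariates
        ],
        "doses": [
            {
                "drug": d.drug,
                "amount_mg": d.amount_mg,
                "start_time": d.start_time.isoformat(),
                "infusion_duration_min": d.infusion_duration_min,
            }
            for d in p.doses
        ],
        "observations": [
            {
                "time": o.time.isoformat(),
                "concentration_mg_L": o.concentration_mg_L,
                "drug": o.drug,
            }
            for o in p.observations
        ],
    }


def load_patient(path: Union[str, Path]) -> PatientRecord:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    return parse_patient(doc)


def save_patient(p: PatientRecord, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(patient_to_dict(p), indent=2) + "\n")


def load_cohort_jsonl(path: Union[str, Path]) -> list[PatientRecord]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            out.append(parse_patient(json.loads(line)))
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}:{ln}: not valid JSON ({exc})") from None
    return out


def save_cohort_jsonl(cohort: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in cohort:
            fh.write(json.dumps(patient_to_dict(p)) + "\n")


def advice_to_dict(advice: DoseAdvice) -> dict:
    r = advice.regimen
    return {
        "status": advice.status.value,
        "drug": advice.drug,
        "md_mg": r.maintenance_dose_mg if r else None,
        "interval_h": r.interval_h if r else None,
        "ld_mg": r.loading_dose_mg if r else None,
        "start_time": (
            advice.recommended_start_time.isoformat()
            if advice.recommended_start_time
            else None
        ),
        "predicted": (
            {
                "auc24": r.predicted.auc_mg_h_L,
                "cmin": r.predicted.cmin_mg_L,
                "cmax": r.predicted.cmax_mg_L,
                "pct_t_above_mic": r.predicted.pct_time_above_mic,
            }
            if r and r.predicted
            else None
        ),
        "warnings": [{"code": w.code, "text": w.text} for w in advice.warnings],
    }


def export_cohort_tables(cohort: Iterable[PatientRecord], out_dir: Union[str, Path]) -> None:
    """Flat CSVs (covariates, doses, levels) for spreadsheet-level inspection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = list(cohort)
    with open(out / "covariates.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "time", "weight_kg", "serum_creatinine_mg_dL",
                    "age_years", "sex", "clcr_ml_min", "albumin_g_L", "sofa"])
        for p in cohort:
            for c in p.covariates:
                w.writerow([p.id, c.time.isoformat(), c.weight_kg,
                            c.serum_creatinine_mg_dL, c.age_years, c.sex.value,
                            c.clcr_ml_min, c.albumin_g_L, c.sofa])
    with open(out / "doses.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug", "amount_mg", "start_time", "infusion_duration_min"])
        for p in cohort:
            for d in p.doses:
                w.writerow([p.id, d.drug, d.amount_mg, d.start_time.isoformat(),
                            d.infusion_duration_min])
    with open(out / "levels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug", "time", "concentration_mg_L"])
        for p in cohort:
            for o in p.observations:
                w.writerow([p.id, o.drug, o.time.isoformat(), o.concentration_mg_L])
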