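"""File plumbing: schema-versioned CSV/JSON readers and writers,
config (de)serialisation and seeded run manifests.

All CSVs are UTF-8, ISO-8601 dates, decimal point, and carry a leading
schema comment line (``# amiomon-schema: <name>-v1``).  Malformed input
rows are rejected with line-numbered messages rather than silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .evaluation import PairedOrder
from .rules import ANALYTES, Classification, LabPanel, RuleConfig, TechnicalError
from .scheduler import ErrorLedger, OrderEvent, Patient, WorklistItem

__all__ = [
    "PanelValidationError",
    "read_panels",
    "read_panels_json",
    "write_panels",
    "write_classifications",
    "read_cohort",
    "write_cohort",
    "read_pairs",
    "write_pairs",
    "write_orders",
    "write_worklist",
    "write_ledger",
    "RunManifest",
    "file_digest",
]

SCHEMA_VERSION = 1

PANEL_COLUMNS = ["patient_id", "sample_date", "tsh", "ft4", "ft3", "ast", "alt", "trab", "tpo"]
_ANALYTE_COLUMNS = list(ANALYTES) + ["trab", "tpo"]


class PanelValidationError(ValueError):
    """Raised on malformed panel files; carries line-numbered messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid panel file:\n" + "\n".join(problems))


def _schema_line(name: str) -> str:
    return f"# amiomon-schema: {name}-v{SCHEMA_VERSION}"


def _write_df(df: pd.DataFrame, path: Path | str, schema: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_schema_line(schema) + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path | str) -> tuple[pd.DataFrame, int]:
    """Read a CSV, returning the frame and the 1-based line of the header."""
    path = Path(path)
    n_comments = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    return df, n_comments + 1


def _rows_to_panels(df: pd.DataFrame, header_line: int, source: str) -> list[LabPanel]:
    missing_cols = [c for c in PANEL_COLUMNS[:7] if c not in df.columns]
    if missing_cols:
        raise PanelValidationError([f"{source}: missing column(s) {missing_cols}"])
    problems: list[str] = []
    panels: list[LabPanel] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        line = header_line + 1 + int(idx)
        try:
            sample_date = date.fromisoformat(str(row["sample_date"]))
        except ValueError:
            problems.append(f"{source}:{line}: invalid sample_date {row['sample_date']!r}")
            continue
        key = (str(row["patient_id"]), str(sample_date))
        if key in seen:
            problems.append(f"{source}:{line}: duplicate (patient_id, sample_date) {key}")
            continue
        seen.add(key)
        values: dict[str, Optional[float]] = {}
        row_ok = True
        for a in _ANALYTE_COLUMNS:
            raw = row.get(a)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw) == "":
                values[a] = None
                continue
            try:
                v = float(raw)
            except (TypeError, ValueError):
                problems.append(f"{source}:{line}: non-numeric {a} value {raw!r}")
                row_ok = False
                continue
            if not math.isfinite(v) or v < 0:
                problems.append(f"{source}:{line}: {a} must be finite and >= 0, got {v}")
                row_ok = False
                continue
            values[a] = v
        if not row_ok:
            continue
        panels.append(LabPanel(patient_id=str(row["patient_id"]), sample_date=sample_date, **values))
    if problems:
        raise PanelValidationError(problems)
    return panels


def read_panels(path: Path | str) -> list[LabPanel]:
    """Read laboratory panels from CSV (empty cell = missing analyte)."""
    df, header_line = _read_csv(path)
    return _rows_to_panels(df, header_line, str(path))


def read_panels_json(path: Path | str) -> list[LabPanel]:
    """Read panels from a JSON array of records (same schema as the CSV)."""
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    df = pd.DataFrame.from_records(records)
    return _rows_to_panels(df, 0, str(path))


def write_panels(path: Path | str, panels: Sequence[LabPanel]) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "sample_date": p.sample_date.isoformat(),
            **{a: p.value(a) for a in ANALYTES},
            "trab": p.trab,
            "tpo": p.tpo,
        }
        for p in panels
    ]
    _write_df(pd.DataFrame(rows, columns=PANEL_COLUMNS), path, "panels")


def write_classifications(
    path: Path | str,
    rows: Sequence[tuple[LabPanel, Classification | TechnicalError]],
) -> None:
    """One output row per panel, with an explicit technical_error column."""
    out = []
    for panel, outcome in rows:
        base = {"patient_id": panel.patient_id, "sample_date": panel.sample_date.isoformat()}
        if isinstance(outcome, TechnicalError):
            out.append(
                {
                    **base,
                    "technical_error": True,
                    "error_reason": f"{outcome.reason}: {','.join(outcome.missing_analytes)}",
                    "class_id": "", "color": "", "interval_months": "",
                    "suspected_condition": "", "referral": "",
                    "order_antibodies": "", "recommendation": "",
                }
            )
        else:
            out.append(
                {
                    **base,
                    "technical_error": False,
                    "error_reason": "",
                    "class_id": outcome.class_id,
                    "color": outcome.color,
                    "interval_months": outcome.interval_months,
                    "suspected_condition": outcome.suspected_condition,
                    "referral": outcome.referral,
                    "order_antibodies": outcome.order_antibodies,
                    "recommendation": outcome.recommendation,
                }
            )
    _write_df(pd.DataFrame(out), path, "classifications")


def write_cohort(path: Path | str, patients: Sequence[Patient]) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "treatment_start_date": p.treatment_start_date.isoformat(),
            "treatment_stop_date": (
                p.treatment_stop_date.isoformat() if p.treatment_stop_date else ""
            ),
            "active": p.active,
            "age": p.age if p.age is not None else "",
            "male": p.male if p.male is not None else "",
        }
        for p in patients
    ]
    _write_df(pd.DataFrame(rows), path, "cohort")


def read_cohort(path: Path | str) -> list[Patient]:
    df, _ = _read_csv(path)
    patients = []
    for _, row in df.iterrows():
        stop = row.get("treatment_stop_date")
        stop_date = (
            date.fromisoformat(str(stop))
            if stop is not None and str(stop) not in ("", "nan")
            else None
        )
        age = row.get("age")
        male = row.get("male")
        patients.append(
            Patient(
                patient_id=str(row["patient_id"]),
                treatment_start_date=date.fromisoformat(str(row["treatment_start_date"])),
                treatment_stop_date=stop_date,
                active=bool(row.get("active", True)),
                age=None if age is None or (isinstance(age, float) and math.isnan(age)) else float(age),
                male=None if male is None or (isinstance(male, float) and math.isnan(male)) else bool(male),
            )
        )
    return patients


def write_pairs(path: Path | str, pairs: Sequence[PairedOrder]) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "sample_date": p.sample_date.isoformat(),
            "robot_class": p.robot_class,
            "robot_interval_months": p.robot_interval_months,
            "physician_interval_months": p.physician_interval_months,
            "physician_noticed_pathology": p.physician_noticed_pathology,
        }
        for p in pairs
    ]
    _write_df(pd.DataFrame(rows), path, "pairs")


def read_pairs(path: Path | str) -> list[PairedOrder]:
    df, _ = _read_csv(path)
    return [
        PairedOrder(
            patient_id=str(row["patient_id"]),
            sample_date=date.fromisoformat(str(row["sample_date"])),
            robot_class=int(row["robot_class"]),
            robot_interval_months=int(row["robot_interval_months"]),
            physician_interval_months=int(row["physician_interval_months"]),
            physician_noticed_pathology=bool(row["physician_noticed_pathology"]),
        )
        for _, row in df.iterrows()
    ]


def write_orders(path: Path | str, orders: Sequence[OrderEvent]) -> None:
    rows = [
        {
            "patient_id": o.patient_id,
            "issue_date": o.issue_date.isoformat(),
            "due_date": o.due_date.isoformat(),
            "status": o.status,
            "reminded": o.reminded,
            "result_date": o.result_date.isoformat() if o.result_date else "",
        }
        for o in orders
    ]
    _write_df(pd.DataFrame(rows), path, "orders")


def write_worklist(path: Path | str, items: Sequence[WorklistItem]) -> None:
    rows = []
    for w in items:
        rows.append(
            {
                "patient_id": w.patient_id,
                "created_date": w.created_date.isoformat(),
                "technical_error": w.technical_error is not None,
                "class_id": w.classification.class_id if w.classification else "",
                "suspected_condition": (
                    w.classification.suspected_condition if w.classification else ""
                ),
                "immediate": w.immediate,
                "confirmed": w.confirmed,
                "physician_interval_months": (
                    w.physician_interval_months if w.physician_interval_months is not None else ""
                ),
            }
        )
    _write_df(pd.DataFrame(rows), path, "worklist")


def write_ledger(path: Path | str, ledger: ErrorLedger) -> None:
    rows = [
        {
            "checkpoint_date": c.checkpoint_date.isoformat(),
            "runs": c.runs,
            "errors": c.errors,
            "proportion": c.proportion,
        }
        for c in ledger.checkpoints
    ]
    _write_df(pd.DataFrame(rows), path, "ledger")


def read_cases(path: Path | str):
    """Read side-effect case records (structured response criteria)."""
    from .evaluation import SideEffectCase

    df, _ = _read_csv(path)
    bool_cols = ("acknowledged", "reevaluated", "adjusted_or_stopped", "referred",
                 "repeat_test_ordered")
    cases = []
    for _, row in df.iterrows():
        repeat = row.get("repeat_interval_months")
        cases.append(
            SideEffectCase(
                case_id=str(row["case_id"]),
                event_type=str(row["event_type"]),
                robot_class=int(row["robot_class"]),
                **{c: bool(row.get(c, False)) for c in bool_cols},
                repeat_interval_months=(
                    None if repeat is None or (isinstance(repeat, float) and math.isnan(repeat))
                    else int(repeat)
                ),
            )
        )
    return cases


def write_responses(path: Path | str, assessments) -> None:
    rows = [
        {
            "case_id": a.case_id,
            "event_type": a.event_type,
            "robot_assessment": a.robot_assessment,
            "physician_assessment": a.physician_assessment,
            "criteria_met": ";".join(sorted(a.criteria_met)),
        }
        for a in assessments
    ]
    _write_df(pd.DataFrame(rows), path, "responses")


def file_digest(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one seeded run (timestamp excluded from any
    reproducibility comparison)."""

    command: str
    seed: int
    config_digest: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path: Path | str) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n", encoding="utf-8")
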