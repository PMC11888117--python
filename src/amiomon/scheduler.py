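"""Event-driven surveillance workflow over calendar time.

Reproduces the monitoring loop around the triage engine: lab orders are
issued on a schedule (first follow-up 3 months after treatment start,
second at 6 months, thereafter at the interval confirmed for the previous
result), results are matched to orders, absent results trigger a reminder
and eventually lapse, every resulted order is classified and queued for a
human-in-the-loop decision, and the confirmed interval schedules the next
cycle.  Technical errors (non-1/2/3 outputs) are tallied in an error
ledger over time.

Patients who stop amiodarone remain under surveillance for a
configurable post-discontinuation window, reflecting the drug's
months-long biological half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Literal, Optional, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .rules import Classification, LabPanel, RuleConfig, TechnicalError, classify_panel

__all__ = [
    "Patient",
    "SchedulingPolicy",
    "OrderEvent",
    "WorklistItem",
    "ErrorLedger",
    "add_months",
    "run_surveillance",
    "decide",
]


def add_months(d: date, months: int) -> date:
    """Calendar-month arithmetic with day-of-month clamping."""
    total = d.month - 1 + months
    year = d.year + total // 12
    month = total % 12 + 1
    # clamp day to the target month's length
    if month == 12:
        month_days = 31
    else:
        month_days = (date(year, month + 1, 1) - timedelta(days=1)).day
    return date(year, month, min(d.day, month_days))


class Patient(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    treatment_start_date: date
    treatment_stop_date: Optional[date] = None
    active: bool = True
    age: Optional[float] = None
    male: Optional[bool] = None

    @model_validator(mode="after")
    def _check_dates(self) -> "Patient":
        if self.treatment_stop_date is not None and self.treatment_stop_date < self.treatment_start_date:
            raise ValueError("treatment_stop_date before treatment_start_date")
        return self


class SchedulingPolicy(BaseModel):
    """Tunable workflow parameters (all durations in days unless noted)."""

    first_followup_months: int = 3
    second_followup_months: int = 6
    #: days allowed for the patient to get sampled after an order is issued
    due_days: int = Field(default=14, gt=0)
    reminder_delay_days: int = 14
    lapse_after_reminder_days: int = 60
    post_discontinuation_months: int = 12
    #: surveillance horizon from each patient's treatment start
    horizon_months: int = 24
    #: retest interval confirmed for a technical-error item under accept-all
    error_retest_months: int = 1


class OrderEvent(BaseModel):
    patient_id: str
    issue_date: date
    due_date: date
    status: Literal["issued", "resulted", "reminded", "lapsed"]
    panel: Optional[LabPanel] = None
    reminded: bool = False
    result_date: Optional[date] = None

    @model_validator(mode="after")
    def _check(self) -> "OrderEvent":
        if self.due_date <= self.issue_date:
            raise ValueError("due_date must be after issue_date")
        return self


class WorklistItem(BaseModel):
    """One classified result awaiting (or carrying) a physician decision."""

    patient_id: str
    panel: LabPanel
    classification: Optional[Classification] = None
    technical_error: Optional[TechnicalError] = None
    created_date: date
    #: class-3 items are flagged for immediate attention
    immediate: bool = False
    confirmed: bool = False
    physician_interval_months: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "WorklistItem":
        if (self.classification is None) == (self.technical_error is None):
            raise ValueError("exactly one of classification/technical_error must be set")
        if self.confirmed and self.physician_interval_months is None:
            raise ValueError("confirmed item must carry a physician interval")
        return self


@dataclass(frozen=True)
class LedgerCheckpoint:
    checkpoint_date: date
    runs: int  # cumulative classification attempts
    errors: int  # cumulative technical errors
    proportion: float


@dataclass
class ErrorLedger:
    """Cumulative technical-error proportion at each classification date."""

    checkpoints: list[LedgerCheckpoint] = field(default_factory=list)

    @property
    def total_runs(self) -> int:
        return self.checkpoints[-1].runs if self.checkpoints else 0

    @property
    def total_errors(self) -> int:
        return self.checkpoints[-1].errors if self.checkpoints else 0


class DecisionModel(Protocol):
    def draw(self, class_id: int, rng: np.random.Generator) -> tuple[int, bool]:
        """Return (interval_months, noticed_pathology) for a robot class."""


def decide(
    item: WorklistItem,
    physician_model: Optional[DecisionModel] = None,
    rng: Optional[np.random.Generator] = None,
    error_retest_months: int = 1,
) -> WorklistItem:
    """Confirm a worklist item, fixing the follow-up interval.

    With no model (accept-all) the robot's own interval is confirmed;
    technical-error items get ``error_retest_months``.  A behavior model
    draws the interval from its class-conditional distribution.
    """
    if item.confirmed:
        raise ValueError("worklist item already confirmed")
    if item.classification is None:
        interval = error_retest_months
    elif physician_model is None:
        interval = item.classification.interval_months
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        interval, _ = physician_model.draw(item.classification.class_id, rng)
    return item.model_copy(update={"confirmed": True, "physician_interval_months": int(interval)})


def run_surveillance(
    cohort: Sequence[Patient],
    panels: Iterable[LabPanel],
    config: RuleConfig,
    policy: SchedulingPolicy | None = None,
    seed: int = 0,
    physician_model: Optional[DecisionModel] = None,
) -> tuple[list[OrderEvent], list[WorklistItem], ErrorLedger]:
    """Simulate the full surveillance loop for a cohort.

    Panels act as the result stream: an order is "resulted" by the first
    unconsumed panel dated inside its sampling window; otherwise a
    reminder goes out and, failing that, the order lapses and is
    reissued.  Every resulted order yields exactly one worklist item, the
    decision (accept-all unless a behavior model is supplied) confirms
    the follow-up interval, and the next order is issued at decision date
    plus that interval.  Identical inputs and seed yield identical event
    streams.
    """
    if policy is None:
        policy = SchedulingPolicy()
    ids = [p.patient_id for p in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id(s) in cohort: {dupes}")
    by_patient: dict[str, list[LabPanel]] = {pid: [] for pid in ids}
    patients = {p.patient_id: p for p in cohort}
    for panel in panels:
        if panel.patient_id not in by_patient:
            raise ValueError(f"panel for unknown patient {panel.patient_id!r}")
        if panel.sample_date < patients[panel.patient_id].treatment_start_date:
            raise ValueError(
                f"panel for {panel.patient_id} dated {panel.sample_date} before treatment start"
            )
        by_patient[panel.patient_id].append(panel)
    for stream in by_patient.values():
        stream.sort(key=lambda p: p.sample_date)

    rng = np.random.default_rng(seed)
    orders: list[OrderEvent] = []
    worklist: list[WorklistItem] = []
    attempts: list[tuple[date, bool]] = []  # (date, is_error)

    for pid in sorted(patients):
        patient = patients[pid]
        if not patient.active and patient.treatment_stop_date is None:
            continue
        start = patient.treatment_start_date
        surv_end = add_months(start, policy.horizon_months)
        if patient.treatment_stop_date is not None:
            surv_end = min(
                surv_end, add_months(patient.treatment_stop_date, policy.post_discontinuation_months)
            )
        stream = by_patient[pid]
        cursor = 0

        def take_panel(lo: date, hi: date) -> Optional[LabPanel]:
            nonlocal cursor
            while cursor < len(stream) and stream[cursor].sample_date < lo:
                cursor += 1
            if cursor < len(stream) and lo <= stream[cursor].sample_date <= hi:
                panel = stream[cursor]
                cursor += 1
                return panel
            return None

        issue = add_months(start, policy.first_followup_months)
        first_cycle = True
        while issue <= surv_end:
            due = issue + timedelta(days=policy.due_days)
            panel = take_panel(issue, due)
            reminded = False
            if panel is None:
                remind_date = due + timedelta(days=policy.reminder_delay_days)
                lapse_date = remind_date + timedelta(days=policy.lapse_after_reminder_days)
                reminded = True
                panel = take_panel(due + timedelta(days=1), lapse_date)
                if panel is None:
                    if lapse_date > surv_end:
                        orders.append(
                            OrderEvent(
                                patient_id=pid, issue_date=issue, due_date=due,
                                status="reminded", reminded=True,
                            )
                        )
                        break
                    orders.append(
                        OrderEvent(
                            patient_id=pid, issue_date=issue, due_date=due,
                            status="lapsed", reminded=True,
                        )
                    )
                    issue = lapse_date
                    continue
            orders.append(
                OrderEvent(
                    patient_id=pid, issue_date=issue, due_date=due, status="resulted",
                    panel=panel, reminded=reminded, result_date=panel.sample_date,
                )
            )
            months_on = (panel.sample_date - start).days // 30
            outcome = classify_panel(panel, config, months_on_treatment=months_on)
            is_error = isinstance(outcome, TechnicalError)
            attempts.append((panel.sample_date, is_error))
            item = WorklistItem(
                patient_id=pid,
                panel=panel,
                classification=None if is_error else outcome,
                technical_error=outcome if is_error else None,
                created_date=panel.sample_date,
                immediate=(not is_error and outcome.class_id == 3),
            )
            item = decide(
                item, physician_model=physician_model, rng=rng,
                error_retest_months=policy.error_retest_months,
            )
            worklist.append(item)
            decision_date = panel.sample_date
            next_issue = add_months(decision_date, item.physician_interval_months)
            if first_cycle:
                # routine start-up: the second test is due no later than
                # 6 months after treatment start
                next_issue = min(next_issue, add_months(start, policy.second_followup_months))
                first_cycle = False
            if next_issue <= decision_date and item.physician_interval_months > 0:
                next_issue = add_months(decision_date, item.physician_interval_months)
            issue = next_issue

    ledger = ErrorLedger()
    runs = errors = 0
    for d, is_error in sorted(attempts, key=lambda t: t[0]):
        runs += 1
        errors += int(is_error)
        ledger.checkpoints.append(
            LedgerCheckpoint(checkpoint_date=d, runs=runs, errors=errors, proportion=errors / runs)
        )
    return orders, worklist, ledger
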