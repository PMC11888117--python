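"""Synthetic longitudinal cohort generator.

Real amiodarone surveillance data is protected clinical information, so
every downstream module is exercised on synthetic cohorts that emulate
the published epidemiology of the drug's laboratory side effects:

* baseline analyte levels drawn from log-normal distributions matched to
  the cohort's median/IQR (TSH 1.9 (1.3–2.8) mIU/L, fT4 15 (13–17)
  pmol/L, AST 0.44 (0.36–0.56) and ALT 0.40 (0.29–0.63) µkat/L), clamped
  into the reference interval — surveillance baselines are screened
  normal, and clamping preserves the configured median;
* side-effect events (amiodarone-induced hypothyroidism/thyrotoxicosis,
  hepatotoxicity) injected with configurable prevalence and log-normal
  time-to-onset (median 183 days for AIH, 720 days for AIT —
  hypothyroidism typically appears much sooner than thyrotoxicosis);
* a physician ordering-behavior model whose interval distribution peaks
  at 3–4 months even for normal results, with a configurable probability
  of missing definite pathology.

Post-onset analyte displacement is deterministic and scaled against the
rule table so that a ``definite`` severity crosses the red band at the
first post-onset sample by construction, while ``minor`` lands in the
yellow band.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .rules import (
    ANALYTES,
    LabPanel,
    RuleConfig,
    default_profile,
)
from .scheduler import Patient, add_months

__all__ = [
    "AnalyteBaseline",
    "OnsetDistribution",
    "CohortParams",
    "TrajectorySpec",
    "PhysicianModel",
    "PhysicianOrder",
    "generate_cohort",
    "sample_panels",
    "sample_physician_orders",
    "routine_schedule",
]

EventType = Literal["none", "aih", "ait", "hepatotoxicity"]

#: z(0.75) - z(0.25); converts an IQR ratio into a log-normal sigma
_IQR_Z_SPAN = 1.3489795003921634


class AnalyteBaseline(BaseModel):
    """Median and quartiles of an analyte's baseline distribution."""

    median: float = Field(gt=0)
    q25: float = Field(gt=0)
    q75: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "AnalyteBaseline":
        if not self.q25 <= self.median <= self.q75:
            raise ValueError("quartiles must bracket the median")
        return self

    @property
    def log_sigma(self) -> float:
        return float(np.log(self.q75 / self.q25) / _IQR_Z_SPAN)


class OnsetDistribution(BaseModel):
    """Log-normal time-to-onset in days."""

    median_days: float = Field(gt=0)
    log_sigma: float = Field(default=0.85, gt=0)


def _default_baselines() -> dict[str, AnalyteBaseline]:
    return {
        "tsh": AnalyteBaseline(median=1.9, q25=1.3, q75=2.8),
        "ft4": AnalyteBaseline(median=15.0, q25=13.0, q75=17.0),
        "ft3": AnalyteBaseline(median=4.9, q25=4.2, q75=5.6),
        "ast": AnalyteBaseline(median=0.44, q25=0.36, q75=0.56),
        "alt": AnalyteBaseline(median=0.40, q25=0.29, q75=0.63),
    }


def _default_onsets() -> dict[str, OnsetDistribution]:
    return {
        "aih": OnsetDistribution(median_days=183.0),
        "ait": OnsetDistribution(median_days=720.0),
        "hepatotoxicity": OnsetDistribution(median_days=90.0),
    }


class CohortParams(BaseModel):
    """Simulation conditions for one synthetic cohort."""

    n_patients: int = Field(default=198, gt=0)
    age_mean: float = 73.0
    age_sd: float = 12.0
    male_fraction: float = Field(default=0.626, ge=0, le=1)
    baselines: dict[str, AnalyteBaseline] = Field(default_factory=_default_baselines)
    #: multiplicative measurement noise, coefficient of variation per analyte
    noise_cv: dict[str, float] = Field(
        default_factory=lambda: {a: 0.05 for a in ANALYTES}
    )
    #: per-patient probability of each side effect over the horizon
    event_mix: dict[str, float] = Field(
        default_factory=lambda: {"aih": 0.04, "ait": 0.03, "hepatotoxicity": 0.02}
    )
    onsets: dict[str, OnsetDistribution] = Field(default_factory=_default_onsets)
    #: probability that an injected event is of definite (red) severity
    definite_fraction: float = Field(default=0.5, ge=0, le=1)
    horizon_months: int = Field(default=24, gt=0)
    enrollment_start: date = date(2022, 1, 1)
    #: enrollment staggering window in days (start dates drawn uniformly)
    enrollment_window_days: int = 0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortParams":
        missing = set(ANALYTES) - set(self.baselines)
        if missing:
            raise ValueError(f"baselines missing analytes: {sorted(missing)}")
        if sum(self.event_mix.values()) > 1:
            raise ValueError("event probabilities must sum to <= 1")
        unknown = set(self.event_mix) - {"aih", "ait", "hepatotoxicity"}
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")
        return self


class TrajectorySpec(BaseModel):
    """Per-patient simulation plan."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    baselines: dict[str, float]
    event: EventType = "none"
    onset_day: Optional[int] = None
    severity: Literal["minor", "definite"] = "definite"

    @model_validator(mode="after")
    def _check(self) -> "TrajectorySpec":
        if (self.event == "none") != (self.onset_day is None):
            raise ValueError("onset_day must be set iff an event is present")
        return self


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(patient_id.encode())])


def generate_cohort(params: CohortParams) -> tuple[list[Patient], list[TrajectorySpec]]:
    """Draw a synthetic cohort: patients plus their trajectory plans.

    Baselines are log-normal draws matched to the configured median/IQR
    and clamped into the rule table's reference interval, so an
    event-free noise-free cohort classifies entirely class 1.  Events are
    assigned by the configured mix; onset days are log-normal.  Identical
    (params, seed) yield identical cohorts.
    """
    cfg = default_profile()
    rng = np.random.default_rng(params.seed & 0x7FFFFFFF)
    events = list(params.event_mix)
    probs = [params.event_mix[e] for e in events]
    p_none = 1.0 - sum(probs)

    patients: list[Patient] = []
    specs: list[TrajectorySpec] = []
    horizon_days = params.horizon_months * 30
    for i in range(params.n_patients):
        pid = f"P{i:05d}"
        offset = (
            int(rng.integers(0, params.enrollment_window_days + 1))
            if params.enrollment_window_days > 0
            else 0
        )
        start = params.enrollment_start + timedelta(days=offset)
        age = float(rng.normal(params.age_mean, params.age_sd))
        male = bool(rng.random() < params.male_fraction)
        patients.append(
            Patient(
                patient_id=pid, treatment_start_date=start, active=True,
                age=round(max(age, 18.0), 1), male=male,
            )
        )

        baselines: dict[str, float] = {}
        for a in ANALYTES:
            b = params.baselines[a]
            draw = float(np.exp(rng.normal(np.log(b.median), b.log_sigma)))
            rule = cfg.analytes[a]
            lo = rule.reference_low if rule.reference_low > 0 else min(draw, b.q25)
            baselines[a] = float(np.clip(draw, lo, rule.reference_high))

        u = float(rng.random())
        event: EventType = "none"
        acc = 0.0
        for e, p in zip(events, probs):
            acc += p
            if u < acc:
                event = e  # type: ignore[assignment]
                break
        onset: Optional[int] = None
        severity: Literal["minor", "definite"] = "definite"
        if event != "none":
            od = params.onsets[event]
            onset = int(
                round(float(np.exp(rng.normal(np.log(od.median_days), od.log_sigma))))
            )
            onset = max(onset, 1)
            severity = "definite" if rng.random() < params.definite_fraction else "minor"
        else:
            rng.normal()  # keep the draw count aligned across event branches
            rng.random()
        _ = horizon_days  # onset may exceed the horizon; such events never manifest
        specs.append(
            TrajectorySpec(
                patient_id=pid, baselines=baselines, event=event,
                onset_day=onset, severity=severity,
            )
        )
    return patients, specs


def _event_targets(
    event: EventType, severity: Literal["minor", "definite"], cfg: RuleConfig
) -> dict[str, float]:
    """Deterministic displaced values per affected analyte.

    ``definite`` values land beyond the red threshold, ``minor`` values in
    the interior of the yellow band, evaluated against *cfg*.
    """
    tsh, ft4, ft3 = cfg.analytes["tsh"], cfg.analytes["ft4"], cfg.analytes["ft3"]
    ast, alt = cfg.analytes["ast"], cfg.analytes["alt"]
    if event == "aih":
        if severity == "definite":
            # TSH deep in the red, fT4 below reference (hypothyroid pattern)
            return {"tsh": 2.0 * tsh.red_high, "ft4": (ft4.red_low + ft4.reference_low) / 2}
        return {"tsh": (tsh.reference_high + tsh.red_high) / 2,
                "ft4": (ft4.red_low + ft4.reference_low) / 2}
    if event == "ait":
        if severity == "definite":
            # suppressed TSH with elevated free hormones (thyrotoxic pattern)
            return {
                "tsh": tsh.red_low / 5.0,
                "ft4": (ft4.reference_high + ft4.red_high) / 2,
                "ft3": (ft3.reference_high + ft3.red_high) / 2,
            }
        return {
            "tsh": (tsh.red_low + tsh.reference_low) / 2,
            "ft4": (ft4.reference_high + ft4.red_high) / 2,
        }
    if event == "hepatotoxicity":
        factor = 4.0 if severity == "definite" else 2.0
        return {"ast": factor * ast.reference_high, "alt": factor * alt.reference_high}
    return {}


def sample_panels(
    spec: TrajectorySpec,
    schedule: Sequence[date],
    params: CohortParams,
    treatment_start: Optional[date] = None,
    config: Optional[RuleConfig] = None,
) -> list[LabPanel]:
    """Sample one panel per scheduled date along a trajectory.

    Pre-onset values fluctuate multiplicatively around baseline with the
    configured CV; from the onset day on, affected analytes take their
    deterministic displaced values (no noise), guaranteeing the intended
    band crossing at the first post-onset sample.
    """
    if list(schedule) != sorted(schedule):
        raise ValueError("schedule must be sorted ascending")
    cfg = config or default_profile()
    start = treatment_start or params.enrollment_start
    rng = _patient_rng(params.seed, spec.patient_id)
    targets = _event_targets(spec.event, spec.severity, cfg) if spec.event != "none" else {}
    onset_date = (
        start + timedelta(days=int(spec.onset_day)) if spec.onset_day is not None else None
    )
    panels: list[LabPanel] = []
    for d in schedule:
        values: dict[str, float] = {}
        post = onset_date is not None and d >= onset_date
        for a in ANALYTES:
            if post and a in targets:
                values[a] = targets[a]
            else:
                cv = params.noise_cv.get(a, 0.0)
                if cv > 0:
                    sigma = float(np.sqrt(np.log1p(cv**2)))
                    values[a] = spec.baselines[a] * float(np.exp(rng.normal(0.0, sigma)))
                else:
                    values[a] = spec.baselines[a]
        panels.append(LabPanel(patient_id=spec.patient_id, sample_date=d, **values))
    return panels


def routine_schedule(start: date, horizon_months: int) -> list[date]:
    """The routine testing grid: 3 and 6 months after start, then every 6."""
    months = [3, 6]
    m = 12
    while m <= horizon_months:
        months.append(m)
        m += 6
    return [add_months(start, m) for m in months]


class PhysicianModel(BaseModel):
    """Ordering-behavior model: interval distribution conditional on class.

    The class-1 default reproduces the observed clustering of physician
    orders at 3–4 months even for normal results; ``miss_probability`` is
    the chance that definite (class-3) pathology goes unnoticed, in which
    case a short repeat-test interval is drawn instead of an immediate
    (0-month) response.
    """

    class1_dist: dict[int, float] = Field(
        default_factory=lambda: {1: 0.08, 2: 0.14, 3: 0.30, 4: 0.28, 5: 0.10, 6: 0.10}
    )
    class2_dist: dict[int, float] = Field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.20}
    )
    #: interval drawn when definite pathology is missed (repeat test 1-3 mo)
    missed_class3_dist: dict[int, float] = Field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    miss_probability: float = Field(default=1 / 3, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "PhysicianModel":
        for name in ("class1_dist", "class2_dist", "missed_class3_dist"):
            dist = getattr(self, name)
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(not 0 <= k <= 6 for k in dist):
                raise ValueError(f"{name} keys must be intervals in 0..6")
        return self

    def draw(self, class_id: int, rng: np.random.Generator) -> tuple[int, bool]:
        """Draw (interval_months, noticed_pathology) for one robot class."""
        if class_id == 3:
            if rng.random() < self.miss_probability:
                return self._draw_from(self.missed_class3_dist, rng), False
            return 0, True
        dist = self.class1_dist if class_id == 1 else self.class2_dist
        return self._draw_from(dist, rng), True

    @staticmethod
    def _draw_from(dist: dict[int, float], rng: np.random.Generator) -> int:
        intervals = sorted(dist)
        probs = np.array([dist[k] for k in intervals])
        return int(rng.choice(intervals, p=probs / probs.sum()))


class AcceptAllModel(BaseModel):
    """Degenerate behavior model: always confirms the robot's interval."""

    def draw(self, class_id: int, rng: np.random.Generator) -> tuple[int, bool]:
        from .rules import CLASS_INTERVALS

        return CLASS_INTERVALS[class_id], True


@dataclass(frozen=True)
class PhysicianOrder:
    interval_months: int
    noticed_pathology: bool


def sample_physician_orders(
    classifications: Sequence,
    model: PhysicianModel,
    seed: int = 0,
) -> list[PhysicianOrder]:
    """Draw one physician order per robot classification."""
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    orders = []
    for c in classifications:
        interval, noticed = model.draw(c.class_id, rng)
        orders.append(PhysicianOrder(interval_months=interval, noticed_pathology=noticed))
    return orders
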