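"""Three-class diagnostic triage over thyroid/liver laboratory panels.

Amiodarone surveillance rests on five analytes: TSH (mIU/L), free T4 and
free T3 (pmol/L), and the transaminases AST and ALT (µkat/L).  Each panel
is mapped to one of three color-coded urgency classes:

* class 1 (green)  — all values acceptable, next test in 6 months;
* class 2 (yellow) — minor deviation of uncertain significance, retest in
  1 month;
* class 3 (red)    — definite laboratory pathology, immediate physician
  handling (encoded as a 0-month interval).

Per-analyte grading uses a reference interval flanked by a "yellow" band
(minor deviation) and a "red" band (definite pathology).  Pattern rules
combine graded analytes into suspected conditions: amiodarone-induced
thyrotoxicosis (AIT: suppressed TSH with elevated free T4/T3, routed to
endocrinology), amiodarone-induced hypothyroidism (AIH: elevated TSH with
low free T4, routed to primary care), and hepatotoxicity (transaminases
above three times the upper reference limit).

A panel with a missing core analyte yields an explicit
:class:`TechnicalError` outcome — never a silent default class — mirroring
the operational definition of a technical error as any output that is not
one of classes 1–3.
"""

from __future__ import annotations

import math
from datetime import date
from enum import Enum
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "ANALYTES",
    "THYROID_ANALYTES",
    "LIVER_ANALYTES",
    "LabPanel",
    "Grade",
    "AnalyteGrade",
    "AnalyteRule",
    "RuleConfig",
    "Classification",
    "TechnicalError",
    "default_profile",
    "grade_analyte",
    "classify_panel",
    "render_recommendation",
    "ukat_from_ul",
]

ANALYTES: tuple[str, ...] = ("tsh", "ft4", "ft3", "ast", "alt")
THYROID_ANALYTES: tuple[str, ...] = ("tsh", "ft4", "ft3")
LIVER_ANALYTES: tuple[str, ...] = ("ast", "alt")

#: Interval (months) implied by each class: 6 (green), 1 (yellow), 0 (red —
#: "directly to physician" translated to zero months).
CLASS_INTERVALS: dict[int, int] = {1: 6, 2: 1, 3: 0}
CLASS_COLORS: dict[int, str] = {1: "green", 2: "yellow", 3: "red"}


def ukat_from_ul(value_ul: float) -> float:
    """Convert an enzyme activity from U/L to µkat/L (divide by 60)."""
    return value_ul / 60.0


class LabPanel(BaseModel):
    """One dated five-analyte measurement for one patient.

    ``trab``/``tpo`` (TSH-receptor and thyroid-peroxidase antibodies) are
    complementary tests: they never influence the class, only the rendered
    recommendation.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    sample_date: date
    tsh: Optional[float] = None
    ft4: Optional[float] = None
    ft3: Optional[float] = None
    ast: Optional[float] = None
    alt: Optional[float] = None
    trab: Optional[float] = None
    tpo: Optional[float] = None

    @field_validator("tsh", "ft4", "ft3", "ast", "alt", "trab", "tpo")
    @classmethod
    def _non_negative_finite(cls, v: Optional[float]) -> Optional[float]:
        if v is None:
            return v
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"analyte value must be finite and >= 0, got {v!r}")
        return v

    def value(self, analyte: str) -> Optional[float]:
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        return getattr(self, analyte)


class Grade(str, Enum):
    NORMAL = "normal"
    MINOR = "minor"
    DEFINITE = "definite"
    MISSING = "missing"


#: Severity ordering used when aggregating grades into a class.
_SEVERITY = {Grade.NORMAL: 0, Grade.MINOR: 1, Grade.DEFINITE: 2}


class AnalyteGrade(BaseModel):
    model_config = ConfigDict(frozen=True)

    analyte: str
    value: Optional[float]
    grade: Grade
    #: side of the reference interval the value falls on ("low", "high",
    #: or "none" for normal/missing); needed by the pattern rules.
    direction: Literal["low", "high", "none"] = "none"


class AnalyteRule(BaseModel):
    """Reference interval plus yellow/red banding for one analyte.

    Values in ``[reference_low, reference_high]`` are normal (endpoints
    inclusive).  Above the range, ``(reference_high, red_high]`` is the
    yellow band and ``(red_high, inf)`` the red band.  Below the range,
    ``[red_low, reference_low)`` is yellow and ``[0, red_low)`` red.
    ``red_low`` may be omitted only when ``reference_low`` is 0 (no values
    below the range exist, as for the transaminases).
    """

    reference_low: float = Field(ge=0)
    reference_high: float
    red_low: Optional[float] = None
    red_high: float

    @model_validator(mode="after")
    def _check_bands(self) -> "AnalyteRule":
        if not self.reference_low < self.reference_high:
            raise ValueError("reference_low must be < reference_high")
        if self.red_high < self.reference_high:
            raise ValueError("red_high must be >= reference_high")
        if self.red_low is None:
            if self.reference_low != 0:
                raise ValueError("red_low required when reference_low > 0")
        elif not 0 <= self.red_low <= self.reference_low:
            raise ValueError("red_low must lie in [0, reference_low]")
        return self

    def grade_value(self, value: float) -> tuple[Grade, str]:
        if self.reference_low <= value <= self.reference_high:
            return Grade.NORMAL, "none"
        if value > self.reference_high:
            return (Grade.MINOR if value <= self.red_high else Grade.DEFINITE), "high"
        # below the reference range
        if self.red_low is not None and value < self.red_low:
            return Grade.DEFINITE, "low"
        return Grade.MINOR, "low"


class RuleConfig(BaseModel):
    """Full rule table: per-analyte bands plus pattern-rule switches.

    The shipped default profile is a documented stand-in built from
    standard adult reference intervals; it is overridable wholesale via
    YAML (:meth:`to_yaml` / :meth:`from_yaml` round-trip losslessly).
    """

    profile: str = "default"
    analytes: dict[str, AnalyteRule]
    #: pattern rules evaluated on the graded panel, in priority order
    patterns: tuple[str, ...] = ("ait", "aih", "hepatotoxicity")
    #: months after treatment start during which isolated minor TSH/fT4
    #: deviations are tolerated as expected amiodarone effects
    early_treatment_grace_months: int = Field(default=3, ge=0)
    #: order antibodies on any abnormal thyroid analyte, or only at red level
    antibody_trigger: Literal["any_abnormal", "red_only"] = "any_abnormal"
    #: when False, a panel missing only fT3 is classified on four analytes
    strict_missing_ft3: bool = True

    @model_validator(mode="after")
    def _check_analytes(self) -> "RuleConfig":
        missing = set(ANALYTES) - set(self.analytes)
        if missing:
            raise ValueError(f"rule table missing analytes: {sorted(missing)}")
        unknown = set(self.analytes) - set(ANALYTES)
        if unknown:
            raise ValueError(f"rule table has unknown analytes: {sorted(unknown)}")
        return self

    def required_analytes(self) -> tuple[str, ...]:
        if self.strict_missing_ft3:
            return ANALYTES
        return tuple(a for a in ANALYTES if a != "ft3")

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RuleConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(text))


def default_profile() -> RuleConfig:
    """The shipped default rule table (see docs/methods.md for rationale).

    TSH 0.4–4.0 mIU/L with yellow 4.0–10 / red >10 toward hypothyroidism
    and yellow 0.1–0.4 / red <0.1 toward thyrotoxicosis; fT4 12–22 pmol/L;
    fT3 3.1–6.8 pmol/L; transaminase upper limits 0.76 (AST) and 1.1 (ALT)
    µkat/L with yellow up to 3× the limit and red beyond it.
    """
    return RuleConfig(
        profile="default",
        analytes={
            "tsh": AnalyteRule(reference_low=0.4, reference_high=4.0, red_low=0.1, red_high=10.0),
            "ft4": AnalyteRule(reference_low=12.0, reference_high=22.0, red_low=9.0, red_high=30.0),
            "ft3": AnalyteRule(reference_low=3.1, reference_high=6.8, red_low=2.3, red_high=10.0),
            "ast": AnalyteRule(reference_low=0.0, reference_high=0.76, red_low=None, red_high=3 * 0.76),
            "alt": AnalyteRule(reference_low=0.0, reference_high=1.1, red_low=None, red_high=3 * 1.1),
        },
    )


class Classification(BaseModel):
    model_config = ConfigDict(frozen=True)

    class_id: Literal[1, 2, 3]
    color: Literal["green", "yellow", "red"]
    interval_months: Literal[6, 1, 0]
    suspected_condition: Literal["none", "AIH", "AIT", "hepatotoxicity", "mixed"] = "none"
    recommendation: str = ""
    referral: Literal[
        "none", "physician_immediate", "endocrinologist", "primary_care", "gastroenterology_advice"
    ] = "none"
    order_antibodies: bool = False

    @model_validator(mode="after")
    def _check_bijection(self) -> "Classification":
        if CLASS_COLORS[self.class_id] != self.color:
            raise ValueError("class/color mismatch")
        if CLASS_INTERVALS[self.class_id] != self.interval_months:
            raise ValueError("class/interval mismatch")
        if self.class_id == 1 and (
            self.suspected_condition != "none" or self.referral != "none" or self.order_antibodies
        ):
            raise ValueError("class 1 must carry no condition, referral or antibody order")
        return self


class TechnicalError(BaseModel):
    """A robot output that is not class 1, 2 or 3 (e.g. missing analyte)."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    sample_date: date
    reason: str
    missing_analytes: tuple[str, ...] = ()


def grade_analyte(analyte: str, value: Optional[float], config: RuleConfig) -> AnalyteGrade:
    """Grade one analyte value against its configured bands.

    Returns ``missing`` for an absent value; raises on an unknown analyte
    or a negative/non-finite value.
    """
    if analyte not in config.analytes:
        raise KeyError(f"unknown analyte {analyte!r}")
    if value is None:
        return AnalyteGrade(analyte=analyte, value=None, grade=Grade.MISSING)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"invalid value for {analyte}: {value!r}")
    grade, direction = config.analytes[analyte].grade_value(value)
    return AnalyteGrade(analyte=analyte, value=value, grade=grade, direction=direction)


def _red_patterns(grades: dict[str, AnalyteGrade], panel: LabPanel, config: RuleConfig) -> list[str]:
    """Pattern rules firing at red (definite) level, in priority order."""

    def above_ref(a: str) -> bool:
        g = grades.get(a)
        return g is not None and g.grade in (Grade.MINOR, Grade.DEFINITE) and g.direction == "high"

    def below_ref(a: str) -> bool:
        g = grades.get(a)
        return g is not None and g.grade in (Grade.MINOR, Grade.DEFINITE) and g.direction == "low"

    fired: list[str] = []
    tsh = grades.get("tsh")
    if "ait" in config.patterns:
        if tsh is not None and tsh.grade is Grade.DEFINITE and tsh.direction == "low" and (
            above_ref("ft4") or above_ref("ft3")
        ):
            fired.append("AIT")
    if "aih" in config.patterns:
        if tsh is not None and tsh.grade is Grade.DEFINITE and tsh.direction == "high" and below_ref("ft4"):
            fired.append("AIH")
    if "hepatotoxicity" in config.patterns:
        if any(
            grades.get(a) is not None and grades[a].grade is Grade.DEFINITE for a in LIVER_ANALYTES
        ):
            fired.append("hepatotoxicity")
    return fired


def _yellow_condition(grades: dict[str, AnalyteGrade], config: RuleConfig, grace: bool) -> str:
    """Suspected condition for a class-2 panel (never changes the class)."""
    tsh = grades.get("tsh")
    if not grace and tsh is not None and tsh.grade is Grade.MINOR:
        if "ait" in config.patterns and tsh.direction == "low":
            return "AIT"
        if "aih" in config.patterns and tsh.direction == "high":
            return "AIH"
    if "hepatotoxicity" in config.patterns and any(
        grades.get(a) is not None and grades[a].grade is Grade.MINOR for a in LIVER_ANALYTES
    ):
        return "hepatotoxicity"
    return "none"


def classify_panel(
    panel: LabPanel,
    config: RuleConfig,
    months_on_treatment: Optional[int] = None,
) -> Classification | TechnicalError:
    """Map a laboratory panel to a three-class urgency classification.

    The class is the maximum severity over per-analyte grades; pattern
    rules firing at red level set the suspected condition and referral
    routing (AIT → endocrinologist, AIH → primary care, transaminase
    red → gastroenterology advice, otherwise immediate physician).

    During the first ``early_treatment_grace_months`` of treatment an
    isolated minor TSH and/or fT4 deviation is tolerated as an expected
    amiodarone effect and the panel stays class 1.  ``months_on_treatment
    = None`` means unknown and disables the grace (the safe default).

    A missing required analyte yields a :class:`TechnicalError`, the
    robot's non-1/2/3 output.
    """
    missing = tuple(a for a in config.required_analytes() if panel.value(a) is None)
    if missing:
        return TechnicalError(
            patient_id=panel.patient_id,
            sample_date=panel.sample_date,
            reason="missing required analyte(s)",
            missing_analytes=missing,
        )

    grades = {
        a: grade_analyte(a, panel.value(a), config)
        for a in ANALYTES
        if panel.value(a) is not None
    }
    max_sev = max(_SEVERITY[g.grade] for g in grades.values())
    red_fired = _red_patterns(grades, panel, config)

    in_grace = (
        months_on_treatment is not None
        and 0 <= months_on_treatment < config.early_treatment_grace_months
    )

    if max_sev == 2 or red_fired:
        class_id = 3
    elif max_sev == 1:
        class_id = 2
        if in_grace:
            # expected early-treatment perturbation: tolerate isolated
            # minor TSH/fT4 deviations (everything else normal)
            abnormal = {a for a, g in grades.items() if g.grade is not Grade.NORMAL}
            if abnormal <= {"tsh", "ft4"}:
                class_id = 1
    else:
        class_id = 1

    if class_id == 3:
        thyroid_red = [c for c in red_fired if c in ("AIT", "AIH")]
        liver_red = [c for c in red_fired if c == "hepatotoxicity"]
        if thyroid_red and liver_red:
            condition = "mixed"
        elif red_fired:
            condition = red_fired[0]
        else:
            condition = "none"
        referral = {
            "AIT": "endocrinologist",
            "AIH": "primary_care",
            "hepatotoxicity": "gastroenterology_advice",
        }.get(condition, "physician_immediate")
    elif class_id == 2:
        condition = _yellow_condition(grades, config, grace=in_grace)
        referral = "none"
    else:
        condition = "none"
        referral = "none"

    if class_id == 1:
        order_antibodies = False
    else:
        trigger = Grade.DEFINITE if config.antibody_trigger == "red_only" else Grade.MINOR
        order_antibodies = any(
            grades.get(a) is not None
            and _SEVERITY.get(grades[a].grade, 0) >= _SEVERITY[trigger]
            for a in THYROID_ANALYTES
        )

    cls = Classification(
        class_id=class_id,
        color=CLASS_COLORS[class_id],
        interval_months=CLASS_INTERVALS[class_id],
        suspected_condition=condition,
        referral=referral,
        order_antibodies=order_antibodies,
    )
    return cls.model_copy(update={"recommendation": render_recommendation(cls)})


_REFERRAL_TEXT = {
    "none": "No referral required.",
    "physician_immediate": "Refer directly to the responsible physician for immediate handling.",
    "endocrinologist": "Refer to an endocrinologist.",
    "primary_care": "Refer to primary care.",
    "gastroenterology_advice": "Seek gastroenterology advice.",
}


def render_recommendation(classification: Classification) -> str:
    """Deterministic written instruction for a classification.

    Identical input yields byte-identical output; the text names the
    class, interval, suspected condition and referral route.
    """
    c = classification
    lines = [f"Class {c.class_id} ({c.color})."]
    if c.class_id == 1:
        lines.append("Overall normal laboratory values. Next follow-up test in 6 months.")
    elif c.class_id == 2:
        lines.append(
            "Minor deviation from normal values of uncertain significance. "
            "Follow-up testing in 1 month."
        )
    else:
        lines.append(
            "Definite laboratory pathology indicating a clear side effect. "
            "Prompt management by a physician (0 months)."
        )
    if c.suspected_condition != "none":
        names = {
            "AIH": "amiodarone-induced hypothyroidism",
            "AIT": "amiodarone-induced thyrotoxicosis",
            "hepatotoxicity": "hepatotoxicity",
            "mixed": "combined thyroid and liver pathology",
        }
        lines.append(f"Suspected condition: {names[c.suspected_condition]}.")
    lines.append(_REFERRAL_TEXT[c.referral])
    if c.order_antibodies:
        lines.append("Order complementary TSH-receptor and thyroid-peroxidase antibodies.")
    return " ".join(lines)
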