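"""Paired-order evaluation: confusion matrix, interval comparison,
per-class agreement and side-effect response assessment.

The evaluation treats the rule engine ("robot") as ground truth and asks
how the physician's real-world follow-up orders compare.  Each lab event
yields one :class:`PairedOrder` — the robot's recommended interval and the
physician's ordered interval, in whole months.  Labels:

* the robot's own label is TP when its class is 2 or 3 (pathological) and
  TN when class 1 (normal);
* if the two intervals differ by at most one month the physician receives
  the robot's label;
* an interval more than one month *shorter* than the robot's is FP (the
  physician judged the case more urgent than ground truth);
* an interval more than one month *longer*, or a pathological result the
  physician did not notice at all, is FN — the unnoticed-pathology clause
  takes precedence over the interval tolerance.

Because the robot is ground truth, the matrix has only TP and TN actual
rows; FP and FN live in the predicted columns of those rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._stats import WilcoxonResult, wilcoxon_signed_rank
from .rules import CLASS_INTERVALS

__all__ = [
    "PairedOrder",
    "PairLabel",
    "ConfusionMatrix",
    "IntervalComparison",
    "SideEffectCase",
    "ResponseAssessment",
    "label_pair",
    "build_confusion_matrix",
    "compare_intervals",
    "per_class_agreement",
    "assess_response",
]

MAX_INTERVAL = 6


class PairLabel(str, Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


class PairedOrder(BaseModel):
    """One robot order and one physician order for the same lab event."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    sample_date: date
    robot_class: Literal[1, 2, 3]
    robot_interval_months: int
    physician_interval_months: int
    physician_noticed_pathology: bool = True

    @model_validator(mode="after")
    def _check(self) -> "PairedOrder":
        if self.robot_interval_months != CLASS_INTERVALS[self.robot_class]:
            raise ValueError(
                f"robot interval {self.robot_interval_months} inconsistent with "
                f"class {self.robot_class}"
            )
        if not 0 <= self.physician_interval_months <= MAX_INTERVAL:
            raise ValueError("physician interval must be in 0..6 months")
        return self


def label_pair(pair: PairedOrder) -> PairLabel:
    """Label one paired order (see module docstring for the rules)."""
    actual_positive = pair.robot_class in (2, 3)
    if actual_positive and not pair.physician_noticed_pathology:
        return PairLabel.FN
    d = pair.physician_interval_months - pair.robot_interval_months
    if abs(d) <= 1:
        return PairLabel.TP if actual_positive else PairLabel.TN
    return PairLabel.FP if d < -1 else PairLabel.FN


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts and row-proportions, robot (actual) × physician (predicted).

    Actual rows are limited to the robot's own true labels: the positive
    row splits into predicted TP/FN, the negative row into TN/FP.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def row_proportions(self) -> dict[str, dict[str, float]]:
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        return {
            "actual_positive": {
                "TP": self.tp / pos if pos else float("nan"),
                "FN": self.fn / pos if pos else float("nan"),
            },
            "actual_negative": {
                "TN": self.tn / neg if neg else float("nan"),
                "FP": self.fp / neg if neg else float("nan"),
            },
        }

    def to_dict(self) -> dict:
        return {
            "counts": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
            "row_proportions": self.row_proportions,
            "n": self.n,
        }


def build_confusion_matrix(pairs: Sequence[PairedOrder]) -> ConfusionMatrix:
    if not pairs:
        raise ValueError("cannot build a confusion matrix from an empty pair list")
    tally = {label: 0 for label in PairLabel}
    for p in pairs:
        tally[label_pair(p)] += 1
    return ConfusionMatrix(
        tp=tally[PairLabel.TP], fn=tally[PairLabel.FN], tn=tally[PairLabel.TN], fp=tally[PairLabel.FP]
    )


@dataclass(frozen=True)
class IntervalComparison:
    """Per-source interval statistics plus the paired signed-rank test."""

    n: int
    robot_mean: float
    robot_sd: float
    robot_median: float
    robot_iqr: tuple[float, float]
    physician_mean: float
    physician_sd: float
    physician_median: float
    physician_iqr: tuple[float, float]
    #: frequency of each ordered interval 0..6 months, per source
    robot_frequencies: dict[int, int]
    physician_frequencies: dict[int, int]
    wilcoxon: WilcoxonResult

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "robot": {
                "mean": self.robot_mean,
                "sd": self.robot_sd,
                "median": self.robot_median,
                "iqr": list(self.robot_iqr),
                "frequencies": {str(k): v for k, v in self.robot_frequencies.items()},
            },
            "physician": {
                "mean": self.physician_mean,
                "sd": self.physician_sd,
                "median": self.physician_median,
                "iqr": list(self.physician_iqr),
                "frequencies": {str(k): v for k, v in self.physician_frequencies.items()},
            },
            "wilcoxon": {
                "statistic": self.wilcoxon.statistic,
                "pvalue": self.wilcoxon.pvalue,
                "n_nonzero": self.wilcoxon.n_nonzero,
                "method": self.wilcoxon.method,
                "degenerate": self.wilcoxon.degenerate,
            },
        }


def _freq_table(values: Iterable[int]) -> dict[int, int]:
    table = {m: 0 for m in range(MAX_INTERVAL + 1)}
    for v in values:
        table[int(v)] += 1
    return table


def compare_intervals(pairs: Sequence[PairedOrder]) -> IntervalComparison:
    """Summarise robot vs physician intervals and test the paired shift.

    The Wilcoxon signed-rank test is two-sided, drops zero differences
    and uses mid-ranks; the null distribution is exact for n <= 25
    non-zero differences and a tie-corrected normal approximation beyond.
    When every difference is zero the statistic is undefined and p = 1 is
    reported with the degenerate flag set.
    """
    if len(pairs) < 2:
        raise ValueError("interval comparison needs at least 2 pairs")
    robot = np.array([p.robot_interval_months for p in pairs], dtype=float)
    phys = np.array([p.physician_interval_months for p in pairs], dtype=float)
    wc = wilcoxon_signed_rank(robot, phys, alternative="two-sided")

    def q(a: np.ndarray, p: float) -> float:
        return float(np.quantile(a, p))

    return IntervalComparison(
        n=len(pairs),
        robot_mean=float(robot.mean()),
        robot_sd=float(robot.std(ddof=1)),
        robot_median=float(np.median(robot)),
        robot_iqr=(q(robot, 0.25), q(robot, 0.75)),
        physician_mean=float(phys.mean()),
        physician_sd=float(phys.std(ddof=1)),
        physician_median=float(np.median(phys)),
        physician_iqr=(q(phys, 0.25), q(phys, 0.75)),
        robot_frequencies=_freq_table(robot.astype(int)),
        physician_frequencies=_freq_table(phys.astype(int)),
        wilcoxon=wc,
    )


def per_class_agreement(pairs: Sequence[PairedOrder]) -> pd.DataFrame:
    """Agreement breakdown by robot class.

    "True" counts pairs whose label equals the robot's own label (TP for
    classes 2–3, TN for class 1); "False" counts FP/FN discrepancies.
    """
    if not pairs:
        raise ValueError("per-class agreement needs at least one pair")
    rows = []
    for cls in (1, 2, 3):
        in_class = [p for p in pairs if p.robot_class == cls]
        if not in_class:
            continue
        own = PairLabel.TN if cls == 1 else PairLabel.TP
        n_true = sum(label_pair(p) is own for p in in_class)
        n_false = len(in_class) - n_true
        rows.append(
            {
                "robot_class": cls,
                "n": len(in_class),
                "n_true": n_true,
                "n_false": n_false,
                "prop_true": n_true / len(in_class),
                "prop_false": n_false / len(in_class),
            }
        )
    return pd.DataFrame(rows)


class SideEffectCase(BaseModel):
    """One laboratory-diagnosed side effect with the physician's actions.

    The four response criteria arrive as structured booleans:
    acknowledgement of the side effect, re-evaluation of the amiodarone
    indication, dose adjustment or discontinuation, and specialist
    referral/consultation.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str
    event_type: Literal["AIH", "AIT", "hepatotoxicity", "other"]
    robot_class: Literal[1, 2, 3]
    acknowledged: bool = False
    reevaluated: bool = False
    adjusted_or_stopped: bool = False
    referred: bool = False
    repeat_test_ordered: bool = False
    repeat_interval_months: Optional[int] = None


@dataclass(frozen=True)
class ResponseAssessment:
    case_id: str
    event_type: str
    robot_assessment: Literal["red", "other"]
    physician_assessment: Literal["correct", "questionable", "unclassifiable"]
    criteria_met: frozenset[str] = field(default_factory=frozenset)


def assess_response(case: SideEffectCase) -> ResponseAssessment:
    """Assess the response to a diagnosed side effect.

    The physician's response is correct (red) if at least one of the four
    criteria is met; questionable (yellow) if none is met but a repeat
    laboratory test was ordered; otherwise explicitly unclassifiable.
    The robot side is correct iff it output class 3 (red).
    """
    met = frozenset(
        name
        for name in ("acknowledged", "reevaluated", "adjusted_or_stopped", "referred")
        if getattr(case, name)
    )
    if met:
        phys = "correct"
    elif case.repeat_test_ordered:
        phys = "questionable"
    else:
        phys = "unclassifiable"
    return ResponseAssessment(
        case_id=case.case_id,
        event_type=case.event_type,
        robot_assessment="red" if case.robot_class == 3 else "other",
        physician_assessment=phys,
        criteria_met=met,
    )
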