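"""End-to-end pipeline: simulate a cohort, run surveillance, pair the
robot's confirmed orders with sampled physician orders, and evaluate.

All randomness flows from the single ``seed`` argument; two runs with
identical inputs and seed produce byte-identical evaluation outputs
(the manifest timestamp excluded).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from . import io
from .cohort import (
    CohortParams,
    PhysicianModel,
    generate_cohort,
    routine_schedule,
    sample_panels,
    sample_physician_orders,
)
from .evaluation import (
    PairedOrder,
    build_confusion_matrix,
    compare_intervals,
    label_pair,
    per_class_agreement,
)
from .rules import RuleConfig, default_profile
from .scheduler import SchedulingPolicy, run_surveillance

__all__ = ["run_pipeline"]


def run_pipeline(
    out_dir: Path | str,
    seed: int,
    params: Optional[CohortParams] = None,
    config: Optional[RuleConfig] = None,
    policy: Optional[SchedulingPolicy] = None,
    physician_model: Optional[PhysicianModel] = None,
) -> dict:
    """Run simulate → surveil → evaluate and write the full artifact set.

    Returns the evaluation summary as a dict (the same content written to
    ``intervals_summary.json`` plus the confusion matrix and pair count).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = (params or CohortParams()).model_copy(update={"seed": seed})
    config = config or default_profile()
    policy = policy or SchedulingPolicy(horizon_months=params.horizon_months)
    physician_model = physician_model or PhysicianModel()

    patients, specs = generate_cohort(params)
    spec_by_id = {s.patient_id: s for s in specs}
    panels = []
    for patient in patients:
        schedule = routine_schedule(patient.treatment_start_date, params.horizon_months)
        panels.extend(
            sample_panels(
                spec_by_id[patient.patient_id], schedule, params,
                treatment_start=patient.treatment_start_date, config=config,
            )
        )

    # accept-all decisions drive the surveillance schedule; the robot's
    # confirmed intervals are the "actual" side of each pair
    orders, worklist, ledger = run_surveillance(
        patients, panels, config, policy=policy, seed=seed
    )

    classified = [w for w in worklist if w.classification is not None]
    phys_orders = sample_physician_orders(
        [w.classification for w in classified], physician_model, seed=seed
    )
    pairs = [
        PairedOrder(
            patient_id=w.patient_id,
            sample_date=w.created_date,
            robot_class=w.classification.class_id,
            robot_interval_months=w.classification.interval_months,
            physician_interval_months=po.interval_months,
            physician_noticed_pathology=po.noticed_pathology,
        )
        for w, po in zip(classified, phys_orders)
    ]

    io.write_cohort(out / "cohort.csv", patients)
    io.write_panels(out / "panels.csv", panels)
    io.write_orders(out / "orders.csv", orders)
    io.write_worklist(out / "worklist.csv", worklist)
    io.write_ledger(out / "ledger.csv", ledger)
    io.write_pairs(out / "pairs.csv", pairs)

    summary: dict = {"n_pairs": len(pairs)}
    if pairs:
        labels = [label_pair(p).value for p in pairs]
        import pandas as pd

        io._write_df(
            pd.DataFrame(
                {
                    "patient_id": [p.patient_id for p in pairs],
                    "sample_date": [p.sample_date.isoformat() for p in pairs],
                    "label": labels,
                }
            ),
            out / "labels.csv",
            "labels",
        )
        cm = build_confusion_matrix(pairs)
        (out / "confusion.json").write_text(
            json.dumps(cm.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        summary["confusion"] = cm.to_dict()
        if len(pairs) >= 2:
            comparison = compare_intervals(pairs)
            (out / "intervals_summary.json").write_text(
                json.dumps(comparison.to_dict(), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            summary["intervals"] = comparison.to_dict()
        agreement = per_class_agreement(pairs)
        io._write_df(agreement, out / "per_class.csv", "per_class")
        summary["per_class"] = agreement.to_dict(orient="records")

    manifest = io.RunManifest(command="run", seed=seed)
    manifest.write(out / "manifest.json")
    return summary
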