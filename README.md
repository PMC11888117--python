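# amiomon

Rule-based laboratory triage and surveillance evaluation for amiodarone
side-effect monitoring.

Amiodarone, an iodine-rich antiarrhythmic with a biological half-life of
months, requires recurring thyroid and liver laboratory follow-up:
roughly 15% of patients develop adverse effects in the first year, most
often amiodarone-induced hypothyroidism (AIH, median onset ≈ 183 days),
amiodarone-induced thyrotoxicosis (AIT, median onset ≈ 720 days) and
transaminase elevation. `amiomon` is for clinical-informatics and
drug-safety researchers who want a tested, reusable implementation of an
automated monitoring process for this setting:

* **`amiomon.rules`** — a three-class triage over five analytes (TSH,
  fT4, fT3, AST, ALT). Class 1 (green) → retest in 6 months, class 2
  (yellow, minor deviation) → 1 month, class 3 (red, definite
  pathology) → immediate physician handling (0 months). Pattern rules
  flag AIT (TSH < 0.1 mIU/L with elevated free hormones →
  endocrinology), AIH (TSH > 10 mIU/L with low fT4 → primary care) and
  hepatotoxicity (transaminases > 3× the upper limit). Missing analytes
  yield an explicit technical-error outcome, never a default class.
* **`amiomon.scheduler`** — the surveillance loop over calendar time:
  orders, reminders, lapses, a human-in-the-loop decision queue, and an
  error ledger.
* **`amiomon.cohort`** — a synthetic longitudinal cohort generator
  (log-normal baselines matched to published median/IQR, injectable
  side effects with log-normal onset, a physician ordering-behavior
  model), so everything is testable without clinical data.
* **`amiomon.evaluation`** — paired-order analysis with the robot as
  ground truth: TP/TN/FP/FN labeling with a ±1-month tolerance, the
  confusion matrix, interval statistics with an exact Wilcoxon
  signed-rank test, per-class agreement, and side-effect response
  assessment.

See `docs/methods.md` for the model, parameter defaults and their
rationale.

## Worked example

```python
from datetime import date
from amiomon import LabPanel, classify_panel, default_profile

panel = LabPanel(
    patient_id="P17", sample_date=date(2023, 3, 6),
    tsh=0.04,   # mIU/L  — deeply suppressed
    ft4=27.5,   # pmol/L — above the 12–22 reference range
    ft3=8.1,    # pmol/L — above the 3.1–6.8 reference range
    ast=0.52, alt=0.61,  # µkat/L — normal
)
c = classify_panel(panel, default_profile())
print(c.class_id, c.color, c.interval_months, c.suspected_condition, c.referral)
print(c.recommendation)
```

prints

```
3 red 0 AIT endocrinologist
Class 3 (red). Definite laboratory pathology indicating a clear side effect. Prompt management by a physician (0 months). Suspected condition: amiodarone-induced thyrotoxicosis. Refer to an endocrinologist. Order complementary TSH-receptor and thyroid-peroxidase antibodies.
```

The suppressed TSH with elevated free hormones matches the thyrotoxic
pattern: class 3 (red), a zero-month interval (straight to the
physician), endocrinology referral and a complementary antibody order.

The same logic is available from the shell; an end-to-end synthetic run
(simulate → surveil → pair → evaluate) is:

```sh
amiomon run --seed 1 --out-dir out/
```

which writes `cohort.csv`, `panels.csv`, `orders.csv`, `worklist.csv`,
`ledger.csv`, `pairs.csv`, `labels.csv`, `confusion.json`,
`intervals_summary.json`, `per_class.csv` and a run manifest.
Subcommands `simulate`, `classify`, `surveil` and `evaluate` run the
stages individually.

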