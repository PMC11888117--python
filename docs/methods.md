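# Methods

## The triage model

Amiodarone surveillance monitors five analytes — TSH (mIU/L), free T4 and
free T3 (pmol/L), AST and ALT (µkat/L) — on a recurring laboratory
schedule. `amiomon` reproduces a rule-based classifier over such panels
with three color-coded urgency classes and a fixed class→interval
bijection:

| class | color  | meaning                         | next test |
|-------|--------|---------------------------------|-----------|
| 1     | green  | overall normal values           | 6 months  |
| 2     | yellow | minor deviation, unclear import | 1 month   |
| 3     | red    | definite laboratory pathology   | 0 months (straight to physician) |

Each analyte is graded against a reference interval flanked by a yellow
band (minor) and a red band (definite); the panel class is the maximum
severity over grades. Pattern rules set the suspected condition and the
referral route on red panels:

* **AIT** (amiodarone-induced thyrotoxicosis): TSH suppressed below the
  red threshold with free T4 or free T3 above reference → endocrinology.
* **AIH** (amiodarone-induced hypothyroidism): TSH above the red
  threshold with free T4 below reference → primary care.
* **Hepatotoxicity**: AST or ALT above three times the upper reference
  limit → gastroenterology advice.

When several patterns fire at red level the condition priority is
AIT > AIH > hepatotoxicity (AIT being the most treatment-resistant), and
`mixed` is recorded when both a thyroid and a liver pattern fire. Red
panels without a firing pattern (e.g. isolated TSH suppression with
normal free hormones) route to the physician directly with no named
condition. Any abnormal thyroid analyte triggers a complementary
antibody order (TRAb/TPO); a config switch restricts this to red-level
abnormality. Antibody values themselves never influence the class.

A panel missing a required analyte yields an explicit `TechnicalError` —
the operational definition of a robot error is any output that is not
class 1, 2 or 3 — and is never silently defaulted. Whether a missing
free T3 alone is an error is configurable (`strict_missing_ft3`,
default strict).

### Default rule table

Supplementary threshold tables for the deployed system are not public,
so the shipped `default` profile is a documented stand-in built from
standard adult reference intervals in the same units, overridable
wholesale via YAML:

* TSH 0.4–4.0 mIU/L; 4.0–10 yellow, >10 red (hypothyroid direction);
  0.1–0.4 yellow, <0.1 red (thyrotoxic direction);
* fT4 12–22 pmol/L, yellow 9–12 and 22–30, red beyond;
* fT3 3.1–6.8 pmol/L, yellow 2.3–3.1 and 6.8–10, red beyond;
* AST ≤0.76, ALT ≤1.1 µkat/L; up to 3× the limit yellow, >3× red. The
  3× rule separates the common mild transaminase elevation on amiodarone
  (roughly a quarter of patients) from overt hepatotoxicity.

Reference-range endpoints are inclusive (a value exactly at the limit is
normal), avoiding spurious yellow classifications from rounding. An
I/O-level helper converts transaminases from U/L to µkat/L (÷60); the
rule table itself is single-unit.

### Early-treatment grace

Amiodarone transiently perturbs thyroid indices early in treatment. For
the first `early_treatment_grace_months` (default 3) an *isolated* minor
TSH and/or fT4 deviation — nothing else abnormal, nothing definite — is
tolerated and the panel stays class 1. Unknown treatment duration
disables the grace (the safe default), and definite pathology is never
blunted.

## Surveillance workflow

`run_surveillance` replays the monitoring loop per patient: tests at 3
and 6 months after treatment start, thereafter at the interval confirmed
for the previous result. An order is resulted by the first unconsumed
panel dated within its 14-day sampling window; otherwise a reminder goes
out 14 days after the due date, and 60 days later the order lapses and
is reissued. Every resulted order yields exactly one worklist item
carrying the classification; class-3 items are flagged for immediate
attention. The decision step (`decide`) is accept-all by default —
confirming the robot's interval, with a 1-month retest for
technical-error items — or draws from a physician behavior model. The
next order is issued at decision date + confirmed interval, with the
start-up exception that the second test is due no later than 6 months
after treatment start. Patients who stop treatment remain under
surveillance for 12 further months (the drug's half-life extends to
months), configurable. The error ledger records the cumulative
technical-error proportion at every classification date.

Time is whole days; scheduling months are calendar months with
day-of-month clamping. The loop is a pure function of (inputs, seed).

## Synthetic cohort

No surveillance data is public, so the generator emulates the study
conditions:

* **Baselines** per analyte are log-normal with the cohort's median/IQR
  (TSH 1.9 (1.3–2.8) mIU/L, fT4 15 (13–17) pmol/L, AST 0.44 (0.36–0.56),
  ALT 0.40 (0.29–0.63) µkat/L; fT3, unreported, uses 4.9 (4.2–5.6)
  pmol/L), clamped into the reference interval: surveillance baselines
  are screened-normal, and clamping (unlike truncation-resampling)
  preserves the configured median exactly. The price is a small
  probability atom at the range limits, which with measurement noise
  produces occasional borderline yellow panels — a realistic feature.
* **Measurement noise** is multiplicative log-normal with CV 5% per
  analyte (typical combined analytical + within-person variation at
  this granularity).
* **Events**: each patient draws at most one side effect with
  per-patient probabilities over the horizon (defaults AIH 0.04,
  AIT 0.03, hepatotoxicity 0.02 — desk-scale values inside the wide
  published incidence ranges). Time-to-onset is log-normal with medians
  183 d (AIH), 720 d (AIT) and 90 d (hepatotoxicity, a choice: mild
  hepatic effects appear early) and log-sigma 0.85, making the IQR span
  roughly half an order of magnitude (only medians are published).
  Onsets are drawn unconditionally; an onset beyond the horizon simply
  never manifests, so recovered onset medians are unbiased.
* **Displacement**: from the onset day, affected analytes take
  deterministic values computed from the rule table — `definite`
  severity beyond the red threshold, `minor` in the interior of the
  yellow band — so a definite event is classified red at the first
  post-onset panel with probability 1 by construction. Per-event
  severities and magnitudes are unpublished; these are simulation
  choices, and the sensitivity property they guarantee mirrors the
  observed all-events-detected behavior as a property, not a count.
* **Physician behavior**: intervals are drawn conditional on the robot
  class. The class-1 default puts mass 0.30 at 3 months and 0.28 at
  4 months (the observed clustering for normal results), 0.10 at
  6 months, remainder over 1, 2 and 5. Definite pathology is missed
  with probability 1/3 (4 of 12 in the study), in which case a 1–3-month
  repeat test is ordered instead of an immediate response.

What the generator does **not** emulate: comorbidity-dependent risk,
dose effects, within-patient autocorrelated drift, laboratory
calibration shifts, or more than one event per patient. Passing tests
therefore demonstrate correctness of the algorithmic machinery under
controlled conditions, not clinical performance on real data.

## Evaluation

Pairs of (robot order, physician order) for the same lab event are
labeled with the robot as ground truth: the robot's own label is TP for
class 2–3 and TN for class 1; a physician interval within ±1 month
(inclusive) inherits that label; more than 1 month shorter is FP, more
than 1 month longer is FN, and unnoticed pathology forces FN regardless
of interval. A class-2 pair with a 0-month physician order has d = −1
and is therefore TP. The confusion matrix is restricted to TP/TN actual
rows by construction, with FP/FN as the discordant predicted columns.

The interval comparison reports mean/SD, median/IQR and the 0–6-month
frequency table per source plus a two-sided Wilcoxon signed-rank test:
zero differences dropped, mid-ranks on ties, exact null distribution
(dynamic programming over doubled ranks) for ≤25 non-zero differences,
tie-corrected normal approximation (no continuity correction) beyond.
If all differences are zero the statistic is undefined and p = 1 is
reported with a degenerate flag. P-values are single pre-specified
comparisons; no multiplicity correction.

Side-effect responses are assessed from four structured criteria
(acknowledgement, indication re-evaluation, dose adjustment/stop,
specialist referral): any criterion met → correct (red); none met but a
repeat test ordered → questionable (yellow); neither → explicitly
unclassifiable. The robot side is correct iff it output class 3.

## Numerical and design choices

* All randomness flows from a single integer seed; per-patient panel
  noise uses a (seed, CRC32(patient id)) stream so cohorts are
  byte-identical across runs and insensitive to patient ordering.
* Exact signed-rank probabilities are integer-count ratios over 2^n, so
  they match full sign enumeration to floating-point exactness.
* Problem sizes: the default pipeline uses the cohort's scale (198
  patients, 24-month horizon ≈ 1,000 panels); parameter-recovery checks
  use n = 10,000 patients; grid oracles enumerate all 294 pair-label
  combinations. These sizes keep every check deterministic and
  desk-scale while leaving Monte-Carlo error well inside the stated
  tolerances.
* Known limitations: the default rule table is a stand-in, not a claim
  about any deployed system; AIT type 1 vs type 2 is not
  differentiated; no dosing, imaging or free-text handling; the
  scheduler models an event-driven robot rather than a polling cadence.
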