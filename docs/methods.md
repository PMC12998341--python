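# Methods

## Time model

All timing is month-granular: claims carry a billing year/month and the
linkage gives the child's birth year/month. Months are encoded as
`year*12 + (month-1)`; observation windows are half-open `[start, end)`
and default to 2014-04 through 2023-01 inclusive (`end = 2023-02`),
matching the extract period the reference conditions describe. Ages are
completed years from month arithmetic — a woman born 1990-04 turns 30 in
2020-04 — which is the finest resolution a month-granular extract allows.

## Code sets and matching

Diagnosis matching is by ICD-10 three-character category: full codes
normalise by stripping dots and truncating to three characters, so O80.1,
O801 and O80 all match through category O80. The default diagnosis set is
the explicit expansion of the childbirth category ranges (34 categories);
the preterm-exclusion subset defaults to {O45, O60, O69} (placental
abruption, preterm labour, cord complications), whose removal defines the
preterm-excluded conditions. Rationale: preterm deliveries systematically
shift code timing relative to a term reference and dilute month agreement.
The Z37–38 block (delivery outcome / liveborn infant) is included as
written; "Z37–8" style block notation is read as Z37–Z38.

Procedure and medication codes are opaque exact-match strings supplied via
YAML/JSON config (`diagnosis_ranges`, `preterm_exclusion`,
`procedure_codes`, `medication_codes`; omitted keys fall back to
defaults). The shipped defaults (`PROC_*`, `MED_*`) are deliberately
synthetic placeholders for the simulator: real fee-schedule values are
jurisdiction-specific and belong in user configuration, not package
constants.

## Detection semantics

The six conditions are evaluated per woman. [A+susp] is read as
"suspected flag *permitted*" — flagged and unflagged diagnosis lines both
qualify — and [A] as "unflagged only", so [A] months are always a subset
of [A+susp] months. This superset reading is the only one under which the
flagged variant can have the higher sensitivity that motivates it (a
rule-out flag adds candidate lines; it cannot subtract).

AND combinations are satisfied at the woman level by default: each
condition must hold somewhere in the window, not in the same billing
month, because one delivery's diagnosis, procedure and medication lines
routinely post in different months (admission vs discharge vs pharmacy).
A `same-month` mode is provided for sensitivity analysis; it requires the
whole expression within one billing month and dates the event to the
latest satisfying month.

When an algorithm fires, the event month is the **maximum** over the
union of qualifying months of every referenced, non-empty condition —
including for OR expressions. The discharge convention means claims may
trail the birth month by one, which the matching tolerance absorbs:
reference month = algorithm month or algorithm month − 1, asymmetric by
construction (claims may lag a birth; they cannot precede a birth they
bill for, and prepartum codes are handled as dating noise, not tolerance).

## Gold standard

Eligible population: husband-identified women (without the husband's
insurance linkage, a child may attach only to the father and the mother's
linkage silently fail, deflating PPV/sensitivity estimates). A linked
birth qualifies if it lies in the window and the mother is 15–49 in
completed years in that month; age eligibility is evaluated per birth, so
a woman with births on both sides of the boundary contributes only the
qualifying ones. The "time of parent–child ID assignment" is
operationalised as the child's birth month — the only month-granular
anchor the linkage provides. Women whose every linked birth fails the age
filter remain eligible gold-negatives, flagged `age_ineligible`; women
with several qualifying births contribute their most recent as
`gold_month`, with the full history retained for the second-birth
analysis. Stillbirths and abortions never appear: the linkage is assigned
only for live births, and the simulator never links them.

A structural consequence used as a test invariant: TP+FN and TN+FP are
constant across algorithms on a fixed dataset, because the margins come
from the gold standard alone. This also forces the classification rule
for detected-but-mismatched gold-positives: they are FN (a dating
failure), never FP.

## Metrics

Sensitivity, specificity, PPV and NPV are the usual ratios; Cohen's κ
uses observed agreement p₀ = (TP+TN)/n against the two-margin product
expectation pₑ; Youden J = sensitivity + specificity − 1 holds to machine
precision by construction. Binomial CIs default to the Wald normal
approximation clipped to [0,1] — at the reference cohort's denominators
(tens of thousands and up) Wald and Wilson agree to the reported decimal,
and Wald reproduces every published CI column; Wilson is available via
`ci_method="wilson"` for small-sample use. Report output rounds half-up:
percentages to one decimal, κ/Youden to two. Internal values are never
rounded. Zero-denominator metrics are NaN ("undefined"), not errors: an
algorithm detecting nobody has no PPV.

## Second-birth washout scan

Population: eligible women with ≥1 qualifying linkage birth. The anchor
is the earliest *linkage* birth (not the algorithm-detected first birth):
anchoring on the reference isolates the washout question from first-birth
detection error; an algorithm-anchored mode would conflate the two. A
woman is second-birth positive with ≥2 qualifying births; the matched
reference is her second-earliest birth by default (`reference="latest"`
selects the most recent instead — with more than two births the two
disagree, and the second is the event a 2–24-month washout is probing
for). Detection applies the algorithm to claims at or after
`first + k` months and dates the event to the **earliest** qualifying
month there — the next distinct event after the washout; latest-month
dating would alias third births. Matching reuses the one-month tolerance
unchanged, and each k's confusion table goes through the same metrics
code path as the first-birth validation. The scan reports all k in 2–24
and flags the k with the highest Youden index, ties broken toward the
smaller washout (prefer the least data discarded when performance is
equal).

Two monotonicities hold structurally and are tested: specificity is
non-decreasing in k (a longer washout can only remove detections among
second-negatives), and sensitivity eventually falls once k exceeds
realised inter-birth gaps.

## Synthetic claims generator

The generator emulates the structure a claims-only childbirth algorithm
confronts; defaults are the reference study conditions, chosen once:

| parameter | default | meaning |
|---|---|---|
| `n_women` | 100,000 | cohort size (scaled from the 854,626-woman reference for routine runs) |
| `p_husband_identified` | 1.0 | the validation cohort is husband-identified by construction |
| `age_bands` | 1.0/8.6/24.1/34.7/24.7/6.6/0.3% over 15–19…45–49 | maternal age at birth |
| `birth_rate` | 4.4% | women with ≥1 birth in window |
| `p_second_birth` | 0.30 | second birth given a first |
| `gap_mean/sd/min` | 24 / 6 / 10 months | inter-birth gap, normal rounded and floored at `gap_min` |
| `p_silent_birth` | 0.30 | birth leaves no claim (uncovered normal delivery) |
| `p_dx/p_proc/p_med` | 0.80 / 0.50 / 0.55 | per-birth domain emission, independent |
| `p_suspected` | 0.10 | suspected flag per diagnosis line (doubled for noise lines — rule-out workups) |
| `p_discharge_shift` | 0.30 | main claims post in birth month + 1 |
| `echo_prepartum` | 0.20/month, months −9…−1 | prenatal-visit diagnosis repeats |
| `echo_postpartum` | 0.12 / 0.05 / 0.03 at +1/+2/+3 | postpartum-check repeats |
| `fp_rate` | 10⁻⁴/month | childbirth-set diagnosis noise in non-birthing women |

Emission probabilities were set so that, under the silent-birth fraction,
an OR-of-everything algorithm lands in the sensitivity band observed on
real claims (low 60s %) with specificity ≈ 99% — a plausibility target,
not a calibration to any published row. Non-birthing women's own ages are
drawn uniformly over 15–69 at window start (the broad insured population;
only maternal age at birth carries a realistic distribution because only
it enters the pipeline). Domains are emitted independently per birth,
which is what makes the closed-form oracle possible; real claims correlate
domains (a caesarean implies uterotonics), so simulated AND-algorithm
sensitivities are conservative relative to real data. Claims falling
outside the observation window are dropped, as in a real extract — births
in the final window month whose shifted claims fall outside are therefore
slightly under-detected (≈0.3% absolute), a real-data edge effect the
simulator shares.

What passing synthetic tests does **not** show: performance on real
claims with correlated domains, miscoded or jurisdiction-specific code
values, insurance switching, or linkage misassignment. The simulator
validates the pipeline's logic and its statistical behaviour under known
truth, not any specific database's operating characteristics.

### Closed-form sensitivity oracle

With independent domain emission, single births, and postpartum echoes
confined to the +1 matching window, every detected birthing woman is also
correctly dated, so sensitivity factorises:
`(1 − p_silent) · Σ_assignments P(assignment) · [expression true]` over
the 2³ domain-presence assignments. The oracle deliberately refuses
configurations outside this regime (second births, later echoes,
preterm-excluded conditions, or [A] with flags on) rather than
approximating them — it exists to be trusted in recovery tests, where
observed sensitivities at n = 100,000 sit within 3 Monte-Carlo standard
errors of it.

## Problem sizes and numerical choices

Routine validation and the bundled test suite run at 10³–10⁵ women —
detection is fully vectorised (per-condition groupby aggregates plus
boolean algebra over arrays), so a 100,000-woman, 32-algorithm validation
completes in seconds. Half-up decimal rounding (not banker's) matches
standard clinical-table presentation. The washout-property cohort uses
postpartum echoes ≤ 3 months, inter-birth gaps ≥ 18 months and no
prepartum echoes: prenatal-visit repeats interact with earliest-month
second-event dating (they pull the detected date into the pregnancy),
which is a dating limitation orthogonal to the washout-length question
the scan answers. With them on, the Youden-optimal washout migrates
upward as k trims prenatal months — visible in the default-parameter scan
and worth knowing before interpreting an optimal k on real data.

## Known limitations

* Month granularity: day-level admission/discharge structure and
  within-month event ordering are invisible.
* Live births only: the linkage cannot validate algorithm behaviour on
  stillbirths, miscarriages or abortions, where procedure/medication
  codes may still occur (a real false-positive channel the simulator
  only approximates through generic noise).
* Claims-only ceiling: silent uncovered deliveries bound attainable
  sensitivity regardless of algorithm.
* The 32-algorithm roster is fixed Boolean logic; no code-frequency
  weighting or episode grouping is attempted.
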