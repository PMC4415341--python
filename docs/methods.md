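# Methods

## Problem and approach

Administrative health data — hospital discharge abstracts, physician
billing claims, and ambulatory/emergency-department records coded in
ICD-9-CM and ICD-10(-CA) — allow population-scale surveillance of chronic
disease and multimorbidity without chart review.  `morbiscan` implements a
panel of 30 validated case-definition algorithms as a deterministic rule
engine.  Each condition is defined by

* a diagnosis-code set (ICD-9-CM and ICD-10 patterns),
* one or more *evidence rules*, combined by OR — each of the form
  "N records from one source stream within window W", optionally restricted
  by diagnosis role (most responsible / post-admit), provider specialty,
  emergency-department setting, or absence of surgery,
* optional exclusions (person-level veto codes, record-level conditional
  carve-outs, surgery-procedure taints), and
* a permanence class: permanent conditions are present continuously from
  the index date; remitting conditions lapse when no relevant code is seen
  for 2 or 5 years.

The index date is the date of the first code of the earliest qualifying
evidence set, minimized over rules.  Chronic kidney disease additionally
has a laboratory pathway (below); the combined definition is
administrative OR laboratory, indexed at the earlier pathway.

## Code matching

Codes are normalized to upper-case, dotless strings.  Matching is by
**prefix**: pattern `250` matches `2500`, `25001`, and any other
descendant.  This is the only consistent semantics when published lists mix
3-digit stems with 5-digit codes and when real data carry 4–6 character
codes (ICD-10-CA adds digits to ICD-10; those descendants match the same
stems).  Prefix matching is deliberately inclusive and is documented here
because it affects sensitivity.  Two refinements exist:

* a single-character wildcard (`433?1`, from printed forms like "433.x1"),
  and
* an *exact* flag for list entries explicitly not meant to generalize
  (the decompensation entry 567.2 must not match 567.22/567.23).

Exclusion codes use the identical matcher.

## Window arithmetic

"Within 2 years" is interpreted as: the last record of the evidence set
falls on or before the **calendar anniversary** of the first
(`first + 2 years`, inclusive).  Calendar anniversaries are leap-year
stable and match how "years" reads clinically.  A configuration switch
(`WindowConvention.DAYS`) implements the fixed day-count alternative
(365 days per year, 30 days per month); the two conventions differ only at
boundary dates, and both boundaries are exercised in the acceptance suite.
Day windows ("within 30 days") are day counts under both conventions.

Records on the same service date count **once** toward a multi-record
rule.  The requirement of distinct service dates guards against
double-billing artifacts; published claims-validation work conventionally
requires distinct dates, and the evaluator enforces it for every rule,
including the kidney-disease 3-claims-in-1-year rule.

Evidence is never pooled across source streams inside one rule: "2
hospitalizations or 2 claims or 2 ambulatory records in 6 months" is three
parallel rules, each drawing only on its own stream.

## Exclusion semantics

Three mechanisms with different scope:

* **Unconditional exclusions** (irritable bowel syndrome, severe
  constipation) are person-level screens: an exclusion code anywhere in the
  person's history — within the active source set — vetoes the condition.
* **Conditional carve-outs** ("560.9 if 789.01/789.02/789.06"; "K56.6 if
  R10.1") void only the co-occurring diagnosis on that record; other
  qualifying codes on the same record still count.
* **Surgery taints**: for rules marked "without surgery", a hospitalization
  carrying a configured surgery procedure code cannot serve as evidence,
  but does not veto the person.  The source procedure classification list
  is site-specific, so the shipped registry leaves it empty;
  `with_surgery_procedures()` injects a deployment's own list.

Hepatic decompensation is encoded as an auxiliary severity set on
cirrhosis, not a 31st condition: cirrhosis is ascertained from the
cirrhosis codes alone, and `evaluate_aux` flags decompensation when any
decompensation code (with its 567.81/567.82/789.51 carve-outs) appears.

## Laboratory criteria for chronic kidney disease

Present when some 12-month window holds **at least two** measurements of
one analyte whose mean crosses the threshold: mean eGFR < 60 mL/min/1.73 m²
or mean urine ACR > 30 mg/g (strict inequalities).  A single measurement is
never a "mean over 12 months".  Windows are realized as runs of consecutive
measurements spanning ≤ 12 months; the index date is the first measurement
date of the earliest qualifying window.  Inpatient/outpatient provenance of
laboratory results is not distinguished.

## Remission and period activity

Remitting conditions stay active while the most recent relevant code on or
before *t* is within `remission_years` of *t* — a closed interval, so the
condition is still active exactly at `last code + remission_years` and
inactive one day later.  Relevant codes are *all* matching codes in the
active source set, regardless of role/specialty restrictions, whether or
not they belonged to the qualifying evidence set.

A condition counts toward a reference period (e.g. a fiscal year) when its
active interval overlaps the period by at least one day.  Age for the age
tabulations is computed at the period start.

## Synthetic cohorts and what they do (not) show

The generator plants, per person and condition, a CASE (a chain minimally
satisfying one randomly chosen rule: exactly `min_count` records, span
strictly inside the window), a NEAR_MISS (violating exactly one
requirement: one record short, one day past the window, wrong role, wrong
specialty, or surgery-tainted), or an EXCLUDED_CASE (qualifying chain plus
an exclusion code).  Defaults, chosen once as plausible study conditions:
0.04 CASE probability per condition, 0.02 for near-misses and excluded
cases, 1 non-matching singleton noise code per person-year, 0.3
normal-range laboratory results per person-year, ages from a mixture
(65% uniform 18–55, 35% uniform 50–90) with a multiplicative
`exp((age−50)/30)` relative risk renormalized so the marginal prevalence
stays at its target — multimorbidity therefore rises with age while
per-condition planted shares remain binomial around the configured value.

Recoverability is guaranteed by construction: evidence codes are
instantiated to full-length descendants that match no other condition's
code set (the four legitimately shared code families are never planted);
noise codes match no include, exclusion, companion, or auxiliary pattern;
condition pairs whose code sets would fire each other's exclusions are
never co-planted in one person; and persons with planted kidney-disease
chains receive no extra laboratory noise, so planted window means are
never diluted.  Truth is defined with respect to ascertainment over all
three sources plus laboratories.

These cohorts exercise the *logic* of the algorithms — windows, roles,
specialties, exclusions, boundaries — exhaustively.  They do not emulate
real coding behaviour: no miscoding, no transfer/readmission structure, no
correlated comorbidity beyond the age effect, no billing idiosyncrasies.
Perfect recovery on synthetic data therefore validates the implementation,
not the diagnostic performance of the algorithms on real data, which is
the subject of the underlying validation literature.

## Problem sizes and numerical choices

The acceptance suite runs the rule evaluator against a brute-force
subset-enumeration oracle on >10,000 random small histories (≤12 records)
covering every distinct rule shape under both window conventions; boundary
chains at window and window+1 day for every windowed rule; a 5,000-person
synthetic cohort for exact planted-truth recovery; and a 600-person cohort
for source monotonicity.  The acceptance script uses a 3,000-person cohort.
These sizes give every condition hundreds of planted chains while keeping
a full run in seconds to minutes on one CPU.

Ties are broken deterministically throughout: histories are sorted by
(date, record id); among equally early evidence sets the first rule in
registry order is reported; results are invariant to input record order
(property-tested).  Percentages are computed from integer counts and
rounded once to one decimal.

## Known limitations

* The surgery-procedure list ships empty (see above); until configured,
  "without surgery" rules treat every hospitalization as non-surgical.
* Claims in some jurisdictions truncate ICD-9 codes to three digits; prefix
  matching tolerates this, but the sensitivity implications are not
  modelled.
* The hospitalization date column is interpreted by the caller (admission
  date recommended); windows use that single date.
* Exclusion screens are evaluated over the person's full available history
  within the active source set; with short data extracts, exclusions may be
  missed.
* The engine is single-threaded and in-memory; cohorts of a few hundred
  thousand persons are feasible, but no out-of-core path is provided.
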