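# morbiscan

Chronic-condition ascertainment and multimorbidity measurement from coded
administrative health data.

Researchers studying multimorbidity — the coexistence of two or more
chronic conditions in one person — need a reproducible way to decide, from
hospital discharge abstracts, physician billing claims, ambulatory-care
records, and laboratory results, *which* conditions each person has and
*since when*.  `morbiscan` implements a panel of 30 validated
case-definition algorithms (16 of high validity, 14 of moderate validity,
graded by the positive predictive value and sensitivity of their source
validation studies) as a deterministic temporal rule engine, together with
multimorbidity summaries and a synthetic-cohort generator so every
behaviour is testable without access to real health data.

## The model

Each condition *c* is defined by a diagnosis-code set 𝒞(ICD-9-CM ∪ ICD-10)
and a disjunction of evidence rules

&nbsp;&nbsp;&nbsp;&nbsp;rule = (source *s*, count *n*, window *W*, restrictions),

read as "*n* records from stream *s* on distinct service dates spanning at
most *W*" — e.g. asthma is `1 hospitalization ∨ 3 ambulatory visits within
2 years` over codes {493, J45}.  Restrictions cover diagnosis role (most
responsible / post-admit), provider specialty, emergency-department
setting, and "without surgery".  The index date is the first date of the
earliest qualifying evidence set; codes match by prefix on dotless,
upper-cased strings (pattern `250` matches `25001`).  Conditions are
*permanent* (present from index onward) or *remitting* (active until 2 or
5 years after the last relevant code, closed interval).  Chronic kidney
disease adds a laboratory pathway — a 12-month window with ≥2 measurements
whose mean eGFR < 60 mL/min/1.73 m² or mean ACR > 30 mg/g — combined with
the administrative rules by OR and indexed at the earlier pathway.
Person-level exclusion codes veto a condition; record-level carve-outs
("560.9 if 789.01") void only the co-occurring record.

The registry of all 30 definitions ships as a single audited JSON file
(`src/morbiscan/data/registry_tonelli30.json`) with per-row provenance;
`docs/registry_audit.md` maps every printed code token to its expanded
patterns, and `docs/methods.md` documents the modelling choices.

## Worked example

A person with one asthma claim in 2006 and three ambulatory visits in
2007–2008:

```python
import datetime as dt
from morbiscan import load_default_registry
from morbiscan.codes import normalize
from morbiscan.engine import SourceSet, ascertain
from morbiscan.records import Diagnosis, EncounterRecord, build_histories

reg = load_default_registry()
records = [
    EncounterRecord("v1", "pt-07", dt.date(2006, 11, 3), "CLAIM",
                    (Diagnosis(normalize("J45.9", "ICD10")),)),
    EncounterRecord("v2", "pt-07", dt.date(2007, 5, 20), "AMBULATORY",
                    (Diagnosis(normalize("J45", "ICD10")),)),
    EncounterRecord("v3", "pt-07", dt.date(2008, 2, 14), "AMBULATORY",
                    (Diagnosis(normalize("J45.0", "ICD10")),)),
    EncounterRecord("v4", "pt-07", dt.date(2008, 9, 1), "AMBULATORY",
                    (Diagnosis(normalize("J45.1", "ICD10")),)),
]
histories, _ = build_histories(records)
res = ascertain(histories["pt-07"], reg["asthma"], SourceSet())
print(f"present={res.present} index={res.index_date} rule={res.satisfied_rule}")
print(f"evidence={res.supporting_record_ids}")
```

prints

```
present=True index=2007-05-20 rule=accs-3-in2y
evidence=('v2', 'v3', 'v4')
```

The 2006 claim alone cannot establish asthma (no claims rule exists for
it), but the three ambulatory visits fall within two years of the first,
so asthma is ascertained with index date 2007-05-20 — the date of the
first record of the qualifying chain — and the person counts as asthmatic
for all later reference periods (asthma is permanent).

## Command line

```sh
morbiscan validate                      # audit the shipped registry
morbiscan synth --n 5000 --seed 42 --out cohort/
morbiscan ascertain \
    --encounters cohort/encounters.csv --labs cohort/labs.csv \
    --demographics cohort/demographics.csv \
    --sources hosp,claim,accs --period 2008-04-01:2009-03-31 --out run/
morbiscan report --matrix run/matrix.csv \
    --demographics cohort/demographics.csv
```

`ascertain` writes per-person results (`results.csv`), the person ×
condition activity matrix for the reference period (`matrix.csv`), a
multimorbidity summary (`multimorbidity.json`), and a `manifest.json` with
input hashes so runs can be reproduced exactly.  `report` renders the
morbidity-count distribution, per-condition prevalence, and the count-by-
age table; restricted `--sources` runs reproduce source-sensitivity
comparisons.

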