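"""Build the shipped condition registry JSON and the code audit table.

Transcribes the 30 published case-definition rows (algorithm shape, code
lists, exclusions, permanence, validity grade, citation) into
src/morbiscan/data/registry_tonelli30.json, and writes
docs/registry_audit.md mapping every printed code token to its expanded
patterns.  Maintenance tool; the JSON file is the shipped artifact.
"""

from __future__ import annotations

from pathlib import Path

from morbiscan.codes import CodeSystem
from morbiscan.registry import (
    AuxCodeSet,
    ConditionDefinition,
    ConditionRegistry,
    ConditionalExclusion,
    EvidenceRule,
    ExclusionSpec,
    expand_code_spec,
    save_registry,
    validate_registry,
)

ROOT = Path(__file__).resolve().parents[1]

Y2 = {"value": 2, "unit": "years"}
Y3 = {"value": 3, "unit": "years"}
Y1 = {"value": 1, "unit": "years"}
M6 = {"value": 6, "unit": "months"}
D30 = {"value": 30, "unit": "days"}


def _win_id(w):
    if w is None:
        return ""
    u = {"years": "y", "months": "mo", "days": "d"}[w["unit"]]
    return f"in{w['value']}{u}"


def rule(src, n, window=None, role=None, specialties=None, ed=False, no_surgery=False):
    short = {"HOSPITALIZATION": "hosp", "CLAIM": "claims", "AMBULATORY": "accs"}[src]
    bits = [short, str(n)]
    if window:
        bits.append(_win_id(window))
    if role == "MOST_RESPONSIBLE":
        bits.append("mr")
    elif role == "MOST_RESPONSIBLE_OR_POST_ADMIT":
        bits.append("mrpa")
    if ed:
        bits.append("ed")
    if no_surgery:
        bits.append("nosurg")
    if specialties:
        bits.append("spec")
    d = {"id": "-".join(bits), "source": src, "min_count": n}
    if window:
        d["window"] = window
    if role:
        d["dx_role"] = role
    if specialties:
        d["specialties"] = list(specialties)
    if ed:
        d["ed_only"] = True
    if no_surgery:
        d["exclude_if_surgery"] = True
    return EvidenceRule.model_validate(d)


def expand_tokens(tokens, system, exact_tokens=()):
    out = []
    for t in tokens:
        out.extend(expand_code_spec(t, system, exact=(t in exact_tokens)))
    return out


CONDITIONS = []


def cond(
    id,
    name,
    validity,
    algorithm,
    icd9,
    icd10,
    rules,
    citation,
    permanent=True,
    remission_years=None,
    uses_lab=False,
    excl9=(),
    excl10=(),
    cond_excl=(),
    notes="",
    aux=(),
    exact9=(),
):
    codes = expand_tokens(icd9, CodeSystem.ICD9CM, exact9) + expand_tokens(icd10, CodeSystem.ICD10)
    exclusions = {}
    uncond = expand_tokens(excl9, CodeSystem.ICD9CM) + expand_tokens(excl10, CodeSystem.ICD10)
    conditional = [
        ConditionalExclusion(
            code=expand_code_spec(c, sys_)[0],
            companions=tuple(p for t in comps for p in expand_code_spec(t, sys_)),
        )
        for (sys_, c, comps) in cond_excl
    ]
    prov = {
        "algorithm": algorithm,
        "printed_codes": {"ICD9CM": list(icd9), "ICD10": list(icd10)},
    }
    if excl9 or excl10:
        prov["printed_exclusions"] = {}
        if excl9:
            prov["printed_exclusions"]["ICD9CM"] = list(excl9)
        if excl10:
            prov["printed_exclusions"]["ICD10"] = list(excl10)
    if notes:
        prov["notes"] = notes
    CONDITIONS.append(
        ConditionDefinition(
            id=id,
            name=name,
            validity=validity,
            permanence="PERMANENT" if permanent else "REMITTING",
            remission_years=remission_years,
            codes=tuple(codes),
            rules=tuple(rules),
            exclusions=ExclusionSpec(unconditional=tuple(uncond), conditional=tuple(conditional)),
            uses_lab_criteria=uses_lab,
            citation=citation,
            provenance=prov,
            aux=tuple(aux),
        )
    )


H, C_, A = "HOSPITALIZATION", "CLAIM", "AMBULATORY"

cond(
    "alcohol_misuse", "Alcohol misuse", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["265.2", "291.1-291.3", "291.5-291.9", "303.0", "303.9", "305.0", "357.5",
     "425.5", "535.3", "571.0-571.3", "980", "V11.3"],
    ["E52", "F10", "G62.1", "I42.6", "K29.2", "K70.0", "K70.3", "K70.9", "T51",
     "Z50.2", "Z71.4", "Z72.1"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
)
cond(
    "asthma", "Asthma", "HIGH",
    "1 hospitalization or 3 ACCS in 2 years or less",
    ["493"], ["J45"],
    [rule(H, 1), rule(A, 3, Y2)],
    "Gershon 2009",
)
cond(
    "atrial_fibrillation", "Atrial fibrillation", "HIGH",
    "1 hospitalization or 2 claims in 2 years or less",
    ["427.3"], ["I48.0"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Alonso 2009",
    notes="In claims the specific fifth-digit code 427.31 was not in use, so the "
          "less specific 427.3 (which includes atrial flutter) is used in its place.",
)
cond(
    "cancer_lymphoma", "Cancer, lymphoma", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["200-202", "203.0", "238.6"],
    ["C81-C85", "C88", "C90.0", "C90.2", "C96"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
    permanent=False, remission_years=5,
)
cond(
    "cancer_metastatic", "Cancer, metastatic", "HIGH",
    "1 hospitalization or 2 claims in 2 years or less",
    ["196-199"], ["C77-C80"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
    permanent=False, remission_years=5,
)
cond(
    "cancer_nonmetastatic", "Cancer, non-metastatic (breast, cervical, colorectal, lung, prostate)",
    "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["153-154", "162-163", "174", "180", "185", "230.3-230.6", "231.2",
     "233.0-233.1", "233.4"],
    ["C18-C21", "C33-C34", "C38.4", "C45.0", "C46.71", "C50", "C53", "C61",
     "D01.0-D01.3", "D02.2", "D05-D06", "D07.5"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Penberthy 2003",
    permanent=False, remission_years=5,
)
cond(
    "chronic_heart_failure", "Chronic heart failure", "HIGH",
    "1 hospitalization or 2 claims in 2 years or less",
    ["398.91", "402.01", "402.11", "402.91", "404.01", "404.03", "404.11",
     "404.13", "404.91", "404.93", "425.4-425.9", "428"],
    ["I09.9", "I25.5", "I42.0", "I42.5-I42.9", "I43", "I50"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
    notes="I11 and I12 were eliminated from the heart-failure list because a "
          "separate heart-failure code is required alongside them.",
)
cond(
    "chronic_kidney_disease", "Chronic kidney disease", "HIGH",
    "Mean eGFR <60 mL/min/1.73 m2 or mean albuminuria >30 mg/g over 12 months; "
    "or 1 hospitalization or 3 claims in 1 year",
    ["583", "584", "585", "586", "592", "593.9"],
    ["N00-N23"],
    [rule(H, 1), rule(C_, 3, Y1)],
    "Ronksley 2012; Stevens 2013",
    uses_lab=True,
)
cond(
    "chronic_pain", "Chronic pain", "HIGH",
    "2 hospitalizations or 2 claims or 2 ACCS in 30 days or less",
    ["307.80", "307.89", "338.0", "338.2", "338.4", "719.41", "719.45-719.47",
     "719.49", "720.0", "720.2", "720.9", "721.0-721.4", "721.6", "721.8",
     "721.9", "722", "723.0", "723.1", "723.3-723.9", "724.0-724.6", "724.70",
     "724.79", "724.8", "724.9", "729.0-729.2", "729.4", "729.5"],
    ["F45.4", "M08.1", "M25.50", "M25.51", "M25.55-M25.57", "M43.2-M43.6",
     "M45", "M46.1", "M46.3", "M46.4", "M46.9", "M47", "M48.0", "M48.1",
     "M48.8", "M48.9", "M50.8", "M50.9", "M51", "M53.1-M53.3", "M53.8",
     "M53.9", "M54", "M60.8", "M60.9", "M63.3", "M79.0-M79.2", "M79.6",
     "M79.7", "M96.1"],
    [rule(H, 2, D30), rule(C_, 2, D30), rule(A, 2, D30)],
    "Tian 2013",
    permanent=False, remission_years=2,
    notes="The 'highly likely' and 'likely' code groups of the source algorithm "
          "are combined.",
)
cond(
    "chronic_pulmonary_disease", "Chronic pulmonary disease", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["416.8", "416.9", "490-492", "494-505", "506.4", "508.1", "508.8"],
    ["I27.8", "I27.9", "J40-J44", "J46-J47", "J60-J67", "J68.4", "J70.1", "J70.3"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
    notes="493 and J45 were removed from this algorithm because they belong to "
          "the asthma algorithm.",
)
cond(
    "hepatitis_b", "Chronic viral hepatitis B", "MODERATE",
    "2 hospitalizations or 2 claims or 2 ACCS in 6 months or less",
    ["070.2-070.3"], ["B16", "B18.0-B18.1"],
    [rule(H, 2, M6), rule(C_, 2, M6), rule(A, 2, M6)],
    "Mahajan 2013",
    notes="Printed as 70.2-70.3; the viral-hepatitis rubric is 070, so the stems "
          "are zero-padded to 070.2-070.3.",
)
cond(
    "cirrhosis", "Cirrhosis", "HIGH",
    "1 hospitalization or 1 claim or 1 ACCS",
    ["571.2", "571.5", "571.6"],
    ["K70.3", "K74.3", "K74.4", "K74.5", "K74.6"],
    [rule(H, 1), rule(C_, 1), rule(A, 1)],
    "Goldberg 2012",
    aux=[
        AuxCodeSet(
            name="hepatic_decompensation",
            codes=tuple(
                expand_tokens(
                    ["456.0", "456.1", "456.20", "456.21", "567.0", "567.2",
                     "567.21", "567.29", "567.8", "567.9", "572.2", "572.4",
                     "789.5"],
                    CodeSystem.ICD9CM, exact_tokens=("567.2",),
                )
                + expand_tokens(
                    ["I85.0", "I85.9", "I98.2", "I98.3", "K65.0", "K65.8",
                     "K65.9", "K67.0", "K67.1", "K67.2", "K67.3", "K67.8",
                     "K76.7", "K93.0", "R18"],
                    CodeSystem.ICD10,
                )
            ),
            exceptions=tuple(expand_tokens(["567.81", "567.82", "789.51"], CodeSystem.ICD9CM)),
            provenance={
                "algorithm": "hepatic decompensation: 1 hospitalization or 1 claim or 1 ACCS",
                "printed_codes": {
                    "ICD9CM": ["456.0", "456.1", "456.20", "456.21", "567.0",
                               "567.2", "567.21", "567.29", "567.8", "567.9",
                               "572.2", "572.4", "789.5"],
                    "ICD10": ["I85.0", "I85.9", "I98.2", "I98.3", "K65.0",
                              "K65.8", "K65.9", "K67.0", "K67.1", "K67.2",
                              "K67.3", "K67.8", "K76.7", "K93.0", "R18"],
                },
                "printed_exclusions": {"ICD9CM": ["567.81", "567.82", "789.51"]},
                "notes": "567.2 does not generalize to 567.22 or 567.23 (matched "
                         "exactly); 567.81/567.82/789.51 are carved out of the "
                         "567.8 and 789.5 stems. Decompensation is a severity "
                         "qualifier on cirrhosis, not a separate condition.",
            },
        )
    ],
)
cond(
    "dementia", "Dementia", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["290", "294.1", "331.2"],
    ["F00-F03", "F05.1", "G30", "G31.1"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
)
cond(
    "depression", "Depression", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["296.2", "296.3", "296.5", "300.4", "309", "311"],
    ["F20.4", "F31.3-F31.5", "F32", "F33", "F34.1", "F41.2", "F43.2"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
    permanent=False, remission_years=2,
)
cond(
    "diabetes", "Diabetes", "HIGH",
    "1 hospitalization or 2 claims in 2 years or less",
    ["250"], ["E10-E14"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Hux 2005",
)
cond(
    "epilepsy", "Epilepsy", "MODERATE",
    "1 most responsible hospitalization or 2 claims in 2 years or less or "
    "1 most responsible ACCS",
    ["345"], ["G40-G41"],
    [rule(H, 1, role="MOST_RESPONSIBLE"), rule(C_, 2, Y2), rule(A, 1, role="MOST_RESPONSIBLE")],
    "Jette 2010",
)
cond(
    "hypertension", "Hypertension", "HIGH",
    "1 hospitalization or 2 claims in 2 years or less",
    ["401-405"], ["I10-I13", "I15"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2009",
)
cond(
    "hypothyroidism", "Hypothyroidism", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["240.9", "243", "244", "246.1", "246.8"],
    ["E00-E03", "E89.0"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
)
cond(
    "inflammatory_bowel_disease", "Inflammatory bowel disease", "MODERATE",
    "2 hospitalizations or 2 GAST or GP claims in 3 years or less",
    ["555", "556"], ["K50", "K51"],
    [rule(H, 2, Y3), rule(C_, 2, Y3, specialties=["gastroenterology", "general practice"])],
    "Liu 2009",
)
cond(
    "irritable_bowel_syndrome", "Irritable bowel syndrome", "HIGH",
    "1 hospitalization without surgery or 2 claims in 2 years or less",
    ["564.1"], ["K58"],
    [rule(H, 1, no_surgery=True), rule(C_, 2, Y2)],
    "Sands 2006",
    excl9=["153-154", "157", "183.0", "197.5", "198.6", "235.2", "239.0",
           "555-556", "571.2", "571.5", "577.1", "579"],
    excl10=["C18-C21", "C25", "C56", "C78.5", "C79.6", "D01.7", "D01.9",
            "D37.1-D37.5", "K50-K51", "K70.2-K70.3", "K74.0", "K74.2",
            "K74.6", "K86.0-K86.1", "K90", "K91.2"],
)
cond(
    "multiple_sclerosis", "Multiple sclerosis", "HIGH",
    "2 hospitalizations or 2 claims in 3 years or less",
    ["323", "340", "341.0", "341.9", "377.3"],
    ["G35", "G36", "G37", "H46"],
    [rule(H, 2, Y3), rule(C_, 2, Y3)],
    "Marrie 2013",
)
cond(
    "myocardial_infarction", "Myocardial infarction", "HIGH",
    "1 hospitalization",
    ["410"], ["I21-I22"],
    [rule(H, 1)],
    "Austin 2002",
)
cond(
    "parkinsons_disease", "Parkinson's disease", "MODERATE",
    "1 hospitalization or 1 claim",
    ["332"], ["G20", "G21", "G22"],
    [rule(H, 1), rule(C_, 1)],
    "Noyes 2007",
)
cond(
    "peptic_ulcer_disease", "Peptic ulcer disease", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["531.7", "531.9", "532.7", "532.9", "533.7", "533.9", "534.7", "534.9"],
    ["K25.7", "K25.9", "K26.7", "K26.9", "K27.7", "K27.9", "K28.7", "K28.9"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
    permanent=False, remission_years=2,
)
cond(
    "peripheral_vascular_disease", "Peripheral vascular disease", "HIGH",
    "1 hospitalization or 1 claim or 1 ACCS",
    ["440.2"], ["I70.2"],
    [rule(H, 1), rule(C_, 1), rule(A, 1)],
    "Fan 2013",
)
cond(
    "psoriasis", "Psoriasis", "HIGH",
    "1 hospitalization or 1 DERM claim",
    ["696.1"],
    ["L40.0-L40.4", "L40.8", "L40.9"],
    [rule(H, 1), rule(C_, 1, specialties=["dermatology"])],
    "Asgari 2013",
)
cond(
    "rheumatoid_arthritis", "Rheumatoid arthritis", "MODERATE",
    "1 hospitalization or 2 claims in 2 years or less",
    ["446.5", "710.0-710.4", "714.0-714.2", "714.8", "725"],
    ["M05", "M06", "M31.5", "M32-M34", "M35.1", "M35.3", "M36.0"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Quan 2008; Quan 2005",
)
cond(
    "schizophrenia", "Schizophrenia", "HIGH",
    "1 hospitalization or 2 claims in 2 years or less",
    ["295"], ["F20", "F21", "F23.2", "F25"],
    [rule(H, 1), rule(C_, 2, Y2)],
    "Lurie 1992; Moscovice 1989",
)
cond(
    "severe_constipation", "Severe constipation", "HIGH",
    "1 hospitalization without surgery or 2 claims in 2 years or less",
    ["560.1", "560.30", "560.39", "560.9", "564.0", "569.83", "569.89"],
    ["K55.8", "K56.0", "K56.4", "K56.7", "K59.0", "K63.1", "K63.4", "K63.81",
     "K63.88", "K92.80", "K92.88"],
    [rule(H, 1, no_surgery=True), rule(C_, 2, Y2)],
    "Sands 2006",
    permanent=False, remission_years=2,
    excl9=["152-154", "158", "179-189", "197.5-197.6", "235.2", "239.0",
           "555-556", "568.0", "614.6"],
    excl10=["C17-C21", "C45.1", "C48", "C51-C58", "C60-C68", "C78.5-C78.6",
            "D01.7", "D01.9", "D37.1-D37.5", "K50-K51", "K66.0", "N73.6",
            "N99.4"],
    cond_excl=[
        (CodeSystem.ICD9CM, "560.9", ["789.01", "789.02", "789.06"]),
        (CodeSystem.ICD10, "K56.6", ["R10.1"]),
    ],
    notes="Surgery procedure codes billed in claims exclude the qualifying "
          "hospitalization; the procedure list is site-specific and shipped "
          "empty (configurable).",
)
cond(
    "stroke_tia", "Stroke or transient ischemic attack", "MODERATE",
    "1 most responsible or post-admittance hospitalization or 1 claim or "
    "1 most responsible ED ACCS",
    ["362.3", "430", "431", "433.x1", "434.x1", "435", "436"],
    ["G45.0-G45.3", "G45.8-G45.9", "H34.1", "I60", "I61", "I63", "I64"],
    [rule(H, 1, role="MOST_RESPONSIBLE_OR_POST_ADMIT"), rule(C_, 1),
     rule(A, 1, role="MOST_RESPONSIBLE", ed=True)],
    "Kokotailo 2005",
)


def _shared(tokens_by_system):
    out = []
    for sys_, tokens in tokens_by_system.items():
        for t in tokens:
            out.extend(expand_code_spec(t, sys_))
    return tuple(out)


PERMITTED = [
    {
        "conditions": ("alcohol_misuse", "chronic_heart_failure"),
        "shared": _shared({CodeSystem.ICD9CM: ["425.5"], CodeSystem.ICD10: ["I42.6"]}),
        "note": "Alcoholic cardiomyopathy codes legitimately belong to both lists.",
    },
    {
        "conditions": ("alcohol_misuse", "cirrhosis"),
        "shared": _shared({CodeSystem.ICD9CM: ["571.2"], CodeSystem.ICD10: ["K70.3"]}),
        "note": "Alcoholic cirrhosis codes legitimately belong to both lists.",
    },
    {
        "conditions": ("chronic_heart_failure", "hypertension"),
        "shared": _shared({CodeSystem.ICD9CM: [
            "402.01", "402.11", "402.91", "404.01", "404.03", "404.11",
            "404.13", "404.91", "404.93"]}),
        "note": "Hypertensive heart disease with heart failure falls under the "
                "401-405 hypertension stems. The published overlap note lists "
                "402.91 and the 404 codes; 402.01 and 402.11 are included here "
                "as well since they fall under the same stems.",
    },
    {
        "conditions": ("depression", "schizophrenia"),
        "shared": _shared({CodeSystem.ICD10: ["F20.4"]}),
        "note": "Post-schizophrenic depression is in both lists.",
    },
]


def main():
    reg = ConditionRegistry(
        schema_version=1,
        name="tonelli30",
        conditions=tuple(CONDITIONS),
        permitted_overlaps=tuple(
            {"conditions": p["conditions"], "shared": p["shared"], "note": p["note"]}
            for p in PERMITTED
        ),
    )
    report = validate_registry(reg)
    print(report.render())
    n_high = sum(1 for c in reg.conditions if c.validity.value == "HIGH")
    print(f"conditions: {len(reg.conditions)} (HIGH {n_high}, MODERATE {len(reg.conditions)-n_high})")
    out = ROOT / "src" / "morbiscan" / "data" / "registry_tonelli30.json"
    save_registry(reg, out)
    print(f"wrote {out} ({out.stat().st_size} bytes)")

    # audit table: every printed token -> expanded patterns
    lines = [
        "# Registry code audit",
        "",
        "Every printed code token in the shipped registry, with the normalized",
        "pattern(s) it expands to. Patterns use prefix semantics; `?` matches",
        "any single character.",
        "",
        "| Condition | System | Printed token | Pattern(s) |",
        "|---|---|---|---|",
    ]
    for c in reg.conditions:
        for sys_name, tokens in c.provenance.get("printed_codes", {}).items():
            for t in tokens:
                pats = expand_code_spec(t, sys_name)
                lines.append(
                    f"| {c.id} | {sys_name} | {t} | {', '.join(p.pattern for p in pats)} |"
                )
    (ROOT / "docs" / "registry_audit.md").write_text("\n".join(lines) + "\n")
    print("wrote docs/registry_audit.md")


if __name__ == "__main__":
    main()
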