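# Registry code audit

Every printed code token in the shipped registry, with the normalized
pattern(s) it expands to. Patterns use prefix semantics; `?` matches
any single character.

| Condition | System | Printed token | Pattern(s) |
|---|---|---|---|
| alcohol_misuse | ICD9CM | 265.2 | 2652 |
| alcohol_misuse | ICD9CM | 291.1-291.3 | 2911, 2912, 2913 |
| alcohol_misuse | ICD9CM | 291.5-291.9 | 2915, 2916, 2917, 2918, 2919 |
| alcohol_misuse | ICD9CM | 303.0 | 3030 |
| alcohol_misuse | ICD9CM | 303.9 | 3039 |
| alcohol_misuse | ICD9CM | 305.0 | 3050 |
| alcohol_misuse | ICD9CM | 357.5 | 3575 |
| alcohol_misuse | ICD9CM | 425.5 | 4255 |
| alcohol_misuse | ICD9CM | 535.3 | 5353 |
| alcohol_misuse | ICD9CM | 571.0-571.3 | 5710, 5711, 5712, 5713 |
| alcohol_misuse | ICD9CM | 980 | 980 |
| alcohol_misuse | ICD9CM | V11.3 | V113 |
| alcohol_misuse | ICD10 | E52 | E52 |
| alcohol_misuse | ICD10 | F10 | F10 |
| alcohol_misuse | ICD10 | G62.1 | G621 |
| alcohol_misuse | ICD10 | I42.6 | I426 |
| alcohol_misuse | ICD10 | K29.2 | K292 |
| alcohol_misuse | ICD10 | K70.0 | K700 |
| alcohol_misuse | ICD10 | K70.3 | K703 |
| alcohol_misuse | ICD10 | K70.9 | K709 |
| alcohol_misuse | ICD10 | T51 | T51 |
| alcohol_misuse | ICD10 | Z50.2 | Z502 |
| alcohol_misuse | ICD10 | Z71.4 | Z714 |
| alcohol_misuse | ICD10 | Z72.1 | Z721 |
| asthma | ICD9CM | 493 | 493 |
| asthma | ICD10 | J45 | J45 |
| atrial_fibrillation | ICD9CM | 427.3 | 4273 |
| atrial_fibrillation | ICD10 | I48.0 | I480 |
| cancer_lymphoma | ICD9CM | 200-202 | 200, 201, 202 |
| cancer_lymphoma | ICD9CM | 203.0 | 2030 |
| cancer_lymphoma | ICD9CM | 238.6 | 2386 |
| cancer_lymphoma | ICD10 | C81-C85 | C81, C82, C83, C84, C85 |
| cancer_lymphoma | ICD10 | C88 | C88 |
| cancer_lymphoma | ICD10 | C90.0 | C900 |
| cancer_lymphoma | ICD10 | C90.2 | C902 |
| cancer_lymphoma | ICD10 | C96 | C96 |
| cancer_metastatic | ICD9CM | 196-199 | 196, 197, 198, 199 |
| cancer_metastatic | ICD10 | C77-C80 | C77, C78, C79, C80 |
| cancer_nonmetastatic | ICD9CM | 153-154 | 153, 154 |
| cancer_nonmetastatic | ICD9CM | 162-163 | 162, 163 |
| cancer_nonmetastatic | ICD9CM | 174 | 174 |
| cancer_nonmetastatic | ICD9CM | 180 | 180 |
| cancer_nonmetastatic | ICD9CM | 185 | 185 |
| cancer_nonmetastatic | ICD9CM | 230.3-230.6 | 2303, 2304, 2305, 2306 |
| cancer_nonmetastatic | ICD9CM | 231.2 | 2312 |
| cancer_nonmetastatic | ICD9CM | 233.0-233.1 | 2330, 2331 |
| cancer_nonmetastatic | ICD9CM | 233.4 | 2334 |
| cancer_nonmetastatic | ICD10 | C18-C21 | C18, C19, C20, C21 |
| cancer_nonmetastatic | ICD10 | C33-C34 | C33, C34 |
| cancer_nonmetastatic | ICD10 | C38.4 | C384 |
| cancer_nonmetastatic | ICD10 | C45.0 | C450 |
| cancer_nonmetastatic | ICD10 | C46.71 | C4671 |
| cancer_nonmetastatic | ICD10 | C50 | C50 |
| cancer_nonmetastatic | ICD10 | C53 | C53 |
| cancer_nonmetastatic | ICD10 | C61 | C61 |
| cancer_nonmetastatic | ICD10 | D01.0-D01.3 | D010, D011, D012, D013 |
| cancer_nonmetastatic | ICD10 | D02.2 | D022 |
| cancer_nonmetastatic | ICD10 | D05-D06 | D05, D06 |
| cancer_nonmetastatic | ICD10 | D07.5 | D075 |
| chronic_heart_failure | ICD9CM | 398.91 | 39891 |
| chronic_heart_failure | ICD9CM | 402.01 | 40201 |
| chronic_heart_failure | ICD9CM | 402.11 | 40211 |
| chronic_heart_failure | ICD9CM | 402.91 | 40291 |
| chronic_heart_failure | ICD9CM | 404.01 | 40401 |
| chronic_heart_failure | ICD9CM | 404.03 | 40403 |
| chronic_heart_failure | ICD9CM | 404.11 | 40411 |
| chronic_heart_failure | ICD9CM | 404.13 | 40413 |
| chronic_heart_failure | ICD9CM | 404.91 | 40491 |
| chronic_heart_failure | ICD9CM | 404.93 | 40493 |
| chronic_heart_failure | ICD9CM | 425.4-425.9 | 4254, 4255, 4256, 4257, 4258, 4259 |
| chronic_heart_failure | ICD9CM | 428 | 428 |
| chronic_heart_failure | ICD10 | I09.9 | I099 |
| chronic_heart_failure | ICD10 | I25.5 | I255 |
| chronic_heart_failure | ICD10 | I42.0 | I420 |
| chronic_heart_failure | ICD10 | I42.5-I42.9 | I425, I426, I427, I428, I429 |
| chronic_heart_failure | ICD10 | I43 | I43 |
| chronic_heart_failure | ICD10 | I50 | I50 |
| chronic_kidney_disease | ICD9CM | 583 | 583 |
| chronic_kidney_disease | ICD9CM | 584 | 584 |
| chronic_kidney_disease | ICD9CM | 585 | 585 |
| chronic_kidney_disease | ICD9CM | 586 | 586 |
| chronic_kidney_disease | ICD9CM | 592 | 592 |
| chronic_kidney_disease | ICD9CM | 593.9 | 5939 |
| chronic_kidney_disease | ICD10 | N00-N23 | N00, N01, N02, N03, N04, N05, N06, N07, N08, N09, N10, N11, N12, N13, N14, N15, N16, N17, N18, N19, N20, N21, N22, N23 |
| chronic_pain | ICD9CM | 307.80 | 30780 |
| chronic_pain | ICD9CM | 307.89 | 30789 |
| chronic_pain | ICD9CM | 338.0 | 3380 |
| chronic_pain | ICD9CM | 338.2 | 3382 |
| chronic_pain | ICD9CM | 338.4 | 3384 |
| chronic_pain | ICD9CM | 719.41 | 71941 |
| chronic_pain | ICD9CM | 719.45-719.47 | 71945, 71946, 71947 |
| chronic_pain | ICD9CM | 719.49 | 71949 |
| chronic_pain | ICD9CM | 720.0 | 7200 |
| chronic_pain | ICD9CM | 720.2 | 7202 |
| chronic_pain | ICD9CM | 720.9 | 7209 |
| chronic_pain | ICD9CM | 721.0-721.4 | 7210, 7211, 7212, 7213, 7214 |
| chronic_pain | ICD9CM | 721.6 | 7216 |
| chronic_pain | ICD9CM | 721.8 | 7218 |
| chronic_pain | ICD9CM | 721.9 | 7219 |
| chronic_pain | ICD9CM | 722 | 722 |
| chronic_pain | ICD9CM | 723.0 | 7230 |
| chronic_pain | ICD9CM | 723.1 | 7231 |
| chronic_pain | ICD9CM | 723.3-723.9 | 7233, 7234, 7235, 7236, 7237, 7238, 7239 |
| chronic_pain | ICD9CM | 724.0-724.6 | 7240, 7241, 7242, 7243, 7244, 7245, 7246 |
| chronic_pain | ICD9CM | 724.70 | 72470 |
| chronic_pain | ICD9CM | 724.79 | 72479 |
| chronic_pain | ICD9CM | 724.8 | 7248 |
| chronic_pain | ICD9CM | 724.9 | 7249 |
| chronic_pain | ICD9CM | 729.0-729.2 | 7290, 7291, 7292 |
| chronic_pain | ICD9CM | 729.4 | 7294 |
| chronic_pain | ICD9CM | 729.5 | 7295 |
| chronic_pain | ICD10 | F45.4 | F454 |
| chronic_pain | ICD10 | M08.1 | M081 |
| chronic_pain | ICD10 | M25.50 | M2550 |
| chronic_pain | ICD10 | M25.51 | M2551 |
| chronic_pain | ICD10 | M25.55-M25.57 | M2555, M2556, M2557 |
| chronic_pain | ICD10 | M43.2-M43.6 | M432, M433, M434, M435, M436 |
| chronic_pain | ICD10 | M45 | M45 |
| chronic_pain | ICD10 | M46.1 | M461 |
| chronic_pain | ICD10 | M46.3 | M463 |
| chronic_pain | ICD10 | M46.4 | M464 |
| chronic_pain | ICD10 | M46.9 | M469 |
| chronic_pain | ICD10 | M47 | M47 |
| chronic_pain | ICD10 | M48.0 | M480 |
| chronic_pain | ICD10 | M48.1 | M481 |
| chronic_pain | ICD10 | M48.8 | M488 |
| chronic_pain | ICD10 | M48.9 | M489 |
| chronic_pain | ICD10 | M50.8 | M508 |
| chronic_pain | ICD10 | M50.9 | M509 |
| chronic_pain | ICD10 | M51 | M51 |
| chronic_pain | ICD10 | M53.1-M53.3 | M531, M532, M533 |
| chronic_pain | ICD10 | M53.8 | M538 |
| chronic_pain | ICD10 | M53.9 | M539 |
| chronic_pain | ICD10 | M54 | M54 |
| chronic_pain | ICD10 | M60.8 | M608 |
| chronic_pain | ICD10 | M60.9 | M609 |
| chronic_pain | ICD10 | M63.3 | M633 |
| chronic_pain | ICD10 | M79.0-M79.2 | M790, M791, M792 |
| chronic_pain | ICD10 | M79.6 | M796 |
| chronic_pain | ICD10 | M79.7 | M797 |
| chronic_pain | ICD10 | M96.1 | M961 |
| chronic_pulmonary_disease | ICD9CM | 416.8 | 4168 |
| chronic_pulmonary_disease | ICD9CM | 416.9 | 4169 |
| chronic_pulmonary_disease | ICD9CM | 490-492 | 490, 491, 492 |
| chronic_pulmonary_disease | ICD9CM | 494-505 | 494, 495, 496, 497, 498, 499, 500, 501, 502, 503, 504, 505 |
| chronic_pulmonary_disease | ICD9CM | 506.4 | 5064 |
| chronic_pulmonary_disease | ICD9CM | 508.1 | 5081 |
| chronic_pulmonary_disease | ICD9CM | 508.8 | 5088 |
| chronic_pulmonary_disease | ICD10 | I27.8 | I278 |
| chronic_pulmonary_disease | ICD10 | I27.9 | I279 |
| chronic_pulmonary_disease | ICD10 | J40-J44 | J40, J41, J42, J43, J44 |
| chronic_pulmonary_disease | ICD10 | J46-J47 | J46, J47 |
| chronic_pulmonary_disease | ICD10 | J60-J67 | J60, J61, J62, J63, J64, J65, J66, J67 |
| chronic_pulmonary_disease | ICD10 | J68.4 | J684 |
| chronic_pulmonary_disease | ICD10 | J70.1 | J701 |
| chronic_pulmonary_disease | ICD10 | J70.3 | J703 |
| hepatitis_b | ICD9CM | 070.2-070.3 | 0702, 0703 |
| hepatitis_b | ICD10 | B16 | B16 |
| hepatitis_b | ICD10 | B18.0-B18.1 | B180, B181 |
| cirrhosis | ICD9CM | 571.2 | 5712 |
| cirrhosis | ICD9CM | 571.5 | 5715 |
| cirrhosis | ICD9CM | 571.6 | 5716 |
| cirrhosis | ICD10 | K70.3 | K703 |
| cirrhosis | ICD10 | K74.3 | K743 |
| cirrhosis | ICD10 | K74.4 | K744 |
| cirrhosis | ICD10 | K74.5 | K745 |
| cirrhosis | ICD10 | K74.6 | K746 |
| dementia | ICD9CM | 290 | 290 |
| dementia | ICD9CM | 294.1 | 2941 |
| dementia | ICD9CM | 331.2 | 3312 |
| dementia | ICD10 | F00-F03 | F00, F01, F02, F03 |
| dementia | ICD10 | F05.1 | F051 |
| dementia | ICD10 | G30 | G30 |
| dementia | ICD10 | G31.1 | G311 |
| depression | ICD9CM | 296.2 | 2962 |
| depression | ICD9CM | 296.3 | 2963 |
| depression | ICD9CM | 296.5 | 2965 |
| depression | ICD9CM | 300.4 | 3004 |
| depression | ICD9CM | 309 | 309 |
| depression | ICD9CM | 311 | 311 |
| depression | ICD10 | F20.4 | F204 |
| depression | ICD10 | F31.3-F31.5 | F313, F314, F315 |
| depression | ICD10 | F32 | F32 |
| depression | ICD10 | F33 | F33 |
| depression | ICD10 | F34.1 | F341 |
| depression | ICD10 | F41.2 | F412 |
| depression | ICD10 | F43.2 | F432 |
| diabetes | ICD9CM | 250 | 250 |
| diabetes | ICD10 | E10-E14 | E10, E11, E12, E13, E14 |
| epilepsy | ICD9CM | 345 | 345 |
| epilepsy | ICD10 | G40-G41 | G40, G41 |
| hypertension | ICD9CM | 401-405 | 401, 402, 403, 404, 405 |
| hypertension | ICD10 | I10-I13 | I10, I11, I12, I13 |
| hypertension | ICD10 | I15 | I15 |
| hypothyroidism | ICD9CM | 240.9 | 2409 |
| hypothyroidism | ICD9CM | 243 | 243 |
| hypothyroidism | ICD9CM | 244 | 244 |
| hypothyroidism | ICD9CM | 246.1 | 2461 |
| hypothyroidism | ICD9CM | 246.8 | 2468 |
| hypothyroidism | ICD10 | E00-E03 | E00, E01, E02, E03 |
| hypothyroidism | ICD10 | E89.0 | E890 |
| inflammatory_bowel_disease | ICD9CM | 555 | 555 |
| inflammatory_bowel_disease | ICD9CM | 556 | 556 |
| inflammatory_bowel_disease | ICD10 | K50 | K50 |
| inflammatory_bowel_disease | ICD10 | K51 | K51 |
| irritable_bowel_syndrome | ICD9CM | 564.1 | 5641 |
| irritable_bowel_syndrome | ICD10 | K58 | K58 |
| multiple_sclerosis | ICD9CM | 323 | 323 |
| multiple_sclerosis | ICD9CM | 340 | 340 |
| multiple_sclerosis | ICD9CM | 341.0 | 3410 |
| multiple_sclerosis | ICD9CM | 341.9 | 3419 |
| multiple_sclerosis | ICD9CM | 377.3 | 3773 |
| multiple_sclerosis | ICD10 | G35 | G35 |
| multiple_sclerosis | ICD10 | G36 | G36 |
| multiple_sclerosis | ICD10 | G37 | G37 |
| multiple_sclerosis | ICD10 | H46 | H46 |
| myocardial_infarction | ICD9CM | 410 | 410 |
| myocardial_infarction | ICD10 | I21-I22 | I21, I22 |
| parkinsons_disease | ICD9CM | 332 | 332 |
| parkinsons_disease | ICD10 | G20 | G20 |
| parkinsons_disease | ICD10 | G21 | G21 |
| parkinsons_disease | ICD10 | G22 | G22 |
| peptic_ulcer_disease | ICD9CM | 531.7 | 5317 |
| peptic_ulcer_disease | ICD9CM | 531.9 | 5319 |
| peptic_ulcer_disease | ICD9CM | 532.7 | 5327 |
| peptic_ulcer_disease | ICD9CM | 532.9 | 5329 |
| peptic_ulcer_disease | ICD9CM | 533.7 | 5337 |
| peptic_ulcer_disease | ICD9CM | 533.9 | 5339 |
| peptic_ulcer_disease | ICD9CM | 534.7 | 5347 |
| peptic_ulcer_disease | ICD9CM | 534.9 | 5349 |
| peptic_ulcer_disease | ICD10 | K25.7 | K257 |
| peptic_ulcer_disease | ICD10 | K25.9 | K259 |
| peptic_ulcer_disease | ICD10 | K26.7 | K267 |
| peptic_ulcer_disease | ICD10 | K26.9 | K269 |
| peptic_ulcer_disease | ICD10 | K27.7 | K277 |
| peptic_ulcer_disease | ICD10 | K27.9 | K279 |
| peptic_ulcer_disease | ICD10 | K28.7 | K287 |
| peptic_ulcer_disease | ICD10 | K28.9 | K289 |
| peripheral_vascular_disease | ICD9CM | 440.2 | 4402 |
| peripheral_vascular_disease | ICD10 | I70.2 | I702 |
| psoriasis | ICD9CM | 696.1 | 6961 |
| psoriasis | ICD10 | L40.0-L40.4 | L400, L401, L402, L403, L404 |
| psoriasis | ICD10 | L40.8 | L408 |
| psoriasis | ICD10 | L40.9 | L409 |
| rheumatoid_arthritis | ICD9CM | 446.5 | 4465 |
| rheumatoid_arthritis | ICD9CM | 710.0-710.4 | 7100, 7101, 7102, 7103, 7104 |
| rheumatoid_arthritis | ICD9CM | 714.0-714.2 | 7140, 7141, 7142 |
| rheumatoid_arthritis | ICD9CM | 714.8 | 7148 |
| rheumatoid_arthritis | ICD9CM | 725 | 725 |
| rheumatoid_arthritis | ICD10 | M05 | M05 |
| rheumatoid_arthritis | ICD10 | M06 | M06 |
| rheumatoid_arthritis | ICD10 | M31.5 | M315 |
| rheumatoid_arthritis | ICD10 | M32-M34 | M32, M33, M34 |
| rheumatoid_arthritis | ICD10 | M35.1 | M351 |
| rheumatoid_arthritis | ICD10 | M35.3 | M353 |
| rheumatoid_arthritis | ICD10 | M36.0 | M360 |
| schizophrenia | ICD9CM | 295 | 295 |
| schizophrenia | ICD10 | F20 | F20 |
| schizophrenia | ICD10 | F21 | F21 |
| schizophrenia | ICD10 | F23.2 | F232 |
| schizophrenia | ICD10 | F25 | F25 |
| severe_constipation | ICD9CM | 560.1 | 5601 |
| severe_constipation | ICD9CM | 560.30 | 56030 |
| severe_constipation | ICD9CM | 560.39 | 56039 |
| severe_constipation | ICD9CM | 560.9 | 5609 |
| severe_constipation | ICD9CM | 564.0 | 5640 |
| severe_constipation | ICD9CM | 569.83 | 56983 |
| severe_constipation | ICD9CM | 569.89 | 56989 |
| severe_constipation | ICD10 | K55.8 | K558 |
| severe_constipation | ICD10 | K56.0 | K560 |
| severe_constipation | ICD10 | K56.4 | K564 |
| severe_constipation | ICD10 | K56.7 | K567 |
| severe_constipation | ICD10 | K59.0 | K590 |
| severe_constipation | ICD10 | K63.1 | K631 |
| severe_constipation | ICD10 | K63.4 | K634 |
| severe_constipation | ICD10 | K63.81 | K6381 |
| severe_constipation | ICD10 | K63.88 | K6388 |
| severe_constipation | ICD10 | K92.80 | K9280 |
| severe_constipation | ICD10 | K92.88 | K9288 |
| stroke_tia | ICD9CM | 362.3 | 3623 |
| stroke_tia | ICD9CM | 430 | 430 |
| stroke_tia | ICD9CM | 431 | 431 |
| stroke_tia | ICD9CM | 433.x1 | 433?1 |
| stroke_tia | ICD9CM | 434.x1 | 434?1 |
| stroke_tia | ICD9CM | 435 | 435 |
| stroke_tia | ICD9CM | 436 | 436 |
| stroke_tia | ICD10 | G45.0-G45.3 | G450, G451, G452, G453 |
| stroke_tia | ICD10 | G45.8-G45.9 | G458, G459 |
| stroke_tia | ICD10 | H34.1 | H341 |
| stroke_tia | ICD10 | I60 | I60 |
| stroke_tia | ICD10 | I61 | I61 |
| stroke_tia | ICD10 | I63 | I63 |
| stroke_tia | ICD10 | I64 | I64 |
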