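# Default concept sets for the SLE phenotype algorithms.
#
# This is the main-text subset of codes: SLE itself is identified by SNOMED
# 257628 / ICD-10 M32.9 / ICD-9 710.0; the comparator algorithms exclude
# dermatomyositis (710.3) and systemic sclerosis (710.1).  Users running
# against real data should supply their complete local code lists through a
# config file with this same schema.
concept_sets:
  - name: sle_diagnosis
    role: sle_diagnosis
    codes:
      - [SNOMED, "257628", "Systemic lupus erythematosus"]
      - [ICD10, "M32.9", "Systemic lupus erythematosus, unspecified"]
      - [ICD9, "710.0", "Systemic lupus erythematosus"]

  - name: sle_signs_symptoms
    role: sle_sign_symptom
    codes:
      - [ICD10, "R53.81", "Malaise"]
      - [ICD10, "R53.83", "Fatigue"]
      - [ICD10, "M25.50", "Joint pain, unspecified joint"]
      - [ICD10, "M54.5", "Low back pain"]
      - [ICD10, "D64.9", "Anemia, unspecified"]

  - name: sle_treatment_drugs
    role: sle_treatment_drug
    codes:
      - [RxNorm, "8640", "prednisone"]
      - [RxNorm, "6902", "methylprednisolone"]
      - [RxNorm, "5521", "hydroxychloroquine"]

  - name: antimalarials
    role: antimalarial
    codes:
      - [RxNorm, "5521", "hydroxychloroquine"]
      - [RxNorm, "2393", "chloroquine"]

  - name: barnado_exclusions
    role: exclusion_dx
    codes:
      - [ICD9, "710.3", "Dermatomyositis"]
      - [ICD9, "710.1", "Systemic sclerosis"]

  - name: rheumatoid_arthritis
    role: comorbidity
    codes:
      - [ICD10, "M06.9", "Rheumatoid arthritis, unspecified"]

  - name: renal_impairment
    role: comorbidity
    codes:
      - [ICD10, "N18.9", "Chronic kidney disease, unspecified"]
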