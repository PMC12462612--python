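# Default sentence feature schema (50 features).  An editable manifest:
# deployments with richer dictionaries and pattern libraries extend this
# list toward the several-hundred-feature matrices used in large builds.
#
# Feature kinds:
#   binary       - 1 iff the operand (entity class / keyword family /
#                  quantitative pattern) has at least one hit
#   count        - number of hits of the operand
#   cooccurrence - 1 iff EVERY operand group has at least one hit in the
#                  sentence, order and distance ignored
#   sum          - arithmetic sum of previously defined features
#
# Operand syntax: "entity:<class>", "keyword:<family>", "pattern:<name>",
# or a bare feature name (sum only).
features:
  - {name: has_entity_phenotype_of_interest, kind: binary, operands: ["entity:phenotype_of_interest"]}
  - {name: has_entity_clinical, kind: binary, operands: ["entity:clinical"]}
  - {name: has_entity_procedure, kind: binary, operands: ["entity:procedure"]}
  - {name: has_entity_drug, kind: binary, operands: ["entity:drug"]}
  - {name: n_entity_phenotype_of_interest, kind: count, operands: ["entity:phenotype_of_interest"]}
  - {name: n_entity_clinical, kind: count, operands: ["entity:clinical"]}
  - {name: n_entity_procedure, kind: count, operands: ["entity:procedure"]}
  - {name: n_entity_drug, kind: count, operands: ["entity:drug"]}
  - {name: has_kw_definition, kind: binary, operands: ["keyword:definition"]}
  - {name: has_kw_nlp_use, kind: binary, operands: ["keyword:nlp_use"]}
  - {name: has_kw_data_source, kind: binary, operands: ["keyword:data_source"]}
  - {name: has_kw_medication_use, kind: binary, operands: ["keyword:medication_use"]}
  - {name: has_kw_code_mention, kind: binary, operands: ["keyword:code_mention"]}
  - {name: has_kw_negative_computational, kind: binary, operands: ["keyword:negative_computational"]}
  - {name: has_kw_negative_location, kind: binary, operands: ["keyword:negative_location"]}
  - {name: has_kw_negative_financial, kind: binary, operands: ["keyword:negative_financial"]}
  - {name: n_kw_definition, kind: count, operands: ["keyword:definition"]}
  - {name: n_kw_nlp_use, kind: count, operands: ["keyword:nlp_use"]}
  - {name: n_kw_data_source, kind: count, operands: ["keyword:data_source"]}
  - {name: n_kw_medication_use, kind: count, operands: ["keyword:medication_use"]}
  - {name: n_kw_code_mention, kind: count, operands: ["keyword:code_mention"]}
  - {name: n_kw_negative_computational, kind: count, operands: ["keyword:negative_computational"]}
  - {name: n_kw_negative_location, kind: count, operands: ["keyword:negative_location"]}
  - {name: n_kw_negative_financial, kind: count, operands: ["keyword:negative_financial"]}
  - {name: has_pat_blood_pressure, kind: binary, operands: ["pattern:blood_pressure"]}
  - {name: has_pat_lab_value, kind: binary, operands: ["pattern:lab_value"]}
  - {name: has_pat_age, kind: binary, operands: ["pattern:age"]}
  - {name: has_pat_height, kind: binary, operands: ["pattern:height"]}
  - {name: has_pat_weight, kind: binary, operands: ["pattern:weight"]}
  - {name: has_pat_bmi, kind: binary, operands: ["pattern:bmi"]}
  - {name: has_pat_icd_code, kind: binary, operands: ["pattern:icd_code"]}
  - {name: has_pat_cpt_code, kind: binary, operands: ["pattern:cpt_code"]}
  - {name: n_pat_blood_pressure, kind: count, operands: ["pattern:blood_pressure"]}
  - {name: n_pat_lab_value, kind: count, operands: ["pattern:lab_value"]}
  - {name: n_pat_age, kind: count, operands: ["pattern:age"]}
  - {name: n_pat_height, kind: count, operands: ["pattern:height"]}
  - {name: n_pat_weight, kind: count, operands: ["pattern:weight"]}
  - {name: n_pat_bmi, kind: count, operands: ["pattern:bmi"]}
  - {name: n_pat_icd_code, kind: count, operands: ["pattern:icd_code"]}
  - {name: n_pat_cpt_code, kind: count, operands: ["pattern:cpt_code"]}
  - {name: cooc_phenotype_of_interest_definition, kind: cooccurrence, operands: ["entity:phenotype_of_interest", "keyword:definition"]}
  - {name: cooc_clinical_definition, kind: cooccurrence, operands: ["entity:clinical", "keyword:definition"]}
  - {name: cooc_procedure_definition, kind: cooccurrence, operands: ["entity:procedure", "keyword:definition"]}
  - {name: cooc_drug_definition, kind: cooccurrence, operands: ["entity:drug", "keyword:definition"]}
  - {name: cooc_phenotype_of_interest_code, kind: cooccurrence, operands: ["entity:phenotype_of_interest", "keyword:code_mention"]}
  - {name: cooc_clinical_code, kind: cooccurrence, operands: ["entity:clinical", "keyword:code_mention"]}
  - {name: cooc_procedure_code, kind: cooccurrence, operands: ["entity:procedure", "keyword:code_mention"]}
  - {name: cooc_drug_code, kind: cooccurrence, operands: ["entity:drug", "keyword:code_mention"]}
  - name: positive_evidence_sum
    kind: sum
    operands:
      - has_kw_definition
      - has_kw_nlp_use
      - has_kw_data_source
      - has_kw_medication_use
      - has_kw_code_mention
      - has_pat_blood_pressure
      - has_pat_lab_value
      - has_pat_age
      - has_pat_height
      - has_pat_weight
      - has_pat_bmi
      - has_pat_icd_code
      - has_pat_cpt_code
  - name: negative_evidence_sum
    kind: sum
    operands:
      - has_kw_negative_computational
      - has_kw_negative_location
      - has_kw_negative_financial
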