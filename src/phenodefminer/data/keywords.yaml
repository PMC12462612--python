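# Keyword families for sentence-level feature engineering.  Positive-
# evidence families signal that a sentence states how a phenotype was
# defined; negative-evidence families mark computational/statistical,
# location, and financial content that labels a sentence irrelevant.
# Matching is on word boundaries; multiword keywords match token-by-token.
# Lists are stored unstemmed and stemmed at schema-compile time.
definition:
  - defined
  - definition
  - defined as
  - classified
  - classified as
  - identification
  - identified
  - diagnosis of
  - diagnostic criteria
  - case identification
  - case definition
  - ascertained
  - ascertainment
  - inclusion criteria
  - exclusion criteria
nlp_use:
  - natural language processing
  - nlp
  - text mining
  - named entity recognition
data_source:
  - electronic health record
  - electronic health records
  - ehr
  - emr
  - electronic medical record
  - electronic medical records
  - claims data
  - registry
  - medical records
  - chart review
  - administrative data
  - demographics
  - vital signs
  - clinical notes
medication_use:
  - medication
  - medications
  - prescription
  - prescriptions
  - pharmacy records
  - dispensing
  - drug exposure
code_mention:
  - icd
  - icd-9
  - icd-10
  - icd9
  - icd10
  - cpt
  - snomed
  - snomed-ct
  - read codes
  - phecode
  - billing code
  - billing codes
  - code
  - codes
negative_computational:
  - statistical
  - statistics
  - regression
  - p-value
  - confidence interval
  - software
  - algorithmic complexity
  - bootstrap
  - simulation
  - computational
negative_location:
  - hospital
  - clinic
  - city
  - county
  - province
  - country
  - region
  - site
  - catchment area
negative_financial:
  - cost
  - costs
  - insurance
  - reimbursement
  - funding
  - grant
  - budget
  - economic
  - expenditure
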