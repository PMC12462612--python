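# Template grammar for the synthetic corpus generator.  Slots: {entity}
# (a dictionary surface form), {defkw} (a definition keyword), {negkw}
# (negative-evidence vocabulary), numeric slots filled by pattern emitters.
# Shipped as data so tests can extend the grammar without code changes.
sentence:
  positive_cooccurrence:
    - "{entity} cases were {defkw} according to standard criteria."
    - "We {defkw} patients with {entity} from the source cohort."
    - "Subjects with {entity} were {defkw} by expert adjudication."
    - "Incident {entity} was {defkw} using structured electronic records."
  positive_weak_entity:
    - "Patients with {entity} were enrolled in the study."
    - "The cohort comprised adults with {entity}."
  positive_weak_keyword:
    - "Cases were {defkw} from the source population."
    - "Outcomes were {defkw} during follow-up."
  pattern_clauses:
    - "Eligibility required blood pressure above {bp_s}/{bp_d} mmHg."
    - "Cases required a value of {lab} mg/dl on two occasions."
    - "We used ICD-9 code {icd} to select encounters."
    - "Participants were aged {age} years at entry."
    - "Body mass index was {bmi} kg/m2 or higher."
  negative_plain:
    - "The follow-up period lasted several months."
    - "Baseline characteristics were similar between groups."
    - "Findings were consistent across prespecified subgroups."
    - "Participants completed the questionnaire at enrollment."
    - "The response rate exceeded expectations."
  negative_evidence:
    computational:
      - "Analyses were performed using {negkw} methods."
      - "Estimates were obtained with {negkw} procedures."
    location:
      - "Participants were recruited at a {negkw} in the area."
      - "Recruitment took place at each participating {negkw}."
    financial:
      - "The {negkw} of treatment was assessed separately."
      - "Estimates of {negkw} were reported by payers."
  negative_lone_entity:
    - "Patients with {entity} attended scheduled visits."
    - "Some participants reported a history of {entity}."
  negative_lone_keyword:
    - "The study protocol was {defkw} before enrollment."
    - "Variables were {defkw} in the analysis plan."
  negkw:
    computational: [statistical, regression, bootstrap, simulation, computational]
    location: [hospital, clinic, site, region, county]
    financial: [cost, insurance, reimbursement, funding, budget]
  defkw_single: [defined, classified, identified, ascertained]
abstract:
  positive_pool:
    - "Cases were defined using ICD-9 diagnosis codes and medication records."
    - "We identified patients using diagnostic criteria and laboratory values."
    - "The phenotype definition combined billing codes with chart review."
    - "Inclusion criteria required two outpatient codes and one prescription."
    - "Case identification relied on SNOMED concepts and laboratory tests."
    - "We classified subjects as cases using an electronic health record algorithm."
  negative_pool:
    - "The mechanism of the observed association remains unclear."
    - "We measured gene expression in cultured cells after treatment."
    - "The survey assessed lifestyle factors in the general population."
    - "Model organisms were used to study developmental pathways."
    - "This review summarizes recent advances in imaging methods."
    - "Participants reported dietary intake using a food frequency questionnaire."
  shared_filler:
    - "The study included adult participants from multiple sites."
    - "Data were collected over a ten year period."
    - "Analyses were adjusted for age and sex."
    - "Limitations include the modest sample size."
fulltext:
  intro:
    - "This condition is an important public health problem."
    - "Previous studies reported conflicting results."
    - "We aimed to characterize outcomes in a large cohort."
  results:
    - "The primary outcome occurred in a minority of participants."
    - "Effect estimates were stable in sensitivity analyses."
  methods_headings:
    - "Methods"
    - "METHODS"
    - "Materials and Methods"
    - "MATERIALS AND METHODS"
    - "Patients and Methods"
    - "PATIENTS AND METHODS"
    - "Subjects and Methods"
    - "Study Design"
    - "Methodology"
  end_headings:
    - "Results"
    - "RESULTS"
    - "Discussion"
    - "Conclusions"
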