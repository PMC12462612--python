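# Manifest for the bundled toy NER dictionary.  Real deployments point the
# same schema at locally licensed vocabulary exports (MedDRA, SNOMED-CT,
# MEDIC, ICD-9 procedures, DrugBank), which are never distributed here.
sources:
  - file: phenotypes_meddra.tsv
    source: MedDRA_PT
    entity_class: phenotype_of_interest
  - file: phenotypes_snomed.tsv
    source: SNOMED_CT
    entity_class: phenotype_of_interest
  - file: phenotypes_medic.tsv
    source: MEDIC_MESH
    entity_class: phenotype_of_interest
  - file: clinical_snomed.tsv
    source: SNOMED_CT
    entity_class: clinical
  - file: clinical_medic_mesh.tsv
    source: MEDIC_MESH
    entity_class: clinical
  - file: clinical_medic_omim.tsv
    source: MEDIC_OMIM
    entity_class: clinical
  - file: procedures_snomed.tsv
    source: SNOMED_CT
    entity_class: procedure
  - file: procedures_icd9.tsv
    source: ICD9_PROC
    entity_class: procedure
  - file: drugs_drugbank.tsv
    source: DrugBank
    entity_class: drug
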