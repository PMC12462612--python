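# phenodefminer

Mining **clinical phenotype definitions** from biomedical literature.

Defining a phenotype in electronic health records (EHRs) — which diagnosis
codes, laboratory thresholds, medications, or NLP outputs identify the
patients who *have* the condition — is expensive expert work, and most
phenotypes have no ready-made definition. Published studies, however,
routinely state how they defined their cases, usually in one or two
sentences of the methods section ("Cases were defined as patients with two
ICD-9 401.x codes and an antihypertensive prescription"). `phenodefminer`
implements a staged text-mining pipeline that finds those sentences at
scale and turns them into a queryable knowledgebase:

1. **Abstract triage** — abstracts are represented as bags of 1–3-grams
   over lowercased, stopword-filtered, Lovins-style-stemmed tokens, with
   the vocabulary capped at the 1000 most frequent grams and cells
   weighted by TF (log(1+c)) and IDF (log(N/df)) transforms; classical
   classifiers (linear SVM, logistic regression, naive Bayes, decision
   tree) score relevance.
2. **Methods-section extraction** — full texts (plain text or a
   GENIA-style XML container) are sentence-tokenized and the methods
   section is located by rule-based matching of short heading sentences
   against configurable heading lexicons.
3. **Sentence classification** — each methods sentence is described by a
   declarative feature schema over three hit inventories: exact-match
   dictionary entities (phenotypes of interest, clinical terms,
   procedures, drugs), definition/negative-evidence keyword families, and
   regexes for measurable values (blood pressure, labs, age, height,
   weight, BMI) and ICD/CPT codes. The signature feature is the
   *co-occurrence* of an entity and a definition keyword in one sentence,
   order and distance ignored. Classifiers are calibrated to a **recall
   target** (default 95%): the threshold is the largest score cutoff whose
   recall meets the target, ties broken by precision.
4. **Knowledgebase** — preferred terms are matched (with character
   offsets) in positively classified sentences; queries support partial
   (substring) or exact (word-boundary) term matching, five keyword
   filters (ICD, CPT, SNOMED, Laboratory, Medication) combinable with
   AND/OR, and CSV export.

Licensed vocabularies (MedDRA, SNOMED-CT, DrugBank, …) are **not**
bundled; the package ships a 200-term toy dictionary with the production
file schema, plus a seeded synthetic-corpus generator that plants the
statistical structure the classifiers assume, so every stage is fully
testable offline.

## Worked example

The sentence from PMID 12952547 — *"Confirmed adult-onset asthma (AOA)
cases were defined as those potential cases with either new-onset asthma
or reactivated mild intermittent asthma that had been quiescent for at
least one year"* — is the canonical demonstration of the feature scheme:

```python
from phenodefminer import (
    SentenceRecord, Lexicon, LexiconEntry,
    tag_entities, match_keywords, build_feature_vector, load_default_schema,
)

sent = SentenceRecord(pmid="12952547", sentence_index=0, text=(
    "Confirmed adult-onset asthma (AOA) cases were defined as those potential "
    "cases with either new-onset asthma or reactivated mild intermittent "
    "asthma that had been quiescent for at least one year"))
lex = Lexicon([LexiconEntry("asthma", "asthma", "clinical", "SNOMED_CT", "SCT:195967001")])

print([a.surface for a in tag_entities(sent, lex)])
print([m.surface for m in match_keywords(sent, "definition")])
fv = build_feature_vector(sent, load_default_schema(), lex).as_dict()
print(fv["n_entity_clinical"], fv["cooc_clinical_definition"])
```

prints

```
['asthma', 'asthma', 'asthma']
['defined as']
3.0 1.0
```

— three clinical-entity mentions, one definition keyword, and the
entity×definition co-occurrence feature set to 1: positive evidence that
the sentence states a phenotype definition.

An end-to-end synthetic screening run from the shell:

```bash
phenodefminer synth sentences --n-positive 200 --n-negative 200 --seed 3 --out sent.tsv
phenodefminer train sent.tsv --granularity sentence --algorithm logistic_regression
phenodefminer kb build sent.tsv --out kb.tsv
phenodefminer kb query kb.tsv --term coma --exact-match --filter ICD --filter Medication --boolean-op OR
```

## Layout

| module | contents |
| --- | --- |
| `corpus_io` | record types, tab-delimited corpora, GENIA-style XML |
| `section_extractor` | sentence tokenizer, methods-heading rules |
| `lexicon` | multi-vocabulary NER dictionary, exact mapping, summaries |
| `ner_features` | entity/keyword/pattern tagging, feature schema engine |
| `classifiers` | n-gram vectorizer, training, recall calibration, metrics |
| `kb` | knowledgebase build/query/export |
| `synthcorpus` | seeded template-grammar corpus generator |
| `pipeline` | three-phase screening orchestration |

See `docs/methods.md` for the modelling choices, defaults, and known
limitations.
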