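# Methods

This note records the modelling and engineering choices behind
`phenodefminer`, the defaults that matter, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Problem setting

A *phenotype-definition sentence* states how a study identified its cases
in EHR data: diagnosis/procedure codes, diagnostic criteria, laboratory
thresholds, medications, data sources, or NLP use. The pipeline screens
literature in three phases — abstract relevance, methods-section
localization, sentence classification — and indexes the positive
sentences by the preferred terms they mention.

## Abstract representation

Abstracts (title + abstract concatenated) become bag-of-n-grams vectors:

* tokens are maximal runs of letters/digits (hyphens join tokens),
  lowercased, filtered against a ~130-word English stopword list, and
  stemmed;
* n-grams of length 1–3 are formed over the filtered token stream;
* the vocabulary is truncated to the `words_to_keep` (default 1000) grams
  with the highest **total** frequency in the training corpus, frequency
  ties broken lexicographically so fits are reproducible;
* cell values are `log(1 + count) * log(N / df)` — the TF and IDF
  transforms, each independently switchable. `N` and `df` come from the
  training corpus only; `transform` never extends the vocabulary, so no
  information leaks from held-out documents.

The stemmer is a compact Lovins-family iterated longest-suffix stripper:
at each pass the longest listed ending whose removal leaves ≥ 2
characters is removed and a terminal doubled consonant is undoubled,
iterating to a fixed point. The ending inventory (~50 suffixes) is a
curated subset tuned for method prose, not a transcription of the
original 294-ending table; because keywords and sentence tokens are
stemmed with the same function, matching only requires that inflectional
families collapse consistently ("classified"/"classifying" → "classif").
Known coarseness: unrelated words occasionally share a stem (e.g.
"county"/"counted" → "count"); dictionary *entity* terms are therefore
never stemmed — entity matching is exact on a normalized surface form.

## Sentence features

Each sentence yields three hit inventories:

* **entities** — case-insensitive exact matches of dictionary terms on
  token boundaries, longest match first, leftmost on ties; all dictionary
  entries tied at the winning length (same term in several vocabularies)
  are reported. Normalization is case-folding, whitespace collapsing and
  edge-punctuation stripping.
* **keywords** — eight configurable families: `definition`, `nlp_use`,
  `data_source`, `medication_use`, `code_mention` (positive evidence) and
  `negative_computational`, `negative_location`, `negative_financial`
  (negative evidence). Matching is token-wise on stems by default;
  multiword keywords match token-by-token.
* **patterns** — case-insensitive regexes for blood pressure (`140/90
  mmHg`), laboratory values (number + clinical unit), age, height,
  weight, BMI, and ICD/CPT code strings. The expressions are documented
  stand-ins covering canonical surface forms, versioned in
  `data/patterns.yaml`.

The default schema (`data/schema.yaml`) realizes 50 features: binary +
count per entity class (8), per keyword family (16), per pattern (16),
entity×definition and entity×code co-occurrences (8), and positive/
negative evidence sums (2). A co-occurrence feature is 1 iff *every*
operand group has at least one hit anywhere in the sentence — order and
distance are deliberately ignored. The schema is an editable manifest;
production deployments with licensed vocabularies extend it to several
hundred features without code changes. Entity hits inside keyword spans
are counted independently (no double-count suppression).

## Classifiers and calibration

Four classical algorithms (scikit-learn estimators behind a uniform
wrapper): linear-kernel SVM, logistic regression, Gaussian naive Bayes,
and a CART decision tree standing in for C4.5. Scores are the SVM margin
or the class-1 probability (leaf class frequency for the tree); the
contract is only that higher = more positive, which is all threshold
sweeping needs.

`calibrate_threshold(scores, labels, target_recall=0.95)` selects the
largest cutoff (over the distinct scores plus one sentinel above the
maximum) whose recall meets the target; among cutoffs achieving that same
recall the one maximizing precision wins, residual ties going to the
larger threshold. A recall target of 0 legitimately selects the
empty-prediction sentinel; precision and F use the
zero-denominator-gives-0 convention throughout. The operating point
records achieved recall/precision and a `reachable` flag. Deep models
(CNN / BERT-family) are not trained here; `AdapterConfig` documents the
contract (512-token truncation, zero padding, 5e-5 fine-tuning rate,
higher-is-positive scores) under which externally computed scores reuse
the same calibration and evaluation path.

Evaluation reports positive-class accuracy/precision/recall/F; a
support-weighted variant (`evaluate_weighted`) is provided as well,
because published tables sometimes average over classes, which makes the
metrics coincide on balanced errors — the package does not claim either
convention for any external report. Splits are stratified 70/30 by
default with a mandatory seed.

## Methods-section rules

Headings match case-insensitively against whole sentences of at most 6
word tokens, after stripping numbering ("2.1 Methods") and edge
punctuation — prose mentioning "methods" mid-paragraph never triggers.
Default lexicons (configurable in `data/sections.yaml`):
start = {methods, materials and methods, patients and methods, subjects
and methods, study design, methodology}; end = {results, discussion,
conclusion(s), references, acknowledg(e)ments}. The first start heading
wins; nested start headings inside the section are dropped as headings
but do not terminate the span; the span is half-open, ends at the first
end heading or document end, and may be empty (a heading directly
followed by an end heading). Heading sentences are excluded from content.

The sentence tokenizer splits after `.!?` runs followed by whitespace,
with an abbreviation whitelist (Dr., e.g., Fig., et al., …) and inherent
decimal protection (a period inside `2.5` is never followed by
whitespace). Concatenating sentence texts reconstructs the input up to
inter-sentence whitespace, and each sentence carries 0-based half-open
character offsets. All offsets in the package follow that convention.

## Synthetic corpora

The generator (`synthcorpus`) plants the structure the classifiers
assume, from a template grammar shipped as data:

* positive sentences contain an entity×definition-keyword co-occurrence
  with probability `signal` (default 0.9), else only weak evidence (lone
  entity or lone keyword); a quantitative-value/code clause is appended
  with probability `pattern_rate` (0.5);
* negative sentences are bland method prose, contaminated with a lone
  entity or lone keyword with probability `contamination` (0.2) and
  carrying computational/location/financial vocabulary with probability
  `negative_evidence_rate` (0.6);
* positive abstracts include definition/code-rich sentences with
  probability `signal`; both classes share filler sentences;
* full texts are Introduction / methods-heading / definition sentences /
  end-heading / Results, returned with the ground-truth span.

Defaults are the package's study conditions: a strong but imperfect
signal with realistic lone-evidence contamination, sized (n ≈ 2000
sentences, 1000 abstracts, 100 full texts) so the whole suite and the
acceptance script run in seconds on one CPU. One global seed drives
per-operation substreams, so regenerating one corpus never perturbs
another and document *k* of a full-text corpus is stable as the corpus
grows.

What the generator does **not** emulate: real scientific prose and its
ambiguity (hedging, anaphora, abbreviations), OCR/PDF-conversion noise,
section-heading variety beyond the configured lexicons, class imbalance
at literature scale, and sentences whose evidence spans sentence
boundaries. Passing tests therefore demonstrate that the machinery is
correct and that planted structure at the stated rates is recovered; they
do not certify performance on real corpora, which depends on annotation
quality and licensed dictionary coverage.

## Knowledgebase semantics

Records are one row per preferred-term occurrence with character offsets
validated against the sentence (`sentence[start:end] == term`, case-
insensitively). Partial query matching is case-insensitive substring
containment of the query in the stored term (so "coma" retrieves
"glucoma"); exact matching requires the query to occur in the stored term
on word boundaries (so "coma" does not retrieve "glucoma", but "diabetes"
still retrieves "type 2 diabetes mellitus"). Exact results are provably a
subset of partial results, and AND-filtered results of OR-filtered ones.
Filter trigger vocabularies are explicit configuration
(`KEYWORD_FILTER_GROUPS`), not hidden heuristics. Storage is a flat
seven-column tab-delimited table — no database server.

## Numerical and degenerate-input conventions

* Empty/whitespace input → empty sentence list; empty lexicon → no entity
  annotations (an error only where a non-empty dictionary is required:
  generation, KB build).
* A corpus consisting solely of stopwords raises an explicit
  empty-vocabulary error naming the cause.
* Single-class training labels, non-finite features, calibration without
  positives, and dimension mismatches all raise with specific messages.
* Screening artifacts are byte-deterministic: timestamps are excluded
  from serialized reports (an opt-in flag records them in memory), and a
  16-hex-digit SHA-256 config digest ties artifacts to their settings.

## Limitations

* Exact dictionary matching misses lexical variants, abbreviations and
  misspellings; abbreviation resolution is out of scope by design.
* The 50-feature default schema is a faithful reconstruction of the
  feature *kinds* (binary, count, co-occurrence, sum over the named
  entity classes, keyword families and value patterns), not of any
  specific production feature list.
* Heading lexicons cover standard IMRaD structure; unconventional section
  titles require configuration.
* PDF-to-text conversion, PubMed harvesting, negation detection, fuzzy
  matching, and primary-phenotype disambiguation within a sentence are
  out of scope.
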