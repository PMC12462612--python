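"""Sentence-level tagging and declarative feature engineering.

A sentence is described by three hit inventories:

* **entities** — exact, case-insensitive, word-boundary dictionary matches
  (longest match wins on overlap, leftmost on ties); the mechanism behind
  "asthma" being tagged three times in a sentence that mentions it thrice;
* **keywords** — word-boundary matches of configured keyword families
  (definition vocabulary, NLP use, data sources, medication use, code
  mentions, and the three negative-evidence families), optionally compared
  on stems so "classified" matches "classify";
* **quantitative patterns** — regexes for measurable values (blood
  pressure, laboratory values, age, height, weight, BMI) and ICD/CPT code
  strings.

A :class:`FeatureSchema` compiled from a manifest turns those inventories
into a fixed-length numeric vector per sentence: binary presence flags,
hit counts, order/distance-free co-occurrence indicators (a clinical
entity AND a definition keyword anywhere in the sentence), and arithmetic
sums of previously defined features.  Extraction is deterministic and
sentence-local, so feature matrices are order-independent across corpora.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from ._stem import stem
from .corpus_io import SentenceRecord
from .lexicon import ENTITY_CLASSES, Lexicon

__all__ = [
    "KEYWORD_FAMILIES",
    "PATTERN_NAMES",
    "EntityAnnotation",
    "KeywordMatch",
    "PatternHit",
    "FeatureSchema",
    "FeatureVector",
    "SchemaConfigError",
    "load_keyword_families",
    "load_patterns",
    "load_default_schema",
    "tag_entities",
    "match_keywords",
    "extract_quantitative_patterns",
    "build_feature_vector",
    "build_feature_matrix",
]

KEYWORD_FAMILIES = (
    "definition",
    "nlp_use",
    "data_source",
    "medication_use",
    "code_mention",
    "negative_computational",
    "negative_location",
    "negative_financial",
)
PATTERN_NAMES = (
    "blood_pressure",
    "lab_value",
    "age",
    "height",
    "weight",
    "bmi",
    "icd_code",
    "cpt_code",
)


class SchemaConfigError(ValueError):
    """A schema manifest references an unknown operand or is malformed."""


@dataclass(frozen=True)
class EntityAnnotation:
    """A dictionary match in a sentence; offsets are 0-based half-open."""

    start: int
    end: int
    surface: str
    entity_class: str
    term_id: str
    source: str


@dataclass(frozen=True)
class KeywordMatch:
    family: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class PatternHit:
    pattern_name: str
    start: int
    end: int
    surface: str


# ---------------------------------------------------------------------------
# Config loading

def _read_data_yaml(name: str, path: Optional[Union[str, Path]]):
    if path is None:
        raw = resources.files("phenodefminer.data").joinpath(name).read_text("utf-8")
    else:
        raw = Path(path).read_text("utf-8")
    return yaml.safe_load(raw)


def load_keyword_families(path: Optional[Union[str, Path]] = None) -> dict[str, list[str]]:
    """Keyword lists per family (bundled default when no path given)."""
    cfg = _read_data_yaml("keywords.yaml", path)
    return {family: [str(k).lower() for k in terms] for family, terms in cfg.items()}


def load_patterns(path: Optional[Union[str, Path]] = None) -> dict[str, "re.Pattern[str]"]:
    """Compiled case-insensitive quantitative-value/code regexes."""
    cfg = _read_data_yaml("patterns.yaml", path)
    return {name: re.compile(expr, re.IGNORECASE) for name, expr in cfg.items()}


_DEFAULT_KEYWORDS: Optional[dict[str, list[str]]] = None
_DEFAULT_PATTERNS: Optional[dict[str, "re.Pattern[str]"]] = None


def _default_keywords() -> dict[str, list[str]]:
    global _DEFAULT_KEYWORDS
    if _DEFAULT_KEYWORDS is None:
        _DEFAULT_KEYWORDS = load_keyword_families()
    return _DEFAULT_KEYWORDS


def _default_patterns() -> dict[str, "re.Pattern[str]"]:
    global _DEFAULT_PATTERNS
    if _DEFAULT_PATTERNS is None:
        _DEFAULT_PATTERNS = load_patterns()
    return _DEFAULT_PATTERNS


# ---------------------------------------------------------------------------
# Tokenization shared by the taggers

# word characters are letters/digits; hyphens join tokens ("snomed-ct")
_TOKEN = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def _tokens_with_offsets(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]


# ---------------------------------------------------------------------------
# Entity tagging


def tag_entities(sentence: SentenceRecord, lex: Lexicon) -> list[EntityAnnotation]:
    """Exact-match dictionary tagging with longest-match resolution.

    Scans left to right over word tokens; at each position the longest
    dictionary term (in tokens, then characters) anchored there wins, and
    every dictionary entry tied at that length (same term in several
    vocabularies or classes) yields an annotation for the same span.  The
    scan resumes after the matched span, so overlapping shorter candidates
    are suppressed (ties broken leftmost).  Word boundaries are token
    boundaries: "coma" never matches inside "glaucoma".
    """
    text = sentence.text
    if not text:
        return []
    tokens = _tokens_with_offsets(text)
    lowered = [t[0].casefold() for t in tokens]
    annotations: list[EntityAnnotation] = []
    i = 0
    while i < len(tokens):
        bucket = lex.candidates(lowered[i])
        best_len = 0
        best_entries: list = []
        for term_tokens, entry in bucket:
            n = len(term_tokens)
            if n < best_len:
                break  # bucket sorted longest-first
            if i + n <= len(tokens) and tuple(lowered[i : i + n]) == term_tokens:
                if n > best_len:
                    best_len = n
                    best_entries = [entry]
                else:
                    best_entries.append(entry)
        if best_len:
            start = tokens[i][1]
            end = tokens[i + best_len - 1][2]
            surface = text[start:end]
            for entry in best_entries:
                annotations.append(
                    EntityAnnotation(
                        start=start,
                        end=end,
                        surface=surface,
                        entity_class=entry.entity_class,
                        term_id=entry.term_id,
                        source=entry.source,
                    )
                )
            i += best_len
        else:
            i += 1
    annotations.sort(key=lambda a: (a.start, -(a.end - a.start), a.entity_class, a.source))
    return annotations


# ---------------------------------------------------------------------------
# Keyword matching


def _match_token_sequence(
    sentence_tokens: Sequence[str],
    keyword_tokens: Sequence[str],
    position: int,
) -> bool:
    n = len(keyword_tokens)
    if position + n > len(sentence_tokens):
        return False
    return all(sentence_tokens[position + j] == keyword_tokens[j] for j in range(n))


def match_keywords(
    sentence: SentenceRecord,
    family: str,
    stem_match: bool = True,
    keyword_families: Optional[Mapping[str, list[str]]] = None,
) -> list[KeywordMatch]:
    """Word-boundary keyword matching for one family.

    With ``stem_match`` the comparison is between stemmed sentence tokens
    and stemmed keyword tokens (multiword keywords token-by-token), so
    inflectional variants match.  Overlapping keywords of one family are
    resolved longest-first at each position.

    Raises
    ------
    SchemaConfigError
        ``family`` has no configured keyword list.
    """
    families = keyword_families if keyword_families is not None else _default_keywords()
    if family not in families:
        raise SchemaConfigError(f"no keyword list configured for family {family!r}")
    text = sentence.text
    tokens = _tokens_with_offsets(text)
    sent_forms = [stem(t[0].casefold()) if stem_match else t[0].casefold() for t in tokens]

    compiled: list[tuple[list[str], str]] = []
    for kw in families[family]:
        kw_tokens = [t.casefold() for t in _TOKEN.findall(kw)]
        if stem_match:
            kw_tokens = [stem(t) for t in kw_tokens]
        if kw_tokens:
            compiled.append((kw_tokens, kw))
    compiled.sort(key=lambda pair: -len(pair[0]))

    matches: list[KeywordMatch] = []
    i = 0
    while i < len(tokens):
        hit_len = 0
        for kw_tokens, _ in compiled:
            if len(kw_tokens) <= hit_len:
                break
            if _match_token_sequence(sent_forms, kw_tokens, i):
                hit_len = len(kw_tokens)
        if hit_len:
            start = tokens[i][1]
            end = tokens[i + hit_len - 1][2]
            matches.append(KeywordMatch(family=family, start=start, end=end, surface=text[start:end]))
            i += hit_len
        else:
            i += 1
    return matches


# ---------------------------------------------------------------------------
# Quantitative patterns


def extract_quantitative_patterns(
    sentence: SentenceRecord,
    patterns: Optional[Mapping[str, "re.Pattern[str]"]] = None,
) -> list[PatternHit]:
    """Regex hits for measurable values and code strings.

    Hits of different pattern types may overlap; within one type
    ``re.finditer`` guarantees non-overlapping hits.  Results are sorted by
    (start, pattern name).
    """
    pats = patterns if patterns is not None else _default_patterns()
    text = sentence.text
    hits = [
        PatternHit(pattern_name=name, start=m.start(), end=m.end(), surface=m.group(0))
        for name, pat in pats.items()
        for m in pat.finditer(text)
    ]
    hits.sort(key=lambda h: (h.start, h.pattern_name))
    return hits


# ---------------------------------------------------------------------------
# Feature schema


@dataclass(frozen=True)
class _FeatureDef:
    name: str
    kind: str  # binary | count | cooccurrence | sum
    operands: tuple[str, ...]


class FeatureSchema:
    """A compiled, fixed-length ordered list of feature definitions.

    Compile once from a manifest (:meth:`from_manifest` /
    :func:`load_default_schema`); operand references are validated at
    compile time so per-sentence extraction cannot fail on configuration.
    """

    _KINDS = ("binary", "count", "cooccurrence", "sum")

    def __init__(
        self,
        definitions: Iterable[_FeatureDef],
        keyword_families: Optional[Mapping[str, list[str]]] = None,
        patterns: Optional[Mapping[str, "re.Pattern[str]"]] = None,
        stem_keywords: bool = True,
    ):
        self.keyword_families = dict(
            keyword_families if keyword_families is not None else _default_keywords()
        )
        self.patterns = dict(patterns if patterns is not None else _default_patterns())
        self.stem_keywords = stem_keywords
        self.definitions: list[_FeatureDef] = []
        seen: set[str] = set()
        for d in definitions:
            if d.kind not in self._KINDS:
                raise SchemaConfigError(f"feature {d.name!r}: unknown kind {d.kind!r}")
            if d.name in seen:
                raise SchemaConfigError(f"duplicate feature name {d.name!r}")
            for op in d.operands:
                self._validate_operand(d, op, seen)
            seen.add(d.name)
            self.definitions.append(d)

    def _validate_operand(self, d: _FeatureDef, op: str, seen: set[str]) -> None:
        if d.kind == "sum":
            if op not in seen:
                raise SchemaConfigError(
                    f"sum feature {d.name!r} references {op!r}, which is not a previously defined feature"
                )
            return
        if op.startswith("entity:"):
            if op.split(":", 1)[1] not in ENTITY_CLASSES:
                raise SchemaConfigError(f"feature {d.name!r}: unknown entity class in {op!r}")
        elif op.startswith("keyword:"):
            if op.split(":", 1)[1] not in self.keyword_families:
                raise SchemaConfigError(f"feature {d.name!r}: unconfigured keyword family in {op!r}")
        elif op.startswith("pattern:"):
            if op.split(":", 1)[1] not in self.patterns:
                raise SchemaConfigError(f"feature {d.name!r}: unconfigured pattern in {op!r}")
        else:
            raise SchemaConfigError(
                f"feature {d.name!r}: operand {op!r} must be entity:/keyword:/pattern:"
            )

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.definitions]

    @classmethod
    def from_manifest(
        cls,
        path: Optional[Union[str, Path]] = None,
        keyword_families: Optional[Mapping[str, list[str]]] = None,
        patterns: Optional[Mapping[str, "re.Pattern[str]"]] = None,
    ) -> "FeatureSchema":
        cfg = _read_data_yaml("schema.yaml", path)
        defs = [
            _FeatureDef(name=item["name"], kind=item["kind"], operands=tuple(item["operands"]))
            for item in cfg["features"]
        ]
        return cls(defs, keyword_families=keyword_families, patterns=patterns)


def load_default_schema() -> FeatureSchema:
    """The bundled 50-feature schema."""
    return FeatureSchema.from_manifest()


@dataclass(frozen=True)
class FeatureVector:
    """Realized features for one sentence, aligned to a schema."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    sentence: SentenceRecord

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.values.tolist()))


def _hit_counts(
    sentence: SentenceRecord, schema: FeatureSchema, lex: Lexicon
) -> dict[str, int]:
    """Count hits per operand key used anywhere in the schema."""
    needed_entities = set()
    needed_families = set()
    needed_patterns = set()
    for d in schema.definitions:
        if d.kind == "sum":
            continue
        for op in d.operands:
            kind, _, value = op.partition(":")
            if kind == "entity":
                needed_entities.add(value)
            elif kind == "keyword":
                needed_families.add(value)
            elif kind == "pattern":
                needed_patterns.add(value)

    counts: dict[str, int] = {}
    if needed_entities:
        annotations = tag_entities(sentence, lex)
        for cls in needed_entities:
            counts[f"entity:{cls}"] = sum(1 for a in annotations if a.entity_class == cls)
    for family in needed_families:
        counts[f"keyword:{family}"] = len(
            match_keywords(
                sentence,
                family,
                stem_match=schema.stem_keywords,
                keyword_families=schema.keyword_families,
            )
        )
    if needed_patterns:
        hits = extract_quantitative_patterns(sentence, patterns=schema.patterns)
        for name in needed_patterns:
            counts[f"pattern:{name}"] = sum(1 for h in hits if h.pattern_name == name)
    return counts


def build_feature_vector(
    sentence: SentenceRecord, schema: FeatureSchema, lex: Lexicon
) -> FeatureVector:
    """Realize the schema on one sentence.

    binary = 1 iff the operand has ≥1 hit; count = number of hits;
    cooccurrence = 1 iff all operand groups have ≥1 hit; sum = arithmetic
    sum of the referenced feature values.  An empty sentence yields the
    all-zero vector.
    """
    counts = _hit_counts(sentence, schema, lex)
    values = np.zeros(len(schema), dtype=float)
    by_name: dict[str, float] = {}
    for j, d in enumerate(schema.definitions):
        if d.kind == "binary":
            v = 1.0 if counts.get(d.operands[0], 0) > 0 else 0.0
        elif d.kind == "count":
            v = float(counts.get(d.operands[0], 0))
        elif d.kind == "cooccurrence":
            v = 1.0 if all(counts.get(op, 0) > 0 for op in d.operands) else 0.0
        else:  # sum
            v = float(sum(by_name[op] for op in d.operands))
        values[j] = v
        by_name[d.name] = v
    return FeatureVector(values=values, feature_names=tuple(schema.feature_names), sentence=sentence)


def build_feature_matrix(
    corpus: Sequence[SentenceRecord], schema: FeatureSchema, lex: Lexicon
) -> tuple[np.ndarray, pd.DataFrame]:
    """Feature matrix for a sentence corpus.

    Returns ``(X, row_index)`` where row *i* of ``X`` (shape
    n_sentences × len(schema)) is ``build_feature_vector(corpus[i])`` and
    ``row_index`` carries (pmid, sentence_index, label) per row.
    """
    X = np.zeros((len(corpus), len(schema)), dtype=float)
    rows = []
    for i, sent in enumerate(corpus):
        X[i] = build_feature_vector(sent, schema, lex).values
        rows.append(
            {"pmid": sent.pmid, "sentence_index": sent.sentence_index, "label": sent.label}
        )
    return X, pd.DataFrame(rows)


def export_feature_matrix(
    X: np.ndarray, schema: FeatureSchema, path: Union[str, Path]
) -> None:
    """Write the matrix as a tab-delimited numeric table, header = names."""
    df = pd.DataFrame(X, columns=schema.feature_names)
    df.to_csv(path, sep="\t", index=False)
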