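"""Phenotype-definition sentence knowledgebase (CliPheKB-style semantics).

Positively classified sentences are scanned for preferred-term occurrences
(MedDRA PTs in real deployments; any lexicon restricted to one source in
general), producing one record per term occurrence with character offsets.
The knowledgebase is a flat single table with seven columns —
``meddra_term, term_id, term_start_position, term_end_position, pmid,
sentence_index, sentence_text`` — persisted as tab-delimited text.

Query semantics:

* **partial match** (default): the query term is contained, case-
  insensitively, anywhere in the stored term — "coma" retrieves "glucoma";
* **exact match**: the query term must match the stored term on word
  boundaries — "coma" no longer retrieves "glucoma";
* **keyword filters**: each selected filter (ICD, CPT, SNOMED, Laboratory,
  Medication) tests the sentence text against a configurable trigger
  vocabulary; multiple filters combine with OR or AND;
* results deduplicate at (pmid, sentence_index, term) level and export as
  RFC-4180 CSV with columns PMID, phenotype, sentence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .corpus_io import SentenceRecord
from .lexicon import Lexicon

__all__ = [
    "KEYWORD_FILTER_GROUPS",
    "KBRecord",
    "KBQuery",
    "build_kb",
    "query_kb",
    "term_frequencies",
    "filter_sentences_by_keyword",
    "export_results_csv",
    "save_kb",
    "load_kb",
]

# Trigger vocabularies behind the five query filters.  The filter names are
# fixed UI-level concepts; the vocabularies are configurable stand-ins.
KEYWORD_FILTER_GROUPS: dict[str, tuple[str, ...]] = {
    "ICD": ("icd", "icd-9", "icd-10", "icd9", "icd10"),
    "CPT": ("cpt",),
    "SNOMED": ("snomed", "snomed-ct"),
    "Laboratory": ("laboratory", "lab value", "lab values", "lab test", "lab tests"),
    "Medication": ("medication", "medications", "drug", "drugs", "prescription"),
}


@dataclass(frozen=True)
class KBRecord:
    """One preferred-term occurrence inside one sentence."""

    meddra_term: str
    term_id: str
    term_start_position: int
    term_end_position: int
    pmid: str
    sentence_index: int
    sentence_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.term_start_position < self.term_end_position <= len(self.sentence_text)):
            raise ValueError("term offsets out of sentence bounds")
        sliced = self.sentence_text[self.term_start_position : self.term_end_position]
        if sliced.casefold() != self.meddra_term.casefold():
            raise ValueError(
                f"sentence slice {sliced!r} does not equal term {self.meddra_term!r} (case-insensitive)"
            )


@dataclass(frozen=True)
class KBQuery:
    """A filterable knowledgebase query."""

    phenotype_term: str
    exact_match: bool = False
    keyword_filters: frozenset[str] = frozenset()
    boolean_op: str = "OR"

    def __post_init__(self) -> None:
        if not self.phenotype_term or not self.phenotype_term.strip():
            raise ValueError("phenotype_term must be non-empty")
        if self.boolean_op not in ("OR", "AND"):
            raise ValueError("boolean_op must be 'OR' or 'AND'")
        unknown = set(self.keyword_filters) - set(KEYWORD_FILTER_GROUPS)
        if unknown:
            raise ValueError(f"unknown keyword filters: {sorted(unknown)}")


def _word_regex(term: str) -> "re.Pattern[str]":
    # boundaries are transitions between word chars and non-word chars
    return re.compile(rf"(?<![^\W_]){re.escape(term)}(?![^\W_])", re.IGNORECASE)


def build_kb(
    sentences: Iterable[SentenceRecord], pt_lexicon: Lexicon
) -> list[KBRecord]:
    """Scan sentences for preferred-term occurrences.

    Every word-boundary occurrence of every preferred term yields one
    record (two mentions of "coma" in one sentence give two records);
    sentences with no occurrence contribute nothing.  Records are sorted
    by (pmid, sentence_index, term_start_position, term).
    """
    if len(pt_lexicon) == 0:
        raise ValueError("pt_lexicon must be non-empty")
    # one representative entry per normalized term is enough for matching
    terms: dict[str, str] = {}
    for e in pt_lexicon.entries:
        terms.setdefault(e.normalized, e.term_id)
    compiled = [(norm, term_id, _word_regex(norm)) for norm, term_id in sorted(terms.items())]

    records: list[KBRecord] = []
    for sent in sentences:
        for norm, term_id, pat in compiled:
            for m in pat.finditer(sent.text):
                records.append(
                    KBRecord(
                        meddra_term=norm,
                        term_id=term_id,
                        term_start_position=m.start(),
                        term_end_position=m.end(),
                        pmid=sent.pmid,
                        sentence_index=sent.sentence_index,
                        sentence_text=sent.text,
                    )
                )
    records.sort(
        key=lambda r: (r.pmid, r.sentence_index, r.term_start_position, r.meddra_term)
    )
    return records


def _sentence_passes_filters(
    sentence_text: str,
    filters: frozenset[str],
    boolean_op: str,
    groups: Mapping[str, tuple[str, ...]],
) -> bool:
    if not filters:
        return True
    lowered = sentence_text.lower()
    hits = [any(kw in lowered for kw in groups[f]) for f in sorted(filters)]
    return all(hits) if boolean_op == "AND" else any(hits)


def query_kb(
    kb: Sequence[KBRecord],
    q: KBQuery,
    filter_groups: Optional[Mapping[str, tuple[str, ...]]] = None,
) -> pd.DataFrame:
    """Run a query; returns a (PMID, phenotype, sentence) table.

    Partial matching is case-insensitive substring containment of the
    query term in the stored term; exact matching requires the query term
    to appear in the stored term on word boundaries.  Keyword filters test
    the sentence text and combine with the query's Boolean operator.
    Results deduplicate at (pmid, sentence_index, phenotype) level.
    """
    groups = dict(filter_groups) if filter_groups is not None else KEYWORD_FILTER_GROUPS
    term = q.phenotype_term.strip().lower()
    exact_pat = _word_regex(term) if q.exact_match else None

    rows = []
    seen: set[tuple[str, int, str]] = set()
    for rec in kb:
        stored = rec.meddra_term.lower()
        if q.exact_match:
            if not exact_pat.search(stored):
                continue
        else:
            if term not in stored:
                continue
        if not _sentence_passes_filters(rec.sentence_text, q.keyword_filters, q.boolean_op, groups):
            continue
        key = (rec.pmid, rec.sentence_index, rec.meddra_term)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {"PMID": rec.pmid, "phenotype": rec.meddra_term, "sentence": rec.sentence_text}
        )
    return pd.DataFrame(rows, columns=["PMID", "phenotype", "sentence"])


def term_frequencies(kb: Sequence[KBRecord]) -> pd.DataFrame:
    """Occurrence counts per stored term, descending (word-cloud input).

    Counts sum to ``len(kb)`` since every record is one occurrence.
    """
    if not kb:
        return pd.DataFrame(columns=["meddra_term", "count"])
    counts: dict[str, int] = {}
    for rec in kb:
        counts[rec.meddra_term] = counts.get(rec.meddra_term, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["meddra_term", "count"],
    )
    return df


def filter_sentences_by_keyword(
    sentences: Sequence[SentenceRecord], keyword: str
) -> list[SentenceRecord]:
    """Sentences containing ``keyword`` case-insensitively (substring)."""
    if not keyword:
        raise ValueError("keyword must be non-empty")
    kw = keyword.lower()
    return [s for s in sentences if kw in s.text.lower()]


def export_results_csv(result: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a query result as RFC-4180-style CSV (header + quoted fields)."""
    result.to_csv(path, index=False, lineterminator="\n")


_KB_COLUMNS = [
    "meddra_term",
    "term_id",
    "term_start_position",
    "term_end_position",
    "pmid",
    "sentence_index",
    "sentence_text",
]


def save_kb(kb: Sequence[KBRecord], path: Union[str, Path]) -> None:
    """Persist the knowledgebase as a seven-column tab-delimited table."""
    df = pd.DataFrame(
        [
            {
                "meddra_term": r.meddra_term,
                "term_id": r.term_id,
                "term_start_position": r.term_start_position,
                "term_end_position": r.term_end_position,
                "pmid": r.pmid,
                "sentence_index": r.sentence_index,
                "sentence_text": r.sentence_text,
            }
            for r in kb
        ],
        columns=_KB_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_kb(path: Union[str, Path]) -> list[KBRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"pmid": str}, keep_default_na=False)
    return [
        KBRecord(
            meddra_term=row.meddra_term,
            term_id=str(row.term_id),
            term_start_position=int(row.term_start_position),
            term_end_position=int(row.term_end_position),
            pmid=str(row.pmid),
            sentence_index=int(row.sentence_index),
            sentence_text=row.sentence_text,
        )
        for row in df.itertuples(index=False)
    ]
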