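"""Multi-vocabulary entity dictionary for exact-match NER.

The dictionary maps surface terms from several source vocabularies
(MedDRA preferred terms, SNOMED-CT, MEDIC/MeSH, MEDIC/OMIM, ICD-9
procedures, DrugBank) onto four entity classes: clinical phenotypes of
interest, general clinical terms, procedures, and drugs.  Matching is exact
on a normalized form — case-folded, internal whitespace collapsed,
leading/trailing punctuation stripped; dictionary terms are never stemmed
(stemming belongs to keyword matching, a separate mechanism).

Licensed vocabularies are never bundled.  The package ships a ~200-term toy
lexicon with the same file schema (tab-delimited ``term<TAB>term_id`` files
plus a YAML manifest assigning each file a source and entity class) so the
whole pipeline is exercisable without downloads.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ENTITY_CLASSES",
    "SOURCES",
    "LexiconEntry",
    "Lexicon",
    "normalize_term",
    "load_lexicon",
    "load_lexicon_from_manifest",
    "load_toy_lexicon",
    "map_terms_exact",
    "lexicon_summary",
]

ENTITY_CLASSES = ("phenotype_of_interest", "clinical", "procedure", "drug")
SOURCES = ("MedDRA_PT", "SNOMED_CT", "MEDIC_MESH", "MEDIC_OMIM", "ICD9_PROC", "DrugBank")

_WS = re.compile(r"\s+")
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$")


def normalize_term(term: str) -> str:
    """Case-fold, collapse whitespace, strip leading/trailing punctuation."""
    term = _WS.sub(" ", term.casefold().strip())
    return _EDGE_PUNCT.sub("", term)


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    normalized: str
    entity_class: str
    source: str
    term_id: str

    def __post_init__(self) -> None:
        if not self.normalized:
            raise ValueError("normalized term must be non-empty")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity_class {self.entity_class!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


class Lexicon:
    """A set of :class:`LexiconEntry` with a first-token lookup index.

    The index maps the normalized first token of each term to the entries
    starting with it, pre-sorted by descending token count so the tagger
    can do longest-match scanning without re-sorting.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()):
        self._entries: dict[tuple[str, str, str], LexiconEntry] = {}
        for e in entries:
            self._entries.setdefault((e.normalized, e.entity_class, e.source), e)
        self._index: dict[str, list[tuple[tuple[str, ...], LexiconEntry]]] = {}
        for e in self._entries.values():
            tokens = tuple(e.normalized.split(" "))
            self._index.setdefault(tokens[0], []).append((tokens, e))
        for bucket in self._index.values():
            bucket.sort(key=lambda pair: (-len(pair[0]), pair[0], pair[1].entity_class, pair[1].source))

    @property
    def entries(self) -> list[LexiconEntry]:
        return sorted(
            self._entries.values(), key=lambda e: (e.entity_class, e.source, e.normalized)
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return set(self._entries) == set(other._entries)

    def candidates(self, first_token: str) -> list[tuple[tuple[str, ...], LexiconEntry]]:
        """Entries whose normalized form starts with ``first_token``,
        longest (most tokens) first."""
        return self._index.get(first_token, [])

    def restrict(
        self,
        sources: Optional[Iterable[str]] = None,
        entity_classes: Optional[Iterable[str]] = None,
    ) -> "Lexicon":
        """Sub-lexicon filtered by source and/or entity class."""
        src = set(sources) if sources is not None else None
        cls = set(entity_classes) if entity_classes is not None else None
        return Lexicon(
            e
            for e in self._entries.values()
            if (src is None or e.source in src) and (cls is None or e.entity_class in cls)
        )

    def normalized_terms(self) -> set[str]:
        return {e.normalized for e in self._entries.values()}


def _read_term_file(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if first and cells[0].strip().lower() == "term":
                first = False
                continue  # optional header
            first = False
            term = cells[0]
            term_id = cells[1] if len(cells) > 1 else ""
            rows.append((term, term_id))
    return rows


def load_lexicon(
    paths: Mapping[str, Union[str, Path]],
    class_assignments: Mapping[str, str],
) -> Lexicon:
    """Build a :class:`Lexicon` from one term-list file per source.

    Parameters
    ----------
    paths:
        Mapping source tag → term file (``term<TAB>term_id`` rows, optional
        header).  A source tag may appear once; a file may be shared.
    class_assignments:
        Mapping source tag → entity class for the entries of that file.

    Duplicate (normalized, class, source) rows collapse to one entry with a
    logged count; rows whose term normalizes to the empty string are skipped
    with a warning.  An unknown source or class tag raises ``ValueError``.
    """
    entries: list[LexiconEntry] = []
    n_dupes = 0
    for source, path in paths.items():
        if source not in SOURCES:
            raise ValueError(f"unknown source tag {source!r}; expected one of {SOURCES}")
        entity_class = class_assignments[source]
        if entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {entity_class!r} for source {source!r}")
        seen: set[str] = set()
        for term, term_id in _read_term_file(Path(path)):
            norm = normalize_term(term)
            if not norm:
                logger.warning("skipping term %r (%s): empty after normalization", term, source)
                continue
            if norm in seen:
                n_dupes += 1
                continue
            seen.add(norm)
            entries.append(
                LexiconEntry(
                    surface=term.strip(),
                    normalized=norm,
                    entity_class=entity_class,
                    source=source,
                    term_id=term_id,
                )
            )
    if n_dupes:
        logger.info("collapsed %d duplicate term rows", n_dupes)
    return Lexicon(entries)


def load_lexicon_from_manifest(manifest_path: Union[str, Path]) -> Lexicon:
    """Load a lexicon from a YAML manifest listing term files.

    Manifest schema::

        sources:
          - file: phenotypes_meddra.tsv   # relative to the manifest
            source: MedDRA_PT
            entity_class: phenotype_of_interest
    """
    manifest_path = Path(manifest_path)
    cfg = yaml.safe_load(manifest_path.read_text("utf-8"))
    entries: list[LexiconEntry] = []
    for item in cfg["sources"]:
        sub = load_lexicon(
            {item["source"]: manifest_path.parent / item["file"]},
            {item["source"]: item["entity_class"]},
        )
        entries.extend(sub.entries)
    return Lexicon(entries)


def load_toy_lexicon() -> Lexicon:
    """The bundled ~200-term toy dictionary (same schema as real builds)."""
    manifest = resources.files("phenodefminer.data").joinpath("lexicon.yaml")
    return load_lexicon_from_manifest(Path(str(manifest)))


def map_terms_exact(
    source_terms: Iterable[str], target: Lexicon
) -> tuple[dict[str, list[LexiconEntry]], float]:
    """Exact-match source terms into a (sub-)lexicon.

    Each source term maps to every target entry whose normalized form
    equals its own normalized form.  Returns the mapping and the coverage
    fraction (mapped terms / total terms; 0.0 for an empty input).
    """
    source_terms = list(source_terms)
    by_norm: dict[str, list[LexiconEntry]] = {}
    for e in target.entries:
        by_norm.setdefault(e.normalized, []).append(e)
    mapping: dict[str, list[LexiconEntry]] = {}
    n_mapped = 0
    for term in source_terms:
        hits = by_norm.get(normalize_term(term), [])
        mapping[term] = hits
        if hits:
            n_mapped += 1
    coverage = n_mapped / len(source_terms) if source_terms else 0.0
    return mapping, coverage


def lexicon_summary(lex: Lexicon) -> pd.DataFrame:
    """Table-style summary: term counts and within-class percentages.

    One row per (entity_class, source) present in the lexicon, with
    ``n_terms`` and ``percentage`` (share of the class total, rounded to one
    decimal; rounding is per-row so percentages may sum to 100 ± 0.1).
    An empty lexicon yields an empty table.
    """
    rows = [
        {"entity_class": e.entity_class, "source": e.source}
        for e in lex.entries
    ]
    if not rows:
        return pd.DataFrame(columns=["entity_class", "source", "n_terms", "percentage"])
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["entity_class", "source"], sort=False).size().reset_index(name="n_terms")
    )
    class_totals = counts.groupby("entity_class")["n_terms"].transform("sum")
    counts["percentage"] = (100.0 * counts["n_terms"] / class_totals).round(1)
    order = {c: i for i, c in enumerate(ENTITY_CLASSES)}
    counts = counts.sort_values(
        by=["entity_class", "n_terms"],
        key=lambda col: col.map(order) if col.name == "entity_class" else col,
        ascending=[True, False],
    ).reset_index(drop=True)
    return counts
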