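"""Labeled corpora and full-text containers.

Every stage of the screening pipeline consumes the three record types
defined here: :class:`AbstractDocument` (title + abstract, the unit of
abstract-level triage), :class:`SentenceRecord` (the unit of sentence-level
classification), and :class:`FullTextDocument` (an ordered sentence list for
one article).

Exchange formats are deliberately plain: UTF-8 tab-delimited tables with a
header for labeled corpora, and a small GENIA-style XML container (root
``article`` element with an ``id`` attribute, a ``title`` element and one
``sentence`` element per sentence) for full texts.  Tabs inside text fields
are rejected rather than escaped.  All writers are deterministic
byte-for-byte for identical inputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

from lxml import etree

__all__ = [
    "AbstractDocument",
    "SentenceRecord",
    "FullTextDocument",
    "CorpusSchemaError",
    "CorpusValueError",
    "read_labeled_corpus",
    "write_labeled_corpus",
    "write_genia_xml",
    "parse_genia_xml",
]


class CorpusSchemaError(ValueError):
    """A corpus or XML file does not have the expected columns/elements."""


class CorpusValueError(ValueError):
    """A corpus file has a malformed value; the message cites the row."""


def _check_label(label: Optional[int]) -> Optional[int]:
    if label is not None and label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    return label


@dataclass(frozen=True)
class AbstractDocument:
    """A PubMed-style abstract with optional relevance label.

    ``label`` is 1 when the abstract carries phenotype-definition evidence
    (standard codes, inclusion/exclusion criteria), 0 otherwise.  The
    classification unit is title and abstract concatenated (:meth:`text`).
    """

    pmid: str
    title: str = ""
    abstract_text: str = ""
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        _check_label(self.label)

    def text(self) -> str:
        """Title and abstract joined — the unit fed to the vectorizer."""
        if self.title and self.abstract_text:
            return f"{self.title} {self.abstract_text}"
        return self.title or self.abstract_text


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of a document, optionally labeled and offset-anchored.

    Offsets, when present, are 0-based half-open character positions into
    the source document text.
    """

    pmid: str
    sentence_index: int
    text: str
    label: Optional[int] = None
    char_start: Optional[int] = None
    char_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be >= 0")
        _check_label(self.label)
        if self.char_start is not None and self.char_end is not None:
            if self.char_end <= self.char_start:
                raise ValueError("char_end must be > char_start")


@dataclass
class FullTextDocument:
    """An article as an ordered list of sentences.

    Sentence indices must be contiguous from 0; ``section_tags`` may carry a
    per-sentence section label (parallel list) once sectioning has run.
    """

    pmid: str
    title: str = ""
    sentences: list[SentenceRecord] = field(default_factory=list)
    section_tags: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        for i, sent in enumerate(self.sentences):
            if sent.sentence_index != i:
                raise ValueError(
                    "sentence indices must be contiguous from 0; "
                    f"position {i} has index {sent.sentence_index}"
                )
        if self.section_tags is not None and len(self.section_tags) != len(self.sentences):
            raise ValueError("section_tags must parallel sentences")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FullTextDocument):
            return NotImplemented
        return (
            self.pmid == other.pmid
            and self.title == other.title
            and [(s.sentence_index, s.text, s.label) for s in self.sentences]
            == [(s.sentence_index, s.text, s.label) for s in other.sentences]
        )


Granularity = Literal["abstract", "sentence"]

_REQUIRED = {"abstract": ("pmid", "text", "label"), "sentence": ("pmid", "text", "label")}
_OPTIONAL = {"abstract": ("title",), "sentence": ("sentence_index",)}


def _parse_label(raw: str, row_number: int) -> Optional[int]:
    raw = raw.strip()
    if raw == "":
        return None
    if raw not in ("0", "1"):
        raise CorpusValueError(f"row {row_number}: label must be 0 or 1, got {raw!r}")
    return int(raw)


def read_labeled_corpus(
    path: Union[str, Path], granularity: Granularity
) -> list[AbstractDocument] | list[SentenceRecord]:
    """Read a tab-delimited labeled corpus, preserving row order.

    Parameters
    ----------
    path:
        Tab-delimited UTF-8 file with a header row.  Required columns are
        ``pmid``, ``text`` and ``label``; abstracts may add ``title`` and
        sentences may add ``sentence_index`` (defaulting to the row ordinal
        within each pmid when absent).
    granularity:
        ``"abstract"`` or ``"sentence"`` — selects the record type.

    Raises
    ------
    CorpusSchemaError
        A required column is missing (the message names it).
    CorpusValueError
        A label outside {0, 1} or a malformed index, citing the row number
        (1-based over data rows).
    """
    if granularity not in _REQUIRED:
        raise ValueError(f"granularity must be 'abstract' or 'sentence', got {granularity!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise CorpusSchemaError(f"{path}: empty file, missing header")
        header = header_line.rstrip("\n").rstrip("\r").split("\t")
        for col in _REQUIRED[granularity]:
            if col not in header:
                raise CorpusSchemaError(f"{path}: missing required column {col!r}")
        idx = {name: i for i, name in enumerate(header)}

        records: list = []
        per_pmid_counter: dict[str, int] = {}
        for row_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise CorpusValueError(
                    f"row {row_number}: expected {len(header)} columns, got {len(cells)}"
                )
            pmid = cells[idx["pmid"]]
            text = cells[idx["text"]]
            label = _parse_label(cells[idx["label"]], row_number)
            if granularity == "abstract":
                title = cells[idx["title"]] if "title" in idx else ""
                records.append(
                    AbstractDocument(pmid=pmid, title=title, abstract_text=text, label=label)
                )
            else:
                if "sentence_index" in idx:
                    raw_idx = cells[idx["sentence_index"]]
                    try:
                        sentence_index = int(raw_idx)
                    except ValueError:
                        raise CorpusValueError(
                            f"row {row_number}: sentence_index must be an integer, got {raw_idx!r}"
                        ) from None
                else:
                    sentence_index = per_pmid_counter.get(pmid, 0)
                per_pmid_counter[pmid] = sentence_index + 1
                records.append(
                    SentenceRecord(
                        pmid=pmid, sentence_index=sentence_index, text=text, label=label
                    )
                )
    return records


def _no_tabs(value: str, what: str) -> str:
    if "\t" in value:
        raise ValueError(f"tab character not allowed inside {what}")
    return value


def write_labeled_corpus(
    records: Sequence[Union[AbstractDocument, SentenceRecord]],
    path: Union[str, Path],
) -> None:
    """Write records as a tab-delimited corpus (inverse of the reader).

    The column set is inferred from the first record's type.  Unlabeled
    records write an empty label cell.
    """
    path = Path(path)
    buf = io.StringIO()
    if records and isinstance(records[0], AbstractDocument):
        buf.write("pmid\ttitle\ttext\tlabel\n")
        for rec in records:
            assert isinstance(rec, AbstractDocument)
            label = "" if rec.label is None else str(rec.label)
            buf.write(
                f"{_no_tabs(rec.pmid, 'pmid')}\t{_no_tabs(rec.title, 'title')}\t"
                f"{_no_tabs(rec.abstract_text, 'text')}\t{label}\n"
            )
    else:
        buf.write("pmid\tsentence_index\ttext\tlabel\n")
        for rec in records:
            assert isinstance(rec, SentenceRecord)
            label = "" if rec.label is None else str(rec.label)
            buf.write(
                f"{_no_tabs(rec.pmid, 'pmid')}\t{rec.sentence_index}\t"
                f"{_no_tabs(rec.text, 'text')}\t{label}\n"
            )
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# GENIA-style XML container


def write_genia_xml(doc: FullTextDocument, path: Union[str, Path]) -> None:
    """Serialize a full-text document to the GENIA-style XML container.

    Layout: ``<article id=PMID><title>…</title><sentence index=i>…</sentence>
    …</article>``.  lxml handles escaping of XML-special characters, so a
    write→parse round trip is lossless on pmid, title, sentence texts and
    order.
    """
    root = etree.Element("article", id=doc.pmid)
    title_el = etree.SubElement(root, "title")
    title_el.text = doc.title
    for sent in doc.sentences:
        el = etree.SubElement(root, "sentence", index=str(sent.sentence_index))
        el.text = sent.text
    tree = etree.ElementTree(root)
    tree.write(str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)


def parse_genia_xml(path: Union[str, Path]) -> FullTextDocument:
    """Parse a GENIA-style XML file back into a :class:`FullTextDocument`.

    Sentence indices are reassigned from element stream order, so a file
    whose ``index`` attributes disagree with the stream is normalized rather
    than rejected.

    Raises
    ------
    etree.XMLSyntaxError
        Malformed XML (lxml's message carries the line number).
    CorpusSchemaError
        Root is not an ``article`` or lacks an ``id`` attribute.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "article":
        raise CorpusSchemaError(f"expected root element 'article', got {root.tag!r}")
    pmid = root.get("id")
    if not pmid:
        raise CorpusSchemaError("article element is missing its 'id' attribute")
    title_el = root.find("title")
    title = title_el.text or "" if title_el is not None else ""
    sentences = [
        SentenceRecord(pmid=pmid, sentence_index=i, text=el.text or "")
        for i, el in enumerate(root.iter("sentence"))
    ]
    return FullTextDocument(pmid=pmid, title=title, sentences=sentences)
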