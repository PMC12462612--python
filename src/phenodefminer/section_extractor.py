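"""Sentence tokenization and rule-based methods-section extraction.

Full texts arrive as plain text (PDF conversion happens upstream, outside
this package).  Phase two of the screening pipeline needs two things from
them: sentence boundaries with character offsets, and the span of sentences
lying inside the methods section, found by matching short heading sentences
against configurable start/end heading lexicons (standard IMRaD structure).

Heading sentences themselves are excluded from the returned span — they
carry no definition content.  When several methods headings occur the first
wins, and subsection headings inside methods do not terminate the span
(only a post-methods heading such as "Results" does).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .corpus_io import FullTextDocument, SentenceRecord

__all__ = [
    "SectionSpan",
    "SectionConfig",
    "load_section_config",
    "tokenize_sentences",
    "extract_methods_section",
    "methods_sentences",
]


@dataclass(frozen=True)
class SectionSpan:
    """A 0-based half-open sentence range carrying a section label.

    A zero-length span (``end == start``) is legal and means the heading was
    found but no content sentences follow before the next section.
    """

    section_name: str
    start_sentence_index: int
    end_sentence_index: int

    def __post_init__(self) -> None:
        if self.start_sentence_index < 0:
            raise ValueError("start_sentence_index must be >= 0")
        if self.end_sentence_index < self.start_sentence_index:
            raise ValueError("end must be >= start")

    def __len__(self) -> int:
        return self.end_sentence_index - self.start_sentence_index


@dataclass(frozen=True)
class SectionConfig:
    methods_start: tuple[str, ...]
    methods_end: tuple[str, ...]
    max_heading_tokens: int = 6
    abbreviations: tuple[str, ...] = ()


def load_section_config(path: Optional[Union[str, Path]] = None) -> SectionConfig:
    """Load heading lexicons and tokenizer abbreviations (bundled default)."""
    if path is None:
        raw = resources.files("phenodefminer.data").joinpath("sections.yaml").read_text("utf-8")
    else:
        raw = Path(path).read_text("utf-8")
    cfg = yaml.safe_load(raw)
    return SectionConfig(
        methods_start=tuple(s.lower() for s in cfg["methods_start"]),
        methods_end=tuple(s.lower() for s in cfg["methods_end"]),
        max_heading_tokens=int(cfg.get("max_heading_tokens", 6)),
        abbreviations=tuple(a.lower().rstrip(".") for a in cfg.get("abbreviations", ())),
    )


_DEFAULT_CONFIG: Optional[SectionConfig] = None


def _default_config() -> SectionConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = load_section_config()
    return _DEFAULT_CONFIG


# ---------------------------------------------------------------------------
# Sentence tokenizer

_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)")
_WORD = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def _is_abbreviation(text: str, punct_pos: int, abbreviations: tuple[str, ...]) -> bool:
    """True when the period at punct_pos terminates a whitelisted abbreviation."""
    if text[punct_pos] != ".":
        return False
    start = punct_pos
    while start > 0 and (text[start - 1].isalnum() or text[start - 1] == "."):
        start -= 1
    token = text[start:punct_pos].lower().rstrip(".")
    if not token:
        return False
    if token in abbreviations:
        return True
    # "et al." — check two-word abbreviations
    two_start = start - 1
    while two_start > 0 and text[two_start - 1].isalpha():
        two_start -= 1
    two_word = text[two_start:punct_pos].lower()
    return two_word in abbreviations


def tokenize_sentences(
    text: str,
    pmid: str = "",
    config: Optional[SectionConfig] = None,
) -> list[SentenceRecord]:
    """Split plain text into sentences with character offsets.

    Splits occur after runs of ``.!?`` followed by whitespace, except when
    the period terminates a whitelisted abbreviation or sits inside a
    decimal number ("2.5 mg" does not split).  Empty and whitespace-only
    input yields an empty list.  Concatenating the sentence texts and
    collapsing inter-sentence whitespace reconstructs the input, and each
    record's ``[char_start, char_end)`` slices its text out of ``text``.
    """
    cfg = config or _default_config()
    if not text or not text.strip():
        return []
    pmid = pmid or "NA"

    cut_points: list[int] = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        if end >= len(text):
            break
        last = end - 1  # last punctuation char of the run
        if text[last] == "." and _is_abbreviation(text, last, cfg.abbreviations):
            continue
        cut_points.append(end)

    sentences: list[SentenceRecord] = []
    start = 0
    for cut in cut_points + [len(text)]:
        chunk = text[start:cut]
        stripped = chunk.strip()
        if stripped:
            lead = len(chunk) - len(chunk.lstrip())
            char_start = start + lead
            char_end = char_start + len(stripped)
            sentences.append(
                SentenceRecord(
                    pmid=pmid,
                    sentence_index=len(sentences),
                    text=stripped,
                    char_start=char_start,
                    char_end=char_end,
                )
            )
        start = cut
    return sentences


# ---------------------------------------------------------------------------
# Methods-section boundary rules

_HEADING_STRIP = re.compile(r"^[\s\d.\-–—:)(]+|[\s.:\-–—]+$")


def _normalize_heading(text: str) -> str:
    """Lowercase, drop numbering like '2.1' and surrounding punctuation."""
    return re.sub(r"\s+", " ", _HEADING_STRIP.sub("", text.lower()))


def _matches_heading(sentence: SentenceRecord, lexicon: tuple[str, ...], cfg: SectionConfig) -> bool:
    tokens = _WORD.findall(sentence.text)
    if not tokens or len(tokens) > cfg.max_heading_tokens:
        return False
    return _normalize_heading(sentence.text) in lexicon


def extract_methods_section(
    doc: FullTextDocument, config: Optional[SectionConfig] = None
) -> Optional[SectionSpan]:
    """Locate the methods-section content span, or ``None`` when absent.

    The span starts at the sentence after the first methods heading and
    ends before the first subsequent post-methods heading (document end
    otherwise).  Headings match case-insensitively, only against short
    sentences, so prose mentioning "methods" mid-paragraph never triggers.
    """
    cfg = config or _default_config()
    start: Optional[int] = None
    for sent in doc.sentences:
        if start is None:
            if _matches_heading(sent, cfg.methods_start, cfg):
                start = sent.sentence_index + 1
        else:
            if _matches_heading(sent, cfg.methods_end, cfg):
                return SectionSpan("methods", start, sent.sentence_index)
    if start is None:
        return None
    return SectionSpan("methods", start, len(doc.sentences))


def methods_sentences(
    doc: FullTextDocument, config: Optional[SectionConfig] = None
) -> list[SentenceRecord]:
    """Sentences inside the methods span, original indices preserved.

    Returns an empty list when no methods heading is found.  Subsection
    headings inside methods are kept only if they are not themselves
    methods-start headings (a nested "Study design" heading is dropped like
    the main heading, since headings carry no content).
    """
    cfg = config or _default_config()
    span = extract_methods_section(doc, cfg)
    if span is None:
        return []
    out = []
    for sent in doc.sentences[span.start_sentence_index : span.end_sentence_index]:
        if _matches_heading(sent, cfg.methods_start, cfg):
            continue
        out.append(sent)
    return out
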