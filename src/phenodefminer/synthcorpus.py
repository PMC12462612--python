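"""Seeded synthetic corpora with planted, recoverable structure.

Real training corpora for this task (manually labeled abstracts and
sentence annotations) cannot be redistributed, so the generator emulates
their statistical structure from a template grammar:

* **positive sentences** combine a dictionary entity with a definition
  keyword (an entity×definition co-occurrence) with probability
  ``signal``, optionally carrying a quantitative value or code pattern;
  the remainder carry only weak evidence (a lone entity or lone keyword);
* **negative sentences** draw bland method-prose templates, carry
  computational/location/financial negative-evidence vocabulary with
  probability ``negative_evidence_rate``, and are contaminated with a lone
  entity or lone definition keyword with probability ``contamination``;
* **abstracts** enrich definition/code vocabulary in the positive class
  with probability ``signal``; negatives read like generic research
  abstracts, and both classes share filler sentences;
* **full texts** have Introduction/Methods/Results structure with
  definition-bearing sentences planted only inside the methods section,
  returned together with the ground-truth span.

One global seed drives everything; each operation derives its own
deterministic substream, so generating sentences never perturbs abstracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .corpus_io import AbstractDocument, FullTextDocument, SentenceRecord
from .lexicon import Lexicon
from .section_extractor import SectionSpan

__all__ = [
    "SynthConfig",
    "load_templates",
    "generate_labeled_sentences",
    "generate_labeled_abstracts",
    "generate_fulltext_document",
    "generate_fulltext_corpus",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; probabilities are per-sentence Bernoulli rates."""

    n_positive: int = 1000
    n_negative: int = 1000
    signal: float = 0.9
    contamination: float = 0.2
    pattern_rate: float = 0.5
    negative_evidence_rate: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signal", "contamination", "pattern_rate", "negative_evidence_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be >= 0")


_TEMPLATES: Optional[dict] = None


def load_templates(path: Optional[Union[str, Path]] = None) -> dict:
    """The template grammar (bundled default)."""
    global _TEMPLATES
    if path is not None:
        return yaml.safe_load(Path(path).read_text("utf-8"))
    if _TEMPLATES is None:
        raw = resources.files("phenodefminer.data").joinpath("templates.yaml").read_text("utf-8")
        _TEMPLATES = yaml.safe_load(raw)
    return _TEMPLATES


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    # per-operation substream of the one global seed
    return np.random.default_rng([cfg.seed, stream])


def _choice(rng: np.random.Generator, items: list) -> object:
    return items[int(rng.integers(len(items)))]


def _pattern_clause(rng: np.random.Generator, clauses: list[str]) -> str:
    clause = str(_choice(rng, clauses))
    return clause.format(
        bp_s=int(rng.integers(110, 180)),
        bp_d=int(rng.integers(60, 110)),
        lab=round(float(rng.uniform(1.0, 15.0)), 1),
        icd=f"{int(rng.integers(100, 999))}.{int(rng.integers(0, 9))}",
        age=int(rng.integers(18, 90)),
        bmi=int(rng.integers(18, 45)),
    )


def generate_labeled_sentences(cfg: SynthConfig, lex: Lexicon) -> list[SentenceRecord]:
    """Exactly ``n_positive`` label-1 and ``n_negative`` label-0 sentences.

    Reproducible from the seed; raises ``ValueError`` on an empty lexicon.
    Output order is a seeded shuffle of the two classes.
    """
    if len(lex) == 0:
        raise ValueError("lexicon must be non-empty")
    tpl = load_templates()["sentence"]
    rng = _rng(cfg, 1)
    entities = [e.surface for e in lex.entries]
    defkw_single = tpl["defkw_single"]
    neg_families = list(tpl["negkw"])

    sentences: list[SentenceRecord] = []

    for i in range(cfg.n_positive):
        entity = str(_choice(rng, entities))
        defkw = str(_choice(rng, defkw_single))
        if rng.random() < cfg.signal:
            text = str(_choice(rng, tpl["positive_cooccurrence"])).format(
                entity=entity, defkw=defkw
            )
        else:
            if rng.random() < 0.5:
                text = str(_choice(rng, tpl["positive_weak_entity"])).format(entity=entity)
            else:
                text = str(_choice(rng, tpl["positive_weak_keyword"])).format(defkw=defkw)
        if rng.random() < cfg.pattern_rate:
            text = f"{text} {_pattern_clause(rng, tpl['pattern_clauses'])}"
        sentences.append(
            SentenceRecord(pmid=f"SYN{i:06d}", sentence_index=0, text=text, label=1)
        )

    for i in range(cfg.n_negative):
        if rng.random() < cfg.contamination:
            if rng.random() < 0.5:
                text = str(_choice(rng, tpl["negative_lone_entity"])).format(
                    entity=str(_choice(rng, entities))
                )
            else:
                text = str(_choice(rng, tpl["negative_lone_keyword"])).format(
                    defkw=str(_choice(rng, defkw_single))
                )
        else:
            text = str(_choice(rng, tpl["negative_plain"]))
        if rng.random() < cfg.negative_evidence_rate:
            family = str(_choice(rng, neg_families))
            clause = str(_choice(rng, tpl["negative_evidence"][family])).format(
                negkw=str(_choice(rng, tpl["negkw"][family]))
            )
            text = f"{text} {clause}"
        sentences.append(
            SentenceRecord(
                pmid=f"SYN{cfg.n_positive + i:06d}", sentence_index=0, text=text, label=0
            )
        )

    order = rng.permutation(len(sentences))
    return [
        SentenceRecord(
            pmid=sentences[j].pmid,
            sentence_index=0,
            text=sentences[j].text,
            label=sentences[j].label,
        )
        for j in order
    ]


def generate_labeled_abstracts(cfg: SynthConfig) -> list[AbstractDocument]:
    """Labeled abstracts whose positive class enriches definition/code
    vocabulary with probability ``signal``; reproducible from the seed."""
    tpl = load_templates()["abstract"]
    rng = _rng(cfg, 2)
    docs: list[AbstractDocument] = []

    def compose(pools: list[list[str]], n_sent: int) -> str:
        parts = [str(_choice(rng, _choice(rng, pools))) for _ in range(n_sent)]
        return " ".join(parts)

    for i in range(cfg.n_positive):
        n_sent = int(rng.integers(3, 7))
        if rng.random() < cfg.signal:
            # at least two definition-rich sentences, filler around them
            body = [str(_choice(rng, tpl["positive_pool"])) for _ in range(2)]
            body += [
                str(_choice(rng, _choice(rng, [tpl["positive_pool"], tpl["shared_filler"]])))
                for _ in range(n_sent - 2)
            ]
            idx = rng.permutation(len(body))
            text = " ".join(body[j] for j in idx)
        else:
            text = compose([tpl["negative_pool"], tpl["shared_filler"]], n_sent)
        docs.append(
            AbstractDocument(
                pmid=f"PA{i:06d}",
                title=f"Cohort study {i}",
                abstract_text=text,
                label=1,
            )
        )
    for i in range(cfg.n_negative):
        n_sent = int(rng.integers(3, 7))
        text = compose([tpl["negative_pool"], tpl["shared_filler"]], n_sent)
        docs.append(
            AbstractDocument(
                pmid=f"PA{cfg.n_positive + i:06d}",
                title=f"Cohort study {cfg.n_positive + i}",
                abstract_text=text,
                label=0,
            )
        )
    order = rng.permutation(len(docs))
    return [docs[j] for j in order]


def generate_fulltext_document(
    cfg: SynthConfig, lex: Lexicon, pmid: Optional[str] = None, stream: int = 3
) -> tuple[FullTextDocument, SectionSpan]:
    """One sectioned article plus the ground-truth methods span.

    The document is Introduction prose, a methods heading, ``n_positive``
    definition-bearing sentences (the planted methods content), an ending
    heading, and Results prose.  ``n_positive = 0`` plants a zero-length
    methods span.
    """
    if len(lex) == 0:
        raise ValueError("lexicon must be non-empty")
    tpl = load_templates()
    ft = tpl["fulltext"]
    sent_tpl = tpl["sentence"]
    rng = _rng(cfg, stream)
    pmid = pmid or f"FT{int(rng.integers(10**7)):07d}"

    entities = [e.surface for e in lex.entries]
    texts: list[str] = []
    n_intro = int(rng.integers(2, 4))
    texts += [str(_choice(rng, ft["intro"])) for _ in range(n_intro)]
    texts.append(str(_choice(rng, ft["methods_headings"])))
    truth_start = len(texts)
    for _ in range(cfg.n_positive):
        body = str(_choice(rng, sent_tpl["positive_cooccurrence"])).format(
            entity=str(_choice(rng, entities)),
            defkw=str(_choice(rng, sent_tpl["defkw_single"])),
        )
        if rng.random() < cfg.pattern_rate:
            body = f"{body} {_pattern_clause(rng, sent_tpl['pattern_clauses'])}"
        texts.append(body)
    truth_end = len(texts)
    texts.append(str(_choice(rng, ft["end_headings"])))
    texts += [str(_choice(rng, ft["results"])) for _ in range(int(rng.integers(1, 3)))]

    sentences = [
        SentenceRecord(pmid=pmid, sentence_index=i, text=t) for i, t in enumerate(texts)
    ]
    doc = FullTextDocument(pmid=pmid, title=f"Article {pmid}", sentences=sentences)
    return doc, SectionSpan("methods", truth_start, truth_end)


def generate_fulltext_corpus(
    cfg: SynthConfig, lex: Lexicon, n_documents: int
) -> list[tuple[FullTextDocument, SectionSpan]]:
    """``n_documents`` articles with distinct pmids and per-document
    substreams (document *k* is stable under changes to the others)."""
    return [
        generate_fulltext_document(cfg, lex, pmid=f"FT{k:06d}", stream=1000 + k)
        for k in range(n_documents)
    ]
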