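"""Three-phase screening orchestration.

Phase one scores abstracts and keeps the positives; phase two looks up
each positive abstract's full text and extracts its methods-section
sentences; phase three classifies those sentences at a calibrated
operating point and builds the knowledgebase from the positives.  Every
intermediate is written to disk and the run is summarized by a
:class:`ScreeningReport` whose totals are conserved by construction
(positives + negatives = total at the sentence stage; filters only ever
shrink record sets).

Artifacts are deterministic: report and manifest serialization excludes
wall-clock fields, so re-running with the same seed/config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import __version__
from .classifiers import AbstractVectorizer, OperatingPoint, TrainedClassifier, apply_threshold
from .corpus_io import (
    AbstractDocument,
    FullTextDocument,
    SentenceRecord,
    write_labeled_corpus,
)
from .kb import KBRecord, build_kb, save_kb
from .lexicon import Lexicon
from .ner_features import FeatureSchema, build_feature_matrix
from .section_extractor import SectionConfig, methods_sentences

logger = logging.getLogger(__name__)

__all__ = ["ScreeningReport", "run_screening"]


@dataclass
class ScreeningReport:
    """Counts and provenance for one screening run."""

    n_abstracts_in: int
    n_abstracts_positive: int
    n_fulltexts_in: int
    n_missing_fulltexts: int
    n_sentences_total: int
    n_sentences_positive: int
    n_sentences_negative: int
    n_kb_records: int
    config_digest: str
    started_at: Optional[str] = None
    finished_at: Optional[str] = None

    def __post_init__(self) -> None:
        counts = [
            self.n_abstracts_in,
            self.n_abstracts_positive,
            self.n_fulltexts_in,
            self.n_missing_fulltexts,
            self.n_sentences_total,
            self.n_sentences_positive,
            self.n_sentences_negative,
            self.n_kb_records,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_sentences_positive + self.n_sentences_negative != self.n_sentences_total:
            raise ValueError("positives + negatives must equal total sentences")

    def as_dict(self, include_timestamps: bool = False) -> dict:
        d = {
            "n_abstracts_in": self.n_abstracts_in,
            "n_abstracts_positive": self.n_abstracts_positive,
            "n_fulltexts_in": self.n_fulltexts_in,
            "n_missing_fulltexts": self.n_missing_fulltexts,
            "n_sentences_total": self.n_sentences_total,
            "n_sentences_positive": self.n_sentences_positive,
            "n_sentences_negative": self.n_sentences_negative,
            "n_kb_records": self.n_kb_records,
            "config_digest": self.config_digest,
        }
        if include_timestamps:
            d["started_at"] = self.started_at
            d["finished_at"] = self.finished_at
        return d

    def summary(self) -> str:
        """Human-readable run summary (screening-count table shape)."""
        lines = [
            "Large-scale screening results",
            f"  Abstracts screened                 {self.n_abstracts_in}",
            f"  Predicted positive abstracts       {self.n_abstracts_positive}",
            f"  Full texts available               {self.n_fulltexts_in}",
            f"  Positive abstracts missing text    {self.n_missing_fulltexts}",
            f"  Methods-section sentences          {self.n_sentences_total}",
            f"  Predicted positive sentences       {self.n_sentences_positive}",
            f"  Predicted negative sentences       {self.n_sentences_negative}",
            f"  Knowledgebase records              {self.n_kb_records}",
        ]
        return "\n".join(lines)


def _config_digest(payload: Mapping) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def run_screening(
    abstracts: Sequence[AbstractDocument],
    fulltexts: Mapping[str, FullTextDocument],
    abstract_model: TrainedClassifier,
    abstract_vectorizer: AbstractVectorizer,
    sentence_model: TrainedClassifier,
    sentence_schema: FeatureSchema,
    operating_point: OperatingPoint,
    lex: Lexicon,
    out_dir: Union[str, Path],
    abstract_threshold: float = 0.0,
    pt_sources: Sequence[str] = ("MedDRA_PT",),
    section_config: Optional[SectionConfig] = None,
    record_timestamps: bool = False,
) -> tuple[ScreeningReport, list[KBRecord]]:
    """Run the abstract→methods→sentence→knowledgebase screening.

    Parameters
    ----------
    abstracts:
        Input abstracts (labels, if any, are ignored at prediction time).
    fulltexts:
        pmid → full-text document for (ideally) every positive abstract; a
        missing full text is logged and counted, not fatal.
    abstract_model, abstract_vectorizer:
        Trained triage model and its frozen vectorizer.
    sentence_model, sentence_schema, operating_point:
        Trained sentence classifier, its feature schema, and the
        recall-calibrated threshold used for hard positive/negative calls.
    abstract_threshold:
        Score cutoff for phase one (0.0 = the margin/probability midpoint
        of the default decision rule is used via ``score >= threshold``
        only when scores are margins; pass a calibrated value to change
        triage recall).
    pt_sources:
        Lexicon sources forming the preferred-term sub-lexicon for the
        knowledgebase build.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat() if record_timestamps else None

    digest = _config_digest(
        {
            "abstract_algorithm": abstract_model.algorithm,
            "sentence_algorithm": sentence_model.algorithm,
            "abstract_threshold": abstract_threshold,
            "operating_point": operating_point.threshold,
            "target_recall": operating_point.target_recall,
            "schema": sentence_schema.feature_names,
            "pt_sources": list(pt_sources),
            "lexicon_size": len(lex),
            "version": __version__,
        }
    )

    # ---- phase one: abstract triage
    X_abs = abstract_vectorizer.transform(abstracts)
    abs_scores = abstract_model.scores(X_abs)
    keep = abs_scores >= abstract_threshold
    positives = [doc for doc, k in zip(abstracts, keep) if k]
    write_labeled_corpus(
        [
            AbstractDocument(pmid=d.pmid, title=d.title, abstract_text=d.abstract_text, label=1)
            for d in positives
        ],
        out_dir / "phase1_positive_abstracts.tsv",
    )

    # ---- phase two: methods-section sentences
    exclusions: list[str] = []
    method_sents: list[SentenceRecord] = []
    n_fulltexts = 0
    for doc in positives:
        ft = fulltexts.get(doc.pmid)
        if ft is None:
            exclusions.append(doc.pmid)
            logger.warning("no full text for positive abstract %s; excluded", doc.pmid)
            continue
        n_fulltexts += 1
        method_sents.extend(methods_sentences(ft, section_config))
    (out_dir / "phase2_exclusions.txt").write_text(
        "".join(f"{pmid}\n" for pmid in exclusions), encoding="utf-8"
    )
    write_labeled_corpus(method_sents, out_dir / "phase2_methods_sentences.tsv")

    # ---- phase three: sentence classification at the operating point
    if method_sents:
        X_sent, _ = build_feature_matrix(method_sents, sentence_schema, lex)
        sent_scores = sentence_model.scores(X_sent)
        sent_labels = apply_threshold(sent_scores, operating_point)
    else:
        sent_labels = np.zeros(0, dtype=int)
    labeled = [
        SentenceRecord(
            pmid=s.pmid, sentence_index=s.sentence_index, text=s.text, label=int(lab)
        )
        for s, lab in zip(method_sents, sent_labels)
    ]
    write_labeled_corpus(labeled, out_dir / "phase3_sentence_predictions.tsv")
    positive_sentences = [s for s in labeled if s.label == 1]

    # ---- knowledgebase
    pt_lex = lex.restrict(sources=pt_sources)
    kb = build_kb(positive_sentences, pt_lex) if len(pt_lex) else []
    save_kb(kb, out_dir / "knowledgebase.tsv")

    report = ScreeningReport(
        n_abstracts_in=len(abstracts),
        n_abstracts_positive=len(positives),
        n_fulltexts_in=n_fulltexts,
        n_missing_fulltexts=len(exclusions),
        n_sentences_total=len(labeled),
        n_sentences_positive=int(np.sum(sent_labels == 1)),
        n_sentences_negative=int(np.sum(sent_labels == 0)),
        n_kb_records=len(kb),
        config_digest=digest,
        started_at=started,
        finished_at=datetime.now(timezone.utc).isoformat() if record_timestamps else None,
    )
    (out_dir / "report.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest = {
        "config_digest": digest,
        "package_version": __version__,
        "abstract_algorithm": abstract_model.algorithm,
        "sentence_algorithm": sentence_model.algorithm,
        "operating_point": {
            "threshold": operating_point.threshold,
            "target_recall": operating_point.target_recall,
            "achieved_recall": operating_point.achieved_recall,
            "achieved_precision": operating_point.achieved_precision,
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report, kb
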