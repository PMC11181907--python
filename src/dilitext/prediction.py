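"""Scoring new documents with a saved model, and cross-corpus transfer.

New documents go through the same extraction pipeline as training data,
are TF-IDF weighted with the *training* corpus's document frequencies
(frozen in the model sidecar, so a saved model is a stable prediction
formula), and aligned to the model vocabulary before scoring.  The
``idf_mode="concat"`` variant instead recomputes IDF over the union of
training and new documents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dtm import align_vocabulary, build_count_matrix, weight_with_frozen_idf
from .evaluation import ConsistencyReport, consistency_report
from .modeling import TrainedModel
from .vocab import DocumentRecord, RecodingMap, TermDictionary, extract_corpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionRecord:
    doc_id: str
    probability: float
    predicted_class: int
    matched_terms: int


def predict_new(
    model: TrainedModel,
    new_docs: Sequence[DocumentRecord],
    dictionary: TermDictionary,
    recoding: RecodingMap | None = None,
    idf_mode: str = "frozen",
) -> list[PredictionRecord]:
    """Extract, weight with the model's frozen IDF, align, and score."""
    if not model.vocabulary:
        raise ValueError("model has no vocabulary sidecar")
    if idf_mode not in ("frozen", "concat"):
        raise ValueError(f"unknown idf_mode: {idf_mode!r}")
    if not new_docs:
        return []
    counts_list = extract_corpus(new_docs, dictionary, recoding)
    m = build_count_matrix(counts_list)
    if idf_mode == "frozen":
        n_docs, df_map = model.n_docs, model.doc_freq
    else:
        new_df = dict(zip(m.terms, (int(x) for x in m.doc_freq)))
        df_map = {
            t: model.doc_freq.get(t, 0) + new_df.get(t, 0)
            for t in set(model.doc_freq) | set(new_df)
        }
        n_docs = model.n_docs + len(new_docs)
    weighted = weight_with_frozen_idf(m, n_docs, df_map)
    aligned = align_vocabulary(weighted, model.vocabulary)
    proba = model.predict_proba(aligned.weights)
    vocab = set(model.vocabulary)
    records = []
    for i, tc in enumerate(counts_list):
        matched = sum(c for t, c in tc.counts.items() if t in vocab)
        unseen = sum(c for t, c in tc.counts.items() if t not in vocab)
        if unseen:
            logger.debug(
                "doc %s: %d matched occurrences outside model vocabulary dropped",
                tc.doc_id,
                unseen,
            )
        records.append(
            PredictionRecord(
                doc_id=tc.doc_id,
                probability=float(proba[i]),
                predicted_class=int(proba[i] >= model.threshold),
                matched_terms=matched,
            )
        )
    return records


def cross_corpus_predict(
    model: TrainedModel,
    corpus_b: Sequence[DocumentRecord],
    dictionary: TermDictionary,
    recoding: RecodingMap | None = None,
    idf_mode: str = "frozen",
) -> tuple[list[PredictionRecord], ConsistencyReport | None]:
    """Score corpus B with model A; report label agreement when B is labeled.

    Agreement uses the subtraction rule: rounded-up prediction minus label,
    |difference| = 1 marking an inconsistent classification.
    """
    records = predict_new(model, corpus_b, dictionary, recoding, idf_mode=idf_mode)
    labels = [d.label for d in corpus_b]
    if any(lab is None for lab in labels):
        logger.info("corpus B is (partly) unlabeled: scores only, no consistency")
        return records, None
    scores = np.array([r.probability for r in records])
    report = consistency_report(
        scores, np.asarray(labels, dtype=np.int64), threshold=model.threshold
    )
    return records, report
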