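"""Sparse count-matrix assembly, frequency filtering, and TF-IDF weighting."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .vocab import TermCounts

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    doc_ids: list[str]
    terms: list[str]
    counts: sp.csr_matrix  # docs x terms, non-negative integers

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.doc_ids), len(self.terms)):
            raise ValueError(
                f"shape {self.counts.shape} inconsistent with "
                f"{len(self.doc_ids)} docs x {len(self.terms)} terms"
            )

    @property
    def term_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def doc_freq(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


@dataclass
class DocumentTermMatrix:
    """TF-IDF weighted docs x terms matrix with frozen IDF metadata.

    ``n_docs`` and ``doc_freq`` record the corpus the IDF was computed on,
    so new documents can be weighted with the same (frozen) statistics.
    """

    doc_ids: list[str]
    terms: list[str]
    weights: sp.csr_matrix
    n_docs: int
    doc_freq: np.ndarray  # per term; 0 marks columns absent from the IDF corpus

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.doc_ids), len(self.terms)):
            raise ValueError("weights shape inconsistent with doc/term lists")
        if len(self.doc_freq) != len(self.terms):
            raise ValueError("doc_freq length must equal number of terms")


def build_count_matrix(
    counts_list: Sequence[TermCounts], doc_ids: Sequence[str] | None = None
) -> CountMatrix:
    """Union of observed terms (sorted) -> sparse count matrix."""
    if doc_ids is None:
        doc_ids = [tc.doc_id for tc in counts_list]
    doc_ids = [str(d) for d in doc_ids]
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate doc_id in corpus")
    if len(doc_ids) != len(counts_list):
        raise ValueError("doc_ids and counts_list length mismatch")
    terms = sorted({t for tc in counts_list for t in tc.counts})
    if not terms:
        logger.warning("no terms observed in any document: 0-column matrix")
    col = {t: j for j, t in enumerate(terms)}
    rows, cols, data = [], [], []
    for i, tc in enumerate(counts_list):
        for t, c in tc.counts.items():
            rows.append(i)
            cols.append(col[t])
            data.append(c)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(doc_ids), len(terms)), dtype=np.int64
    )
    return CountMatrix(doc_ids=list(doc_ids), terms=terms, counts=counts)


def filter_min_frequency(
    m: CountMatrix, min_freq: int, mode: str = "occurrences"
) -> CountMatrix:
    """Drop term columns below a minimum corpus frequency.

    ``mode="occurrences"`` thresholds the total occurrence count;
    ``mode="documents"`` thresholds the number of documents containing
    the term.
    """
    if min_freq < 1:
        raise ValueError(f"min_freq must be >= 1, got {min_freq}")
    if mode not in ("occurrences", "documents"):
        raise ValueError(f"unknown min-freq mode: {mode!r}")
    totals = m.term_totals if mode == "occurrences" else m.doc_freq
    keep = np.flatnonzero(totals >= min_freq)
    return CountMatrix(
        doc_ids=list(m.doc_ids),
        terms=[m.terms[j] for j in keep],
        counts=sp.csr_matrix(m.counts[:, keep]),
    )


def tfidf_weight(m: CountMatrix) -> DocumentTermMatrix:
    """weight(d, t) = tf(d, t) * log10(N / df(t)).

    Terms present in every document get IDF 0, hence weight 0: ubiquitous
    terms are down-weighted, rare terms up-weighted.
    """
    n_docs = len(m.doc_ids)
    if n_docs == 0:
        raise ValueError("empty matrix: no documents")
    df = m.doc_freq
    idf = np.zeros(len(m.terms))
    present = df > 0
    idf[present] = np.log10(n_docs / df[present])
    weights = sp.csr_matrix(m.counts.astype(np.float64).multiply(idf))
    weights.eliminate_zeros()
    return DocumentTermMatrix(
        doc_ids=list(m.doc_ids),
        terms=list(m.terms),
        weights=weights,
        n_docs=n_docs,
        doc_freq=df.copy(),
    )


def weight_with_frozen_idf(
    m: CountMatrix, n_docs: int, doc_freq_by_term: dict[str, int]
) -> DocumentTermMatrix:
    """TF-IDF for new documents using a training corpus's N and df.

    Terms without a recorded df (unseen in training) get weight 0.
    """
    df = np.array([doc_freq_by_term.get(t, 0) for t in m.terms], dtype=np.int64)
    idf = np.zeros(len(m.terms))
    present = df > 0
    idf[present] = np.log10(n_docs / df[present])
    weights = sp.csr_matrix(m.counts.astype(np.float64).multiply(idf))
    weights.eliminate_zeros()
    return DocumentTermMatrix(
        doc_ids=list(m.doc_ids),
        terms=list(m.terms),
        weights=weights,
        n_docs=n_docs,
        doc_freq=df,
    )


def align_vocabulary(
    dtm: DocumentTermMatrix, reference_terms: Sequence[str]
) -> DocumentTermMatrix:
    """Restrict/reorder columns to ``reference_terms``; absent terms -> zero."""
    if not len(reference_terms):
        raise ValueError("empty reference term list")
    pos = {t: j for j, t in enumerate(dtm.terms)}
    n_docs, n_ref = dtm.weights.shape[0], len(reference_terms)
    weights = sp.lil_matrix((n_docs, n_ref))
    doc_freq = np.zeros(n_ref, dtype=np.int64)
    for j, t in enumerate(reference_terms):
        if t in pos:
            weights[:, j] = dtm.weights[:, pos[t]]
            doc_freq[j] = dtm.doc_freq[pos[t]]
    return DocumentTermMatrix(
        doc_ids=list(dtm.doc_ids),
        terms=list(reference_terms),
        weights=sp.csr_matrix(weights),
        n_docs=dtm.n_docs,
        doc_freq=doc_freq,
    )


def export_dtm(dtm: DocumentTermMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus text sidecars for docs, terms, and IDF stats."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(dtm.weights))
    prefix.with_name(prefix.name + ".docs.txt").write_text(
        "\n".join(dtm.doc_ids) + ("\n" if dtm.doc_ids else ""), encoding="utf-8"
    )
    prefix.with_name(prefix.name + ".terms.txt").write_text(
        "\n".join(dtm.terms) + ("\n" if dtm.terms else ""), encoding="utf-8"
    )
    meta = {"n_docs": dtm.n_docs, "doc_freq": [int(x) for x in dtm.doc_freq]}
    prefix.with_name(prefix.name + ".meta.json").write_text(
        json.dumps(meta), encoding="utf-8"
    )


def import_dtm(prefix: str | Path) -> DocumentTermMatrix:
    prefix = Path(prefix)
    weights = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    doc_ids = prefix.with_name(prefix.name + ".docs.txt").read_text(
        encoding="utf-8"
    ).splitlines()
    terms = prefix.with_name(prefix.name + ".terms.txt").read_text(
        encoding="utf-8"
    ).splitlines()
    meta = json.loads(
        prefix.with_name(prefix.name + ".meta.json").read_text(encoding="utf-8")
    )
    if weights.shape != (len(doc_ids), len(terms)):
        raise ValueError(
            f"MTX shape {weights.shape} does not match sidecars "
            f"({len(doc_ids)} docs, {len(terms)} terms)"
        )
    return DocumentTermMatrix(
        doc_ids=doc_ids,
        terms=terms,
        weights=weights,
        n_docs=int(meta["n_docs"]),
        doc_freq=np.asarray(meta["doc_freq"], dtype=np.int64),
    )
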