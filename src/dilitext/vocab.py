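"""Controlled-vocabulary loading, tokenization, and whitelist term extraction.

Instead of removing a stop-word list from free text, this module keeps
*only* tokens and phrases found in a preferred-term dictionary (optionally
canonicalized through an explicit recoding table) and discards everything
else.  The dictionary is user-supplied plain text; licensed vocabularies
such as MedDRA or FMQ are never shipped.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class DocumentRecord:
    """One text unit: a label section, an abstract, etc."""

    doc_id: str
    text: str
    label: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(
                f"label must be 0 or 1, got {self.label!r} for doc {self.doc_id!r}"
            )


@dataclass
class TermDictionary:
    """Set of normalized preferred terms (each one or more word tokens)."""

    entries: frozenset[str]
    name: str = "user-dictionary"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty dictionary")
        for e in self.entries:
            if not e or not e.split():
                raise ValueError(f"dictionary entry has no tokens: {e!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term in self.entries


@dataclass
class RecodingMap:
    """Idempotent source-term -> canonical-term mapping (chains resolved)."""

    rules: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.rules.items():
            if src == dst:
                raise ValueError(f"rule maps term to itself: {src!r}")
            if dst in self.rules:
                raise ValueError(f"map is not idempotent: {src!r} -> {dst!r} -> ...")

    def apply(self, term: str) -> str:
        return self.rules.get(term, term)

    @property
    def sources(self) -> set[str]:
        return set(self.rules)

    @property
    def targets(self) -> set[str]:
        return set(self.rules.values())

    def __len__(self) -> int:
        return len(self.rules)


@dataclass
class TermCounts:
    """Per-document canonical term occurrence counts (all >= 1)."""

    doc_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for t, c in self.counts.items():
            if c < 1:
                raise ValueError(f"count for {t!r} must be >= 1, got {c}")


def normalize_text(text: str) -> list[str]:
    """Lowercase word tokens; punctuation (incl. hyphens) separates tokens."""
    return _TOKEN_RE.findall(text.lower())


def normalize_term(term: str) -> str:
    """Canonical form of a dictionary/recoding term: tokenized and re-joined."""
    return " ".join(normalize_text(term))


def load_dictionary(
    path: str | Path, name: str | None = None, column: str | None = None
) -> TermDictionary:
    """Load a preferred-term dictionary.

    Accepts plain text (one term per line) or TSV/CSV with a named
    ``column``.  Entries are lowercased, whitespace-collapsed and
    punctuation-stripped; duplicates are removed.
    """
    path = Path(path)
    if column is not None:
        frame = pd.read_csv(path, sep=None, engine="python")
        raw: Iterable[str] = frame[column].astype(str)
    else:
        raw = path.read_text(encoding="utf-8").splitlines()
    entries = {normalize_term(line) for line in raw}
    entries.discard("")
    if not entries:
        raise ValueError(f"empty dictionary: {path}")
    logger.info("loaded dictionary %s: %d unique terms", path, len(entries))
    return TermDictionary(entries=frozenset(entries), name=name or path.name)


def _resolve_chains(rules: dict[str, str]) -> dict[str, str]:
    """Follow a->b, b->c to a->c; raise on cycles."""
    resolved: dict[str, str] = {}
    for src in rules:
        seen = [src]
        dst = rules[src]
        while dst in rules:
            if dst in seen:
                cycle = " -> ".join(seen + [dst])
                raise ValueError(f"recoding cycle detected: {cycle}")
            seen.append(dst)
            dst = rules[dst]
        resolved[src] = dst
    return resolved


def load_recoding(path: str | Path) -> RecodingMap:
    """Load a two-column TSV of source -> canonical term rules.

    A header row is optional.  Chains are resolved so the resulting map is
    idempotent; cycles are an error.
    """
    path = Path(path)
    rules: dict[str, str] = {}
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i + 1}: expected 2 tab-separated columns")
        src, dst = normalize_term(parts[0]), normalize_term(parts[1])
        if i == 0 and {src, dst} <= {"source", "target", "from", "to", "term", "canonical"}:
            continue  # header row
        if not src or not dst or src == dst:
            continue
        rules[src] = dst
    resolved = _resolve_chains(rules)
    logger.info("loaded recoding map %s: %d rules", path, len(resolved))
    return RecodingMap(rules=resolved)


def build_matcher(
    dictionary: TermDictionary, recoding: RecodingMap | None = None
) -> dict[tuple[str, ...], str]:
    """Phrase patterns -> canonical term.

    Patterns are dictionary entries plus recoding sources (so multi-word
    variants absent from the dictionary are still found and canonicalized).
    """
    recoding = recoding or RecodingMap()
    patterns: dict[tuple[str, ...], str] = {}
    for entry in dictionary.entries:
        patterns[tuple(entry.split())] = recoding.apply(entry)
    for src in recoding.sources:
        patterns[tuple(src.split())] = recoding.apply(src)
    return patterns


def extract_terms(
    doc: DocumentRecord,
    dictionary: TermDictionary,
    recoding: RecodingMap | None = None,
    *,
    matcher: dict[tuple[str, ...], str] | None = None,
) -> TermCounts:
    """Whitelist extraction: longest-match-first, non-overlapping scan.

    Tokens not covered by any dictionary/recoding phrase are discarded
    (the universal stop-word rule).  Pass a prebuilt ``matcher`` when
    extracting many documents against the same vocabulary.
    """
    if matcher is None:
        matcher = build_matcher(dictionary, recoding)
    tokens = normalize_text(doc.text)
    if not matcher:
        return TermCounts(doc_id=doc.doc_id, counts={})
    max_len = max(len(p) for p in matcher)
    counts: Counter[str] = Counter()
    i, n = 0, len(tokens)
    while i < n:
        for length in range(min(max_len, n - i), 0, -1):
            window = tuple(tokens[i : i + length])
            if window in matcher:
                counts[matcher[window]] += 1
                i += length
                break
        else:
            i += 1
    return TermCounts(doc_id=doc.doc_id, counts=dict(counts))


def extract_corpus(
    docs: Sequence[DocumentRecord],
    dictionary: TermDictionary,
    recoding: RecodingMap | None = None,
) -> list[TermCounts]:
    """Extract every document with a shared matcher."""
    matcher = build_matcher(dictionary, recoding)
    return [
        extract_terms(d, dictionary, recoding, matcher=matcher) for d in docs
    ]


def load_corpus(path: str | Path) -> list[DocumentRecord]:
    """Read a corpus CSV/TSV with columns doc_id, text[, label][, source]."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype={"doc_id": str})
    missing = {"doc_id", "text"} - set(frame.columns)
    if missing:
        raise ValueError(f"corpus {path} missing columns: {sorted(missing)}")
    if frame["doc_id"].duplicated().any():
        dups = frame.loc[frame["doc_id"].duplicated(), "doc_id"].tolist()
        raise ValueError(f"duplicate doc_id values: {dups[:5]}")
    records = []
    for row in frame.itertuples(index=False):
        label = getattr(row, "label", None)
        if label is not None and pd.isna(label):
            label = None
        records.append(
            DocumentRecord(
                doc_id=str(row.doc_id),
                text="" if pd.isna(row.text) else str(row.text),
                label=None if label is None else int(label),
                source=str(getattr(row, "source", None) or "") or None,
            )
        )
    return records


def save_corpus(docs: Sequence[DocumentRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "doc_id": [d.doc_id for d in docs],
            "text": [d.text for d in docs],
            "label": [d.label for d in docs],
            "source": [d.source for d in docs],
        }
    )
    frame.to_csv(path, index=False)
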