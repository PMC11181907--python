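"""Synthetic fixtures: toy dictionaries, recoding maps, and labeled corpora
with planted label-associated signal terms.

Lets every pipeline stage be exercised without licensed vocabularies or
external corpora.  Occurrences follow a Poisson bag-of-words: each signal
term's rate is multiplied by ``rate_ratio`` in positive documents, so
``rate_ratio`` is the single effect-size knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .vocab import DocumentRecord, RecodingMap, TermDictionary


def filler_words() -> list[str]:
    """The fixed common-word list used as non-dictionary filler."""
    text = (
        resources.files("dilitext").joinpath("data/fillers.txt").read_text("utf-8")
    )
    seen: dict[str, None] = {}
    for w in text.split():
        seen.setdefault(w, None)
    return list(seen)


@dataclass(frozen=True)
class GeneratorSpec:
    n_docs: int = 200
    positive_fraction: float = 0.35
    vocabulary_size: int = 100
    n_signal_terms: int = 10
    rate_ratio: float = 4.0
    mean_doc_length: float = 150.0
    filler_fraction: float = 0.3
    n_phrases: int = 10
    recode_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_ratio < 1:
            raise ValueError("rate_ratio must be >= 1")
        for name in ("positive_fraction", "filler_fraction", "recode_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_docs", "vocabulary_size", "mean_doc_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_signal_terms > self.vocabulary_size:
            raise ValueError("n_signal_terms exceeds vocabulary_size")
        if self.n_phrases > self.vocabulary_size:
            raise ValueError("n_phrases exceeds vocabulary_size")


def _pseudo_words(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic pronounceable pseudo-words, unique, non-filler."""
    consonants = "bcdfghjklmnpqrstvwz"
    vowels = "aeiou"
    fillers = set(filler_words())
    words: list[str] = []
    seen: set[str] = set(fillers)
    while len(words) < n:
        syllables = rng.integers(2, 4)
        w = "".join(
            consonants[rng.integers(len(consonants))]
            + vowels[rng.integers(len(vowels))]
            for _ in range(syllables)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def make_toy_dictionary(spec: GeneratorSpec) -> tuple[TermDictionary, RecodingMap]:
    """Pseudo-term dictionary (singles + phrases) with recoding variants.

    Variants mirror the shapes of real recoding rules: plural -> singular
    for single-word terms, and a "chronic <phrase>" prefix form for
    phrases, each mapping onto a dictionary entry.
    """
    rng = np.random.default_rng(spec.seed)
    n_single = spec.vocabulary_size - spec.n_phrases
    words = _pseudo_words(n_single + 2 * spec.n_phrases, rng)
    singles = words[:n_single]
    phrase_words = words[n_single:]
    phrases = [
        f"{phrase_words[2 * i]} {phrase_words[2 * i + 1]}"
        for i in range(spec.n_phrases)
    ]
    entries = singles + phrases
    rules: dict[str, str] = {}
    n_recode = int(round(spec.recode_fraction * len(entries)))
    for t in [entries[i] for i in rng.permutation(len(entries))[:n_recode]]:
        if " " in t:
            rules[f"chronic {t}"] = t
        else:
            rules[f"{t}s"] = t
    return (
        TermDictionary(entries=frozenset(entries), name=f"toy-{spec.seed}"),
        RecodingMap(rules=rules),
    )


def signal_terms(spec: GeneratorSpec, dictionary: TermDictionary) -> list[str]:
    """The planted signal subset (deterministic in the spec seed)."""
    rng = np.random.default_rng(spec.seed + 1)
    entries = sorted(dictionary.entries)
    idx = rng.permutation(len(entries))[: spec.n_signal_terms]
    return [entries[i] for i in sorted(idx)]


def term_rates(
    spec: GeneratorSpec, dictionary: TermDictionary
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(terms, negative-class rates, positive-class rates) per Poisson draw."""
    entries = sorted(dictionary.entries)
    lengths = np.array([len(t.split()) for t in entries])
    budget = spec.mean_doc_length * (1.0 - spec.filler_fraction)
    if budget < 1.0:
        raise ValueError(
            "infeasible document length: dictionary-token budget below 1"
        )
    mu = budget / float(lengths.sum())
    neg = np.full(len(entries), mu)
    pos = neg.copy()
    sig = set(signal_terms(spec, dictionary))
    for j, t in enumerate(entries):
        if t in sig:
            pos[j] = mu * spec.rate_ratio
    return entries, neg, pos


def simulate_corpus(
    spec: GeneratorSpec,
    dictionary: TermDictionary | None = None,
    recoding: RecodingMap | None = None,
    corpus_seed: int | None = None,
) -> list[DocumentRecord]:
    """Labeled corpus with planted class-dependent term rates.

    A fraction of dictionary-term mentions is emitted through its recoding
    variant, so extraction must canonicalize to recover the full signal.
    Word order is randomized at the mention level (phrases stay intact).
    ``corpus_seed`` redraws the documents while keeping the dictionary and
    the planted signal subset fixed (for transfer experiments).
    """
    if dictionary is None or recoding is None:
        dictionary, recoding = make_toy_dictionary(spec)
    rng = np.random.default_rng(
        spec.seed + 2 if corpus_seed is None else corpus_seed
    )
    entries, neg_rates, pos_rates = term_rates(spec, dictionary)
    variant_of = {dst: src for src, dst in recoding.rules.items()}
    fillers = filler_words()
    labels = (rng.random(spec.n_docs) < spec.positive_fraction).astype(int)
    rate_matrix = np.where(labels[:, None] == 1, pos_rates, neg_rates)
    counts = rng.poisson(rate_matrix)  # docs x terms
    n_filler = rng.poisson(
        spec.mean_doc_length * spec.filler_fraction, size=spec.n_docs
    )
    docs: list[DocumentRecord] = []
    for i in range(spec.n_docs):
        chunks: list[str] = []
        for j in np.flatnonzero(counts[i]):
            term = entries[j]
            for _ in range(counts[i, j]):
                if term in variant_of and rng.random() < spec.recode_fraction:
                    chunks.append(variant_of[term])
                else:
                    chunks.append(term)
        chunks.extend(
            fillers[idx] for idx in rng.integers(len(fillers), size=n_filler[i])
        )
        order = rng.permutation(len(chunks))
        text = " ".join(chunks[o] for o in order)
        docs.append(
            DocumentRecord(
                doc_id=f"doc{i:05d}", text=text, label=int(labels[i]), source="toy"
            )
        )
    return docs
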