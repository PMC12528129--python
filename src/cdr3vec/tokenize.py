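"""Sliding-window k-mer tokenization of CDR3 amino-acid sequences.

A CDR3 of length L yields the L-k+1 overlapping k-mers read left to
right; with the default k=3 a typical 15-residue CDR3 yields 13 trigrams.
Consecutive tokens overlap by k-1 characters, so the token list losslessly
encodes the sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


class SequenceTooShortError(ValueError):
    """Sequence shorter than k cannot be tokenized."""


class EmptyVocabularyError(ValueError):
    """No token survived the min_count threshold."""


def kmerize(seq: str, k: int = 3) -> list[str]:
    """Return the overlapping k-mers of ``seq``, in order, duplicates kept.

    >>> kmerize("CASSF", 3)
    ['CAS', 'ASS', 'SSF']
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise SequenceTooShortError(
            f"sequence of length {len(seq)} is shorter than k={k}")
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


@dataclass
class KmerVocab:
    """Token vocabulary with deterministic indexing.

    Indices run 0..V-1 ordered by descending count, ties broken
    lexicographically — fixed so that embedding training is reproducible.
    """

    index: dict[str, int]
    counts: dict[str, int]
    k: int
    min_count: int = 1
    tokens: list[str] = field(init=False)

    def __post_init__(self):
        self.tokens = sorted(self.index, key=self.index.__getitem__)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index


def build_vocab(corpus: list[list[str]], min_count: int = 1) -> KmerVocab:
    """Count tokens across the corpus and index those with count >= min_count."""
    if not corpus or all(len(toks) == 0 for toks in corpus):
        raise ValueError("corpus is empty")
    counter: Counter[str] = Counter()
    for toks in corpus:
        counter.update(toks)
    lengths = {len(t) for t in counter}
    if len(lengths) != 1:
        raise ValueError(f"tokens have mixed lengths {sorted(lengths)}; "
                         "a vocabulary holds k-mers of a single k")
    kept = {t: c for t, c in counter.items() if c >= min_count}
    if not kept:
        raise EmptyVocabularyError(
            f"no token reaches min_count={min_count}")
    ordered = sorted(kept, key=lambda t: (-kept[t], t))
    return KmerVocab(index={t: i for i, t in enumerate(ordered)},
                     counts={t: kept[t] for t in ordered},
                     k=lengths.pop(), min_count=min_count)


def corpus_stats(corpus: list[list[str]], k: int = 3) -> dict:
    """Corpus bookkeeping: sequence/token counts and mean CDR3 length.

    ``mean_length`` refers to the untokenized sequences (len(tokens)+k-1).
    An empty corpus returns all-zero stats.
    """
    if not corpus:
        return {"n_sequences": 0, "n_tokens": 0, "n_unique_tokens": 0,
                "mean_length": 0.0}
    n_tokens = sum(len(toks) for toks in corpus)
    unique = set()
    for toks in corpus:
        unique.update(toks)
    mean_length = sum(len(toks) + k - 1 for toks in corpus) / len(corpus)
    return {"n_sequences": len(corpus), "n_tokens": n_tokens,
            "n_unique_tokens": len(unique), "mean_length": mean_length}
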