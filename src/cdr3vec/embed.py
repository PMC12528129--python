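"""Skip-gram embeddings with negative sampling for CDR3 k-mer corpora.

The model learns two V×d matrices: input (center) vectors ``W_in`` and
output (context) vectors ``W_out``, for 2·V·d trainable parameters. For
every center token the model is pushed to score its true context tokens
(within ``window`` positions) above ``negatives`` noise tokens drawn from
the unigram^0.75 distribution, via the logistic loss

    L(c, o, n_1..n_m) = -log σ(u_o·v_c) - Σ_j log σ(-u_{n_j}·v_c)

optimized by SGD with a linearly decaying learning rate. Training is
single-threaded and fully determined by the seed: identical inputs and
seed give bit-identical matrices.

A whole CDR3 sequence is embedded as the unweighted mean of the ``W_in``
rows of its tokens (order-invariant; ``sum`` reduction also available).
By convention the model is trained on the pooled healthy-control corpus
and then applied to every cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .tokenize import KmerVocab


class EmptyCorpusError(ValueError):
    """No trainable (center, context) pair in the corpus."""


class UnembeddableSequenceError(ValueError):
    """Every token of a sequence is absent from the vocabulary."""


@dataclass
class SkipGramConfig:
    """Hyperparameters; defaults are the study profile (d=100, window 5,
    10 epochs) with canonical negative-sampling settings."""

    vector_size: int = 100
    window: int = 5
    epochs: int = 10
    negatives: int = 5
    lr_start: float = 0.025
    lr_end: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.vector_size < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("vector_size, window and epochs must be >= 1")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")
        if not (0 < self.lr_end <= self.lr_start):
            raise ValueError("require 0 < lr_end <= lr_start")


@dataclass
class SkipGramModel:
    vocab: KmerVocab
    config: SkipGramConfig
    W_in: np.ndarray
    W_out: np.ndarray
    n_skipped_tokens: int = 0  # out-of-vocabulary tokens seen during training

    def param_count(self) -> int:
        """Number of trainable parameters: 2 · V · d (both matrices)."""
        return 2 * len(self.vocab) * self.config.vector_size

    def vector(self, token: str) -> np.ndarray:
        return self.W_in[self.vocab.index[token]]


def pair_loss(W_in: np.ndarray, W_out: np.ndarray, center: int,
              context: int, negatives: np.ndarray) -> float:
    """Negative-sampling logistic loss for one (center, context) pair."""
    v = W_in[center]
    s_pos = float(W_out[context] @ v)
    s_neg = W_out[negatives] @ v
    # -log σ(x) = log(1 + e^{-x}), computed stably
    return float(np.logaddexp(0.0, -s_pos) + np.logaddexp(0.0, s_neg).sum())


def pair_gradients(W_in: np.ndarray, W_out: np.ndarray, center: int,
                   context: int, negatives: np.ndarray):
    """Analytic gradients of :func:`pair_loss`.

    Returns ``(g_center, rows, g_rows)``: the gradient w.r.t. the center's
    input vector, the W_out row indices touched, and the gradient for each
    of those rows (aligned with ``rows``; duplicate rows each carry their
    own contribution and must be summed by the caller).
    """
    v = W_in[center]
    rows = np.concatenate(([context], negatives)).astype(np.int64)
    labels = np.zeros(len(rows))
    labels[0] = 1.0
    g = expit(W_out[rows] @ v) - labels       # dL/d(score)
    g_center = g @ W_out[rows]
    g_rows = g[:, None] * v[None, :]
    return g_center, rows, g_rows


def train_skipgram(corpus: list[list[str]], vocab: KmerVocab,
                   config: SkipGramConfig | None = None) -> SkipGramModel:
    """Train skip-gram embeddings on a token corpus.

    All context tokens within ``window`` positions of each center are used
    (no random window shrinking — determinism is part of the contract).
    The updates for one center position are applied as a single vectorized
    SGD step. Tokens absent from the vocabulary are skipped and counted.
    """
    config = config or SkipGramConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    V, d = len(vocab), config.vector_size

    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    index = vocab.index
    encoded, n_skipped = [], 0
    for toks in corpus:
        ids = np.array([index[t] for t in toks if t in index], dtype=np.int64)
        n_skipped += len(toks) - len(ids)
        if len(ids) >= 2:  # a single token has no context
            encoded.append(ids)
    total_centers = config.epochs * sum(len(s) for s in encoded)
    if total_centers == 0:
        raise EmptyCorpusError("corpus yields no (center, context) pairs")

    # unigram^0.75 noise distribution over vocabulary indices
    counts = np.array([vocab.counts[t] for t in vocab.tokens], dtype=float)
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    window, m = config.window, config.negatives
    lr_span = config.lr_start - config.lr_end
    processed = 0
    for _ in range(config.epochs):
        for s in encoded:
            n = len(s)
            for i in range(n):
                lr = config.lr_start - lr_span * (processed / max(total_centers - 1, 1))
                processed += 1
                lo, hi = max(0, i - window), min(n, i + window + 1)
                ctx = np.concatenate((s[lo:i], s[i + 1:hi]))
                if ctx.size == 0:
                    continue
                c = s[i]
                v = W_in[c].copy()
                if m > 0:
                    negs = np.searchsorted(noise_cdf, rng.random(ctx.size * m))
                    # a draw that hits its own positive context is skipped
                    keep = negs != np.repeat(ctx, m)
                    rows = np.concatenate((ctx, negs[keep]))
                    labels = np.concatenate((np.ones(ctx.size), np.zeros(int(keep.sum()))))
                else:
                    rows, labels = ctx, np.ones(ctx.size)
                g = expit(W_out[rows] @ v) - labels
                W_in[c] -= lr * (g @ W_out[rows])
                np.add.at(W_out, rows, (-lr * g)[:, None] * v[None, :])
    return SkipGramModel(vocab=vocab, config=config, W_in=W_in, W_out=W_out,
                         n_skipped_tokens=n_skipped)


def embed_sequence(model: SkipGramModel, tokens: list[str],
                   sequence_id: str = "?", reduction: str = "mean") -> np.ndarray:
    """Embed one tokenized sequence as the mean (or sum) of its token vectors.

    Out-of-vocabulary tokens are skipped; a sequence with no in-vocabulary
    token raises :class:`UnembeddableSequenceError` naming the sequence.
    """
    ids = [model.vocab.index[t] for t in tokens if t in model.vocab]
    if not ids:
        raise UnembeddableSequenceError(
            f"sequence {sequence_id!r}: no token found in the vocabulary")
    vecs = model.W_in[ids]
    if reduction == "mean":
        return vecs.mean(axis=0)
    if reduction == "sum":
        return vecs.sum(axis=0)
    raise ValueError(f"unknown reduction {reduction!r}")


@dataclass
class EmbeddedRepertoire:
    """Per-sequence vectors plus carried-through metadata.

    ``X`` is N×d after embedding (or N×L after PCA); ``meta`` has one row
    per sequence with columns sequence_id, sample_id, group.
    """

    X: np.ndarray
    meta: pd.DataFrame
    n_skipped: int = 0   # sequences dropped under on_unknown="skip"

    def __post_init__(self):
        if len(self.X) != len(self.meta):
            raise ValueError("matrix and metadata row counts differ")
        if not np.isfinite(self.X).all():
            raise ValueError("embedding matrix contains non-finite values")


def embed_corpus(model: SkipGramModel, corpus: list[list[str]],
                 meta: pd.DataFrame, on_unknown: str = "raise",
                 reduction: str = "mean") -> EmbeddedRepertoire:
    """Embed every sequence of a cohort; metadata rows are carried through.

    ``on_unknown`` controls sequences with no in-vocabulary token:
    ``"raise"`` propagates the error (default), ``"skip"`` drops them and
    counts the drops — the pipeline uses skip because cohorts embedded with
    a control-trained model can contain entirely novel trigram sets.
    """
    if on_unknown not in ("raise", "skip"):
        raise ValueError(f"unknown on_unknown policy {on_unknown!r}")
    if len(corpus) != len(meta):
        raise ValueError("corpus and metadata lengths differ")
    rows, kept_idx = [], []
    for i, tokens in enumerate(corpus):
        seq_id = str(meta.iloc[i]["sequence_id"])
        try:
            rows.append(embed_sequence(model, tokens, seq_id, reduction))
            kept_idx.append(i)
        except UnembeddableSequenceError:
            if on_unknown == "raise":
                raise
    if not rows:
        raise UnembeddableSequenceError("no sequence could be embedded")
    X = np.vstack(rows)
    return EmbeddedRepertoire(X=X, meta=meta.iloc[kept_idx].reset_index(drop=True),
                              n_skipped=len(corpus) - len(rows))


def save_model(model: SkipGramModel, path) -> None:
    """Serialize config, vocabulary and both matrices to JSON (exact round trip)."""
    payload = {
        "config": asdict(model.config),
        "k": model.vocab.k,
        "min_count": model.vocab.min_count,
        "tokens": model.vocab.tokens,
        "counts": [model.vocab.counts[t] for t in model.vocab.tokens],
        "W_in": [[float.hex(float(x)) for x in row] for row in model.W_in],
        "W_out": [[float.hex(float(x)) for x in row] for row in model.W_out],
        "n_skipped_tokens": model.n_skipped_tokens,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SkipGramModel:
    with open(path) as fh:
        payload = json.load(fh)
    tokens = payload["tokens"]
    vocab = KmerVocab(index={t: i for i, t in enumerate(tokens)},
                      counts=dict(zip(tokens, payload["counts"])),
                      k=payload["k"], min_count=payload["min_count"])
    W_in = np.array([[float.fromhex(x) for x in row] for row in payload["W_in"]])
    W_out = np.array([[float.fromhex(x) for x in row] for row in payload["W_out"]])
    return SkipGramModel(vocab=vocab, config=SkipGramConfig(**payload["config"]),
                         W_in=W_in, W_out=W_out,
                         n_skipped_tokens=payload["n_skipped_tokens"])
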