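"""Minimal skip-gram word embeddings with negative sampling.

A compact, deterministic (single-worker, seeded) implementation of the
skip-gram-with-negative-sampling objective: for each (center, context) pair
within a dynamic window, the center vector is pushed toward the context's
output vector and away from ``negative`` sampled noise words drawn from the
unigram distribution raised to 3/4. Frequent words are downsampled with the
standard threshold rule. Defaults follow the hyperparameters used for the
corpus this package emulates: learning rate 0.05, 512 dimensions, window 5,
subsample threshold 1e-3, 10 training iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass
class EmbeddingSet:
    """Trained word vectors: ``words`` (ordered) and ``vectors`` (words x dim)."""

    words: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.words) != self.vectors.shape[0]:
            raise ValueError("words and vectors disagree in length")
        if np.isnan(self.vectors).any():
            raise ValueError("embedding vectors contain NaN")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, words: Sequence[str]) -> tuple["EmbeddingSet", list[str]]:
        """Vectors for ``words``; absent words are reported, never silently
        dropped."""
        index = {w: i for i, w in enumerate(self.words)}
        present = [w for w in words if w in index]
        missing = [w for w in words if w not in index]
        vecs = self.vectors[[index[w] for w in present]] if present else np.empty((0, self.dim))
        return EmbeddingSet(words=present, vectors=vecs), missing

    def similarity(self, a: str, b: str) -> float:
        sub, missing = self.lookup([a, b])
        if missing:
            raise KeyError(f"words not in vocabulary: {missing}")
        va, vb = sub.vectors
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_sgns(
    sentences: Iterable[Sequence[str]],
    size: int = 512,
    window: int = 5,
    alpha: float = 0.05,
    sample: float = 1e-3,
    negative: int = 5,
    epochs: int = 10,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingSet:
    """Train skip-gram embeddings on tokenized sentences.

    Deterministic for a fixed seed (single worker, fixed update order).
    """
    sents = [list(s) for s in sentences if s]
    if not sents:
        raise ValueError("no sentences to train on")
    counts: dict[str, int] = {}
    for s in sents:
        for w in s:
            counts[w] = counts.get(w, 0) + 1
    vocab = [w for w, c in sorted(counts.items()) if c >= min_count]
    if len(vocab) < 2:
        raise ValueError("vocabulary too small for embedding training")
    index = {w: i for i, w in enumerate(vocab)}
    freq = np.array([counts[w] for w in vocab], dtype=float)
    total = freq.sum()

    # subsampling keep-probability (threshold rule on corpus frequency)
    f = freq / total
    keep = np.minimum(1.0, (np.sqrt(f / sample) + 1.0) * sample / f) if sample > 0 else np.ones_like(f)

    noise = freq ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W = (rng.random((V, size)) - 0.5) / size  # input vectors
    C = np.zeros((V, size))  # output vectors

    encoded = [np.array([index[w] for w in s if w in index], dtype=np.int64) for s in sents]
    n_tokens = sum(len(s) for s in encoded)
    total_updates = max(1, epochs * n_tokens)
    done = 0
    min_alpha = alpha * 1e-4

    for _ in range(epochs):
        for sent in encoded:
            if len(sent) == 0:
                continue
            kept = sent[rng.random(len(sent)) < keep[sent]]
            done += len(sent)
            if len(kept) < 2:
                continue
            lr = max(min_alpha, alpha * (1.0 - done / total_updates))
            reduced = rng.integers(1, window + 1, size=len(kept))
            for i, center in enumerate(kept):
                b = reduced[i]
                lo, hi = max(0, i - b), min(len(kept), i + b + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = kept[j]
                    neg = np.searchsorted(noise_cdf, rng.random(negative))
                    targets = np.concatenate(([ctx], neg))
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    w_vec = W[center]
                    c_vecs = C[targets]
                    g = (labels - _sigmoid(c_vecs @ w_vec)) * lr
                    W[center] = w_vec + g @ c_vecs
                    C[targets] = c_vecs + np.outer(g, w_vec)
    return EmbeddingSet(words=vocab, vectors=W)


def save_embeddings(emb: EmbeddingSet, path: str | Path) -> None:
    """Write vectors in the standard word2vec text format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.words)} {emb.dim}\n")
        for w, v in zip(emb.words, emb.vectors):
            fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")


def load_embeddings(path: str | Path) -> EmbeddingSet:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        words, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            words.append(parts[0])
            rows.append([float(x) for x in parts[1 : dim + 1]])
    if len(words) != n:
        raise ValueError(f"embedding file declared {n} words, found {len(words)}")
    return EmbeddingSet(words=words, vectors=np.array(rows))
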