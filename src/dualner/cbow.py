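"""Continuous-bag-of-words character embeddings.

The CBOW objective predicts a center character from the average of the input
vectors of the characters inside a symmetric context window. Scores against
every vocabulary item go through a full softmax and the mean cross-entropy is
minimised by full-batch gradient descent, which keeps training exactly
reproducible for a fixed seed and (for a small enough learning rate)
monotonically non-increasing in the epoch-wise loss. Negative sampling is
available for larger vocabularies.

The unit is the CHARACTER: Chinese clinical NER is character-tagged, so
character vectors align one-to-one with the tags and with transformer tokens.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus, LabeledSequence

PAD, UNK = "<PAD>", "<UNK>"


class TrainingError(RuntimeError):
    pass


@dataclass
class EmbeddingTable:
    """Char -> vector lookup with <PAD> (all zeros) and <UNK> rows."""

    vocab: dict[str, int]  # includes <PAD> at 0 and <UNK> at 1
    vectors: np.ndarray  # (|vocab|, d)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def index(self, char: str) -> int:
        return self.vocab.get(char, self.vocab[UNK])

    def indices(self, chars: list[str]) -> np.ndarray:
        return np.array([self.index(c) for c in chars], dtype=int)

    def __getitem__(self, char: str) -> np.ndarray:
        return self.vectors[self.index(char)]

    def lookup(self, seq: LabeledSequence | list[str]) -> np.ndarray:
        """Embed a sequence: (len, d) matrix; unseen characters map to <UNK>."""
        chars = seq.chars if isinstance(seq, LabeledSequence) else list(seq)
        if not chars:
            return np.zeros((0, self.dim))
        return self.vectors[self.indices(chars)]

    def save_word2vec(self, path: str | Path) -> None:
        """word2vec text format: header `vocab dim`, then token + floats."""
        inv = sorted(self.vocab, key=self.vocab.get)
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(inv)} {self.dim}\n")
            for tok in inv:
                row = " ".join(f"{x:.8g}" for x in self.vectors[self.vocab[tok]])
                fh.write(f"{tok} {row}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with Path(path).open(encoding="utf-8") as fh:
            n, d = map(int, fh.readline().split())
            vocab: dict[str, int] = {}
            vectors = np.zeros((n, d))
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1 : d + 1]]
        return cls(vocab, vectors)


def build_vocab(corpus: Corpus, min_count: int = 1) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in corpus:
        for c in seq.chars:
            counts[c] = counts.get(c, 0) + 1
    vocab = {PAD: 0, UNK: 1}
    for c in sorted(counts):  # sorted: vocabulary order independent of dict order
        if counts[c] >= min_count:
            vocab[c] = len(vocab)
    return vocab


def _context_pairs(
    corpus: Corpus, vocab: dict[str, int], window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (context-index-matrix, context-count, center) training examples.

    Context rows are padded with 0 (<PAD>); <PAD>'s vector is pinned to zero
    so padded slots contribute nothing to the context average.
    """
    ctx_rows: list[list[int]] = []
    centers: list[int] = []
    for seq in corpus:
        ids = [vocab.get(c, 1) for c in seq.chars]
        for i, center in enumerate(ids):
            ctx = ids[max(0, i - window) : i] + ids[i + 1 : i + 1 + window]
            if ctx:
                ctx_rows.append(ctx)
                centers.append(center)
    if not ctx_rows:
        raise TrainingError("corpus has no context windows (sentences too short)")
    width = max(len(r) for r in ctx_rows)
    mat = np.zeros((len(ctx_rows), width), dtype=int)
    cnt = np.empty(len(ctx_rows))
    for i, row in enumerate(ctx_rows):
        mat[i, : len(row)] = row
        cnt[i] = len(row)
    return mat, cnt, np.array(centers, dtype=int)


def train_cbow(
    corpus: Corpus,
    d: int = 200,
    window: int = 5,
    epochs: int = 10,
    seed: int = 0,
    learning_rate: float = 0.5,
    min_count: int = 1,
    negative: int = 0,
    return_losses: bool = False,
) -> EmbeddingTable | tuple[EmbeddingTable, list[float]]:
    """Train character vectors; deterministic for a fixed seed.

    With ``negative=0`` (default) the objective is full-softmax cross-entropy
    minimised by one full-batch gradient step per epoch; ``negative=k`` trains
    with k negative samples per example instead. ``epochs=0`` returns the
    seeded random initialisation untouched.
    """
    if d < 1 or window < 1:
        raise ValueError("d and window must be >= 1")
    if not corpus.sequences:
        raise TrainingError("empty corpus")
    vocab = build_vocab(corpus, min_count=min_count)
    n_real = len(vocab) - 2
    if n_real < 2:
        raise TrainingError(f"vocabulary too small ({n_real} non-special symbols)")

    rng = np.random.default_rng(seed)
    v_in = rng.normal(0.0, 0.5 / np.sqrt(d), size=(len(vocab), d))
    v_out = rng.normal(0.0, 0.5 / np.sqrt(d), size=(len(vocab), d))
    v_in[0] = 0.0  # <PAD> pinned to zero

    ctx, cnt, centers = _context_pairs(corpus, vocab, window)
    losses: list[float] = []
    for _ in range(epochs):
        h = v_in[ctx].sum(axis=1) / cnt[:, None]  # (N, d) context means
        if negative <= 0:
            scores = h @ v_out.T  # (N, V) full softmax
            scores -= scores.max(axis=1, keepdims=True)
            p = np.exp(scores)
            p /= p.sum(axis=1, keepdims=True)
            loss = float(
                -np.mean(np.log(p[np.arange(len(centers)), centers] + 1e-300))
            )
            g = p
            g[np.arange(len(centers)), centers] -= 1.0
            g /= len(centers)
            d_vout = g.T @ h
            d_h = g @ v_out
        else:
            neg = rng.integers(2, len(vocab), size=(len(centers), negative))
            pos_s = np.einsum("nd,nd->n", h, v_out[centers])
            neg_s = np.einsum("nd,nkd->nk", h, v_out[neg])
            loss = float(
                np.mean(np.logaddexp(0, -pos_s))
                + np.mean(np.logaddexp(0, neg_s).sum(axis=1))
            )
            gp = (-1.0 / (1.0 + np.exp(pos_s))) / len(centers)
            gn = (1.0 / (1.0 + np.exp(-neg_s))) / len(centers)
            d_vout = np.zeros_like(v_out)
            np.add.at(d_vout, centers, gp[:, None] * h)
            np.add.at(d_vout, neg.ravel(), (gn[..., None] * h[:, None, :]).reshape(-1, d))
            d_h = gp[:, None] * v_out[centers] + np.einsum(
                "nk,nkd->nd", gn, v_out[neg]
            )
        losses.append(loss)
        d_vin = np.zeros_like(v_in)
        scaled = d_h / cnt[:, None]
        np.add.at(d_vin, ctx.ravel(), np.repeat(scaled, ctx.shape[1], axis=0).reshape(-1, d))
        d_vin[0] = 0.0
        v_in -= learning_rate * d_vin
        v_out -= learning_rate * d_vout

    v_in[1] = v_in[2:].mean(axis=0) if epochs > 0 else v_in[1]  # <UNK> = mean vector
    v_in[0] = 0.0
    table = EmbeddingTable(vocab, v_in)
    return (table, losses) if return_losses else table
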