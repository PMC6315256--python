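"""Character embeddings trained by skip-gram with negative sampling.

Chinese clinical text is embedded at the single-character level (no
segmentation needed).  The objective for a (center, context) pair with k
negatives drawn from the unigram^0.75 distribution is

    -log sigmoid(u_ctx . v_center) - sum_neg log sigmoid(-u_neg . v_center)

optimized by plain SGD over the corpus, fully seeded.  A random-init
fallback table is provided so the neural tagger is usable without any
pretraining.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

UNK = "<UNK>"


@dataclass
class EmbeddingTable:
    """Character -> dense vector lookup with an UNK row."""

    vocab: dict[str, int]
    matrix: np.ndarray  # [len(vocab) x dim]
    dim: int

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        if UNK not in self.vocab:
            raise ValueError("vocabulary must contain the UNK token")
        if self.matrix.shape != (len(self.vocab), self.dim):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.vocab)} vocabulary entries of dimension {self.dim}"
            )

    def vector(self, ch: str) -> np.ndarray:
        return self.matrix[self.vocab.get(ch, self.vocab[UNK])]

    @classmethod
    def random(cls, chars: list[str], dim: int, seed: int, scale: float = 0.05) -> "EmbeddingTable":
        """Seeded uniform(-scale, scale) fallback table."""
        rng = np.random.default_rng(seed)
        vocab = {UNK: 0}
        for ch in chars:
            vocab.setdefault(ch, len(vocab))
        return cls(vocab, rng.uniform(-scale, scale, size=(len(vocab), dim)), dim)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def train_char_embeddings(
    text: str,
    dim: int = 100,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 0.025,
    min_count: int = 1,
) -> EmbeddingTable:
    """Train skip-gram character embeddings on a raw text stream.

    Returns an :class:`EmbeddingTable` whose UNK row is the mean of all
    trained rows.  The per-epoch mean negative-sampling loss is recorded on
    the returned table as ``epoch_losses``.
    """
    if not text:
        raise ValueError("empty training text")
    if len(text) < window:
        raise ValueError(f"text length {len(text)} shorter than window {window}")
    counts = Counter(text)
    chars = sorted(ch for ch, c in counts.items() if c >= min_count)
    vocab = {ch: i for i, ch in enumerate(chars)}
    V = len(vocab)
    rng = np.random.default_rng(seed)

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[ch] for ch in chars], dtype=np.float64) ** 0.75
    neg_prob = freq / freq.sum()

    W = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim))  # center vectors
    C = np.zeros((V, dim))  # context vectors
    ids = np.array([vocab[ch] for ch in text if ch in vocab], dtype=np.intp)
    n = ids.shape[0]

    epoch_losses: list[float] = []
    for _ in range(epochs):
        total = 0.0
        pairs = 0
        for i in range(n):
            center = ids[i]
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                ctx = ids[j]
                negs = rng.choice(V, size=negatives, p=neg_prob)
                rows = np.concatenate([[ctx], negs])
                targets = np.zeros(negatives + 1)
                targets[0] = 1.0
                v = W[center]
                u = C[rows]
                s = _sigmoid(u @ v)
                total += -np.log(np.clip(np.where(targets == 1.0, s, 1.0 - s), 1e-12, None)).sum()
                pairs += 1
                g = s - targets  # d loss / d (u . v)
                dv = g @ u
                # duplicate negative rows accumulate correctly via add.at
                np.add.at(C, rows, -lr * np.outer(g, v))
                W[center] = v - lr * dv
        epoch_losses.append(total / max(1, pairs))

    full_vocab = {UNK: 0}
    for ch in chars:
        full_vocab[ch] = len(full_vocab)
    matrix = np.vstack([W.mean(axis=0, keepdims=True), W])
    table = EmbeddingTable(full_vocab, matrix, dim)
    table.epoch_losses = epoch_losses  # type: ignore[attr-defined]
    return table


# ---------------------------------------------------------------------------
# word2vec-compatible text format: header "V D", rows "char v1 ... vD"
# ---------------------------------------------------------------------------

def save_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    lines = [f"{len(table.vocab)} {table.dim}"]
    for ch in sorted(table.vocab, key=table.vocab.get):
        row = table.matrix[table.vocab[ch]]
        lines.append(ch + " " + " ".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_pretrained(path: str | Path) -> EmbeddingTable:
    """Load a word2vec-format text file; UNK is appended as the mean vector
    if the file lacks one."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty embedding file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError(f"{path}:1: expected header 'vocab_size dim'")
    declared_v, dim = int(header[0]), int(header[1])
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(" ")
        if len(parts) != dim + 1:
            raise ValueError(
                f"{path}:{lineno}: expected 1 token + {dim} values, got {len(parts)} fields"
            )
        token = parts[0]
        try:
            vec = np.array([float(x) for x in parts[1:]])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric embedding value") from None
        if token in vocab:
            raise ValueError(f"{path}:{lineno}: duplicate token {token!r}")
        vocab[token] = len(rows)
        rows.append(vec)
    if len(rows) != declared_v:
        raise ValueError(f"{path}: header declares {declared_v} rows, found {len(rows)}")
    matrix = np.vstack(rows)
    if UNK not in vocab:
        vocab = {tok: i + 1 for tok, i in vocab.items()}
        vocab[UNK] = 0
        matrix = np.vstack([matrix.mean(axis=0, keepdims=True), matrix])
    return EmbeddingTable(vocab, matrix, dim)
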