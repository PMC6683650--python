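"""Skip-gram embeddings with negative sampling, and the projection model.

The projection model adapts embeddings trained on a large external corpus
(e.g. an encyclopedia or journal abstracts) to a small in-domain corpus
(e.g. hospital discharge notes) by learning a single D×D linear map P while
the base vectors stay frozen.  Every base-vocabulary word — including words
the internal corpus never mentions — is moved by P, so the adapted space
keeps the external corpus's vocabulary diversity while absorbing in-domain
co-occurrence structure.  At D=50 the only trainable tensor is the 50×50
matrix: 2500 parameters.

A concatenation baseline (stacking two embedding spaces over their shared
vocabulary) is provided for comparison; unlike projection it cannot extend
coverage beyond the vocabulary intersection.

Training is plain SGD with momentum on the negative-sampling objective

    L = -log σ(u·v) - Σ_i log σ(-u·n_i)

with noise words drawn from the unigram distribution raised to 0.75.  All
randomness (shuffling, noise draws, initialization) flows from one seed, and
single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import Corpus, TokenSequence, Vocabulary, build_vocab

__all__ = [
    "SkipGramConfig",
    "EmbeddingTable",
    "ProjectionModel",
    "generate_training_pairs",
    "ns_loss",
    "train_skipgram",
    "train_projection",
    "materialize",
    "concat_embeddings",
    "save_table",
    "load_table",
]


@dataclass
class SkipGramConfig:
    """Hyperparameters shared by the skip-gram and projection trainers.

    Defaults are the full-scale settings: skip-gram, window 12, dimension 50,
    minimum word frequency 20, 5 negative samples, learning rate 0.1,
    momentum 0.9.  Small synthetic corpora typically use dim 16, window 5
    and min_count 1.
    """

    dim: int = 50
    window: int = 12
    negatives: int = 5
    min_count: int = 20
    learning_rate: float = 0.1
    momentum: float = 0.9
    epochs: int = 5
    seed: int = 0
    batch_size: int = 256
    noise_power: float = 0.75
    #: "nce" adds the log-partition correction to the noise scores; the
    #: default is the standard word2vec negative-sampling objective.
    loss: str = "negative_sampling"

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negatives < 0:
            raise ValueError("need dim >= 1, window >= 1, negatives >= 0")


class EmbeddingTable:
    """A vocabulary plus its V×D real vector table.

    ``context_vectors`` optionally carries the skip-gram output (context)
    table from the same training run; the projection trainer uses it for the
    context path when available.  It is not part of the word2vec text format
    and is dropped on save/load.
    """

    def __init__(
        self,
        vocabulary: Vocabulary,
        vectors: np.ndarray,
        context_vectors: np.ndarray | None = None,
    ):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(vocabulary):
            raise ValueError(
                f"vectors shape {vectors.shape} does not match vocabulary size {len(vocabulary)}"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding vectors must be finite")
        self.vocabulary = vocabulary
        self.vectors = vectors
        if context_vectors is not None:
            context_vectors = np.asarray(context_vectors, dtype=np.float64)
            if context_vectors.shape != vectors.shape:
                raise ValueError("context table must match the embedding table's shape")
        self.context_vectors = context_vectors

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        idx = self.vocabulary.get(token)
        if idx is None:
            raise KeyError(f"token {token!r} not in embedding vocabulary")
        return self.vectors[idx]


@dataclass
class ProjectionModel:
    """Frozen base embeddings plus the trainable D×D projection P.

    ``base`` is never modified by training; the trainable parameter count is
    exactly D² (2500 at the default D=50).
    """

    base: EmbeddingTable
    P: np.ndarray
    trained_on: str = ""

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        d = self.base.dim
        if self.P.shape != (d, d):
            raise ValueError(f"projection must be {d}x{d}, got {self.P.shape}")

    @classmethod
    def identity(cls, base: EmbeddingTable) -> "ProjectionModel":
        return cls(base, np.eye(base.dim))

    @property
    def n_parameters(self) -> int:
        return self.P.size


def generate_training_pairs(
    doc: TokenSequence, window: int, vocab: Vocabulary
) -> list[tuple[int, int]]:
    """Enumerate (center id, context id) skip-gram pairs from one document.

    Out-of-vocabulary tokens are skipped but keep their position, so they do
    not shrink the ±window span around their neighbours.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ids = [vocab.get(t) for t in doc]
    pairs: list[tuple[int, int]] = []
    n = len(ids)
    for t, center in enumerate(ids):
        if center is None:
            continue
        lo, hi = max(0, t - window), min(n, t + window + 1)
        for j in range(lo, hi):
            if j == t or ids[j] is None:
                continue
            pairs.append((center, ids[j]))
    return pairs


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def ns_loss(center_vec: np.ndarray, context_vec: np.ndarray, noise_vecs: np.ndarray) -> float:
    """Negative-sampling loss for one (center, context, noise set) triple.

    ``-ln σ(c·o) - Σ_i ln σ(-c·n_i)`` with σ the logistic function.
    """
    c = np.asarray(center_vec, dtype=np.float64)
    o = np.asarray(context_vec, dtype=np.float64)
    noise = np.asarray(noise_vecs, dtype=np.float64).reshape(-1, c.shape[0]) if np.size(noise_vecs) else np.zeros((0, c.shape[0]))
    if o.shape != c.shape:
        raise ValueError(f"dimension mismatch: center {c.shape} vs context {o.shape}")
    pos = -np.log(_sigmoid(c @ o))
    neg = -np.sum(np.log(_sigmoid(-(noise @ c)))) if noise.shape[0] else 0.0
    return float(pos + neg)


def _noise_distribution(counts: np.ndarray, power: float) -> np.ndarray:
    p = counts.astype(np.float64) ** power
    return p / p.sum()


def _corpus_pairs(docs: Iterable[TokenSequence], window: int, vocab: Vocabulary) -> np.ndarray:
    pairs: list[tuple[int, int]] = []
    for doc in docs:
        pairs.extend(generate_training_pairs(doc, window, vocab))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def _lr_schedule(lr0: float, step: int, total: int) -> float:
    # linear decay to (almost) zero over the run, word2vec-style
    return lr0 * max(1.0 - step / max(total, 1), 1e-4)


def train_skipgram(corpus: Corpus, config: SkipGramConfig) -> EmbeddingTable:
    """Train skip-gram embeddings with negative sampling; returns the input table.

    Both the input (embedding) and output (context) tables are trained; the
    input table is returned.  Deterministic given ``config.seed``.
    """
    vocab = build_vocab(corpus, config.min_count)
    rng = np.random.default_rng(config.seed)
    V, D = len(vocab), config.dim
    W_in = (rng.random((V, D)) - 0.5) / D
    W_out = np.zeros((V, D))
    pairs = _corpus_pairs(corpus, config.window, vocab)
    if pairs.shape[0] == 0:
        return EmbeddingTable(vocab, W_in)  # degenerate: no co-occurrence signal
    counts_vec = np.array([vocab.counts[t] for t in vocab.index_to_token], dtype=np.float64)
    noise_p = _noise_distribution(counts_vec, config.noise_power)
    log_noise = np.log(noise_p * max(config.negatives, 1)) if config.loss == "nce" else None

    m_in = np.zeros_like(W_in)
    m_out = np.zeros_like(W_out)
    B = config.batch_size
    n_batches = -(-pairs.shape[0] // B)
    total_steps = config.epochs * n_batches
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(pairs.shape[0])
        for b in range(n_batches):
            batch = pairs[order[b * B : (b + 1) * B]]
            c_ids, o_ids = batch[:, 0], batch[:, 1]
            n_ids = rng.choice(V, size=(batch.shape[0], config.negatives), p=noise_p)
            vc = W_in[c_ids]
            vo = W_out[o_ids]
            vn = W_out[n_ids]
            s_pos = np.einsum("bd,bd->b", vc, vo)
            s_neg = np.einsum("bd,bkd->bk", vc, vn)
            if config.loss == "nce":
                s_pos = s_pos - log_noise[o_ids]
                s_neg = s_neg - log_noise[n_ids]
            g_pos = _sigmoid(s_pos) - 1.0  # dL/ds for the positive term
            g_neg = _sigmoid(s_neg)  # dL/ds for each noise term
            grad_vc = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", g_neg, vn)
            grad_vo = g_pos[:, None] * vc
            grad_vn = g_neg[..., None] * vc[:, None, :]

            g_in = np.zeros_like(W_in)
            g_out = np.zeros_like(W_out)
            np.add.at(g_in, c_ids, grad_vc)
            np.add.at(g_out, o_ids, grad_vo)
            np.add.at(g_out, n_ids.ravel(), grad_vn.reshape(-1, D))
            scale = 1.0 / batch.shape[0]
            lr = _lr_schedule(config.learning_rate, step, total_steps)
            m_in = config.momentum * m_in - lr * scale * g_in
            m_out = config.momentum * m_out - lr * scale * g_out
            W_in += m_in
            W_out += m_out
            step += 1
    return EmbeddingTable(vocab, W_in, context_vectors=W_out)


def train_projection(
    base: EmbeddingTable, internal: Corpus, config: SkipGramConfig
) -> ProjectionModel:
    """Learn the D×D projection P on an internal corpus; ``base`` stays frozen.

    Skip-gram pairs drawn from the internal corpus (tokens absent from the
    base vocabulary are skipped) drive the negative-sampling loss computed on
    projected vectors: the center path uses the frozen base input table
    composed with P and the context path uses the frozen base context table
    (from the same skip-gram run, when available) composed with the same P.
    P starts at the identity, so zero epochs leave the materialized table
    equal to the base.
    """
    vocab = base.vocabulary
    pairs = _corpus_pairs(internal, config.window, vocab)
    internal_counts = np.zeros(len(vocab))
    for doc in internal:
        for tok in doc:
            idx = vocab.get(tok)
            if idx is not None:
                internal_counts[idx] += 1
    if internal_counts.sum() == 0:
        raise ValueError("internal corpus shares no tokens with the base vocabulary")

    D = base.dim
    P = np.eye(D)
    if pairs.shape[0] == 0 or config.epochs == 0:
        return ProjectionModel(base, P, trained_on=internal.source_id)

    rng = np.random.default_rng(config.seed)
    E = base.vectors  # frozen input table
    Ectx = base.context_vectors if base.context_vectors is not None else base.vectors
    present = np.flatnonzero(internal_counts)
    noise_p = _noise_distribution(internal_counts[present], config.noise_power)

    mP = np.zeros_like(P)
    B = config.batch_size
    n_batches = -(-pairs.shape[0] // B)
    total_steps = config.epochs * n_batches
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(pairs.shape[0])
        for b in range(n_batches):
            batch = pairs[order[b * B : (b + 1) * B]]
            nb = batch.shape[0]
            c_ids, o_ids = batch[:, 0], batch[:, 1]
            n_ids = present[rng.choice(present.size, size=(nb, config.negatives), p=noise_p)]
            Ec, Eo, En = E[c_ids], Ectx[o_ids], Ectx[n_ids]
            u = Ec @ P  # projected centers
            v = Eo @ P
            w = En @ P
            g_pos = _sigmoid(np.einsum("bd,bd->b", u, v)) - 1.0
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", u, w))
            # ds/dP for s=(eP)·(fP): e^T(fP) + f^T(eP)
            gradP = Ec.T @ (g_pos[:, None] * v) + Eo.T @ (g_pos[:, None] * u)
            w_flat = w.reshape(-1, D)
            En_flat = En.reshape(-1, D)
            gn = g_neg.ravel()[:, None]
            u_rep = np.repeat(u, config.negatives, axis=0) if config.negatives else u[:0]
            gradP += Ec.T @ np.einsum("bk,bkd->bd", g_neg, w) + En_flat.T @ (gn * u_rep)
            lr = _lr_schedule(config.learning_rate, step, total_steps)
            mP = config.momentum * mP - lr * (gradP / nb)
            P += mP
            step += 1
    return ProjectionModel(base, P, trained_on=internal.source_id)


def materialize(model: ProjectionModel) -> EmbeddingTable:
    """Apply P to every base vector; the vocabulary is shared unchanged."""
    return EmbeddingTable(model.base.vocabulary, model.base.vectors @ model.P)


def concat_embeddings(a: EmbeddingTable, b: EmbeddingTable) -> EmbeddingTable:
    """Concatenate two embedding spaces over their vocabulary intersection.

    The result has dimension ``a.dim + b.dim`` (100 for two 50-dimensional
    tables); words present in only one table are dropped, so concatenation
    cannot increase vocabulary coverage.
    """
    shared = sorted(
        set(a.vocabulary.token_to_index) & set(b.vocabulary.token_to_index),
        key=lambda t: (a.vocabulary[t], t),
    )
    if not shared:
        raise ValueError("embedding vocabularies do not intersect")
    counts = {t: a.vocabulary.counts.get(t, 1) for t in shared}
    vocab = Vocabulary({t: i for i, t in enumerate(shared)}, counts, min_count=1)
    vecs = np.hstack(
        [
            a.vectors[[a.vocabulary[t] for t in shared]],
            b.vectors[[b.vocabulary[t] for t in shared]],
        ]
    )
    return EmbeddingTable(vocab, vecs)


def save_table(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table in word2vec text format (gzip if ``.gz``)."""
    path = Path(path)
    lines = [f"{len(table)} {table.dim}"]
    for i, tok in enumerate(table.vocabulary.index_to_token):
        if any(ch.isspace() for ch in tok):
            raise ValueError(f"token {tok!r} contains whitespace; cannot be saved")
        lines.append(tok + " " + " ".join(f"{x:.6f}" for x in table.vectors[i]))
    data = ("\n".join(lines) + "\n").encode("utf-8")
    if path.suffix == ".gz":
        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        path.write_bytes(data)


def load_table(path: str | Path) -> EmbeddingTable:
    """Read a word2vec text format embedding file (gzip if ``.gz``)."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    else:
        lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    try:
        V, D = (int(x) for x in lines[0].split())
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed word2vec header") from exc
    if len(lines) - 1 != V:
        raise ValueError(f"{path}: header claims {V} rows but file has {len(lines) - 1}")
    tokens, vectors = [], np.empty((V, D))
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != D + 1:
            raise ValueError(f"{path}: row {i} has {len(parts) - 1} values, expected {D}")
        tokens.append(parts[0])
        vectors[i] = [float(x) for x in parts[1:]]
    vocab = Vocabulary({t: i for i, t in enumerate(tokens)}, {t: 1 for t in tokens}, 1)
    return EmbeddingTable(vocab, vectors)
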