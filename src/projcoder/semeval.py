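"""Intrinsic evaluation of embeddings against human similarity judgments.

Term pairs (possibly multi-word, e.g. "renal failure") are embedded as the
mean of their word vectors; out-of-vocabulary words are replaced by the
closest in-vocabulary word under Levenshtein distance before lookup.  Model
scores are cosine similarities, compared with the human judgments by Pearson
correlation.  A nearest-neighbour query supports qualitative inspection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
from scipy import stats

from .corpus import Vocabulary, tokenize
from .embedding import EmbeddingTable

__all__ = [
    "TermPair",
    "SimilarityDataset",
    "cosine",
    "oov_substitute",
    "term_vector",
    "score_dataset",
    "nearest_neighbors",
    "load_pairs",
]


@dataclass
class TermPair:
    term1: str
    term2: str
    human_score: float

    def __post_init__(self) -> None:
        if not self.term1.strip() or not self.term2.strip():
            raise ValueError("term pair has an empty term")


@dataclass
class SimilarityDataset:
    name: str
    pairs: list[TermPair]

    def __len__(self) -> int:
        return len(self.pairs)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u·v / (|u||v|); zero vectors are an error."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def oov_substitute(word: str, vocab: Vocabulary) -> str:
    """Map ``word`` to itself if in-vocabulary, else to the vocabulary token
    with minimal Levenshtein distance (ties broken lexicographically)."""
    if word in vocab:
        return word
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    best_tok, best_d = None, None
    for tok in sorted(vocab.token_to_index):
        d = _levenshtein(word, tok)
        if best_d is None or d < best_d:
            best_tok, best_d = tok, d
    return best_tok


def term_vector(term: str, table: EmbeddingTable) -> np.ndarray:
    """Mean vector of a (possibly multi-word) term after OOV substitution."""
    words = tokenize(term)
    if not words:
        raise ValueError(f"term {term!r} tokenizes to nothing")
    resolved = [oov_substitute(w, table.vocabulary) for w in words]
    return np.mean([table.vector(w) for w in resolved], axis=0)


def score_dataset(
    table: EmbeddingTable, dataset: SimilarityDataset
) -> tuple[list[float], float]:
    """Cosine score every pair and correlate with the human judgments.

    Returns (per-pair cosines, Pearson r).  Degenerate score lists (zero
    variance on either side) raise ``ValueError`` naming the flat side.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    model_scores = [
        cosine(term_vector(p.term1, table), term_vector(p.term2, table)) for p in dataset.pairs
    ]
    human = [p.human_score for p in dataset.pairs]
    if np.std(model_scores) == 0.0:
        raise ValueError("model cosines have zero variance")
    if np.std(human) == 0.0:
        raise ValueError("human scores have zero variance")
    r = float(stats.pearsonr(model_scores, human).statistic)
    return model_scores, r


def nearest_neighbors(word: str, table: EmbeddingTable, n: int = 5) -> list[str]:
    """Top-``n`` vocabulary tokens by cosine to ``word`` (itself excluded).

    The query is resolved through ``oov_substitute`` first; ties are broken
    lexicographically.
    """
    if n >= len(table):
        raise ValueError(f"n={n} must be smaller than the vocabulary size {len(table)}")
    query = oov_substitute(word, table.vocabulary)
    q = table.vector(query)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(table.vectors, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    sims = (table.vectors @ q) / (safe * (qn if qn else 1.0))
    sims[norms == 0.0] = -np.inf
    order = sorted(
        (i for i in range(len(table)) if table.vocabulary.index_to_token[i] != query),
        key=lambda i: (-sims[i], table.vocabulary.index_to_token[i]),
    )
    return [table.vocabulary.index_to_token[i] for i in order[:n]]


def load_pairs(path: str | Path, name: str | None = None) -> SimilarityDataset:
    """Load a 3-column delimited (term1, term2, score) file; header optional.

    Comma and tab delimiters are auto-detected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    pairs: list[TermPair] = []
    for row in csv.reader(text.splitlines(), delimiter=delim):
        if not row or len(row) < 3:
            continue
        try:
            score = float(row[2])
        except ValueError:
            continue  # header row
        pairs.append(TermPair(row[0].strip(), row[1].strip(), score))
    return SimilarityDataset(name or path.stem, pairs)
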