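"""Tokenization, vocabulary construction, and corpus / note I/O.

Corpora are plain UTF-8 text, one document per line.  Labeled discharge
notes are JSON lines, each ``{"text": ..., "codes": [...]}``; diagnostic
codes are accepted with or without dot-suffixes and are truncated to the
three-character category level on read.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TokenSequence",
    "Corpus",
    "Vocabulary",
    "tokenize",
    "build_vocab",
    "read_corpus",
    "write_corpus",
    "read_notes",
    "write_notes",
]

#: normalized word tokens, order preserved from the source text
TokenSequence = list[str]

_SPLIT = re.compile(r"[^0-9a-z]+")


@dataclass
class Corpus:
    """A list of tokenized documents with a free-text source label."""

    documents: list[TokenSequence]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


@dataclass
class Vocabulary:
    """Token → contiguous 0-based id bijection with occurrence counts.

    Ids are assigned by descending corpus frequency, ties broken
    lexicographically, so builds are deterministic across platforms.
    """

    token_to_index: dict[str, int]
    counts: dict[str, int]
    min_count: int = 1
    index_to_token: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index_to_token = [""] * len(self.token_to_index)
        for tok, i in self.token_to_index.items():
            self.index_to_token[i] = tok

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def __getitem__(self, token: str) -> int:
        return self.token_to_index[token]

    def get(self, token: str, default: int | None = None) -> int | None:
        return self.token_to_index.get(token, default)

    def tokens(self) -> list[str]:
        return list(self.index_to_token)


def tokenize(text: str) -> TokenSequence:
    """Lowercase and split ``text`` on runs of non-alphanumeric characters.

    Pure-digit tokens are kept; empty fragments are dropped.  Deterministic,
    whitespace- and case-insensitive.
    """
    return [t for t in _SPLIT.split(text.lower()) if t]


def build_vocab(corpus: Corpus | Iterable[TokenSequence], min_count: int = 1) -> Vocabulary:
    """Build the vocabulary of tokens whose corpus-wide count >= ``min_count``.

    Raises ``ValueError`` if no token survives the threshold.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(doc)
    kept = {t: c for t, c in counts.items() if c >= min_count}
    if not kept:
        raise ValueError(
            f"no token reaches min_count={min_count} (corpus has {len(counts)} distinct tokens)"
        )
    ordered = sorted(kept, key=lambda t: (-kept[t], t))
    return Vocabulary({t: i for i, t in enumerate(ordered)}, kept, min_count)


def read_corpus(path: str | Path, source_id: str | None = None) -> Corpus:
    """Read a one-document-per-line plain-text corpus."""
    path = Path(path)
    docs = [tokenize(line) for line in path.read_text(encoding="utf-8").splitlines()]
    return Corpus(docs, source_id if source_id is not None else path.name)


def write_corpus(corpus: Iterable[Sequence[str]], path: str | Path) -> None:
    docs = corpus.documents if isinstance(corpus, Corpus) else list(corpus)
    Path(path).write_text("\n".join(" ".join(doc) for doc in docs) + "\n", encoding="utf-8")


def read_notes(path: str | Path, keep_excluded: bool = False):
    """Read labeled discharge notes from a JSON-lines file.

    Each line is ``{"text": str, "codes": [str, ...]}``.  Codes are parsed
    and truncated to three characters; codes in the excluded external-causes
    chapter are dropped unless ``keep_excluded``.  A malformed line raises
    ``ValueError`` naming its 1-based line number.
    """
    from .icd import DischargeNote, parse_icd

    notes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                text = rec["text"]
                raw_codes = rec["codes"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed notes line {lineno}: {exc}") from exc
            codes = set()
            for raw in raw_codes:
                code = parse_icd(raw)
                if code.excluded and not keep_excluded:
                    continue
                codes.add(code)
            notes.append(DischargeNote(tokenize(text), codes))
    return notes


def write_notes(notes, path: str | Path) -> None:
    """Write notes as JSON lines in the format ``read_notes`` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            rec = {"text": " ".join(note.tokens), "codes": sorted(c.code for c in note.codes)}
            fh.write(json.dumps(rec) + "\n")
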