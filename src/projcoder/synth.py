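"""Seeded synthetic corpora and labeled discharge notes.

These generators emulate the statistical structure the methods assume, so
every pipeline stage is exercisable without any external download:

* topic-structured corpora (documents drawn from disjoint topic
  vocabularies mixed with background words) for skip-gram sanity checks;
* paired external/internal corpora with a planted synonym pair — the two
  words never co-occur in the external corpus but are interchangeable in
  identical internal contexts — plus a control pair receiving no internal
  signal, for testing projection adaptation;
* keyword-driven multi-label notes with disjoint keyword→code mappings and
  anti-correlated code pairs that never co-occur (mirroring the cancer /
  pregnancy anti-correlation in real discharge data).

Every generator is fully determined by its seed and returns a manifest
sufficient to verify its planted structure without re-inspecting internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Corpus
from .icd import DischargeNote, ICDCode, parse_icd

__all__ = [
    "TopicSpec",
    "CodeKeywordMap",
    "gen_corpus",
    "gen_synonym_pair_corpora",
    "gen_notes",
    "default_topic_specs",
    "default_code_keyword_map",
]


@dataclass
class TopicSpec:
    """One topic: its private vocabulary, shared background, and mixing rate."""

    topic_id: str
    topic_vocab: list[str]
    background_vocab: list[str]
    mixing: float = 0.8  # probability a token is topical


@dataclass
class CodeKeywordMap:
    """Keyword lists per code, forbidden code pairs, and a noise rate.

    Keyword lists are pairwise disjoint by default so per-code recovery has
    a known ceiling of 1.  ``noise_rate`` is the probability a token is a
    background word instead of a keyword (default 0: the keyword→code
    mapping is deterministic and noiseless).
    """

    keywords: dict[str, list[str]]
    anti_pairs: list[tuple[str, str]] = field(default_factory=list)
    noise_rate: float = 0.0
    background_vocab: list[str] = field(default_factory=list)
    #: ward-vocabulary bias: probability that a noise token is drawn from the
    #: background words "homed" at the note's own chapter (background words
    #: are assigned home chapters round-robin).  Emulates ward- or
    #: department-specific phrasing, the source of spuriously negative terms.
    ward_bias: float = 0.0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for code, kws in self.keywords.items():
            overlap = seen & set(kws)
            if overlap:
                raise ValueError(f"keyword lists not disjoint: {sorted(overlap)}")
            seen |= set(kws)
        for a, b in self.anti_pairs:
            if a not in self.keywords or b not in self.keywords:
                raise ValueError(f"anti-pair ({a},{b}) names an unknown code")
        if self.noise_rate > 0 and not self.background_vocab:
            raise ValueError("noise_rate > 0 requires a background vocabulary")

    @property
    def codes(self) -> list[str]:
        return sorted(self.keywords)


def default_topic_specs(
    n_topics: int = 2, vocab_per_topic: int = 30, n_background: int = 20, mixing: float = 0.8
) -> list[TopicSpec]:
    background = [f"bg{i}" for i in range(n_background)]
    return [
        TopicSpec(
            f"topic{t}",
            [f"t{t}w{i}" for i in range(vocab_per_topic)],
            background,
            mixing,
        )
        for t in range(n_topics)
    ]


def gen_corpus(
    specs: Sequence[TopicSpec],
    n_docs: int = 200,
    doc_len: tuple[int, int] = (30, 80),
    seed: int = 0,
) -> tuple[Corpus, dict]:
    """Draw each document from one topic; the manifest records assignments."""
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    for s in specs:
        if not s.topic_vocab:
            raise ValueError(f"topic {s.topic_id} has an empty vocabulary")
    rng = np.random.default_rng(seed)
    docs, assignment = [], []
    for _ in range(n_docs):
        t = int(rng.integers(len(specs)))
        spec = specs[t]
        length = int(rng.integers(doc_len[0], doc_len[1] + 1))
        doc = []
        for _ in range(length):
            if spec.background_vocab and rng.random() >= spec.mixing:
                doc.append(spec.background_vocab[rng.integers(len(spec.background_vocab))])
            else:
                doc.append(spec.topic_vocab[rng.integers(len(spec.topic_vocab))])
        docs.append(doc)
        assignment.append(spec.topic_id)
    manifest = {
        "seed": seed,
        "doc_topics": assignment,
        "topics": {s.topic_id: s.topic_vocab for s in specs},
        "mixing": {s.topic_id: s.mixing for s in specs},
    }
    return Corpus(docs, source_id=f"synthetic-topics-seed{seed}"), manifest


def gen_synonym_pair_corpora(
    seed: int = 0,
    n_context: int = 10,
    n_fillers: int = 40,
    sentences_per_word: int = 40,
    sentence_len: int = 9,
    n_templates: int = 60,
) -> tuple[Corpus, Corpus, tuple[str, str], tuple[str, str]]:
    """External/internal corpus pair with a planted synonym pair.

    In the external corpus the planted pair (x, y) never share a document —
    x lives among context group A, y among context group B — so a skip-gram
    model trained on it keeps them apart.  The internal corpus presents x
    and y in identical contexts (every context sentence appears once with x
    and once with y), the signal a projection should exploit.  The control
    pair (u, v) is equally separated externally and absent from the internal
    corpus.
    """
    rng = np.random.default_rng(seed)
    ctx_a = [f"ca{i}" for i in range(n_context)]
    ctx_b = [f"cb{i}" for i in range(n_context)]
    ctx_u = [f"cu{i}" for i in range(n_context // 2)]
    ctx_v = [f"cv{i}" for i in range(n_context // 2)]
    fillers = [f"fl{i}" for i in range(n_fillers)]

    def sentences(word: str, ctx: list[str]) -> list[list[str]]:
        out = []
        for _ in range(sentences_per_word):
            words = [
                ctx[rng.integers(len(ctx))]
                if rng.random() < 0.6
                else fillers[rng.integers(len(fillers))]
                for _ in range(sentence_len - 1)
            ]
            pos = int(rng.integers(sentence_len))
            words.insert(pos, word)
            out.append(words)
        return out

    external_docs = (
        sentences("synx", ctx_a)
        + sentences("syny", ctx_b)
        + sentences("ctlu", ctx_u)
        + sentences("ctlv", ctx_v)
    )
    # filler-only documents keep the background vocabulary well sampled
    for _ in range(sentences_per_word):
        external_docs.append([fillers[rng.integers(n_fillers)] for _ in range(sentence_len)])
    order = rng.permutation(len(external_docs))
    external = Corpus([external_docs[i] for i in order], source_id=f"synthetic-external-seed{seed}")

    internal_docs = []
    mixed = ctx_a + ctx_b
    for _ in range(n_templates):
        left = mixed[rng.integers(len(mixed))]
        right = mixed[rng.integers(len(mixed))]
        template = [left, "{w}", right, fillers[rng.integers(n_fillers)]]
        for w in ("synx", "syny"):
            internal_docs.append([t if t != "{w}" else w for t in template])
    internal = Corpus(internal_docs, source_id=f"synthetic-internal-seed{seed}")
    return external, internal, ("synx", "syny"), ("ctlu", "ctlv")


def default_code_keyword_map(
    n_codes: int = 20, keywords_per_code: int = 4, n_background: int = 60, noise_rate: float = 0.0
) -> CodeKeywordMap:
    """Twenty three-character codes over five chapters with disjoint keywords.

    Every cancer-chapter code is anti-paired with every pregnancy-chapter
    code, mirroring the cancer/pregnancy anti-correlation of real discharge
    data.
    """
    inventory = [
        "C17", "C18", "C50", "C53", "C61",
        "I10", "I21", "I25", "I50", "I63",
        "J15", "J18", "J44", "J45", "J96",
        "K29", "K85", "K91",
        "O34", "O60", "O80",
        "N17", "N18", "N39",
    ]
    codes = inventory[:n_codes] if n_codes <= len(inventory) else inventory
    keywords = {
        code: [f"{code.lower()}kw{i}" for i in range(keywords_per_code)] for code in codes
    }
    anti = [
        (a, b)
        for a in codes
        if a.startswith("C")
        for b in codes
        if b.startswith("O")
    ]
    background = [f"note{i}" for i in range(n_background)]
    return CodeKeywordMap(keywords, anti, noise_rate, background)


def _conflicts(code: str, chosen: list[str], anti: set[frozenset]) -> bool:
    return any(frozenset((code, c)) in anti for c in chosen)


def gen_notes(
    cmap: CodeKeywordMap,
    n: int = 2000,
    len_range: tuple[int, int] = (30, 80),
    seed: int = 0,
) -> tuple[list[DischargeNote], dict]:
    """Generate keyword-driven multi-label notes honouring the anti-pairs.

    Each note carries 1–3 codes (never a forbidden pair); its tokens are the
    assigned codes' keywords plus background noise at ``cmap.noise_rate``.
    Each assigned code contributes at least one keyword.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    codes = cmap.codes
    if not codes:
        raise ValueError("code-keyword map is empty")
    anti = {frozenset(p) for p in cmap.anti_pairs}
    if any(len(p) < 2 for p in anti):
        raise ValueError("anti_pairs must name two distinct codes")
    rng = np.random.default_rng(seed)
    notes, labels, wards = [], [], []
    parsed = {c: parse_icd(c) for c in codes}
    chapters = sorted({parsed[c].chapter for c in codes})
    bg_home = {
        w: chapters[i % len(chapters)] for i, w in enumerate(cmap.background_vocab)
    }
    bg_by_chapter = {
        ch: [w for w in cmap.background_vocab if bg_home[w] == ch] for ch in chapters
    }
    for _ in range(n):
        k = int(rng.integers(1, 4))
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < k and attempts < 100:
            c = codes[rng.integers(len(codes))]
            attempts += 1
            if c in chosen or _conflicts(c, chosen, anti):
                continue
            chosen.append(c)
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        tokens: list[str] = []
        for c in chosen:  # guarantee every label is evidenced
            kws = cmap.keywords[c]
            tokens.append(kws[rng.integers(len(kws))])
        ward = parsed[chosen[0]].chapter  # the note's "ward": first code drawn
        home = bg_by_chapter.get(ward) or cmap.background_vocab
        while len(tokens) < length:
            if cmap.background_vocab and rng.random() < cmap.noise_rate:
                pool = home if rng.random() < cmap.ward_bias else cmap.background_vocab
                tokens.append(pool[rng.integers(len(pool))])
            else:
                c = chosen[rng.integers(len(chosen))]
                kws = cmap.keywords[c]
                tokens.append(kws[rng.integers(len(kws))])
        rng.shuffle(tokens)
        notes.append(DischargeNote(tokens, {parsed[c] for c in chosen}))
        labels.append(sorted(chosen))
        wards.append(ward)
    manifest = {
        "seed": seed,
        "labels": labels,
        "wards": wards,
        "keywords": cmap.keywords,
        "anti_pairs": [list(p) for p in cmap.anti_pairs],
        "noise_rate": cmap.noise_rate,
        "ward_bias": cmap.ward_bias,
        "background_home": bg_home,
    }
    return notes, manifest
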