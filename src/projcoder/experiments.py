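"""Reproducibility harness: the package's standard synthetic experiments.

Each function sets up a seeded synthetic study, runs the relevant pipeline
stage end to end, and returns plain numbers.  The same routines back the
test suite and ``scripts/acceptance.py``, so the reported quantities are
always recomputed from scratch.

Problem sizes are desk-scale: skip-gram fixtures use dimension 16, window 5
and min_count 1 (the full-scale defaults of dimension 50 / window 12 /
min_count 20 apply to real corpora); the coder-recovery study uses 2000
keyword-driven notes with 20 codes; the hybrid-sampling study uses a
scaled-down generator (500 notes, 6 codes in two anti-correlated chapters).
"""

from __future__ import annotations

import numpy as np

from .coder import (
    CoderConfig,
    conv_parameter_count,
    predict,
    train_coder,
    word_score_matrix,
)
from .corpus import Corpus, Vocabulary, build_vocab
from .embedding import (
    EmbeddingTable,
    ProjectionModel,
    SkipGramConfig,
    concat_embeddings,
    materialize,
    train_projection,
    train_skipgram,
)
from .metrics import macro_f, prf
from .semeval import cosine
from .synth import (
    CodeKeywordMap,
    default_code_keyword_map,
    default_topic_specs,
    gen_corpus,
    gen_notes,
    gen_synonym_pair_corpora,
)

__all__ = [
    "make_random_table",
    "projection_parameter_count",
    "identity_projection_error",
    "vocabulary_preservation",
    "projection_recovery",
    "topic_separation",
    "coder_recovery",
    "hybrid_sampling_effect",
    "concat_baseline_shape",
]

#: fixture-scale skip-gram settings (full-scale defaults are 50/12/20);
#: 20 epochs at batch 64 are needed for the small corpora to leave the
#: near-isotropic initialization and develop real co-occurrence geometry
_SG_FIXTURE = dict(dim=16, window=5, negatives=5, min_count=1, epochs=20, batch_size=64)


def make_random_table(tokens: list[str], dim: int, seed: int) -> EmbeddingTable:
    """A deterministic random embedding table over the given tokens."""
    vocab = Vocabulary({t: i for i, t in enumerate(tokens)}, {t: 1 for t in tokens}, 1)
    rng = np.random.default_rng(seed)
    vecs = rng.normal(size=(len(tokens), dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return EmbeddingTable(vocab, vecs)


def projection_parameter_count(dim: int = 50) -> int:
    """Trainable parameters of the projection stage at embedding dim ``dim``."""
    base = make_random_table([f"w{i}" for i in range(4)], dim, seed=0)
    return ProjectionModel.identity(base).n_parameters


def identity_projection_error(seed: int = 0, n_tokens: int = 40, dim: int = 16) -> dict:
    """Element-wise and pairwise-cosine deviation of the identity projection."""
    base = make_random_table([f"w{i}" for i in range(n_tokens)], dim, seed)
    mat = materialize(ProjectionModel.identity(base))
    elem = float(np.max(np.abs(mat.vectors - base.vectors)))
    cos_err = 0.0
    for i in range(n_tokens):
        for j in range(i + 1, n_tokens):
            cos_err = max(
                cos_err,
                abs(cosine(mat.vectors[i], mat.vectors[j]) - cosine(base.vectors[i], base.vectors[j])),
            )
    return {"max_elementwise_diff": elem, "max_cosine_diff": cos_err}


def vocabulary_preservation(seed: int = 0) -> dict:
    """Train a projection on an internal corpus and compare vocabularies."""
    external, internal, _, _ = gen_synonym_pair_corpora(seed)
    cfg = SkipGramConfig(seed=seed, **_SG_FIXTURE)
    base = train_skipgram(external, cfg)
    model = train_projection(base, internal, SkipGramConfig(seed=seed + 1, **{**_SG_FIXTURE, "epochs": 2}))
    mat = materialize(model)
    same = mat.vocabulary.token_to_index == base.vocabulary.token_to_index
    return {"base_vocab": len(base), "materialized_vocab": len(mat), "identical": bool(same)}


def projection_recovery(seeds: list[int]) -> dict:
    """Planted-synonym recovery: does projection pull the pair together?

    For each seed: train skip-gram on the external corpus (where the planted
    pair never co-occur), then the projection on the internal corpus (where
    they share identical contexts).  Success means the planted pair's cosine
    rises and rises more than the control pair's.
    """
    results = []
    for seed in seeds:
        external, internal, planted, control = gen_synonym_pair_corpora(seed)
        cfg = SkipGramConfig(seed=seed, **_SG_FIXTURE)
        base = train_skipgram(external, cfg)
        proj_cfg = SkipGramConfig(seed=seed + 1, **{**_SG_FIXTURE, "epochs": 5})
        model = train_projection(base, internal, proj_cfg)
        mat = materialize(model)

        def pair_cos(table: EmbeddingTable, pair: tuple[str, str]) -> float:
            return cosine(table.vector(pair[0]), table.vector(pair[1]))

        gain_planted = pair_cos(mat, planted) - pair_cos(base, planted)
        gain_control = pair_cos(mat, control) - pair_cos(base, control)
        results.append(
            {
                "seed": seed,
                "gain_planted": gain_planted,
                "gain_control": gain_control,
                "success": bool(gain_planted > 0 and gain_planted > gain_control),
            }
        )
    frac = sum(r["success"] for r in results) / len(results)
    return {"per_seed": results, "success_fraction": frac}


def topic_separation(seeds: list[int]) -> dict:
    """Skip-gram sanity: within-topic cosines should beat between-topic ones."""
    results = []
    for seed in seeds:
        specs = default_topic_specs(n_topics=2, mixing=0.9)
        corpus, manifest = gen_corpus(specs, n_docs=200, doc_len=(20, 40), seed=seed)
        table = train_skipgram(corpus, SkipGramConfig(seed=seed, **_SG_FIXTURE))
        by_topic = {
            tid: [w for w in vocab_words if w in table]
            for tid, vocab_words in manifest["topics"].items()
        }
        (ta, wa), (tb, wb) = sorted(by_topic.items())
        within, between = [], []
        for group in (wa, wb):
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    within.append(cosine(table.vector(group[i]), table.vector(group[j])))
        for u in wa:
            for v in wb:
                between.append(cosine(table.vector(u), table.vector(v)))
        results.append(
            {
                "seed": seed,
                "within": float(np.mean(within)),
                "between": float(np.mean(between)),
                "success": bool(np.mean(within) > np.mean(between)),
            }
        )
    frac = sum(r["success"] for r in results) / len(results)
    return {"per_seed": results, "success_fraction": frac}


def _notes_vocab(notes) -> list[str]:
    toks = sorted({t for n in notes for t in n.tokens})
    return toks


def coder_recovery(seed: int = 0, n_train: int = 2000, n_valid: int = 500) -> dict:
    """Train the CNN coder on keyword-driven notes and measure recovery.

    20 codes over 5 chapters, deterministic noiseless keyword→code mapping,
    one 32-dimensional random embedding channel, filter counts
    (48, 36, 18, 12, 6) — the full-scale counts divided by 50.
    """
    cmap = default_code_keyword_map()
    train, _ = gen_notes(cmap, n=n_train, len_range=(30, 80), seed=seed)
    valid, _ = gen_notes(cmap, n=n_valid, len_range=(30, 80), seed=seed + 10_000)
    table = make_random_table(_notes_vocab(train + valid), dim=32, seed=seed + 1)
    config = CoderConfig(
        channels=[table],
        filter_counts=(48, 36, 18, 12, 6),
        max_len=80,
        max_epochs=12,
        seed=seed,
    )
    model = train_coder(train, valid, config)
    preds = [predict(model, n)[0] for n in valid]
    truths = [n.codes for n in valid]
    codes = sorted({c for n in train for c in n.codes})
    records = [prf(preds, truths, c) for c in codes]
    mp, mr, mf = macro_f(records, set(codes))
    train_freq = {c: sum(1 for n in train if c in n.codes) for c in codes}
    well_supported = [r.f_measure for r in records if train_freq[r.code] >= 50]
    return {
        "macro_precision": mp,
        "macro_recall": mr,
        "macro_f": mf,
        "min_f_well_supported": min(well_supported) if well_supported else float("nan"),
        "n_codes": len(codes),
        "n_train": len(train),
        "per_code_f": {r.code.code: r.f_measure for r in records},
    }


def hybrid_sampling_effect(seeds: list[int], n_notes: int = 500) -> dict:
    """Mirror of the single-word score diagnostic, scaled down.

    Two anti-correlated chapters (cancer-like C codes vs pregnancy-like O
    codes, never co-occurring) with ward-biased background vocabulary: the
    anti-correlation extends beyond the code keywords to the everyday words
    of each "ward", which is exactly what tempts a classifier into learning
    negative terms.  For each seed the coder is trained twice — with and
    without hybrid sampling (every training sample pasted, union labels) —
    and the whole note vocabulary is scored word by word (pre-logistic
    output for a one-token input; chapter score = max over the chapter's
    codes).  Success for a seed means the fraction of words with positive
    chapter score is strictly higher with hybrid sampling for both affected
    chapters, and the cross-chapter keywords' mean score is strictly less
    negative under hybrid sampling.  Training uses 4 epochs — long enough
    for both models to classify well, short of the heavily overfit margins
    that blur word-level contrasts on a small separable task.
    """
    c_codes, o_codes = ("C17", "C18", "C50"), ("O34", "O60", "O80")
    cmap = CodeKeywordMap(
        {c: [f"{c.lower()}kw{i}" for i in range(4)] for c in c_codes + o_codes},
        anti_pairs=[(a, b) for a in c_codes for b in o_codes],
        noise_rate=0.4,
        background_vocab=[f"note{i}" for i in range(60)],
        ward_bias=0.8,
    )
    results = []
    for seed in seeds:
        train, _ = gen_notes(cmap, n=n_notes, len_range=(10, 25), seed=seed)
        valid, _ = gen_notes(cmap, n=150, len_range=(10, 25), seed=seed + 10_000)
        vocab = _notes_vocab(train + valid)
        table = make_random_table(vocab, dim=16, seed=seed + 1)
        base_cfg = dict(
            channels=[table],
            filter_counts=(64, 48, 24, 16, 8),
            max_len=60,
            max_epochs=4,
            seed=seed,
        )
        plain = train_coder(train, valid, CoderConfig(**base_cfg))
        hybrid = train_coder(
            train, valid, CoderConfig(hybrid_sampling=True, hybrid_prob=1.0, **base_cfg)
        )
        per_chapter = {}
        means = {}
        for name, model in (("plain", plain), ("hybrid", hybrid)):
            codes, scores = word_score_matrix(model, vocab)
            chapters = sorted({c.chapter for c in codes})
            ch_scores = {
                ch: scores[:, [i for i, c in enumerate(codes) if c.chapter == ch]].max(axis=1)
                for ch in chapters
            }
            per_chapter[name] = {ch: float(np.mean(s > 0)) for ch, s in ch_scores.items()}
            # cross-chapter keywords: O-code keywords scored against the C
            # chapter and vice versa (the would-be "negative terms")
            cross = []
            for ch, s in ch_scores.items():
                foreign = [
                    i
                    for i, w in enumerate(vocab)
                    if any(
                        w in cmap.keywords[c]
                        for c in cmap.keywords
                        if (c[0] == "O") == (ch.startswith("C"))
                    )
                ]
                cross.extend(s[foreign].tolist())
            means[name] = float(np.mean(cross))
        fractions_ok = all(
            per_chapter["hybrid"][ch] > per_chapter["plain"][ch] for ch in per_chapter["plain"]
        )
        cross_ok = means["hybrid"] > means["plain"]
        results.append(
            {
                "seed": seed,
                "positive_fraction": per_chapter,
                "cross_keyword_mean": means,
                "success": bool(fractions_ok and cross_ok),
            }
        )
    frac = sum(r["success"] for r in results) / len(results)
    return {"per_seed": results, "success_fraction": frac}


def concat_baseline_shape(seed: int = 0, dim: int = 50) -> dict:
    """Dimension and vocabulary behaviour of the concatenation baseline."""
    shared = [f"s{i}" for i in range(20)]
    a = make_random_table(shared + ["onlya"], dim, seed)
    b = make_random_table(shared + ["onlyb"], dim, seed + 1)
    cat = concat_embeddings(a, b)
    return {
        "dim": cat.dim,
        "vocab_size": len(cat),
        "intersection_size": len(shared),
        "only_in_one_dropped": bool("onlya" not in cat and "onlyb" not in cat),
    }
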