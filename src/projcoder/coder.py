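"""Hierarchical multi-channel CNN for three-character ICD-10-CM coding.

Architecture, per chapter ("level-1 category"): each embedding channel turns
the n-token note into a D×n grid; convolutions of widths 1–5 (spanning the
full vector depth, K₁..K₅ filters) are globally max-pooled per filter; the
pooled features of all channels are concatenated and fed to an affine output
layer with one logistic unit per three-character code in the chapter.  Code
probabilities are then max-pooled up the ICD hierarchy: two-character group
probability = max over member codes, chapter probability = max over groups.

Multi-channel models divide each Kᵢ by the number of channels so the
convolution stage keeps the same total parameter count as the one-channel
model.

Training is SGD with Nesterov momentum, inverse-code-frequency weighted
binary cross-entropy (the oversampling surrogate for rare codes), and a
plateau schedule that divides the learning rate by 10 up to three times.

Hybrid sampling is the augmentation for positive-only clinical text: a
training note is concatenated with a random note sharing none of its codes,
and the pasted note is labeled with the union of both code sets.  Because
the paste makes "foreign" disease terms appear inside positive examples, the
classifier cannot profit from treating them as negative evidence — mirroring
how a human coder only looks for positive mentions.

The single-word score diagnostic reports, for a one-token input, the last
fully connected output before the logistic transformation; a score above 0
means the model assigns that word alone a probability above 50%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Vocabulary
from .embedding import EmbeddingTable
from .icd import DischargeNote, ICDCode, ICDHierarchy, build_hierarchy, parse_icd

__all__ = [
    "CoderConfig",
    "CoderModel",
    "parse_icd",
    "encode_note",
    "forward",
    "forward_logits",
    "hierarchical_pool",
    "hybrid_sample",
    "choose_negative",
    "weighted_loss",
    "train_coder",
    "predict",
    "word_score",
    "word_score_matrix",
    "conv_parameter_count",
    "save_model",
    "load_model",
]

_WIDTHS = (1, 2, 3, 4, 5)


@dataclass
class CoderConfig:
    """Classifier hyperparameters.

    ``filter_counts`` are the one-channel reference counts K₁..K₅ (full-scale
    default 2400/1800/900/600/300); multi-channel models use
    ``filter_counts[i] // n_channels`` per channel so total convolution
    parameters match the one-channel model.  Optimizer defaults: SGD, initial
    learning rate 0.05, batch size 32, Nesterov momentum 0.9 without
    dampening, weight decay 1e-4, learning rate divided by 10 on validation
    plateau at most three times.
    """

    channels: list[EmbeddingTable] = field(default_factory=list)
    filter_counts: tuple[int, int, int, int, int] = (2400, 1800, 900, 600, 300)
    max_len: int = 512
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_drops: int = 3
    lr_drop_factor: float = 10.0
    plateau_tol: float = 1e-4
    max_epochs: int = 30
    prob_threshold: float = 0.5
    hybrid_sampling: bool = False
    hybrid_prob: float = 0.5
    #: "union" labels the pasted sample with both notes' codes (both texts
    #: really are present); "positive" keeps only the positive note's codes,
    #: so the pasted foreign text acts as label noise.
    hybrid_labels: str = "union"
    oversample_duplicate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filter_counts) != len(_WIDTHS):
            raise ValueError("filter_counts must give K1..K5")
        if self.channels and any(
            k // len(self.channels) < 1 for k in self.filter_counts
        ):
            raise ValueError("filter_counts too small to split across channels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def per_channel_counts(self) -> tuple[int, ...]:
        n = max(self.n_channels, 1)
        return tuple(k // n for k in self.filter_counts)

    @property
    def k_total(self) -> int:
        return sum(self.per_channel_counts) * max(self.n_channels, 1)


class _ChapterNet:
    """Parameters of one chapter classifier.

    Convolutions carry no bias: an all-zero input therefore produces
    all-zero pooled features, so the output reduces to the logistic of the
    output-layer bias.
    """

    def __init__(self, config: CoderConfig, n_codes: int, rng: np.random.Generator):
        self.W: dict[tuple[int, int], np.ndarray] = {}
        counts = config.per_channel_counts
        feat = 0
        for c, table in enumerate(config.channels):
            D = table.dim
            for w, K in zip(_WIDTHS, counts):
                fan_in = w * D
                self.W[(c, w)] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(K, fan_in))
                feat += K
        self.U = rng.normal(0.0, 1.0 / np.sqrt(feat), size=(n_codes, feat))
        self.c = np.zeros(n_codes)

    def params(self):
        for key in sorted(self.W):
            yield self.W[key]
        yield self.U
        yield self.c


@dataclass
class CoderModel:
    """Per-chapter classifiers over a concrete code hierarchy."""

    nets: dict[str, _ChapterNet]
    hierarchy: ICDHierarchy
    config: CoderConfig
    code_weights: dict[str, np.ndarray]  # chapter -> per-code loss weights

    @property
    def chapters(self) -> list[str]:
        return sorted(self.nets)

    @property
    def all_codes(self) -> list[ICDCode]:
        return [c for ch in self.chapters for c in self.hierarchy.chapters[ch]]


def _channel_ids(tokens: Sequence[str], vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Map tokens to embedding rows, -1 for unknown/padding, truncating the tail."""
    ids = np.full(max_len, -1, dtype=np.int64)
    for i, tok in enumerate(tokens[:max_len]):
        idx = vocab.get(tok)
        if idx is not None:
            ids[i] = idx
    return ids


def encode_note(note: DischargeNote, config: CoderConfig) -> list[np.ndarray]:
    """Embed a note as one D×max_len grid per channel.

    Tokens beyond ``max_len`` are truncated; short notes are zero-padded;
    unknown tokens map to the zero vector.
    """
    if not note.tokens:
        raise ValueError("cannot encode a note with no tokens")
    grids = []
    for table in config.channels:
        ids = _channel_ids(note.tokens, table.vocabulary, config.max_len)
        E_pad = np.vstack([table.vectors, np.zeros((1, table.dim))])
        grids.append(E_pad[ids].T.copy())  # D x n
    return grids


def _windows(X: np.ndarray, w: int) -> np.ndarray:
    """(B, n, D) -> (B, n-w+1, w*D) sliding windows along the token axis."""
    B, n, D = X.shape
    return np.concatenate([X[:, i : n - w + 1 + i, :] for i in range(w)], axis=2)


def _lengths(Xs: list[np.ndarray]) -> np.ndarray:
    """True token count per sample: trailing all-zero columns are padding."""
    nonzero = np.zeros(Xs[0].shape[:2], dtype=bool)
    for X in Xs:
        nonzero |= np.any(X != 0.0, axis=2)
    n = nonzero.shape[1]
    lengths = n - np.argmax(nonzero[:, ::-1], axis=1)
    lengths[~nonzero.any(axis=1)] = 1  # fully unknown note: keep one window
    return lengths


def _forward_chapter(net: _ChapterNet, Xs: list[np.ndarray], need_cache: bool = False):
    """Batch forward for one chapter.  Xs: per channel (B, n, D).

    The global max runs only over windows containing at least one real
    token, so zero padding never contributes features.
    """
    lengths = _lengths(Xs)
    feats, cache = [], []
    for c, X in enumerate(Xs):
        for w in _WIDTHS:
            Xw = _windows(X, w)
            F = Xw @ net.W[(c, w)].T  # (B, P, K)
            P = F.shape[1]
            invalid = np.arange(P)[None, :] >= np.maximum(lengths, 1)[:, None]
            invalid[:, 0] = False  # always keep the first window
            F = np.where(invalid[:, :, None], -np.inf, F)
            arg = F.argmax(axis=1)
            pooled = np.take_along_axis(F, arg[:, None, :], axis=1)[:, 0, :]
            feats.append(pooled)
            if need_cache:
                cache.append((c, w, Xw, arg))
    feat = np.concatenate(feats, axis=1)
    logits = feat @ net.U.T + net.c
    return logits, feat, cache


def forward_logits(model: CoderModel, grids: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Pre-logistic outputs per chapter for one note's D×n grids."""
    Xs = [g.T[None, :, :] for g in grids]  # (1, n, D)
    out = {}
    for ch in model.chapters:
        logits, _, _ = _forward_chapter(model.nets[ch], Xs)
        out[ch] = logits[0]
    return out


def forward(model: CoderModel, grids: list[np.ndarray]) -> dict[ICDCode, float]:
    """Three-character code probabilities for one note's D×n grids."""
    probs: dict[ICDCode, float] = {}
    for ch, logits in forward_logits(model, grids).items():
        for code in model.hierarchy.chapters[ch]:
            probs[code] = float(_sigmoid(logits[model.hierarchy.code_index[code]]))
    return probs


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def hierarchical_pool(
    three_char_probs: dict[ICDCode, float], hierarchy: ICDHierarchy
) -> tuple[dict[str, float], dict[str, float]]:
    """Max-pool code probabilities to two-character groups, then chapters."""
    for code in three_char_probs:
        if code not in hierarchy.code_index:
            raise KeyError(f"code {code} missing from hierarchy")
    two_char: dict[str, float] = {}
    for prefix, members in hierarchy.two_char_groups.items():
        present = [three_char_probs[c] for c in members if c in three_char_probs]
        if present:
            two_char[prefix] = max(present)
    chapter: dict[str, float] = {}
    for ch in hierarchy.chapters:
        groups = [p for prefix, p in two_char.items() if any(c.chapter == ch for c in hierarchy.two_char_groups[prefix])]
        if groups:
            chapter[ch] = max(groups)
    return two_char, chapter


def hybrid_sample(pos: DischargeNote, neg: DischargeNote, rng=None) -> DischargeNote:
    """Paste a negative note after a positive one as a new positive sample.

    The pasted text really contains both notes' disease descriptions, so the
    label set is the union of both code sets.  The negative partner should be
    chosen uniformly among notes sharing no code with ``pos`` (see
    ``choose_negative``).
    """
    return DischargeNote(list(pos.tokens) + list(neg.tokens), set(pos.codes) | set(neg.codes))


def choose_negative(
    pos: DischargeNote, pool: Sequence[DischargeNote], rng: np.random.Generator
) -> DischargeNote:
    """Uniform draw from ``pool`` among notes sharing no code with ``pos``."""
    candidates = [n for n in pool if not (n.codes & pos.codes)]
    if not candidates:
        raise ValueError("no negative note shares zero codes with the positive note")
    return candidates[rng.integers(len(candidates))]


def weighted_loss(
    probs: np.ndarray, labels: np.ndarray, code_weights: np.ndarray, clip: float = 1e-12
) -> float:
    """Frequency-weighted binary cross-entropy summed over codes.

    Weights are positive, one per code, conventionally ∝ 1/frequency and
    normalized to mean 1 (the oversampling surrogate).
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    w = np.asarray(code_weights, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("code weights must be positive")
    if np.any(probs < -clip) or np.any(probs > 1 + clip):
        raise ValueError("probabilities outside [0, 1]")
    p = np.clip(probs, clip, 1 - clip)
    return float(np.sum(w * -(labels * np.log(p) + (1 - labels) * np.log(1 - p))))


def _code_frequency_weights(notes: Sequence[DischargeNote], codes: list[ICDCode]) -> np.ndarray:
    freq = np.array([sum(1 for n in notes if c in n.codes) for c in codes], dtype=np.float64)
    w = 1.0 / np.maximum(freq, 1.0)
    return w / w.mean()


def conv_parameter_count(config: CoderConfig) -> int:
    """Trainable parameters in the convolution stage of one chapter net."""
    total = 0
    for table in config.channels:
        for w, K in zip(_WIDTHS, config.per_channel_counts):
            total += K * (w * table.dim + 1)
    return total


class _Nesterov:
    """SGD with Nesterov momentum (no dampening) and decoupled-from-nothing
    L2 weight decay, pytorch-convention update."""

    def __init__(self, params: list[np.ndarray], momentum: float, weight_decay: float):
        self.params = params
        self.mu = momentum
        self.wd = weight_decay
        self.buf = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        for p, g, buf in zip(self.params, grads, self.buf):
            g = g + self.wd * p
            buf *= self.mu
            buf += g
            p -= lr * (g + self.mu * buf)


def _batch_grids(
    notes_tokens: list[Sequence[str]], config: CoderConfig, pads: list[np.ndarray]
) -> list[np.ndarray]:
    # pad only to the longest note in the batch (capped at max_len, floored
    # at the widest filter) — padding windows are masked out anyway
    n = min(config.max_len, max(max(len(t) for t in notes_tokens), _WIDTHS[-1]))
    Xs = []
    for table, E_pad in zip(config.channels, pads):
        ids = np.stack([_channel_ids(toks, table.vocabulary, n) for toks in notes_tokens])
        Xs.append(E_pad[ids])  # (B, n, D)
    return Xs


def _backward_chapter(net, logits, feat, cache, labels, weights):
    """Gradient of mean-over-batch weighted BCE w.r.t. chapter parameters."""
    B = logits.shape[0]
    dlogits = weights * (_sigmoid(logits) - labels) / B  # (B, n_codes)
    gU = dlogits.T @ feat
    gc = dlogits.sum(axis=0)
    dfeat = dlogits @ net.U
    grads_W = {}
    off = 0
    for c, w, Xw, arg in cache:
        K = net.W[(c, w)].shape[0]
        dpool = dfeat[:, off : off + K]  # (B, K)
        # Xw: (B, P, wD); arg: (B, K) -> gather the windows at the max positions
        Xsel = Xw[np.arange(B)[:, None], arg]  # (B, K, wD)
        grads_W[(c, w)] = np.einsum("bk,bkf->kf", dpool, Xsel)
        off += K
    ordered = [grads_W[key] for key in sorted(grads_W)]
    ordered.append(gU)
    ordered.append(gc)
    return ordered


def _label_matrix(notes: Sequence[DischargeNote], codes: list[ICDCode]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(codes)}
    Y = np.zeros((len(notes), len(codes)))
    for i, note in enumerate(notes):
        for c in note.codes:
            if c in idx:
                Y[i, idx[c]] = 1.0
    return Y


def _dataset_loss(model: CoderModel, notes, pads, batch_size=64) -> float:
    total, count = 0.0, 0
    for start in range(0, len(notes), batch_size):
        chunk = notes[start : start + batch_size]
        Xs = _batch_grids([n.tokens for n in chunk], model.config, pads)
        for ch in model.chapters:
            codes = model.hierarchy.chapters[ch]
            logits, _, _ = _forward_chapter(model.nets[ch], Xs)
            Y = _label_matrix(chunk, codes)
            w = model.code_weights[ch]
            p = np.clip(_sigmoid(logits), 1e-12, 1 - 1e-12)
            total += float(np.sum(w * -(Y * np.log(p) + (1 - Y) * np.log(1 - p))))
        count += len(chunk)
    return total / max(count, 1)


def train_coder(
    train: Sequence[DischargeNote],
    valid: Sequence[DischargeNote],
    config: CoderConfig,
) -> CoderModel:
    """Train per-chapter CNN classifiers on labeled notes.

    Deterministic given ``config.seed``.  Stops after the learning rate has
    been dropped ``config.lr_drops`` times (or at ``config.max_epochs``).
    """
    if not train or not valid:
        raise ValueError("both training and validation splits must be non-empty")
    if not config.channels:
        raise ValueError("config.channels must name at least one embedding table")
    all_codes = {c for n in train for c in n.codes if not c.excluded}
    if not all_codes:
        raise ValueError("no valid (non-excluded) codes in the training data")
    hierarchy = build_hierarchy(all_codes)
    rng = np.random.default_rng(config.seed)

    nets = {ch: _ChapterNet(config, len(codes), rng) for ch, codes in sorted(hierarchy.chapters.items())}
    code_weights = {
        ch: _code_frequency_weights(train, hierarchy.chapters[ch]) for ch in nets
    }
    model = CoderModel(nets, hierarchy, config, code_weights)

    train = list(train)
    if config.oversample_duplicate:
        # physically duplicate notes carrying below-median-frequency codes
        freq = {c: sum(1 for n in train for cc in n.codes if cc == c) for c in all_codes}
        median = float(np.median(list(freq.values())))
        extras = [n for n in train if any(freq[c] < median for c in n.codes if c in freq)]
        train = train + extras

    pads = [np.vstack([t.vectors, np.zeros((1, t.dim))]) for t in config.channels]
    opts = {
        ch: _Nesterov(list(nets[ch].params()), config.momentum, config.weight_decay)
        for ch in nets
    }

    lr = config.learning_rate
    drops = 0
    best = np.inf
    n = len(train)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = []
            for i in idx:
                note = train[i]
                if config.hybrid_sampling and rng.random() < config.hybrid_prob:
                    # rejection-sample a code-disjoint negative partner
                    for _ in range(64):
                        j = int(rng.integers(n))
                        if not (train[j].codes & note.codes):
                            hybrid = hybrid_sample(note, train[j])
                            if config.hybrid_labels == "positive":
                                hybrid = DischargeNote(hybrid.tokens, set(note.codes))
                            note = hybrid
                            break
                batch.append(note)
            Xs = _batch_grids([b.tokens for b in batch], config, pads)
            for ch in model.chapters:
                net = nets[ch]
                codes = hierarchy.chapters[ch]
                logits, feat, cache = _forward_chapter(net, Xs, need_cache=True)
                Y = _label_matrix(batch, codes)
                grads = _backward_chapter(net, logits, feat, cache, Y, code_weights[ch])
                opts[ch].step(grads, lr)
        val_loss = _dataset_loss(model, valid, pads)
        if best - val_loss > config.plateau_tol:
            best = val_loss
        else:
            if drops >= config.lr_drops:
                break
            lr /= config.lr_drop_factor
            drops += 1
    return model


def predict(
    model: CoderModel, note: DischargeNote, threshold: float | None = None
) -> tuple[set[ICDCode], dict[ICDCode, float]]:
    """Codes with probability above the threshold, plus the full report."""
    thr = model.config.prob_threshold if threshold is None else threshold
    probs = forward(model, encode_note(note, model.config))
    return {c for c, p in probs.items() if p > thr}, probs


def word_score(model: CoderModel, word: str, code: ICDCode) -> float:
    """Pre-logistic output of ``code`` for the single-token input ``word``.

    A score above 0 means the word alone pushes the code's probability above
    50%.  Out-of-vocabulary words embed as the zero vector.
    """
    note = DischargeNote([word], set())
    logits = forward_logits(model, encode_note(note, model.config))
    return float(logits[code.chapter][model.hierarchy.code_index[code]])


def word_score_matrix(model: CoderModel, words: Sequence[str], batch_size: int = 256):
    """Pre-logistic scores for every (word, code); returns (codes, matrix).

    Row i gives word i's score for each code, ordered as ``codes``.
    """
    codes = model.all_codes
    pads = [np.vstack([t.vectors, np.zeros((1, t.dim))]) for t in model.config.channels]
    out = np.empty((len(words), len(codes)))
    for start in range(0, len(words), batch_size):
        chunk = words[start : start + batch_size]
        Xs = _batch_grids([[w] for w in chunk], model.config, pads)
        col = 0
        for ch in model.chapters:
            logits, _, _ = _forward_chapter(model.nets[ch], Xs)
            out[start : start + len(chunk), col : col + logits.shape[1]] = logits
            col += logits.shape[1]
    return codes, out


def save_model(model: CoderModel, path: str | Path) -> None:
    """Serialize a trained model (parameters + hierarchy + channel tables)."""
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "chapters": {},
        "config": {
            "filter_counts": list(model.config.filter_counts),
            "max_len": model.config.max_len,
            "prob_threshold": model.config.prob_threshold,
        },
        "n_channels": model.config.n_channels,
    }
    for ch in model.chapters:
        net = model.nets[ch]
        meta["chapters"][ch] = [c.code for c in model.hierarchy.chapters[ch]]
        for (c, w), W in net.W.items():
            arrays[f"{ch}|W|{c}|{w}"] = W
        arrays[f"{ch}|U"] = net.U
        arrays[f"{ch}|c"] = net.c
        arrays[f"{ch}|weights"] = model.code_weights[ch]
    for i, table in enumerate(model.config.channels):
        arrays[f"channel{i}|vectors"] = table.vectors
        arrays[f"channel{i}|tokens"] = np.array(table.vocabulary.index_to_token)
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> CoderModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    channels = []
    for i in range(meta["n_channels"]):
        tokens = [str(t) for t in data[f"channel{i}|tokens"]]
        vocab = Vocabulary({t: j for j, t in enumerate(tokens)}, {t: 1 for t in tokens}, 1)
        channels.append(EmbeddingTable(vocab, data[f"channel{i}|vectors"]))
    config = CoderConfig(
        channels=channels,
        filter_counts=tuple(meta["config"]["filter_counts"]),
        max_len=meta["config"]["max_len"],
        prob_threshold=meta["config"]["prob_threshold"],
    )
    codes = [parse_icd(c) for ch in meta["chapters"] for c in meta["chapters"][ch]]
    hierarchy = build_hierarchy(codes)
    nets, weights = {}, {}
    rng = np.random.default_rng(0)
    for ch, chapter_codes in meta["chapters"].items():
        net = _ChapterNet(config, len(chapter_codes), rng)
        for c in range(meta["n_channels"]):
            for w in _WIDTHS:
                net.W[(c, w)] = data[f"{ch}|W|{c}|{w}"]
        net.U = data[f"{ch}|U"]
        net.c = data[f"{ch}|c"]
        nets[ch] = net
        weights[ch] = data[f"{ch}|weights"]
    return CoderModel(nets, hierarchy, config, weights)
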