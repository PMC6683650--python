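import math

import numpy as np
import pytest

from projcoder.coder import (
    CoderConfig,
    choose_negative,
    conv_parameter_count,
    encode_note,
    forward,
    forward_logits,
    hierarchical_pool,
    hybrid_sample,
    load_model,
    parse_icd,
    predict,
    save_model,
    train_coder,
    weighted_loss,
    word_score,
    word_score_matrix,
)
from projcoder.corpus import Vocabulary
from projcoder.embedding import EmbeddingTable
from projcoder.icd import DischargeNote, build_hierarchy
from projcoder.synth import CodeKeywordMap, gen_notes


def _table(tokens, dim, seed=0):
    rng = np.random.default_rng(seed)
    vocab = Vocabulary({t: i for i, t in enumerate(tokens)}, {t: 1 for t in tokens}, 1)
    return EmbeddingTable(vocab, rng.normal(size=(len(tokens), dim)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _tiny_training_setup(seed=0, n=120):
    cmap = CodeKeywordMap(
        {c: [f"{c.lower()}kw{i}" for i in range(3)] for c in ("C17", "C18", "K85")},
        noise_rate=0.0,
    )
    train, _ = gen_notes(cmap, n=n, len_range=(6, 12), seed=seed)
    valid, _ = gen_notes(cmap, n=max(30, n // 4), len_range=(6, 12), seed=seed + 999)
    vocab = sorted({t for nn in train + valid for t in nn.tokens})
    table = _table(vocab, 8, seed=seed + 1)
    config = CoderConfig(
        channels=[table], filter_counts=(8, 6, 4, 2, 2), max_len=16, max_epochs=6, seed=seed
    )
    return train, valid, config


class TestParseICD:
    @pytest.mark.parametrize(
        "raw,code,chapter",
        [
            ("K85.9", "K85", "K00-K95"),
            ("c17", "C17", "C00-D49"),
            ("O9A", "O9A", "O00-O9A"),
            ("Z3A.22", "Z3A", "Z00-Z99"),
        ],
    )
    def test_truncation_and_chapter(self, raw, code, chapter):
        parsed = parse_icd(raw)
        assert parsed.code == code
        assert parsed.chapter == chapter
        assert parsed.two_char == code[:2]
        assert not parsed.excluded

    def test_external_causes_flagged_excluded(self):
        parsed = parse_icd("Y93")
        assert parsed.excluded and parsed.chapter == "V00-Y99"

    @pytest.mark.parametrize("raw", ["", "5A1", "F00"])
    def test_unresolvable_raises(self, raw):
        with pytest.raises(ValueError):
            parse_icd(raw)


class TestHierarchy:
    def test_two_level_partition(self):
        codes = [parse_icd(c) for c in ("C17", "C18", "C50", "K85", "K91", "O34")]
        h = build_hierarchy(codes)
        # both grouping levels partition the code set
        assert sorted(c for cs in h.chapters.values() for c in cs) == sorted(codes)
        assert sorted(c for cs in h.two_char_groups.values() for c in cs) == sorted(codes)
        for code in codes:
            assert sum(code in cs for cs in h.chapters.values()) == 1
        assert {c.code for c in h.two_char_groups["C1"]} == {"C17", "C18"}

    def test_code_index_is_position_within_chapter(self):
        h = build_hierarchy([parse_icd(c) for c in ("C18", "C17", "K85")])
        chapter_codes = h.chapters["C00-D49"]
        assert [h.code_index[c] for c in chapter_codes] == [0, 1]


class TestEncodeNote:
    def test_shape_and_padding(self):
        table = _table(["a", "b", "c"], 5)
        cfg = CoderConfig(channels=[table], filter_counts=(5, 5, 5, 5, 5), max_len=5)
        grids = encode_note(DischargeNote(["a", "b", "c"], set()), cfg)
        assert len(grids) == 1 and grids[0].shape == (5, 5)
        assert np.array_equal(grids[0][:, 3], np.zeros(5))
        assert np.array_equal(grids[0][:, 0], table.vector("a"))

    def test_truncates_to_max_len(self):
        table = _table(["a"], 4)
        cfg = CoderConfig(channels=[table], filter_counts=(5, 5, 5, 5, 5), max_len=6)
        grids = encode_note(DischargeNote(["a"] * 16, set()), cfg)
        assert grids[0].shape == (4, 6)

    def test_unknown_token_is_zero_vector(self):
        table = _table(["a"], 4)
        cfg = CoderConfig(channels=[table], filter_counts=(5, 5, 5, 5, 5), max_len=5)
        grids = encode_note(DischargeNote(["mystery", "a"], set()), cfg)
        assert np.array_equal(grids[0][:, 0], np.zeros(4))

    def test_two_channels(self):
        t1, t2 = _table(["a", "b"], 4, 1), _table(["a", "b"], 6, 2)
        cfg = CoderConfig(channels=[t1, t2], filter_counts=(4, 4, 4, 4, 4), max_len=5)
        grids = encode_note(DischargeNote(["a", "b"], set()), cfg)
        assert [g.shape for g in grids] == [(4, 5), (6, 5)]

    def test_empty_note_error(self):
        table = _table(["a"], 4)
        cfg = CoderConfig(channels=[table], filter_counts=(5, 5, 5, 5, 5), max_len=5)
        with pytest.raises(ValueError):
            encode_note(DischargeNote([], set()), cfg)


class TestForward:
    def _tiny_model(self, seed=0):
        tokens = [f"w{i}" for i in range(8)]
        table = _table(tokens, 4, seed)
        cfg = CoderConfig(channels=[table], filter_counts=(2, 2, 2, 2, 2), max_len=6, seed=seed)
        train = [
            DischargeNote([tokens[i], tokens[i + 1], tokens[i + 2]], {parse_icd(c)})
            for i, c in enumerate(["C17", "C18", "K85"])
        ]
        model = train_coder(train, train, cfg)
        return model, table, tokens

    def test_all_zero_grid_gives_bias_only(self):
        model, table, _ = self._tiny_model()
        grids = [np.zeros((4, 6))]
        logits = forward_logits(model, grids)
        for ch, net in model.nets.items():
            assert np.allclose(logits[ch], net.c)
        probs = forward(model, grids)
        for code, p in probs.items():
            net = model.nets[code.chapter]
            assert p == pytest.approx(_sigmoid(net.c[model.hierarchy.code_index[code]]))

    def test_matches_naive_loop_oracle(self):
        model, table, tokens = self._tiny_model()
        note = DischargeNote(tokens[:6], set())  # full length: every window valid
        grids = encode_note(note, model.config)
        got = forward_logits(model, grids)
        X = grids[0].T  # (n, D)
        n = X.shape[0]
        for ch, net in model.nets.items():
            feats = []
            for w in (1, 2, 3, 4, 5):
                W = net.W[(0, w)]
                for k in range(W.shape[0]):
                    best = -np.inf
                    for p in range(n - w + 1):
                        window = X[p : p + w].ravel()
                        best = max(best, float(window @ W[k]))
                    feats.append(best)
            feats = np.array(feats)
            expected = net.U @ feats + net.c
            assert np.allclose(got[ch], expected, atol=1e-10)

    def test_padding_length_does_not_change_logits(self):
        model, table, tokens = self._tiny_model()
        note = DischargeNote(tokens[:3], set())
        short_cfg = model.config
        grids6 = encode_note(note, short_cfg)
        logits6 = forward_logits(model, grids6)
        # re-encode with twice the padding
        wide = [np.hstack([g, np.zeros((g.shape[0], 6))]) for g in grids6]
        logits12 = forward_logits(model, wide)
        for ch in logits6:
            assert np.allclose(logits6[ch], logits12[ch])


class TestHierarchicalPool:
    def test_max_of_two(self):
        codes = [parse_icd("C17"), parse_icd("C18")]
        h = build_hierarchy(codes)
        two, chap = hierarchical_pool({codes[0]: 0.9, codes[1]: 0.2}, h)
        assert two == {"C1": 0.9}
        assert chap == {"C00-D49": 0.9}

    def test_single_code_passthrough(self):
        code = parse_icd("K85")
        h = build_hierarchy([code])
        two, chap = hierarchical_pool({code: 0.42}, h)
        assert two["K8"] == pytest.approx(0.42)
        assert chap["K00-K95"] == pytest.approx(0.42)

    def test_matches_bruteforce_grouping(self, rng):
        raw = ["C17", "C18", "C50", "C53", "D12", "I10", "I21", "I25", "I50",
               "J18", "J44", "K29", "K85", "K91", "N17", "N18", "O34", "O60", "Z37", "Z3A"]
        codes = [parse_icd(c) for c in raw]
        h = build_hierarchy(codes)
        probs = {c: float(rng.random()) for c in codes}
        two, chap = hierarchical_pool(probs, h)
        for prefix, members in h.two_char_groups.items():
            assert two[prefix] == pytest.approx(max(probs[c] for c in members))
        for ch_label, members in h.chapters.items():
            assert chap[ch_label] == pytest.approx(max(probs[c] for c in members))

    def test_missing_code_error(self):
        h = build_hierarchy([parse_icd("C17")])
        with pytest.raises(KeyError):
            hierarchical_pool({parse_icd("K85"): 0.5}, h)


class TestHybridSample:
    def test_paste_and_union(self):
        pos = DischargeNote(["a", "b"], {parse_icd("C17")})
        neg = DischargeNote(["c"], {parse_icd("O34")})
        hyb = hybrid_sample(pos, neg)
        assert hyb.tokens == ["a", "b", "c"]
        assert {c.code for c in hyb.codes} == {"C17", "O34"}

    def test_empty_negative_tokens(self):
        pos = DischargeNote(["a"], {parse_icd("C17")})
        neg = DischargeNote([], {parse_icd("O34")})
        hyb = hybrid_sample(pos, neg)
        assert hyb.tokens == ["a"]
        assert {c.code for c in hyb.codes} == {"C17", "O34"}

    def test_choose_negative_never_shares_codes(self, rng):
        cmap = CodeKeywordMap(
            {c: [f"{c.lower()}x{i}" for i in range(2)] for c in ("C17", "C18", "O34", "K85")},
            anti_pairs=[("C17", "O34")],
        )
        pool, _ = gen_notes(cmap, n=200, len_range=(4, 8), seed=5)
        for note in pool[:50]:
            for _ in range(20):
                neg = choose_negative(note, pool, rng)
                assert not (neg.codes & note.codes)

    def test_choose_negative_exhausted_error(self, rng):
        a = DischargeNote(["x"], {parse_icd("C17")})
        with pytest.raises(ValueError):
            choose_negative(a, [a, a], rng)


class TestWeightedLoss:
    def test_uniform_half_probs(self):
        n = 7
        probs = np.full(n, 0.5)
        labels = np.zeros(n)
        assert weighted_loss(probs, labels, np.ones(n)) == pytest.approx(n * math.log(2))

    def test_perfect_confident_predictions_vanish(self):
        probs = np.array([1.0 - 1e-15, 1e-15])
        labels = np.array([1.0, 0.0])
        assert weighted_loss(probs, labels, np.ones(2)) < 1e-10

    def test_matches_hand_sum(self):
        probs = np.array([0.9, 0.2, 0.6])
        labels = np.array([1.0, 0.0, 1.0])
        w = np.array([0.5, 1.5, 1.0])
        expected = -(0.5 * math.log(0.9) + 1.5 * math.log(0.8) + 1.0 * math.log(0.6))
        assert weighted_loss(probs, labels, w) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_loss(np.array([1.2]), np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            weighted_loss(np.array([0.5]), np.array([1.0]), np.array([0.0]))


class TestParameterParity:
    def test_two_channel_conv_params_equal_one_channel(self):
        t1, t2 = _table(["a", "b"], 10, 1), _table(["a", "c"], 10, 2)
        counts = (2400, 1800, 900, 600, 300)
        one = CoderConfig(channels=[t1], filter_counts=counts)
        two = CoderConfig(channels=[t1, t2], filter_counts=counts)
        assert conv_parameter_count(one) == conv_parameter_count(two)
        assert two.per_channel_counts == (1200, 900, 450, 300, 150)


class TestTraining:
    def test_deterministic_given_seed(self):
        train, valid, config = _tiny_training_setup()
        m1 = train_coder(train, valid, config)
        m2 = train_coder(train, valid, config)
        for ch in m1.nets:
            for key in m1.nets[ch].W:
                assert np.array_equal(m1.nets[ch].W[key], m2.nets[ch].W[key])
            assert np.array_equal(m1.nets[ch].U, m2.nets[ch].U)
            assert np.array_equal(m1.nets[ch].c, m2.nets[ch].c)

    def test_recovers_keyword_mapping(self):
        train, valid, config = _tiny_training_setup(n=240)
        model = train_coder(train, valid, config)
        hits = 0
        for note in valid:
            pred, _ = predict(model, note)
            hits += pred == note.codes
        assert hits / len(valid) > 0.8

    def test_empty_split_error(self):
        train, valid, config = _tiny_training_setup()
        with pytest.raises(ValueError):
            train_coder([], valid, config)

    def test_output_units_match_chapter_code_counts(self):
        train, valid, config = _tiny_training_setup()
        model = train_coder(train, valid, config)
        for ch, net in model.nets.items():
            assert net.U.shape[0] == len(model.hierarchy.chapters[ch])


class TestPredictAndWordScore:
    def test_threshold_behaviour(self):
        train, valid, config = _tiny_training_setup()
        model = train_coder(train, valid, config)
        note = valid[0]
        all_codes, probs = predict(model, note, threshold=0.0)
        assert all_codes == set(probs)  # every code above threshold 0
        none, _ = predict(model, note, threshold=1.0)
        assert none == set()
        default, _ = predict(model, note)
        assert default == {c for c, p in probs.items() if p > 0.5}

    def test_word_score_consistent_with_forward(self):
        train, valid, config = _tiny_training_setup()
        model = train_coder(train, valid, config)
        word = train[0].tokens[0]
        note = DischargeNote([word], set())
        probs = forward(model, encode_note(note, config))
        for code in model.all_codes:
            s = word_score(model, word, code)
            assert probs[code] == pytest.approx(_sigmoid(s), rel=1e-12)
            assert (s > 0) == (probs[code] > 0.5)

    def test_word_score_matrix_agrees_with_scan(self):
        train, valid, config = _tiny_training_setup()
        model = train_coder(train, valid, config)
        words = sorted({t for n in train[:10] for t in n.tokens})[:8]
        codes, matrix = word_score_matrix(model, words)
        for i, w in enumerate(words):
            for j, code in enumerate(codes):
                assert matrix[i, j] == pytest.approx(word_score(model, w, code), rel=1e-10)
        frac_batch = float((matrix > 0).mean())
        frac_scan = np.mean(
            [word_score(model, w, c) > 0 for w in words for c in codes]
        )
        assert frac_batch == pytest.approx(frac_scan)

    def test_oov_word_scores_like_zero_input(self):
        train, valid, config = _tiny_training_setup()
        model = train_coder(train, valid, config)
        code = model.all_codes[0]
        s = word_score(model, "neverseenbefore", code)
        grids = [np.zeros((t.dim, config.max_len)) for t in config.channels]
        logits = forward_logits(model, grids)
        assert s == pytest.approx(logits[code.chapter][model.hierarchy.code_index[code]])


class TestModelIO:
    def test_save_load_round_trip(self, tmp_path):
        train, valid, config = _tiny_training_setup()
        model = train_coder(train, valid, config)
        p = tmp_path / "coder.npz"
        save_model(model, p)
        back = load_model(p)
        note = valid[0]
        _, probs1 = predict(model, note)
        _, probs2 = predict(back, note)
        assert set(probs1) == set(probs2)
        for code in probs1:
            assert probs1[code] == pytest.approx(probs2[code], rel=1e-12)
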