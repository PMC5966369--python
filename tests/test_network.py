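"""Vocabularies, embeddings, the NER graph contracts, training, ensembling."""

import numpy as np
import pytest

from chemstitch.corpus import Token
from chemstitch.network import (
    NerConfig,
    NerModel,
    build_word_vocab,
    ensemble_average,
    load_word_vectors,
    predict_probs,
    prepare_sections,
    train_ner_model,
)
from chemstitch.vocab import CharVocab, WordVocab, encode_token_chars


def tiny_config(**overrides) -> NerConfig:
    base = dict(
        word_embedding_dim=4, char_embedding_dim=4, char_rnn_cells=3,
        conv_filters=4, trunk_rnn_cells=3, head_rnn_cells=3,
        min_frequency=1, epochs=1, ensemble_size=1, batch_size=2,
        window_length=6, max_token_chars=6,
    )
    base.update(overrides)
    return NerConfig(**base)


def tiny_model(cfg=None, seed=0):
    cfg = cfg or tiny_config()
    wv = WordVocab({"abc": 2, "de": 3, "x9": 4})
    cv = CharVocab.build(["abcdex9-"])
    rng = np.random.default_rng(seed)
    emb = rng.uniform(-0.05, 0.05, (len(wv), cfg.word_embedding_dim))
    emb[0] = 0
    return NerModel(cfg, emb, cv, wv, seed=seed), wv, cv


class TestWordVocab:
    def test_frequency_cutoff(self):
        vocab = build_word_vocab([["a", "a", "a", "b"]], min_frequency=2)
        assert "a" in vocab and "b" not in vocab
        assert vocab.id_of("b") == vocab.oov_id

    def test_cutoff_one_keeps_everything(self):
        vocab = build_word_vocab([["a", "b"], ["c"]], min_frequency=1)
        assert all(w in vocab for w in "abc")

    def test_ids_dense_and_deterministic(self):
        vocab = build_word_vocab([["b", "b", "a", "a", "c"]], 1)
        # frequency-descending then lexicographic; pad=0 and oov=1 reserved
        assert vocab.id_of("a") == 2 and vocab.id_of("b") == 3 and vocab.id_of("c") == 4

    def test_oov_rate_matches_counting_oracle(self, rng):
        train = [["w%d" % rng.integers(0, 20) for _ in range(30)] for _ in range(5)]
        vocab = build_word_vocab(train, min_frequency=2)
        held = ["w%d" % rng.integers(0, 40) for _ in range(200)]
        ids = vocab.encode(held)
        counts = {}
        for sent in train:
            for w in sent:
                counts[w] = counts.get(w, 0) + 1
        expected = sum(1 for w in held if counts.get(w, 0) < 2)
        assert int((ids == vocab.oov_id).sum()) == expected


class TestWordVectors:
    def test_exact_copy_for_covered_tokens(self, tmp_path):
        vocab = WordVocab({"aa": 2, "bb": 3})
        p = tmp_path / "vec.txt"
        p.write_text("aa 1.0 2.0\nbb 3.0 4.0\n", encoding="utf-8")
        m = load_word_vectors(p, vocab)
        np.testing.assert_array_equal(m[2], [1.0, 2.0])
        np.testing.assert_array_equal(m[3], [3.0, 4.0])
        assert (m[vocab.pad_id] == 0).all()

    def test_missing_tokens_get_seeded_fallback(self, tmp_path):
        vocab = WordVocab({"aa": 2, "zz": 3})
        p = tmp_path / "vec.txt"
        p.write_text("aa 1.0 2.0\n", encoding="utf-8")
        m1 = load_word_vectors(p, vocab, seed=7)
        m2 = load_word_vectors(p, vocab, seed=7)
        np.testing.assert_array_equal(m1, m2)
        assert (np.abs(m1[3]) <= 0.05).all() and m1[3].any()

    def test_no_overlap_warns(self, tmp_path):
        vocab = WordVocab({"qq": 2})
        p = tmp_path / "vec.txt"
        p.write_text("aa 1.0 2.0\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="no overlap"):
            load_word_vectors(p, vocab, dim=2)

    def test_inconsistent_widths_rejected(self, tmp_path):
        vocab = WordVocab({"aa": 2, "bb": 3})
        p = tmp_path / "vec.txt"
        p.write_text("aa 1.0 2.0\nbb 3.0\n", encoding="utf-8")
        with pytest.raises(ValueError, match="width"):
            load_word_vectors(p, vocab)


class TestEncodeTokenChars:
    vocab = CharVocab({"a": 2, "b": 3})

    def test_pad_to_max_len(self):
        np.testing.assert_array_equal(
            encode_token_chars("ab", self.vocab, 4), [2, 3, 0, 0])

    def test_unknown_char(self):
        assert encode_token_chars("z", self.vocab, 2)[0] == self.vocab.unknown_id

    def test_truncation(self):
        assert encode_token_chars("ababab", self.vocab, 3).shape == (3,)


class TestModelContracts:
    def test_outputs_bounded_in_unit_interval(self):
        model, wv, cv = tiny_model()
        words = np.array([[2, 3, 4, 0, 0, 0], [4, 4, 2, 3, 2, 0]])
        chars = np.zeros((2, 6, 6), dtype=np.int64)
        chars[:, :, 0] = 2
        part, start = model.forward(words, chars)
        for out in (part, start):
            assert ((out.data >= 0) & (out.data <= 1)).all()
            assert np.isfinite(out.data).all()

    def test_zero_part_probability_zeroes_coupled_features(self):
        model, wv, cv = tiny_model()
        words = np.array([[2, 3, 4, 2, 3, 4]])
        chars = np.full((1, 6, 6), 2, dtype=np.int64)
        override = np.zeros((1, 6))
        override[0, 2] = 0.0  # explicit: probe forces part prob to 0 everywhere
        _, _, internals = model.forward(words, chars, part_override=override,
                                        return_internals=True)
        assert (internals["coupled"].data == 0).all()
        assert (internals["trunk"].data != 0).any()

    def test_gru_trunk_smaller_than_lstm_trunk(self):
        gru, _, _ = tiny_model(tiny_config(rnn_cell_type="GRU"))
        lstm, _, _ = tiny_model(tiny_config(rnn_cell_type="LSTM"))
        n_gru = sum(p.data.size for layer in gru.trunk for p in layer.params())
        n_lstm = sum(p.data.size for layer in lstm.trunk for p in layer.params())
        assert n_gru < n_lstm

    def test_padded_positions_do_not_affect_loss(self):
        model, wv, cv = tiny_model()
        words = np.array([[2, 3, 4, 0, 0, 0]])
        chars = np.zeros((1, 6, 6), dtype=np.int64)
        chars[0, :3] = 2
        mask = np.array([[1, 1, 1, 0, 0, 0]], dtype=np.int8)
        s = np.array([[1, 0, 0, 0, 0, 0]], dtype=float)
        e = np.array([[1, 1, 0, 0, 0, 0]], dtype=float)
        chunk = {"words": words, "chars": chars, "s": s, "e": e, "mask": mask}
        model.reset_states()
        base = float(model.loss_on_chunk(chunk).data)
        # garbage ids at padded positions
        chunk2 = dict(chunk)
        chunk2["words"] = words.copy()
        chunk2["words"][0, 3:] = 4
        chunk2["chars"] = chars.copy()
        chunk2["chars"][0, 3:, :] = 3
        model.reset_states()
        perturbed = float(model.loss_on_chunk(chunk2).data)
        assert perturbed == pytest.approx(base, abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tiny_config(conv_filters=0).validate()
        with pytest.raises(ValueError):
            tiny_config(rnn_cell_type="ELMAN").validate()
        with pytest.raises(ValueError):
            tiny_config(decision_threshold=1.5).validate()

    def test_embedding_shape_checked_at_construction(self):
        cfg = tiny_config()
        wv = WordVocab({"abc": 2})
        cv = CharVocab.build(["abc"])
        with pytest.raises(ValueError, match="embedding matrix"):
            NerModel(cfg, np.zeros((2, cfg.word_embedding_dim)), cv, wv)


def _toy_sections(n_docs, wv, cv, cfg, rng):
    """Sections where tokens containing '9' are single-token entities."""
    from chemstitch.corpus import Document, EntitySpan

    docs, spans = [], []
    for i in range(n_docs):
        words = []
        for j in range(12):
            words.append("x9" if rng.random() < 0.25 else rng.choice(["abc", "de"]))
        text = " ".join(words)
        doc = Document(f"T{i}", "", text)
        docs.append(doc)
        off = 0
        for w in words:
            if w == "x9":
                spans.append(EntitySpan(f"T{i}", "abstract", off, off + 2, "x9", "FORMULA"))
            off += len(w) + 1
    from chemstitch.tokenizer import primary_segment

    tokenised = {(d.doc_id, "abstract"): primary_segment(d.abstract) for d in docs}
    sections = prepare_sections(docs, tokenised, wv, cv, cfg.max_token_chars, spans)
    return sections


class TestTraining:
    def test_loss_decreases_and_history_reproducible(self, rng):
        cfg = tiny_config(epochs=3, learning_rate=3e-3)
        wv = WordVocab({"abc": 2, "de": 3, "x9": 4})
        cv = CharVocab.build(["abcdex9"])
        emb = np.random.default_rng(0).uniform(-0.05, 0.05, (len(wv), 4))
        emb[0] = 0
        sections = _toy_sections(6, wv, cv, cfg, np.random.default_rng(5))
        _, hist1 = train_ner_model(sections[:5], sections[5:], cfg, emb, wv, cv, seed=3)
        _, hist2 = train_ner_model(sections[:5], sections[5:], cfg, emb, wv, cv, seed=3)
        assert hist1.train_loss[-1] < hist1.train_loss[0]
        assert hist1.train_loss == hist2.train_loss
        assert hist1.val_loss == hist2.val_loss

    def test_empty_training_set_rejected(self):
        cfg = tiny_config()
        wv = WordVocab({"abc": 2})
        cv = CharVocab.build(["abc"])
        with pytest.raises(ValueError):
            train_ner_model([], [], cfg, np.zeros((len(wv), 4)), wv, cv)

    def test_predictions_bounded_and_pad_free(self, rng):
        cfg = tiny_config()
        model, wv, cv = tiny_model(cfg)
        sections = _toy_sections(3, wv, cv, cfg, rng)
        probs = predict_probs(model, sections)
        assert len(probs) == len(sections)
        for sec, p in zip(sections, probs):
            assert p.shape == (len(sec.tokens), 2)
            assert ((p >= 0) & (p <= 1)).all()

    def test_save_load_preserves_predictions(self, tmp_path, rng):
        cfg = tiny_config()
        model, wv, cv = tiny_model(cfg)
        sections = _toy_sections(2, wv, cv, cfg, rng)
        before = predict_probs(model, sections)
        model.save(tmp_path / "m")
        again = NerModel.load(tmp_path / "m")
        after = predict_probs(again, sections)
        for a, b in zip(before, after):
            np.testing.assert_allclose(a, b)


class TestEnsemble:
    def test_average_of_identical_runs_is_that_run(self):
        run = [np.array([[0.2, 0.8], [0.5, 0.5]])]
        out = ensemble_average([run, run, run])
        np.testing.assert_array_equal(out[0], run[0])

    def test_mean_of_zero_and_one(self):
        a = [np.zeros((3, 2))]
        b = [np.ones((3, 2))]
        np.testing.assert_array_equal(ensemble_average([a, b])[0], np.full((3, 2), 0.5))

    def test_permutation_invariance(self, rng):
        runs = [[rng.random((4, 2))] for _ in range(5)]
        out1 = ensemble_average(runs)
        out2 = ensemble_average(runs[::-1])
        np.testing.assert_allclose(out1[0], out2[0])

    def test_misaligned_runs_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([[np.zeros((3, 2))], [np.zeros((4, 2))]])
        with pytest.raises(ValueError):
            ensemble_average([])
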