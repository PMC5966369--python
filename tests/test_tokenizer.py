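"""Break-and-stitch tokenisation: segmentation, stitch tags, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemstitch.corpus import EntitySpan, Token
from chemstitch.tokenizer import (
    StitchModel,
    StitchModelConfig,
    apply_stitches,
    combine_metrics,
    derive_stitch_tags,
    primary_segment,
    tokenizer_metrics,
)
from chemstitch.vocab import CharVocab

SYSTEMATIC_NAME = "2-amino-1-methyl-6-phenylimidazo[4,5-b]pyridine"
NINETEEN = ["2", "-", "amino", "-", "1", "-", "methyl", "-", "6", "-",
            "phenylimidazo", "[", "4", ",", "5", "-", "b", "]", "pyridine"]


class TestPrimarySegment:
    def test_systematic_name_gives_nineteen_fragments(self):
        assert [t.text for t in primary_segment(SYSTEMATIC_NAME)] == NINETEEN

    def test_empty_text(self):
        assert primary_segment("") == []

    def test_offsets_against_character_class_oracle(self):
        # oracle: run-length encoding of per-character classes word/space/other
        text = "H2O !"
        toks = primary_segment(text)
        assert [(t.text, t.start, t.end) for t in toks] == [("H2O", 0, 3), ("!", 4, 5)]
        text2 = "H2O  ! x"
        toks2 = primary_segment(text2)
        assert [(t.text, t.start, t.end) for t in toks2] == [
            ("H2O", 0, 3), ("!", 5, 6), ("x", 7, 8)]


# shared text alphabet for reconstruction properties: letters, digits,
# punctuation-heavy chemical characters, whitespace, and non-ASCII
TEXT_ALPHABET = st.sampled_from(
    list("abcXYZ0189-[],()=+%$.;:'\"/\\ \t\nαβμ≥①漢字ﬁ")
)
texts = st.text(alphabet=TEXT_ALPHABET, max_size=60)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(texts)
def test_partition_and_reconstruction(text):
    """Every non-whitespace character is covered exactly once, whitespace is
    never inside a token, and tokens + gaps reconstruct the input."""
    toks = primary_segment(text)
    covered = np.zeros(len(text), dtype=int)
    for t in toks:
        assert text[t.start:t.end] == t.text
        assert not any(c.isspace() for c in t.text)
        covered[t.start:t.end] += 1
    for i, c in enumerate(text):
        assert covered[i] == (0 if c.isspace() else 1)
    # reconstruction: splice token texts back over the original gaps
    rebuilt, pos = [], 0
    for t in toks:
        rebuilt.append(text[pos:t.start])
        rebuilt.append(t.text)
        pos = t.end
    rebuilt.append(text[pos:])
    assert "".join(rebuilt) == text


class TestStitchTags:
    def test_hyphenated_entity_tags(self):
        text = "x a-b y"
        toks = primary_segment(text)
        span = EntitySpan("d", "abstract", 2, 5, "a-b", "TRIVIAL")
        tags = derive_stitch_tags(text, toks, [span])
        assert sorted(np.nonzero(tags)[0].tolist()) == [3, 4]  # "-" and "b"

    def test_no_spans_no_tags(self):
        text = "a-b c"
        assert not derive_stitch_tags(text, primary_segment(text), []).any()

    def test_single_fragment_span_nothing_to_stitch(self):
        text = "water"
        span = EntitySpan("d", "abstract", 0, 5, "water", "TRIVIAL")
        assert not derive_stitch_tags(text, primary_segment(text), [span]).any()

    def test_whitespace_never_tagged(self):
        text = "q 1-oxo-ethyl w"
        toks = primary_segment(text)
        span = EntitySpan("d", "abstract", 2, 13, "1-oxo-ethyl", "SYSTEMATIC")
        tags = derive_stitch_tags(text, toks, [span])
        assert not any(tags[i] for i, c in enumerate(text) if c.isspace())


class TestApplyStitches:
    def test_merges_tagged_run(self):
        text = "a-b"
        toks = primary_segment(text)
        tags = np.array([0.0, 1.0, 1.0])
        assert [t.text for t in apply_stitches(toks, tags)] == ["a-b"]

    def test_all_false_is_identity(self):
        text = "a-b c!"
        toks = primary_segment(text)
        assert apply_stitches(toks, np.zeros(len(text))) == toks

    def test_never_merges_across_whitespace(self):
        text = "ab cd"
        toks = primary_segment(text)
        tags = np.ones(len(text))  # even a fully positive tag vector
        merged = apply_stitches(toks, tags)
        assert [t.text for t in merged] == ["ab", "cd"]

    def test_covered_character_count_conserved(self):
        text = "x 2-oxo[1,2-b]ol y."
        toks = primary_segment(text)
        tags = (np.random.default_rng(0).random(len(text)) > 0.5).astype(float)
        merged = apply_stitches(toks, tags)
        assert sum(t.end - t.start for t in merged) == sum(t.end - t.start for t in toks)

    def test_derive_then_apply_recovers_contiguous_spans(self, small_corpus):
        """Gold tags applied at threshold 0.5 restore every whitespace-free
        gold entity as one token."""
        docs, spans = small_corpus
        by_sec = {}
        for sp in spans:
            by_sec.setdefault((sp.doc_id, sp.section), []).append(sp)
        checked = 0
        for doc in docs:
            for section in ("title", "abstract"):
                text = doc.section_text(section)
                sec_spans = by_sec.get((doc.doc_id, section), [])
                toks = primary_segment(text)
                tags = derive_stitch_tags(text, toks, sec_spans)
                merged = apply_stitches(toks, tags.astype(float), 0.5)
                starts = {(t.start, t.end) for t in merged}
                for sp in sec_spans:
                    if any(c.isspace() for c in sp.text):
                        continue
                    assert (sp.start, sp.end) in starts, sp
                    checked += 1
        assert checked > 20


# ---------------------------------------------------------------------------
# metrics


def brute_force_metrics(spans, tokens):
    """Oracle: test every span against every contiguous token run."""
    n_rec = n_ovl = 0
    for sp in spans:
        crossing = any(
            t.start < sp.end and t.end > sp.start
            and (t.start < sp.start or t.end > sp.end)
            for t in tokens
        )
        runs = [
            (tokens[i].start, tokens[j].end)
            for i in range(len(tokens))
            for j in range(i, len(tokens))
        ]
        exact = (sp.start, sp.end) in runs
        if crossing:
            n_ovl += 1
        elif exact:
            n_rec += 1
    return n_rec, n_ovl


class TestTokenizerMetrics:
    def test_perfect_tiling(self):
        text = "abc de"
        toks = primary_segment(text)
        spans = [EntitySpan("d", "abstract", 0, 3, "abc", "TRIVIAL")]
        m = tokenizer_metrics(spans, toks)
        assert m.entity_recall == 1.0 and m.overlap_rate == 0.0

    def test_span_split_mid_token_counts_as_overlap(self):
        # token "abcd" straddles the span boundary at 2
        toks = [Token("abcd", 0, 4)]
        spans = [EntitySpan("d", "abstract", 0, 2, "ab", "TRIVIAL")]
        m = tokenizer_metrics(spans, toks)
        assert m.entity_recall == 0.0 and m.overlap_rate == 1.0

    def test_matches_brute_force_on_random_corpora(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 12))
            words = ["".join(rng.choice(list("abXY19-"), size=rng.integers(1, 5)))
                     for _ in range(n)]
            text = " ".join(w.replace(" ", "x") for w in words)
            toks = primary_segment(text)
            # random candidate spans over token boundaries or raw offsets
            spans, used = [], -1
            for _ in range(3):
                a = int(rng.integers(0, max(1, len(text) - 2)))
                b = int(rng.integers(a + 1, min(len(text), a + 6) + 1))
                if a > used and text[a:b].strip() == text[a:b] and text[a:b]:
                    spans.append(EntitySpan("d", "abstract", a, b, text[a:b], "TRIVIAL"))
                    used = b
            # randomly stitch some adjacent tokens to vary the tokenisation
            tags = (rng.random(len(text)) > 0.7).astype(float)
            merged = apply_stitches(toks, tags)
            m = tokenizer_metrics(spans, merged)
            n_rec, n_ovl = brute_force_metrics(spans, merged)
            assert m.n_recovered == n_rec
            assert m.n_overlapping == n_ovl

    def test_combine_pools_counts(self):
        toks = primary_segment("abc")
        spans = [EntitySpan("d", "abstract", 0, 3, "abc", "TRIVIAL")]
        m1 = tokenizer_metrics(spans, toks)
        m2 = tokenizer_metrics([], primary_segment("x y"))
        pooled = combine_metrics([m1, m2])
        assert pooled.n_gold == 1 and pooled.entity_recall == 1.0


class TestStitchModelBasics:
    def test_zero_layer_config_rejected(self):
        with pytest.raises(ValueError):
            StitchModelConfig(conv_layers=0).validate()
        with pytest.raises(ValueError):
            StitchModelConfig(rnn_layers=0).validate()

    def test_untrained_model_outputs_probabilities(self):
        cfg = StitchModelConfig(char_embedding_dim=4, conv_filters=4,
                                rnn_cells=3, batch_size=2, window_length=8,
                                epochs=1)
        vocab = CharVocab.build(["abc-def"])
        model = StitchModel(cfg, vocab, seed=0)
        tags = model.predict_tags(["abc-def ghi", ""])
        assert tags[0].shape == (11,)
        assert ((tags[0] >= 0) & (tags[0] <= 1)).all()
        assert tags[0][7] == 0.0  # whitespace forced to zero
        assert tags[1].shape == (0,)

    def test_save_load_round_trip(self, tmp_path):
        cfg = StitchModelConfig(char_embedding_dim=4, conv_filters=4,
                                rnn_cells=3, batch_size=2, window_length=8,
                                epochs=1)
        vocab = CharVocab.build(["abc-def"])
        model = StitchModel(cfg, vocab, seed=0)
        model.save(tmp_path / "tok")
        again = StitchModel.load(tmp_path / "tok")
        t1 = model.predict_tags(["ab-cd"])[0]
        t2 = again.predict_tags(["ab-cd"])[0]
        np.testing.assert_allclose(t1, t2)
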