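"""End-to-end glue: corpus -> tokeniser -> network ensemble -> annotations.

The functions here wire the library modules into the workflow a user runs
from the command line: train the stitch tokeniser and the NER ensemble on an
annotated corpus, annotate raw documents, and score predictions against gold
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Document, EntitySpan, Token
from .evaluation import CemScores, decode, per_class_recall, score_cem
from .network import (
    NerConfig,
    NerModel,
    SectionTokens,
    build_word_vocab,
    ensemble_average,
    load_word_vectors,
    predict_probs,
    prepare_sections,
)
from .network import train_ner_model
from .tokenizer import StitchModel, StitchModelConfig, train_stitch_model
from .training import TrainHistory
from .vocab import CharVocab, WordVocab

__all__ = ["NerPipeline", "split_documents", "train_pipeline",
           "stitch_point_recall", "desk_configs"]


def desk_configs() -> tuple[StitchModelConfig, NerConfig]:
    """The package's reduced desk-scale configuration.

    A single-CPU-friendly shrink of the reference architecture — 16
    convolution filters, 8 recurrent cells per direction, 16-d embeddings,
    an ensemble of one — used throughout the test corpus experiments.  The
    stitch model trains for 20 epochs; the NER network keeps the reference
    40 epochs with a slightly raised learning rate (3e-3) suited to the
    smaller widths.
    """
    stitch = StitchModelConfig(
        char_embedding_dim=16, conv_filters=16, rnn_cells=8,
        batch_size=16, window_length=96, epochs=20,
    )
    ner = NerConfig(
        word_embedding_dim=16, char_embedding_dim=16, char_rnn_cells=8,
        conv_filters=16, trunk_rnn_cells=8, head_rnn_cells=8,
        min_frequency=2, epochs=40, ensemble_size=1,
        batch_size=16, window_length=32, learning_rate=3e-3,
    )
    return stitch, ner


def split_documents(
    documents: Sequence[Document], fraction: float, seed: int
) -> tuple[list[Document], list[Document]]:
    """Deterministic document-level split: (rest, held-out fraction)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    n_held = int(round(fraction * len(documents)))
    held = {int(i) for i in order[:n_held]}
    return (
        [d for i, d in enumerate(documents) if i not in held],
        [d for i, d in enumerate(documents) if i in held],
    )


def _spans_for(documents: Sequence[Document], spans: Sequence[EntitySpan]) -> list[EntitySpan]:
    ids = {d.doc_id for d in documents}
    return [sp for sp in spans if sp.doc_id in ids]


@dataclass
class NerPipeline:
    """A trained tokeniser plus NER ensemble, ready to annotate text."""

    stitch_model: StitchModel
    members: list[NerModel]
    word_vocab: WordVocab
    char_vocab: CharVocab
    ner_config: NerConfig
    stitch_history: TrainHistory | None = None
    member_histories: list[TrainHistory] = field(default_factory=list)

    def tokenize(self, documents: Sequence[Document]) -> dict[tuple[str, str], list[Token]]:
        out: dict[tuple[str, str], list[Token]] = {}
        for doc in documents:
            for section in ("title", "abstract"):
                text = doc.section_text(section)
                if text:
                    out[(doc.doc_id, section)] = self.stitch_model.tokenize(text)
        return out

    def _sections(
        self,
        documents: Sequence[Document],
        spans: Sequence[EntitySpan] | None = None,
        tokenised: dict[tuple[str, str], list[Token]] | None = None,
    ) -> list[SectionTokens]:
        tokenised = tokenised if tokenised is not None else self.tokenize(documents)
        return prepare_sections(
            documents, tokenised, self.word_vocab, self.char_vocab,
            self.ner_config.max_token_chars, spans,
        )

    def annotate(
        self, documents: Sequence[Document], threshold: float | None = None
    ) -> list[EntitySpan]:
        """Ensemble-averaged, threshold-decoded predicted spans."""
        sections = self._sections(documents)
        if not sections:
            return []
        runs = [predict_probs(m, sections) for m in self.members]
        probs = ensemble_average(runs)
        thr = self.ner_config.decision_threshold if threshold is None else threshold
        out: list[EntitySpan] = []
        for sec, p in zip(sections, probs):
            out.extend(
                decode(p, sec.tokens, thr, doc_id=sec.doc_id,
                       section=sec.section, text=sec.text)
            )
        return out

    def evaluate(
        self, documents: Sequence[Document], gold: Sequence[EntitySpan]
    ) -> tuple[CemScores, dict[str, tuple[float, int]]]:
        predicted = self.annotate(documents)
        gold = _spans_for(documents, gold)
        return score_cem(gold, predicted), per_class_recall(gold, predicted)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        self.stitch_model.save(d / "tokenizer")
        for i, m in enumerate(self.members):
            m.save(d / f"member{i:02d}")

    @classmethod
    def load(cls, directory: str | Path) -> "NerPipeline":
        d = Path(directory)
        stitch = StitchModel.load(d / "tokenizer")
        members = [NerModel.load(p) for p in sorted(d.glob("member*"))]
        if not members:
            raise FileNotFoundError(f"no trained ensemble members under {d}")
        first = members[0]
        return cls(stitch, members, first.word_vocab, first.char_vocab, first.config)


def train_pipeline(
    documents: Sequence[Document],
    spans: Sequence[EntitySpan],
    stitch_config: StitchModelConfig | None = None,
    ner_config: NerConfig | None = None,
    word_vector_path: str | Path | None = None,
    seed: int = 0,
) -> NerPipeline:
    """Train the full pipeline on an annotated corpus.

    The same training/validation document split is used for the tokeniser and
    the NER ensemble.  Without a pretrained word-vector file, word embeddings
    are randomly initialised and fine-tuned on the corpus.  Ensemble member
    *k* is trained from seed ``seed + k``.
    """
    ner_config = ner_config or NerConfig()
    ner_config.validate()
    stitch_config = stitch_config or StitchModelConfig()

    train_docs, val_docs = split_documents(documents, ner_config.validation_fraction, seed)
    if not train_docs:
        raise ValueError("corpus too small to split")
    train_spans = _spans_for(train_docs, spans)
    val_spans = _spans_for(val_docs, spans)

    stitch_model, stitch_history = train_stitch_model(
        documents, spans, stitch_config,
        validation_fraction=ner_config.validation_fraction, seed=seed,
    )

    tokenised = {}
    for doc in documents:
        for section in ("title", "abstract"):
            text = doc.section_text(section)
            if text:
                tokenised[(doc.doc_id, section)] = stitch_model.tokenize(text)

    all_texts = [
        [t.text for t in toks] for toks in tokenised.values()
    ]
    word_vocab = build_word_vocab(all_texts, ner_config.min_frequency)
    char_vocab = stitch_model.char_vocab

    if word_vector_path is not None:
        embeddings = load_word_vectors(word_vector_path, word_vocab,
                                       dim=ner_config.word_embedding_dim, seed=seed)
    else:
        rng = np.random.default_rng(seed)
        embeddings = rng.uniform(-0.05, 0.05,
                                 size=(len(word_vocab), ner_config.word_embedding_dim))
        embeddings[word_vocab.pad_id] = 0.0
        ner_config.fine_tune_word_embeddings = True

    def sections_of(docs, sp):
        return prepare_sections(docs, {k: v for k, v in tokenised.items()
                                       if k[0] in {d.doc_id for d in docs}},
                                word_vocab, char_vocab,
                                ner_config.max_token_chars, sp)

    train_sections = sections_of(train_docs, train_spans)
    val_sections = sections_of(val_docs, val_spans)

    members: list[NerModel] = []
    histories: list[TrainHistory] = []
    for k in range(ner_config.ensemble_size):
        model, hist = train_ner_model(
            train_sections, val_sections, ner_config, embeddings,
            word_vocab, char_vocab, seed=seed + k,
        )
        members.append(model)
        histories.append(hist)

    return NerPipeline(stitch_model, members, word_vocab, char_vocab,
                       ner_config, stitch_history, histories)


def stitch_point_recall(
    model: StitchModel,
    documents: Sequence[Document],
    spans: Sequence[EntitySpan],
    threshold: float | None = None,
) -> float:
    """Fraction of gold stitch points the model tags positive.

    Gold stitch points are derived from the gold spans over the primary
    segmentation of every section; returns 1.0 when there is nothing to
    stitch.
    """
    from .tokenizer import derive_stitch_tags, primary_segment

    thr = model.config.threshold if threshold is None else threshold
    by_sec: dict[tuple[str, str], list[EntitySpan]] = {}
    for sp in spans:
        by_sec.setdefault((sp.doc_id, sp.section), []).append(sp)
    texts, golds = [], []
    for doc in documents:
        for section in ("title", "abstract"):
            text = doc.section_text(section)
            if not text:
                continue
            toks = primary_segment(text)
            texts.append(text)
            golds.append(derive_stitch_tags(text, toks, by_sec.get((doc.doc_id, section), [])))
    if not texts:
        return 1.0
    preds = model.predict_tags(texts)
    n_gold = sum(int(g.sum()) for g in golds)
    if n_gold == 0:
        return 1.0
    n_hit = sum(int((p[g] > thr).sum()) for p, g in zip(preds, golds))
    return n_hit / n_gold
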