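"""The chemical NER network: hybrid word/character embeddings, parallel CNN
branches, a half-stateful bidirectional recurrent trunk and two codependent
sigmoid heads.

Per token the model emits two probabilities: *part* — the token belongs to a
chemical entity — and *start* — the token begins one.  The labels are not
mutually exclusive (unlike IOB tags) and are coupled: the start head consumes
the trunk features scaled, step by step, by the part head's probability, so
errors of either head back-propagate through the multiplication node and the
two detectors reinforce each other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .batching import BatchPlan, build_chunks, make_plan, text_start_masks, unbatch
from .corpus import Document, EntitySpan, LabelPair, Token, char_labels_to_token_labels, spans_to_char_labels
from .nn import BiRNNEncoder, Conv1D, Dense, Embedding, HalfStatefulBiRNN, Tensor, masked_bce
from .nn.autograd import no_grad
from .training import TrainHistory, fit_stateful
from .vocab import CharVocab, WordVocab, encode_token_chars

__all__ = [
    "NerConfig",
    "NerModel",
    "SectionTokens",
    "build_word_vocab",
    "load_word_vectors",
    "prepare_sections",
    "train_ner_model",
    "train_ensemble",
    "predict_probs",
    "ensemble_average",
]


@dataclass
class NerConfig:
    """Architecture and training settings.

    Defaults mirror the reference design: 32-d linear character embeddings
    encoded per token by a 16-cell biGRU (32-d token vectors), 300-d word
    embeddings, two 256-filter width-3 convolution layers per branch, a
    two-layer half-stateful biGRU trunk and one extra half-stateful layer per
    head (32 cells everywhere), trained jointly with Adam for 40 epochs; at
    test time probabilities of 10 independently trained networks are
    averaged and thresholded at 0.5.
    """

    word_embedding_dim: int = 300
    char_embedding_dim: int = 32
    char_rnn_cells: int = 16  # per direction -> 32-d token vector
    conv_layers_per_branch: int = 2
    conv_filters: int = 256
    conv_width: int = 3
    trunk_rnn_layers: int = 2
    trunk_rnn_cells: int = 32
    head_rnn_cells: int = 32
    rnn_cell_type: str = "GRU"
    max_token_chars: int = 40
    min_frequency: int = 2
    epochs: int = 40
    ensemble_size: int = 10
    decision_threshold: float = 0.5
    batch_size: int = 32
    window_length: int = 128
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    fine_tune_word_embeddings: bool = False
    reset_state_at_text_boundaries: bool = False

    def validate(self) -> None:
        for name in (
            "word_embedding_dim", "char_embedding_dim", "char_rnn_cells",
            "conv_layers_per_branch", "conv_filters", "conv_width",
            "trunk_rnn_layers", "trunk_rnn_cells", "head_rnn_cells",
            "max_token_chars", "epochs", "ensemble_size", "batch_size",
            "window_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.rnn_cell_type.upper() not in ("GRU", "LSTM"):
            raise ValueError(f"unknown rnn_cell_type {self.rnn_cell_type!r}")
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise ValueError("decision_threshold must lie in [0, 1]")


# ---------------------------------------------------------------------------
# vocabularies and pretrained vectors


def build_word_vocab(
    tokenised_corpus: Sequence[Sequence[str]], min_frequency: int = 1
) -> WordVocab:
    """Frequency-cutoff vocabulary; sub-cutoff tokens share the OOV id."""
    return WordVocab.build(tokenised_corpus, min_frequency)


def load_word_vectors(
    path: str | Path, vocab: WordVocab, dim: int | None = None, seed: int = 0
) -> np.ndarray:
    """Load plain-text word vectors (token then floats, one per line) into a
    matrix aligned with ``vocab`` ids.

    Vocabulary tokens absent from the file (and the OOV row) fall back to
    uniform random values in [-0.05, 0.05] drawn from ``seed``; the padding
    row 0 stays zero.
    """
    vectors: dict[str, np.ndarray] = {}
    file_dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            token, values = parts[0], parts[1:]
            vec = np.array([float(v) for v in values])
            if file_dim is None:
                file_dim = vec.size
            elif vec.size != file_dim:
                raise ValueError(
                    f"{path}:{lineno}: vector width {vec.size} != {file_dim}"
                )
            if token in vocab:
                vectors[token] = vec
    if dim is None:
        dim = file_dim
    if dim is None:
        raise ValueError(f"{path}: no vectors found and no dim given")
    if file_dim is not None and file_dim != dim:
        raise ValueError(f"{path}: file vectors are {file_dim}-d, expected {dim}-d")
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
    matrix[vocab.pad_id] = 0.0
    for token, tid in vocab.token_to_id.items():
        if token in vectors:
            matrix[tid] = vectors[token]
    if not vectors:
        warnings.warn("no overlap between the vector file and the vocabulary; "
                      "all rows use the random fallback initialiser")
    return matrix


# ---------------------------------------------------------------------------
# per-section encodings


@dataclass
class SectionTokens:
    """One section's tokenisation plus everything the model needs of it."""

    doc_id: str
    section: str
    text: str
    tokens: list[Token]
    word_ids: np.ndarray  # (n_tokens,)
    char_ids: np.ndarray  # (n_tokens, max_token_chars)
    labels: list[LabelPair] | None = None  # gold, when available

    @property
    def s_flags(self) -> np.ndarray:
        return np.array([l.s for l in self.labels], dtype=np.float64)

    @property
    def e_flags(self) -> np.ndarray:
        return np.array([l.e for l in self.labels], dtype=np.float64)


def prepare_sections(
    documents: Sequence[Document],
    tokenised: dict[tuple[str, str], list[Token]],
    word_vocab: WordVocab,
    char_vocab: CharVocab,
    max_token_chars: int,
    spans: Sequence[EntitySpan] | None = None,
) -> list[SectionTokens]:
    """Encode every non-empty section; attaches gold token labels when spans
    are given.  Sections with no tokens are skipped (nothing to label)."""
    by_sec: dict[tuple[str, str], list[EntitySpan]] = {}
    for sp in spans or []:
        by_sec.setdefault((sp.doc_id, sp.section), []).append(sp)
    out: list[SectionTokens] = []
    for doc in documents:
        for section in ("title", "abstract"):
            text = doc.section_text(section)
            tokens = tokenised.get((doc.doc_id, section))
            if tokens is None:
                continue
            if not tokens:
                continue
            word_ids = word_vocab.encode([t.text for t in tokens])
            char_ids = np.stack(
                [encode_token_chars(t.text, char_vocab, max_token_chars) for t in tokens]
            )
            labels = None
            if spans is not None:
                char_labels = spans_to_char_labels(text, by_sec.get((doc.doc_id, section), []))
                labels = char_labels_to_token_labels(tokens, char_labels)
            out.append(SectionTokens(doc.doc_id, section, text, list(tokens),
                                     word_ids, char_ids, labels))
    return out


# ---------------------------------------------------------------------------
# the model


class NerModel:
    """Dual-input CNN + half-stateful biRNN sequence labeller."""

    def __init__(
        self,
        config: NerConfig,
        word_embeddings: np.ndarray,
        char_vocab: CharVocab,
        word_vocab: WordVocab,
        seed: int = 0,
    ):
        config.validate()
        if word_embeddings.shape != (len(word_vocab), config.word_embedding_dim):
            raise ValueError(
                f"word embedding matrix {word_embeddings.shape} does not match "
                f"vocab {len(word_vocab)} x dim {config.word_embedding_dim}"
            )
        self.config = config
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab
        rng = np.random.default_rng(seed)
        cell = config.rnn_cell_type

        self.word_embedding = Embedding(
            len(word_vocab), config.word_embedding_dim, rng,
            weights=word_embeddings, trainable=config.fine_tune_word_embeddings,
        )
        self.char_embedding = Embedding(len(char_vocab), config.char_embedding_dim, rng)
        self.char_encoder = BiRNNEncoder(
            config.char_embedding_dim, config.char_rnn_cells, rng, cell
        )

        def conv_stack(n_in: int) -> list[Conv1D]:
            stack = []
            for _ in range(config.conv_layers_per_branch):
                stack.append(Conv1D(n_in, config.conv_filters, config.conv_width, rng))
                n_in = config.conv_filters
            return stack

        self.word_convs = conv_stack(config.word_embedding_dim)
        self.char_convs = conv_stack(self.char_encoder.out_width)

        self.trunk: list[HalfStatefulBiRNN] = []
        n_in = 2 * config.conv_filters
        for _ in range(config.trunk_rnn_layers):
            self.trunk.append(HalfStatefulBiRNN(n_in, config.trunk_rnn_cells, rng, cell))
            n_in = 2 * config.trunk_rnn_cells
        trunk_out = n_in

        self.part_rnn = HalfStatefulBiRNN(trunk_out, config.head_rnn_cells, rng, cell)
        self.part_head = Dense(2 * config.head_rnn_cells, 1, rng, activation="sigmoid")
        self.start_rnn = HalfStatefulBiRNN(trunk_out, config.head_rnn_cells, rng, cell)
        self.start_head = Dense(2 * config.head_rnn_cells, 1, rng, activation="sigmoid")

    # -- plumbing -------------------------------------------------------------

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in (
            [self.word_embedding, self.char_embedding, self.char_encoder]
            + self.word_convs + self.char_convs + self.trunk
            + [self.part_rnn, self.part_head, self.start_rnn, self.start_head]
        ):
            out += layer.params()
        return out

    def reset_states(self) -> None:
        for rnn in self.trunk + [self.part_rnn, self.start_rnn]:
            rnn.reset_state()

    # -- forward ----------------------------------------------------------------

    def forward(
        self,
        word_ids: np.ndarray,
        char_ids: np.ndarray,
        mask: np.ndarray | None = None,
        reset_mask: np.ndarray | None = None,
        part_override: np.ndarray | None = None,
        return_internals: bool = False,
    ):
        """One chunk batch forward: (part_prob, start_prob), each (B, T).

        ``mask`` (B, T) zeroes embedded features and freezes recurrent state
        at padded token positions, keeping padding inert.  ``part_override``
        replaces the part head's probabilities at the multiplication node (a
        probe used to verify the coupling contract).  ``return_internals``
        appends a dict with the trunk output and the multiplied (coupled)
        features.
        """
        b, t = word_ids.shape
        # character branch: per-token biRNN over (possibly width-trimmed) chars
        width = max(1, int((char_ids != 0).sum(axis=-1).max()) if char_ids.size else 1)
        chars = char_ids[:, :, :width]
        ce = self.char_embedding(chars.reshape(b * t, width))
        token_vec = self.char_encoder(ce).reshape(b, t, self.char_encoder.out_width)
        we = self.word_embedding(word_ids)
        if mask is not None:
            m = Tensor(mask[..., None].astype(np.float64))
            we = we * m
            token_vec = token_vec * m

        hw, hc = we, token_vec
        for conv in self.word_convs:
            hw = conv(hw)
        for conv in self.char_convs:
            hc = conv(hc)

        from .nn import concat

        h = concat([hw, hc], axis=-1)
        for rnn in self.trunk:
            h = rnn(h, reset_mask=reset_mask, step_mask=mask)

        part = self.part_head(self.part_rnn(h, reset_mask=reset_mask, step_mask=mask))
        gate = Tensor(part_override[..., None]) if part_override is not None else part
        coupled = h * gate  # scalar per step scales every channel
        start = self.start_head(self.start_rnn(coupled, reset_mask=reset_mask,
                                               step_mask=mask))
        if return_internals:
            return part.reshape(b, t), start.reshape(b, t), \
                {"trunk": h, "coupled": coupled}
        return part.reshape(b, t), start.reshape(b, t)

    def loss_on_chunk(self, chunk: dict) -> Tensor:
        part, start = self.forward(chunk["words"], chunk["chars"],
                                   mask=chunk["mask"],
                                   reset_mask=chunk.get("reset"))
        return masked_bce(part, chunk["e"], chunk["mask"]) + \
            masked_bce(start, chunk["s"], chunk["mask"])

    # -- data -> chunks --------------------------------------------------------

    def make_chunks(
        self, sections: Sequence[SectionTokens], with_labels: bool = True
    ) -> tuple[list[dict], BatchPlan]:
        lengths = [len(s.tokens) for s in sections]
        plan = make_plan(lengths, self.config.batch_size, self.config.window_length)
        w_chunks, masks = build_chunks([s.word_ids for s in sections], plan)
        c_chunks, _ = build_chunks([s.char_ids for s in sections], plan)
        resets = (
            text_start_masks(plan)
            if self.config.reset_state_at_text_boundaries
            else [None] * plan.total_chunks
        )
        chunks = []
        if with_labels:
            s_chunks, _ = build_chunks([s.s_flags for s in sections], plan)
            e_chunks, _ = build_chunks([s.e_flags for s in sections], plan)
            for w, c, sl, el, m, r in zip(w_chunks, c_chunks, s_chunks, e_chunks, masks, resets):
                chunks.append({"words": w, "chars": c, "s": sl, "e": el,
                               "mask": m, "reset": r})
        else:
            for w, c, m, r in zip(w_chunks, c_chunks, masks, resets):
                chunks.append({"words": w, "chars": c, "mask": m, "reset": r})
        return chunks, plan

    # -- persistence --------------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config)), encoding="utf-8")
        self.word_vocab.save(d / "word_vocab.json")
        self.char_vocab.save(d / "char_vocab.json")
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        arrays["word_embeddings"] = self.word_embedding.table.data
        np.savez(d / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "NerModel":
        d = Path(directory)
        config = NerConfig(**json.loads((d / "config.json").read_text(encoding="utf-8")))
        word_vocab = WordVocab.load(d / "word_vocab.json")
        char_vocab = CharVocab.load(d / "char_vocab.json")
        with np.load(d / "weights.npz") as data:
            model = cls(config, data["word_embeddings"], char_vocab, word_vocab)
            for i, p in enumerate(model.params()):
                p.data = data[f"p{i}"]
            model.word_embedding.table.data = data["word_embeddings"]
        return model


# ---------------------------------------------------------------------------
# training, prediction, ensembling


def train_ner_model(
    train_sections: Sequence[SectionTokens],
    val_sections: Sequence[SectionTokens],
    config: NerConfig,
    word_embeddings: np.ndarray,
    word_vocab: WordVocab,
    char_vocab: CharVocab,
    seed: int = 0,
) -> tuple[NerModel, TrainHistory]:
    """Train one network; best-on-validation-loss weights are retained."""
    if not train_sections:
        raise ValueError("no training sections")
    model = NerModel(config, word_embeddings, char_vocab, word_vocab, seed=seed)
    train_chunks, _ = model.make_chunks(train_sections)
    val_chunks, _ = model.make_chunks(val_sections) if val_sections else ([], None)
    history = fit_stateful(model, train_chunks, val_chunks or [],
                           config.epochs, config.learning_rate)
    return model, history


def predict_probs(
    model: NerModel, sections: Sequence[SectionTokens]
) -> list[np.ndarray]:
    """Per-section (n_tokens, 2) arrays of [part_prob, start_prob]."""
    if not sections:
        return []
    chunks, plan = model.make_chunks(sections, with_labels=False)
    model.reset_states()
    outs = []
    with no_grad():
        for chunk in chunks:
            part, start = model.forward(chunk["words"], chunk["chars"],
                                        mask=chunk["mask"],
                                        reset_mask=chunk.get("reset"))
            outs.append(np.stack([part.data, start.data], axis=-1))
    return unbatch(outs, plan)


def ensemble_average(runs: Sequence[Sequence[np.ndarray]]) -> list[np.ndarray]:
    """Arithmetic mean of per-token probabilities over independently trained
    networks.  All runs must cover the same texts under the same
    tokenisation."""
    if not runs:
        raise ValueError("no runs to average")
    n_texts = len(runs[0])
    for run in runs:
        if len(run) != n_texts:
            raise ValueError("runs cover different numbers of texts")
        for a, b in zip(run, runs[0]):
            if a.shape != b.shape:
                raise ValueError("misaligned runs: differing sequence shapes")
    # mean computed as base + mean(deviations): exact when all runs coincide
    out = []
    for i in range(n_texts):
        base = runs[0][i]
        out.append(base + np.mean([run[i] - base for run in runs], axis=0))
    return out


def train_ensemble(
    train_sections: Sequence[SectionTokens],
    val_sections: Sequence[SectionTokens],
    config: NerConfig,
    word_embeddings: np.ndarray,
    word_vocab: WordVocab,
    char_vocab: CharVocab,
    seed: int = 0,
) -> list[NerModel]:
    """Train ``config.ensemble_size`` networks with member seeds derived as
    ``seed + member_index``."""
    return [
        train_ner_model(train_sections, val_sections, config, word_embeddings,
                        word_vocab, char_vocab, seed=seed + member)[0]
        for member in range(config.ensemble_size)
    ]
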