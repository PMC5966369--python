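"""Break-and-stitch targeted tokenisation.

Chemical names defeat rule-based tokenisers: systematic nomenclature is rich
in hyphens, digits, brackets and commas, so any fixed punctuation policy
either shreds entities or glues them to surrounding prose.  Instead of rules,
the text is first *over*-segmented with the deliberately fine pattern
``\\w+|[^\\s\\w]`` (maximal runs of Unicode word characters; every other
non-whitespace character on its own), and a lightweight character-level
CNN-RNN model is then trained to mark *stitch points* — positions whose
fragment must be merged back into the preceding fragment to restore an
entity-sized token.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .batching import build_chunks, make_plan, unbatch
from .corpus import Document, EntitySpan, Token
from .nn import Conv1D, Dense, Embedding, HalfStatefulBiRNN, Tensor
from .nn.autograd import no_grad
from .training import fit_stateful
from .vocab import CharVocab

__all__ = [
    "PRIMARY_PATTERN",
    "StitchModelConfig",
    "StitchModel",
    "TokenizerMetrics",
    "primary_segment",
    "derive_stitch_tags",
    "apply_stitches",
    "tokenizer_metrics",
    "train_stitch_model",
]

#: Primary over-segmentation: runs of Unicode word characters, or any single
#: character that is neither whitespace nor a word character.
PRIMARY_PATTERN = re.compile(r"\w+|[^\s\w]")


def primary_segment(text: str) -> list[Token]:
    """Extra-fine first-pass segmentation of ``text``.

    Covers every non-whitespace character exactly once; joining the tokens
    with the original gap characters reconstructs the input exactly.
    """
    return [Token(m.group(), m.start(), m.end()) for m in PRIMARY_PATTERN.finditer(text)]


def derive_stitch_tags(
    text: str, tokens: Sequence[Token], spans: Sequence[EntitySpan]
) -> np.ndarray:
    """Gold stitch tags for one section: boolean per character.

    A character is tagged when it is the first character of a token whose
    predecessor lies inside the same gold span and is immediately adjacent
    (zero gap).  Applying these tags reconstructs each contiguous
    (whitespace-free) gold entity as a single token.
    """
    tags = np.zeros(len(text), dtype=bool)
    for prev, tok in zip(tokens, tokens[1:]):
        if prev.end != tok.start:
            continue  # gap characters between fragments: never stitch
        for sp in spans:
            if sp.start <= prev.start and tok.end <= sp.end:
                tags[tok.start] = True
                break
    return tags


def apply_stitches(
    tokens: Sequence[Token], tags: np.ndarray, threshold: float = 0.5
) -> list[Token]:
    """Merge adjacent fragments at positive stitch points.

    A fragment is merged into its predecessor when the two are immediately
    adjacent (no intervening characters) and the tag value at the fragment's
    first character exceeds ``threshold``.  Merging is transitive along runs.
    Tags at or below threshold — or any whitespace gap — leave tokens intact,
    so an all-false tag vector is the identity.
    """
    tags = np.asarray(tags)
    out: list[Token] = []
    for tok in tokens:
        if (
            out
            and out[-1].end == tok.start
            and tok.start < len(tags)
            and float(tags[tok.start]) > threshold
        ):
            prev = out.pop()
            out.append(Token(prev.text + tok.text, prev.start, tok.end))
        else:
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# tokeniser quality


@dataclass(frozen=True)
class TokenizerMetrics:
    """Corpus statistics of a tokenisation against gold entities.

    ``entity_recall`` — fraction of gold spans exactly recoverable as a
    contiguous token run whose outer boundaries coincide with the span and
    which no token crosses.  ``entity_precision`` — fraction of *stitched*
    (multi-fragment) tokens whose boundaries exactly match a gold span.
    ``overlap_rate`` — fraction of gold spans made unrecoverable because some
    token straddles the span boundary (fusing entity and non-entity
    characters, or two entities).
    """

    entity_recall: float
    entity_precision: float
    overlap_rate: float
    n_gold: int
    n_recovered: int
    n_merged_tokens: int
    n_correct_merges: int
    n_overlapping: int


def _is_merged(token: Token) -> bool:
    # a token the primary pattern could not have produced must be stitched
    return len(primary_segment(token.text)) > 1


def tokenizer_metrics(
    spans: Sequence[EntitySpan], tokens: Sequence[Token]
) -> TokenizerMetrics:
    """Score one section's final tokenisation against its gold spans."""
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i for i, t in enumerate(tokens)}
    n_recovered = 0
    n_overlap = 0
    for sp in spans:
        crossed = any(
            t.start < sp.end and t.end > sp.start and (t.start < sp.start or t.end > sp.end)
            for t in tokens
        )
        if crossed:
            n_overlap += 1
        elif sp.start in starts and sp.end in ends and starts[sp.start] <= ends[sp.end]:
            n_recovered += 1
    span_keys = {(sp.start, sp.end) for sp in spans}
    merged = [t for t in tokens if _is_merged(t)]
    n_correct = sum((t.start, t.end) in span_keys for t in merged)
    n_gold = len(spans)
    return TokenizerMetrics(
        entity_recall=n_recovered / n_gold if n_gold else 1.0,
        entity_precision=n_correct / len(merged) if merged else 1.0,
        overlap_rate=n_overlap / n_gold if n_gold else 0.0,
        n_gold=n_gold,
        n_recovered=n_recovered,
        n_merged_tokens=len(merged),
        n_correct_merges=n_correct,
        n_overlapping=n_overlap,
    )


def combine_metrics(parts: Sequence[TokenizerMetrics]) -> TokenizerMetrics:
    """Pool per-section counts into corpus-level rates."""
    n_gold = sum(p.n_gold for p in parts)
    n_rec = sum(p.n_recovered for p in parts)
    n_mrg = sum(p.n_merged_tokens for p in parts)
    n_cor = sum(p.n_correct_merges for p in parts)
    n_ovl = sum(p.n_overlapping for p in parts)
    return TokenizerMetrics(
        entity_recall=n_rec / n_gold if n_gold else 1.0,
        entity_precision=n_cor / n_mrg if n_mrg else 1.0,
        overlap_rate=n_ovl / n_gold if n_gold else 0.0,
        n_gold=n_gold,
        n_recovered=n_rec,
        n_merged_tokens=n_mrg,
        n_correct_merges=n_cor,
        n_overlapping=n_ovl,
    )


# ---------------------------------------------------------------------------
# the stitch-point model


@dataclass
class StitchModelConfig:
    """Architecture and training settings of the stitch-point model.

    Defaults follow the reference design: a linear character embedding, two
    256-filter width-3 convolution layers, two half-stateful bidirectional
    GRU layers of 32 cells, and a per-character sigmoid classifier.
    """

    char_embedding_dim: int = 32
    conv_layers: int = 2
    conv_filters: int = 256
    conv_width: int = 3
    rnn_layers: int = 2
    rnn_cells: int = 32
    rnn_cell_type: str = "GRU"
    batch_size: int = 32
    window_length: int = 128
    epochs: int = 40
    learning_rate: float = 1e-3
    threshold: float = 0.5

    def validate(self) -> None:
        for name in ("char_embedding_dim", "conv_layers", "conv_filters",
                     "conv_width", "rnn_layers", "rnn_cells", "batch_size",
                     "window_length", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.rnn_cell_type.upper() not in ("GRU", "LSTM"):
            raise ValueError(f"unknown rnn_cell_type {self.rnn_cell_type!r}")


class StitchModel:
    """Character-level sequence-to-sequence stitch-point classifier."""

    def __init__(self, config: StitchModelConfig, char_vocab: CharVocab, seed: int = 0):
        config.validate()
        self.config = config
        self.char_vocab = char_vocab
        rng = np.random.default_rng(seed)
        self.embedding = Embedding(len(char_vocab), config.char_embedding_dim, rng)
        self.convs: list[Conv1D] = []
        width_in = config.char_embedding_dim
        for _ in range(config.conv_layers):
            self.convs.append(Conv1D(width_in, config.conv_filters, config.conv_width, rng))
            width_in = config.conv_filters
        self.rnns: list[HalfStatefulBiRNN] = []
        for _ in range(config.rnn_layers):
            self.rnns.append(
                HalfStatefulBiRNN(width_in, config.rnn_cells, rng, config.rnn_cell_type)
            )
            width_in = 2 * config.rnn_cells
        self.head = Dense(width_in, 1, rng, activation="sigmoid")

    def params(self) -> list[Tensor]:
        out = self.embedding.params()
        for layer in self.convs + self.rnns:
            out += layer.params()
        return out + self.head.params()

    def reset_states(self) -> None:
        for rnn in self.rnns:
            rnn.reset_state()

    def forward(self, char_ids: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        """Per-character stitch probabilities for a (batch, window) id chunk.

        ``mask`` zeroes the embedded features at padded steps and freezes the
        recurrent state there, keeping padding inert.
        """
        h = self.embedding(char_ids)
        if mask is not None:
            h = h * Tensor(mask[..., None].astype(np.float64))
        for conv in self.convs:
            h = conv(h)
        for rnn in self.rnns:
            h = rnn(h, step_mask=mask)
        return self.head(h).reshape(*char_ids.shape)

    def loss_on_chunk(self, chunk: dict) -> Tensor:
        from .nn import masked_bce

        probs = self.forward(chunk["chars"], chunk["mask"])
        return masked_bce(probs, chunk["tags"], chunk["mask"])

    # -- data preparation ----------------------------------------------------

    def _chunkify(self, texts: Sequence[str], tags: Sequence[np.ndarray] | None):
        lengths = [len(t) for t in texts]
        plan = make_plan(lengths, self.config.batch_size, self.config.window_length)
        char_seqs = [self.char_vocab.encode(t) for t in texts]
        x_chunks, masks = build_chunks(char_seqs, plan)
        out = []
        if tags is not None:
            y_chunks, _ = build_chunks([t.astype(np.float64) for t in tags], plan)
            for x, y, m in zip(x_chunks, y_chunks, masks):
                out.append({"chars": x, "tags": y, "mask": m})
        else:
            for x, m in zip(x_chunks, masks):
                out.append({"chars": x, "mask": m})
        return out, plan

    def predict_tags(self, texts: Sequence[str]) -> list[np.ndarray]:
        """Per-character stitch probabilities for raw texts; whitespace
        positions are forced to zero."""
        nonempty = [i for i, t in enumerate(texts) if t]
        out: list[np.ndarray] = [np.zeros(len(t)) for t in texts]
        if not nonempty:
            return out
        chunks, plan = self._chunkify([texts[i] for i in nonempty], None)
        self.reset_states()
        probs = []
        with no_grad():
            for chunk in chunks:
                probs.append(self.forward(chunk["chars"], chunk["mask"]).data)
        per_text = unbatch(probs, plan)
        for i, p in zip(nonempty, per_text):
            text = texts[i]
            p = p.copy()
            ws = np.fromiter((c.isspace() for c in text), dtype=bool, count=len(text))
            p[ws] = 0.0
            out[i] = p
        return out

    def tokenize(self, text: str, threshold: float | None = None) -> list[Token]:
        """Primary segmentation refined by predicted stitch points."""
        tags = self.predict_tags([text])[0]
        thr = self.config.threshold if threshold is None else threshold
        return apply_stitches(primary_segment(text), tags, thr)

    # -- persistence -----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config)), encoding="utf-8")
        self.char_vocab.save(d / "char_vocab.json")
        np.savez(d / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(self.params())})

    @classmethod
    def load(cls, directory: str | Path) -> "StitchModel":
        d = Path(directory)
        config = StitchModelConfig(**json.loads((d / "config.json").read_text(encoding="utf-8")))
        vocab = CharVocab.load(d / "char_vocab.json")
        model = cls(config, vocab)
        with np.load(d / "weights.npz") as data:
            for i, p in enumerate(model.params()):
                p.data = data[f"p{i}"]
        return model


def train_stitch_model(
    documents: Sequence[Document],
    spans: Sequence[EntitySpan],
    config: StitchModelConfig | None = None,
    validation_fraction: float = 0.1,
    seed: int = 0,
):
    """Train a stitch-point model on a gold-annotated corpus.

    Stitch labels are derived from the gold spans over the primary
    segmentation of every section.  A document-level split reserves
    ``validation_fraction`` of the corpus to monitor the loss; the weights of
    the best validation epoch are retained.

    Returns ``(model, history)``.
    """
    if not documents:
        raise ValueError("empty corpus")
    config = config or StitchModelConfig()
    config.validate()
    by_doc: dict[tuple[str, str], list[EntitySpan]] = {}
    for sp in spans:
        by_doc.setdefault((sp.doc_id, sp.section), []).append(sp)

    texts: list[str] = []
    tags: list[np.ndarray] = []
    owners: list[int] = []
    for di, doc in enumerate(documents):
        for section in ("title", "abstract"):
            text = doc.section_text(section)
            if not text:
                continue
            sec_spans = by_doc.get((doc.doc_id, section), [])
            toks = primary_segment(text)
            texts.append(text)
            tags.append(derive_stitch_tags(text, toks, sec_spans))
            owners.append(di)

    rng = np.random.default_rng(seed)
    doc_order = rng.permutation(len(documents))
    n_val_docs = max(1, int(round(validation_fraction * len(documents)))) \
        if len(documents) > 1 else 0
    val_docs = set(doc_order[:n_val_docs].tolist())
    train_idx = [i for i, o in enumerate(owners) if o not in val_docs]
    val_idx = [i for i, o in enumerate(owners) if o in val_docs]

    vocab = CharVocab.build(texts[i] for i in train_idx)
    model = StitchModel(config, vocab, seed=seed)
    train_chunks, _ = model._chunkify([texts[i] for i in train_idx],
                                      [tags[i] for i in train_idx])
    val_chunks, _ = (model._chunkify([texts[i] for i in val_idx],
                                     [tags[i] for i in val_idx])
                     if val_idx else ([], None))
    history = fit_stateful(model, train_chunks, val_chunks or [],
                           config.epochs, config.learning_rate)
    return model, history
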