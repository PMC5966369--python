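"""Synthetic CHEMDNER-dialect corpora with controllable statistics.

The generator emits abstracts whose filler text is Zipf-distributed
pseudo-words, with chemical-entity surface forms planted at a configurable
density.  Surface morphology per class mimics what the tokeniser and the
network must cope with: hyphen/digit/bracket-rich systematic names (always
split by the primary segmentation, guaranteeing stitch-training signal),
formula-like strings, short uppercase abbreviations, identifier codes,
recurring trivial/family names, and space-containing MULTIPLE phrases.  No
attempt is made at chemically valid nomenclature — only surface shape
matters here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Document, EntitySpan, write_abstracts, write_annotations

__all__ = ["SynthParams", "generate_entity", "generate_corpus"]

#: Class mixture of the CHEMDNER gold annotations (fractions of all entities).
DEFAULT_CLASS_MIXTURE = {
    "ABBREVIATION": 0.1555,
    "FAMILY": 0.1415,
    "FORMULA": 0.1426,
    "IDENTIFIER": 0.0216,
    "MULTIPLE": 0.0070,
    "SYSTEMATIC": 0.2269,
    "TRIVIAL": 0.3036,
    "NO CLASS": 0.0013,
}

_MORPHEMES = [
    "meth", "eth", "prop", "but", "pent", "hex", "amino", "chloro", "bromo",
    "fluoro", "hydroxy", "oxo", "phenyl", "imidazo", "pyrid", "benz", "acet",
    "nitro", "sulfo", "carb", "oxy", "cyclo", "thio", "keto",
]
_SUFFIXES = ["ane", "ene", "ol", "one", "ine", "ate", "ide", "yl", "oxide", "amine"]
_ELEMENTS = ["C", "H", "N", "O", "S", "P", "Cl", "Na", "K", "Ca", "Fe", "Mg"]
_CONSONANTS = "bdfgjklmnprstvwz"
_VOWELS = "aeiou"


@dataclass
class SynthParams:
    """Knobs of the generator; defaults are the package's study conditions."""

    n_documents: int = 200
    title_tokens_mean: float = 8.0
    abstract_tokens_mean: float = 40.0
    entity_density: float = 10.0  # entities per 100 tokens
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    bracket_rate: float = 0.35  # chance a systematic name carries a bracket group
    hyphen_fragments_min: int = 2
    hyphen_fragments_max: int = 4
    filler_vocab_size: int = 500
    zipf_exponent: float = 1.2
    filler_hyphen_rate: float = 0.02  # hyphenated non-entity compounds
    punctuation_rate: float = 0.12  # chance of , or . glued after a token
    allow_adjacent_entities: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be positive")
        if self.entity_density < 0:
            raise ValueError("entity_density must be non-negative")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        if self.filler_vocab_size < 1 or self.zipf_exponent <= 0:
            raise ValueError("bad filler vocabulary parameters")


# ---------------------------------------------------------------------------
# surface forms


def _pseudo_word(rng: np.random.Generator, n_syllables: int | None = None) -> str:
    n = int(rng.integers(2, 5)) if n_syllables is None else n_syllables
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS)) for _ in range(n)
    )


def _trivial_name(rng: np.random.Generator) -> str:
    return rng.choice(_MORPHEMES) + rng.choice(_MORPHEMES) + rng.choice(_SUFFIXES)


def generate_entity(entity_class: str, params: SynthParams,
                    rng: np.random.Generator) -> str:
    """One surface string of the requested class.

    Systematic-style names always contain at least one non-word character (a
    hyphen), so the primary segmentation is guaranteed to split them;
    MULTIPLE phrases always contain internal spaces.
    """
    if entity_class == "SYSTEMATIC":
        n_frag = int(rng.integers(params.hyphen_fragments_min,
                                  params.hyphen_fragments_max + 1))
        parts = [str(rng.integers(1, 10))]
        for _ in range(n_frag):
            parts.append(rng.choice(_MORPHEMES) + rng.choice(_MORPHEMES))
        name = "-".join(parts) + rng.choice(_SUFFIXES)
        if rng.random() < params.bracket_rate:
            a, b = rng.integers(1, 8), rng.integers(1, 8)
            letter = rng.choice(list("abcd"))
            name += f"[{a},{b}-{letter}]" + rng.choice(_MORPHEMES) + rng.choice(_SUFFIXES)
        return name
    if entity_class == "TRIVIAL":
        return _trivial_name(rng)
    if entity_class == "FAMILY":
        return _trivial_name(rng) + "s"
    if entity_class == "FORMULA":
        n_pairs = int(rng.integers(2, 5))
        s = "".join(
            rng.choice(_ELEMENTS) + (str(rng.integers(2, 13)) if rng.random() < 0.7 else "")
            for _ in range(n_pairs)
        )
        if rng.random() < 0.25:
            s += "(" + rng.choice(_ELEMENTS) + rng.choice(_ELEMENTS).lower() + ")" + \
                str(rng.integers(2, 5))
        return s
    if entity_class == "ABBREVIATION":
        n = int(rng.integers(2, 6))
        return "".join(rng.choice(list("ABCDEFGHIKLMNOPRSTUV")) for _ in range(n))
    if entity_class == "IDENTIFIER":
        prefix = rng.choice(["CID", "CHEMBL", "DB"])
        return prefix + "".join(str(rng.integers(0, 10)) for _ in range(int(rng.integers(4, 7))))
    if entity_class == "MULTIPLE":
        joiner = rng.choice([" and ", " or "])
        return _trivial_name(rng) + joiner + _trivial_name(rng)
    if entity_class == "NO CLASS":
        return _pseudo_word(rng, 3) + rng.choice(_SUFFIXES)
    raise ValueError(f"unknown entity class {entity_class!r}")


# ---------------------------------------------------------------------------
# corpus assembly


def _filler_vocab(params: SynthParams, rng: np.random.Generator) -> list[str]:
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < params.filler_vocab_size:
        w = _pseudo_word(rng)
        if w not in seen:
            seen.add(w)
            vocab.append(w)
    return vocab


def _zipf_probs(n: int, a: float) -> np.ndarray:
    p = 1.0 / np.arange(1, n + 1) ** a
    return p / p.sum()


def _section(
    n_tokens: int,
    n_entities: int,
    params: SynthParams,
    vocab: list[str],
    probs: np.ndarray,
    classes: list[str],
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Build one section; returns (text, [(start, end, surface, class)])."""
    n_tokens = max(n_tokens, 2 * n_entities + 1 if n_entities else 1)
    positions: list[int] = []
    if n_entities:
        candidates = list(range(n_tokens))
        rng.shuffle(candidates)
        for pos in candidates:
            if len(positions) == n_entities:
                break
            if params.allow_adjacent_entities or all(abs(pos - q) > 1 for q in positions):
                positions.append(pos)
    entity_at = {}
    for pos, cls in zip(sorted(positions), classes):
        entity_at[pos] = cls

    text_parts: list[str] = []
    spans: list[tuple[int, int, str, str]] = []
    offset = 0
    for i in range(n_tokens):
        if i > 0:
            text_parts.append(" ")
            offset += 1
        if i in entity_at:
            cls = entity_at[i]
            surface = generate_entity(cls, params, rng)
            spans.append((offset, offset + len(surface), surface, cls))
            text_parts.append(surface)
            offset += len(surface)
        else:
            w = rng.choice(vocab, p=probs)
            if rng.random() < params.filler_hyphen_rate:
                w = w + "-" + rng.choice(vocab, p=probs)
            text_parts.append(w)
            offset += len(w)
        if rng.random() < params.punctuation_rate:
            p = "." if rng.random() < 0.5 else ","
            text_parts.append(p)
            offset += 1
    return "".join(text_parts), spans


def generate_corpus(
    params: SynthParams | None = None, out_dir: str | Path | None = None
) -> tuple[list[Document], list[EntitySpan]]:
    """Generate a corpus; optionally write the CHEMDNER-dialect files.

    The same ``params.seed`` always yields byte-identical output.  When
    ``out_dir`` is given, writes ``abstracts.tsv``, ``annotations.tsv`` and a
    ``params.json`` sidecar there.
    """
    params = params or SynthParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    vocab = _filler_vocab(params, rng)
    probs = _zipf_probs(len(vocab), params.zipf_exponent)
    class_names = list(params.class_mixture.keys())
    class_probs = np.array([params.class_mixture[c] for c in class_names])

    documents: list[Document] = []
    spans: list[EntitySpan] = []
    for d in range(params.n_documents):
        doc_id = f"SYN{d:05d}"
        sections: dict[str, str] = {}
        for section, mean in (("title", params.title_tokens_mean),
                              ("abstract", params.abstract_tokens_mean)):
            n_tokens = max(1, int(rng.poisson(mean)))
            expected = n_tokens * params.entity_density / 100.0
            n_entities = int(np.floor(expected))
            if rng.random() < expected - n_entities:
                n_entities += 1
            classes = [class_names[i] for i in
                       rng.choice(len(class_names), size=n_entities, p=class_probs)]
            text, sec_spans = _section(n_tokens, n_entities, params, vocab,
                                       probs, classes, rng)
            sections[section] = text
            for start, end, surface, cls in sec_spans:
                spans.append(EntitySpan(doc_id, section, start, end, surface, cls))
        documents.append(Document(doc_id, sections["title"], sections["abstract"]))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abstracts(out / "abstracts.tsv", documents)
        write_annotations(out / "annotations.tsv", spans)
        (out / "params.json").write_text(json.dumps(asdict(params), indent=2),
                                         encoding="utf-8")
    return documents, spans
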