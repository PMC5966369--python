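"""CHEMDNER-dialect corpus reading/writing and span <-> label conversions.

A corpus is distributed as two UTF-8 tab-separated files:

* abstracts file — one record per line: ``doc_id<TAB>title<TAB>abstract``;
* annotations file — one record per line:
  ``doc_id<TAB>{T|A}<TAB>start<TAB>end<TAB>text<TAB>class``.

Entity annotations are character-offset spans over a *section* (the title or
the abstract of one document, each treated as an independent character
sequence).  Offsets are 0-based, end-exclusive, counted in Unicode code
points.  Internally every character (or token) carries a pair of boolean
labels ``(s, e)``: *s* — the position begins a chemical entity; *e* — the
position is part of one.  ``s`` implies ``e``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ENTITY_CLASSES",
    "Document",
    "EntitySpan",
    "LabelPair",
    "Token",
    "read_abstracts",
    "write_abstracts",
    "read_annotations",
    "write_annotations",
    "spans_to_char_labels",
    "char_labels_to_token_labels",
    "token_labels_to_spans",
    "char_labels_to_spans",
]

#: The eight CHEMDNER entity classes (file dialect spells NO CLASS with a space).
ENTITY_CLASSES = (
    "ABBREVIATION",
    "FAMILY",
    "FORMULA",
    "IDENTIFIER",
    "MULTIPLE",
    "SYSTEMATIC",
    "TRIVIAL",
    "NO CLASS",
)

_SECTION_CODES = {"T": "title", "A": "abstract"}
_SECTION_NAMES = {v: k for k, v in _SECTION_CODES.items()}


class CorpusError(ValueError):
    """Malformed corpus file or inconsistent annotation."""


@dataclass(frozen=True)
class Document:
    """One abstract record: an id plus two independent text sections."""

    doc_id: str
    title: str
    abstract: str

    def section_text(self, section: str) -> str:
        if section == "title":
            return self.title
        if section == "abstract":
            return self.abstract
        raise ValueError(f"unknown section {section!r}")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A character-offset entity mention within one section of a document.

    ``entity_class`` is ``None`` for predictions (the NER model is
    class-agnostic).
    """

    doc_id: str
    section: str  # "title" | "abstract"
    start: int  # 0-based inclusive, code points
    end: int  # 0-based exclusive
    text: str
    entity_class: str | None = None

    def __post_init__(self) -> None:
        if self.section not in ("title", "abstract"):
            raise ValueError(f"bad section {self.section!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad offsets [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Identity used by exact-match scoring: (doc, section, start, end)."""
        return (self.doc_id, self.section, self.start, self.end)


@dataclass(frozen=True)
class LabelPair:
    """The two-flag label: s = begins an entity, e = part of an entity."""

    s: bool
    e: bool

    def __post_init__(self) -> None:
        if self.s and not self.e:
            raise ValueError("label invariant violated: s implies e")


@dataclass(frozen=True)
class Token:
    """A whitespace-free substring with its character offsets."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.text):
            raise ValueError("token length does not match its offsets")


# ---------------------------------------------------------------------------
# file IO


def read_abstracts(path: str | Path) -> list[Document]:
    """Read an abstracts file; one :class:`Document` per line, in file order."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            doc_id, title, abstract = fields
            if not doc_id:
                raise CorpusError(f"{path}:{lineno}: empty doc_id")
            if doc_id in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(path: str | Path, docs: Iterable[Document]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            for field in (d.doc_id, d.title, d.abstract):
                if "\t" in field or "\n" in field:
                    raise CorpusError(
                        f"document {d.doc_id!r}: fields may not contain tabs/newlines"
                    )
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_annotations(
    path: str | Path,
    corpus: Sequence[Document],
    *,
    require_class: bool = True,
) -> list[EntitySpan]:
    """Read an annotations file, validating every span against the corpus.

    Each span's offsets must select exactly the recorded text from the
    referenced section, and gold spans may not overlap within a section.
    """
    by_id = {d.doc_id: d for d in corpus}
    spans: list[EntitySpan] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CorpusError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            doc_id, code, start_s, end_s, text, cls = fields
            if doc_id not in by_id:
                raise CorpusError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            if code not in _SECTION_CODES:
                raise CorpusError(f"{path}:{lineno}: bad section code {code!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: non-integer offsets") from exc
            section = _SECTION_CODES[code]
            sec_text = by_id[doc_id].section_text(section)
            if not (0 <= start < end <= len(sec_text)):
                raise CorpusError(
                    f"{path}:{lineno}: offsets [{start}, {end}) out of range for "
                    f"{doc_id}/{section} (length {len(sec_text)})"
                )
            if sec_text[start:end] != text:
                raise CorpusError(
                    f"{path}:{lineno}: text mismatch in {doc_id}/{section} at "
                    f"[{start}, {end}): file says {text!r}, section has "
                    f"{sec_text[start:end]!r}"
                )
            if require_class and cls not in ENTITY_CLASSES:
                raise CorpusError(f"{path}:{lineno}: unknown entity class {cls!r}")
            spans.append(
                EntitySpan(doc_id, section, start, end, text,
                           cls if cls in ENTITY_CLASSES else None)
            )
    _check_no_overlap(spans)
    return spans


def write_annotations(
    path: str | Path,
    spans: Iterable[EntitySpan],
    *,
    placeholder_class: str = "NO CLASS",
) -> None:
    """Write spans in the annotations dialect.

    Predictions (class ``None``) get ``placeholder_class`` in the class
    column since the model does not discriminate between entity types.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sp in spans:
            cls = sp.entity_class if sp.entity_class is not None else placeholder_class
            code = _SECTION_NAMES[sp.section]
            fh.write(f"{sp.doc_id}\t{code}\t{sp.start}\t{sp.end}\t{sp.text}\t{cls}\n")


def _check_no_overlap(spans: Sequence[EntitySpan]) -> None:
    by_section: dict[tuple[str, str], list[EntitySpan]] = {}
    for sp in spans:
        by_section.setdefault((sp.doc_id, sp.section), []).append(sp)
    for (doc_id, section), group in by_section.items():
        group = sorted(group, key=lambda s: (s.start, s.end))
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise CorpusError(
                    f"overlapping gold spans in {doc_id}/{section}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


# ---------------------------------------------------------------------------
# span <-> label conversions


def spans_to_char_labels(text: str, spans: Sequence[EntitySpan]) -> list[LabelPair]:
    """Per-character (s, e) labels: e inside any span, s at each span's start."""
    _check_no_overlap(list(spans))
    s = [False] * len(text)
    e = [False] * len(text)
    for sp in spans:
        if sp.end > len(text):
            raise CorpusError(f"span [{sp.start},{sp.end}) exceeds text length {len(text)}")
        s[sp.start] = True
        for i in range(sp.start, sp.end):
            e[i] = True
    return [LabelPair(si, ei) for si, ei in zip(s, e)]


def char_labels_to_token_labels(
    tokens: Sequence[Token], char_labels: Sequence[LabelPair]
) -> list[LabelPair]:
    """Project character labels onto tokens: a flag is true if any covered
    character carries it."""
    out: list[LabelPair] = []
    for tok in tokens:
        if tok.end > len(char_labels):
            raise CorpusError("token extends beyond the labelled text")
        window = char_labels[tok.start : tok.end]
        out.append(LabelPair(any(l.s for l in window), any(l.e for l in window)))
    return out


def token_labels_to_spans(
    tokens: Sequence[Token],
    token_labels: Sequence[LabelPair],
    *,
    doc_id: str = "",
    section: str = "abstract",
    text: str | None = None,
) -> list[EntitySpan]:
    """Decode (s, e) token labels into entity spans.

    A span opens at a token with ``s`` set, or at a token with ``e`` set whose
    predecessor has ``e`` unset (a missed start flag never drops a detected
    entity body), and extends over the maximal following run of ``e``-set,
    ``s``-unset tokens.  Offsets are [first token start, last token end).
    """
    if len(tokens) != len(token_labels):
        raise ValueError("labels must align one-to-one with tokens")
    spans: list[EntitySpan] = []
    open_start: int | None = None
    prev_end = 0

    def close(upto: int) -> None:
        nonlocal open_start
        if open_start is not None:
            spantext = (
                text[open_start:upto]
                if text is not None
                else _reconstruct(tokens, open_start, upto)
            )
            spans.append(EntitySpan(doc_id, section, open_start, upto, spantext))
            open_start = None

    prev_e = False
    for tok, lab in zip(tokens, token_labels):
        opens = lab.s or (lab.e and not prev_e)
        if opens:
            close(prev_end)
            open_start = tok.start
        elif not lab.e:
            close(prev_end)
        prev_e = lab.e
        prev_end = tok.end
    close(prev_end)
    return spans


def char_labels_to_spans(
    text: str, char_labels: Sequence[LabelPair], *, doc_id: str = "", section: str = "abstract"
) -> list[EntitySpan]:
    """Character-level decoding: the token rule applied to one-char tokens."""
    tokens = [Token(c, i, i + 1) for i, c in enumerate(text)]
    return token_labels_to_spans(tokens, char_labels, doc_id=doc_id, section=section, text=text)


def _reconstruct(tokens: Sequence[Token], start: int, end: int) -> str:
    """Best-effort text for a decoded span when the source text is not given:
    token texts joined with single spaces across gaps."""
    parts: list[str] = []
    prev_end: int | None = None
    for tok in tokens:
        if tok.start >= start and tok.end <= end:
            if prev_end is not None and tok.start > prev_end:
                parts.append(" " * (tok.start - prev_end))
            parts.append(tok.text)
            prev_end = tok.end
    return "".join(parts)
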