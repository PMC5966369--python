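"""Token and character vocabularies with reserved padding/unknown ids."""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["WordVocab", "CharVocab", "encode_token_chars"]

PAD_ID = 0


class WordVocab:
    """Frequency-cutoff token vocabulary.

    Ids are dense: 0 is reserved for padding, 1 is the shared
    out-of-vocabulary id, real tokens follow in frequency-descending then
    lexicographic order.  Tokens seen fewer than ``min_frequency`` times map
    to the OOV id.
    """

    pad_id = PAD_ID
    oov_id = 1

    def __init__(self, token_to_id: dict[str, int], min_frequency: int = 1):
        self.token_to_id = token_to_id
        self.min_frequency = min_frequency

    @classmethod
    def build(cls, tokenised_corpus: Iterable[Sequence[str]],
              min_frequency: int = 1) -> "WordVocab":
        counts: Counter[str] = Counter()
        empty = True
        for tokens in tokenised_corpus:
            empty = False
            counts.update(tokens)
        if empty:
            raise ValueError("cannot build a vocabulary from an empty corpus")
        kept = sorted(
            (tok for tok, c in counts.items() if c >= min_frequency),
            key=lambda tok: (-counts[tok], tok),
        )
        mapping = {tok: i + 2 for i, tok in enumerate(kept)}
        return cls(mapping, min_frequency)

    def __len__(self) -> int:
        """Total id count including the pad and OOV rows."""
        return len(self.token_to_id) + 2

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.oov_id)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.id_of(t) for t in tokens], dtype=np.int64)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"min_frequency": self.min_frequency,
                        "token_to_id": self.token_to_id}),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "WordVocab":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(d["token_to_id"], d["min_frequency"])


class CharVocab:
    """Character inventory; 0 is padding, 1 the unknown-character id."""

    pad_id = PAD_ID
    unknown_id = 1

    def __init__(self, char_to_id: dict[str, int]):
        self.char_to_id = char_to_id

    @classmethod
    def build(cls, texts: Iterable[str]) -> "CharVocab":
        chars = sorted({c for text in texts for c in text})
        if not chars:
            raise ValueError("cannot build a character vocabulary from no text")
        return cls({c: i + 2 for i, c in enumerate(chars)})

    def __len__(self) -> int:
        return len(self.char_to_id) + 2

    def id_of(self, char: str) -> int:
        return self.char_to_id.get(char, self.unknown_id)

    def encode(self, text: str) -> np.ndarray:
        return np.array([self.id_of(c) for c in text], dtype=np.int64)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.char_to_id), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CharVocab":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))


def encode_token_chars(token_text: str, char_vocab: CharVocab, max_len: int) -> np.ndarray:
    """Fixed-width character-id vector for one token: truncated or 0-padded
    to ``max_len``."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    ids = np.zeros(max_len, dtype=np.int64)
    for i, c in enumerate(token_text[:max_len]):
        ids[i] = char_vocab.id_of(c)
    return ids
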