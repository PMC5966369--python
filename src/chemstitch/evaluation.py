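"""Exact-match chemical-entity-mention (CEM) scoring.

A predicted span counts as a true positive only when its document, section
and both character offsets equal a gold annotation — no partial credit.
Because the NER model is class-agnostic, per-class numbers are recalls only:
precision cannot be attributed to classes the model never names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import EntitySpan, LabelPair, Token, token_labels_to_spans

__all__ = ["CemScores", "decode", "score_cem", "per_class_recall", "format_report"]


@dataclass(frozen=True)
class CemScores:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def decode(
    probabilities: np.ndarray,
    tokens: Sequence[Token],
    threshold: float = 0.5,
    *,
    doc_id: str = "",
    section: str = "abstract",
    text: str | None = None,
) -> list[EntitySpan]:
    """Threshold per-token [part, start] probabilities and decode to spans.

    Both heads are binarised independently at ``threshold``; the (s, e) runs
    are then decoded by the standard rule (a start flag opens a span; an
    entity-body token after a gap also opens one).
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.shape != (len(tokens), 2):
        raise ValueError(f"expected ({len(tokens)}, 2) probabilities, got {probs.shape}")
    labels = []
    for part, start in probs:
        e = bool(part > threshold)
        s = bool(start > threshold) and e
        labels.append(LabelPair(s, e))
    return token_labels_to_spans(tokens, labels, doc_id=doc_id, section=section, text=text)


def score_cem(
    gold: Sequence[EntitySpan], predicted: Sequence[EntitySpan]
) -> CemScores:
    """Perfect-match set scoring on (doc, section, start, end) keys.

    Duplicate identical predictions are deduplicated first (CEM is a
    set-level task); each gold span can be matched at most once.
    """
    gold_keys = {sp.key for sp in gold}
    pred_keys = {sp.key for sp in predicted}
    tp = len(gold_keys & pred_keys)
    return CemScores(
        true_positives=tp,
        false_positives=len(pred_keys) - tp,
        false_negatives=len(gold_keys) - tp,
    )


def per_class_recall(
    gold: Sequence[EntitySpan], predicted: Sequence[EntitySpan]
) -> dict[str, tuple[float, int]]:
    """Recall and gold count per entity class, perfect-match rule.

    Classes with no gold spans are absent from the result.  Gold spans must
    carry classes.
    """
    pred_keys = {sp.key for sp in predicted}
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for sp in gold:
        if sp.entity_class is None:
            raise ValueError(f"gold span {sp.key} carries no entity class")
        totals[sp.entity_class] = totals.get(sp.entity_class, 0) + 1
        if sp.key in pred_keys:
            hits[sp.entity_class] = hits.get(sp.entity_class, 0) + 1
    return {
        cls: (hits.get(cls, 0) / n, n)
        for cls, n in sorted(totals.items(), key=lambda kv: kv[1])
    }


def format_report(
    scores: CemScores, per_class: Mapping[str, tuple[float, int]] | None = None
) -> str:
    """Human-readable score report; per-class lines sorted by gold count."""
    lines = [
        "CEM exact-match scores",
        f"  precision  {scores.precision:7.2%}",
        f"  recall     {scores.recall:7.2%}",
        f"  F1         {scores.f1:7.2%}",
        f"  TP {scores.true_positives}  FP {scores.false_positives}  "
        f"FN {scores.false_negatives}",
    ]
    if per_class:
        lines.append("")
        lines.append(f"  {'class':<14}{'recall':>9}{'entities':>10}")
        for cls, (rec, n) in per_class.items():
            lines.append(f"  {cls:<14}{rec:>9.2%}{n:>10}")
    return "\n".join(lines)
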