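"""Bin-packing batch construction for stateful recurrent learning.

Stateful recurrent training treats row *j* of chunk batch *i+1* as the direct
continuation of row *j* of chunk batch *i*.  To feed variable-length texts
through such a model we distribute the texts over ``n_bins`` parallel streams
while keeping the accumulated lengths as equal as possible, concatenate each
bin's texts into one super-sequence, and cut the stacked super-sequences into
chunks of ``window_length`` time-steps.  The construction is exactly
reversible, so per-step outputs can be mapped back to individual texts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["BatchPlan", "pack_bins", "make_plan", "build_chunks", "unbatch",
           "text_start_masks"]


@dataclass(frozen=True)
class TextSlot:
    """Where one text lives inside the plan."""

    text_index: int  # position in the original corpus order
    bin_index: int
    order_in_bin: int
    offset: int  # start offset within the bin's super-sequence
    length: int


@dataclass
class BatchPlan:
    """Reversible mapping text -> bin -> super-sequence -> fixed-size chunks."""

    n_bins: int
    window_length: int
    slots: list[TextSlot]
    total_chunks: int
    pad_lengths: list[int] = field(default_factory=list)

    @property
    def lengths(self) -> list[int]:
        out = [0] * len(self.slots)
        for s in self.slots:
            out[s.text_index] = s.length
        return out

    def bin_load(self, b: int) -> int:
        return sum(s.length for s in self.slots if s.bin_index == b)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "window_length": self.window_length,
            "total_chunks": self.total_chunks,
            "pad_lengths": list(self.pad_lengths),
            "slots": [
                [s.text_index, s.bin_index, s.order_in_bin, s.offset, s.length]
                for s in self.slots
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BatchPlan":
        return cls(
            n_bins=d["n_bins"],
            window_length=d["window_length"],
            slots=[TextSlot(*row) for row in d["slots"]],
            total_chunks=d["total_chunks"],
            pad_lengths=list(d["pad_lengths"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BatchPlan":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def pack_bins(lengths: Sequence[int], n_bins: int) -> list[int]:
    """Assign each text to a bin by the longest-processing-time heuristic.

    Texts are taken in decreasing length (ties: lower original index first)
    and each goes to the currently lightest bin (ties: lowest bin index).
    Deterministic; guarantees max load - min load <= max text length.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not len(lengths):
        raise ValueError("lengths must be non-empty")
    order = sorted(range(len(lengths)), key=lambda i: (-lengths[i], i))
    loads = [0] * n_bins
    assignment = [0] * len(lengths)
    for i in order:
        b = min(range(n_bins), key=lambda j: (loads[j], j))
        assignment[i] = b
        loads[b] += lengths[i]
    return assignment


def make_plan(lengths: Sequence[int], n_bins: int, window_length: int) -> BatchPlan:
    """Build the full reversible plan for texts of the given lengths."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    assignment = pack_bins(lengths, n_bins)
    slots: list[TextSlot] = []
    offsets = [0] * n_bins
    order_counters = [0] * n_bins
    # within a bin, texts are laid out in original corpus order
    for i, length in enumerate(lengths):
        b = assignment[i]
        slots.append(TextSlot(i, b, order_counters[b], offsets[b], length))
        order_counters[b] += 1
        offsets[b] += length
    max_load = max(offsets) if offsets else 0
    total_chunks = max(1, -(-max_load // window_length)) if max_load else 0
    pad_lengths = [total_chunks * window_length - o for o in offsets]
    return BatchPlan(n_bins, window_length, slots, total_chunks, pad_lengths)


def build_chunks(
    encoded_texts: Sequence[np.ndarray], plan: BatchPlan
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Stack the planned super-sequences and cut them into chunk batches.

    ``encoded_texts[i]`` is the feature sequence of text *i*, shaped
    ``(length_i, ...)``; all texts must share trailing feature dimensions.
    Returns ``(chunks, masks)``: chunk *k* is shaped
    ``(n_bins, window_length, ...)`` and its mask ``(n_bins, window_length)``
    marks real (1) vs padded (0) steps.  Row *j* of chunk *k+1* directly
    continues row *j* of chunk *k*.
    """
    if len(encoded_texts) != len(plan.slots):
        raise ValueError("plan does not cover these texts")
    for s in plan.slots:
        if len(encoded_texts[s.text_index]) != s.length:
            raise ValueError(
                f"text {s.text_index} has length {len(encoded_texts[s.text_index])}, "
                f"plan says {s.length}"
            )
    l = plan.window_length
    total = plan.total_chunks * l
    feat_shape = encoded_texts[0].shape[1:]
    dtype = encoded_texts[0].dtype
    supers = np.zeros((plan.n_bins, total) + feat_shape, dtype=dtype)
    mask = np.zeros((plan.n_bins, total), dtype=np.int8)
    for s in plan.slots:
        supers[s.bin_index, s.offset : s.offset + s.length] = encoded_texts[s.text_index]
        mask[s.bin_index, s.offset : s.offset + s.length] = 1
    chunks = [supers[:, k * l : (k + 1) * l] for k in range(plan.total_chunks)]
    masks = [mask[:, k * l : (k + 1) * l] for k in range(plan.total_chunks)]
    return chunks, masks


def text_start_masks(plan: BatchPlan) -> list[np.ndarray]:
    """Per-chunk (n_bins, window_length) masks marking the first step of every
    text inside its bin's super-sequence.  Feeding these as recurrent reset
    masks cuts the forward context at text boundaries (off by default)."""
    l = plan.window_length
    full = np.zeros((plan.n_bins, plan.total_chunks * l), dtype=np.int8)
    for s in plan.slots:
        full[s.bin_index, s.offset] = 1
    return [full[:, k * l : (k + 1) * l] for k in range(plan.total_chunks)]


def unbatch(per_step_outputs: Sequence[np.ndarray], plan: BatchPlan) -> list[np.ndarray]:
    """Invert :func:`build_chunks` on per-step model outputs.

    ``per_step_outputs`` has one array per chunk, shaped
    ``(n_bins, window_length, ...)``.  Returns one array per original text,
    in original corpus order, padding discarded.
    """
    if len(per_step_outputs) != plan.total_chunks:
        raise ValueError(
            f"expected {plan.total_chunks} chunk outputs, got {len(per_step_outputs)}"
        )
    for k, arr in enumerate(per_step_outputs):
        if arr.shape[:2] != (plan.n_bins, plan.window_length):
            raise ValueError(f"chunk {k} has shape {arr.shape[:2]}, "
                             f"plan says {(plan.n_bins, plan.window_length)}")
    stacked = np.concatenate(per_step_outputs, axis=1) if per_step_outputs else None
    out: list[np.ndarray | None] = [None] * len(plan.slots)
    for s in plan.slots:
        out[s.text_index] = stacked[s.bin_index, s.offset : s.offset + s.length]
    return out  # type: ignore[return-value]
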