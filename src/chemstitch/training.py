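"""Generic stateful training loop: epochs over ordered chunk batches, Adam,
validation monitoring and best-weights checkpointing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .nn import Adam, Tensor
from .nn.autograd import no_grad

__all__ = ["StatefulModel", "TrainHistory", "fit_stateful"]

ChunkBatch = dict  # numpy arrays keyed by input name, plus "mask"


class StatefulModel(Protocol):
    def params(self) -> list[Tensor]: ...
    def reset_states(self) -> None: ...
    def loss_on_chunk(self, chunk: ChunkBatch) -> Tensor: ...


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def _evaluate(model: StatefulModel, chunks: Sequence[ChunkBatch]) -> float:
    model.reset_states()
    total, steps = 0.0, 0
    with no_grad():
        for chunk in chunks:
            n = int(np.asarray(chunk["mask"]).sum())
            if n == 0:
                continue
            total += float(model.loss_on_chunk(chunk).data) * n
            steps += n
    return total / max(steps, 1)


def fit_stateful(
    model: StatefulModel,
    train_chunks: Sequence[ChunkBatch],
    val_chunks: Sequence[ChunkBatch],
    epochs: int,
    learning_rate: float = 1e-3,
    callback: Callable[[int, float, float], None] | None = None,
) -> TrainHistory:
    """Train for ``epochs`` passes over the ordered chunk sequence.

    Chunk order within an epoch is preserved (row *j* of chunk *i+1*
    continues row *j* of chunk *i*); recurrent states are reset at the start
    of every pass.  Weights with the best validation loss are restored at the
    end, mirroring a save-on-improvement checkpoint callback.
    """
    if not train_chunks:
        raise ValueError("no training batches")
    opt = Adam(model.params(), lr=learning_rate)
    history = TrainHistory()
    best_weights: list[np.ndarray] | None = None
    for epoch in range(epochs):
        model.reset_states()
        total, steps = 0.0, 0
        for chunk in train_chunks:
            n = int(np.asarray(chunk["mask"]).sum())
            if n == 0:
                continue
            opt.zero_grad()
            loss = model.loss_on_chunk(chunk)
            loss.backward()
            opt.step()
            total += float(loss.data) * n
            steps += n
        train_loss = total / max(steps, 1)
        val_loss = _evaluate(model, val_chunks) if val_chunks else train_loss
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_weights = [p.data.copy() for p in model.params()]
        if callback is not None:
            callback(epoch, train_loss, val_loss)
    if best_weights is not None:
        for p, w in zip(model.params(), best_weights):
            p.data = w
    model.reset_states()
    return history
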