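"""Neural layers for stateful sequence labelling.

All layers operate on batch-major sequences shaped ``(batch, time, features)``
and expose ``params()`` returning their trainable tensors.  Weight
initialisation draws from a ``numpy.random.Generator`` passed at construction,
so a model built from a seeded generator is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gather, stack

__all__ = [
    "Layer",
    "Embedding",
    "Dense",
    "TimeDistributedDense",
    "Conv1D",
    "GRUCell",
    "LSTMCell",
    "RNN",
    "HalfStatefulBiRNN",
    "BiRNNEncoder",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, _ = np.linalg.qr(a)
    return q[:n, :m] if q.shape == (max(n, m), min(n, m)) else q.T[:n, :m]


class Layer:
    def params(self) -> list[Tensor]:  # pragma: no cover - trivial default
        return []

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())


class Embedding(Layer):
    """Row-lookup embedding; row 0 is the padding row and is kept at zero
    when ``zero_pad`` is set."""

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator,
                 weights: np.ndarray | None = None, trainable: bool = True,
                 zero_pad: bool = True):
        if weights is None:
            weights = rng.uniform(-0.05, 0.05, size=(n_rows, dim))
        if weights.shape != (n_rows, dim):
            raise ValueError("embedding weight shape mismatch")
        weights = np.array(weights, dtype=np.float64)
        if zero_pad:
            weights[0] = 0.0
        self.zero_pad = zero_pad
        self.table = Tensor(weights, requires_grad=trainable)
        self.trainable = trainable

    def __call__(self, indices: np.ndarray) -> Tensor:
        return gather(self.table, indices)

    def params(self) -> list[Tensor]:
        return [self.table] if self.trainable else []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.w = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w + self.b
        if self.activation == "sigmoid":
            y = y.sigmoid()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation == "relu":
            y = y.relu()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


#: A dense map applied independently at every time-step; with batch-major
#: matmul broadcasting this *is* a Dense layer.
TimeDistributedDense = Dense


class Conv1D(Layer):
    """Same-padded 1D convolution along the time axis."""

    def __init__(self, n_in: int, filters: int, width: int,
                 rng: np.random.Generator, activation: str | None = "relu"):
        if width < 1 or filters < 1 or n_in < 1:
            raise ValueError("Conv1D dimensions must be positive")
        self.width = width
        self.w = Tensor(_glorot(rng, width * n_in, filters), requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        b, t, c = x.shape
        left = (self.width - 1) // 2
        right = self.width - 1 - left
        pieces = []
        if left:
            pieces.append(Tensor(np.zeros((b, left, c))))
        pieces.append(x)
        if right:
            pieces.append(Tensor(np.zeros((b, right, c))))
        xp = concat(pieces, axis=1) if len(pieces) > 1 else x
        windows = concat([xp[:, i : i + t, :] for i in range(self.width)], axis=-1)
        y = windows @ self.w + self.b
        if self.activation == "relu":
            y = y.relu()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class GRUCell(Layer):
    """Gated recurrent unit (2 gates + candidate: 3 input/recurrent blocks)."""

    n_gate_blocks = 3

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.wx = Tensor(_glorot(rng, n_in, 3 * units), requires_grad=True)
        self.wh = Tensor(
            np.concatenate([_orthogonal(rng, units, units) for _ in range(3)], axis=1),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(3 * units), requires_grad=True)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        u = self.units
        gx = x @ self.wx + self.b
        gh = h @ self.wh
        z = (gx[:, 0:u] + gh[:, 0:u]).sigmoid()
        r = (gx[:, u : 2 * u] + gh[:, u : 2 * u]).sigmoid()
        n = (gx[:, 2 * u : 3 * u] + r * gh[:, 2 * u : 3 * u]).tanh()
        return z * h + (1.0 - z) * n

    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b]

    def zero_state(self, batch: int) -> np.ndarray:
        return np.zeros((batch, self.units))

    def state_width(self) -> int:
        return self.units


class LSTMCell(Layer):
    """Long short-term memory cell (3 gates + candidate: 4 blocks).

    State is the concatenation [h, c] so the recurrent wrappers can treat GRU
    and LSTM uniformly.
    """

    n_gate_blocks = 4

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.wx = Tensor(_glorot(rng, n_in, 4 * units), requires_grad=True)
        self.wh = Tensor(
            np.concatenate([_orthogonal(rng, units, units) for _ in range(4)], axis=1),
            requires_grad=True,
        )
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def step(self, x: Tensor, state: Tensor) -> Tensor:
        u = self.units
        h, c = state[:, :u], state[:, u:]
        g = x @ self.wx + h @ self.wh + self.b
        i = g[:, 0:u].sigmoid()
        f = g[:, u : 2 * u].sigmoid()
        o = g[:, 2 * u : 3 * u].sigmoid()
        cand = g[:, 3 * u : 4 * u].tanh()
        c_new = f * c + i * cand
        h_new = o * c_new.tanh()
        return concat([h_new, c_new], axis=-1)

    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b]

    def zero_state(self, batch: int) -> np.ndarray:
        return np.zeros((batch, 2 * self.units))

    def state_width(self) -> int:
        return 2 * self.units


def make_cell(kind: str, n_in: int, units: int, rng: np.random.Generator):
    kind = kind.upper()
    if kind == "GRU":
        return GRUCell(n_in, units, rng)
    if kind == "LSTM":
        return LSTMCell(n_in, units, rng)
    raise ValueError(f"unknown recurrent cell type {kind!r}")


def _cell_output(cell, state: Tensor) -> Tensor:
    """The visible output h of a cell state (LSTM state also carries c)."""
    if isinstance(cell, LSTMCell):
        return state[:, : cell.units]
    return state


class RNN(Layer):
    """Unidirectional recurrence over a (batch, time, features) tensor."""

    def __init__(self, cell):
        self.cell = cell

    def __call__(self, x: Tensor, initial_state: Tensor | None = None,
                 reverse: bool = False,
                 reset_mask: np.ndarray | None = None,
                 step_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        """Run the cell over time; returns (outputs, final_state).

        ``reverse`` consumes the sequence right-to-left and returns outputs
        re-flipped to input order.  ``reset_mask`` (batch, time) zeroes the
        incoming state at marked steps (used to cut context at text
        boundaries inside a super-sequence).  ``step_mask`` (batch, time)
        freezes the state at padded steps, so padding never contaminates the
        recurrence in either direction.
        """
        b, t, _ = x.shape
        state = initial_state if initial_state is not None else Tensor(self.cell.zero_state(b))
        seq = x.flip(1) if reverse else x
        if reverse:
            reset_mask = np.flip(reset_mask, axis=1) if reset_mask is not None else None
            step_mask = np.flip(step_mask, axis=1) if step_mask is not None else None
        outs: list[Tensor] = []
        for i in range(t):
            if reset_mask is not None:
                keep = 1.0 - reset_mask[:, i : i + 1].astype(np.float64)
                state = state * Tensor(keep)
            new_state = self.cell.step(seq[:, i, :], state)
            if step_mask is not None:
                m = Tensor(step_mask[:, i : i + 1].astype(np.float64))
                state = new_state * m + state * (1.0 - m)
            else:
                state = new_state
            outs.append(_cell_output(self.cell, state))
        out = stack(outs, axis=1)
        if reverse:
            out = out.flip(1)
        return out, state

    def params(self) -> list[Tensor]:
        return self.cell.params()


class HalfStatefulBiRNN(Layer):
    """Bidirectional recurrent layer carrying only the forward state across
    successive chunk batches.

    Row *j* of each incoming batch is treated as the continuation of row *j*
    of the previous one: the forward direction resumes from its saved state
    (detached, i.e. truncated back-propagation through time), while the
    backward direction starts fresh at every chunk since future context
    beyond the chunk cannot exist yet.  ``stateful=False`` degrades to a
    conventional biRNN.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 cell_type: str = "GRU", stateful: bool = True):
        self.fwd = make_cell(cell_type, n_in, units, rng)
        self.bwd = make_cell(cell_type, n_in, units, rng)
        self.stateful = stateful
        self.units = units
        self._carry: np.ndarray | None = None

    def reset_state(self) -> None:
        self._carry = None

    def __call__(self, x: Tensor, reset_mask: np.ndarray | None = None,
                 step_mask: np.ndarray | None = None) -> Tensor:
        b = x.shape[0]
        init = None
        if self.stateful and self._carry is not None:
            if self._carry.shape[0] != b:
                raise ValueError("batch size changed between stateful chunks")
            init = Tensor(self._carry)
        out_f, final_f = RNN(self.fwd)(x, initial_state=init,
                                       reset_mask=reset_mask, step_mask=step_mask)
        out_b, _ = RNN(self.bwd)(x, reverse=True, step_mask=step_mask)
        if self.stateful:
            self._carry = final_f.data.copy()
        return concat([out_f, out_b], axis=-1)

    @property
    def out_width(self) -> int:
        return 2 * self.units

    def params(self) -> list[Tensor]:
        return self.fwd.params() + self.bwd.params()


class BiRNNEncoder(Layer):
    """Conventional bidirectional encoder reducing a sequence to one vector
    (the concatenated final states of both directions).

    Used for character-level token embeddings: a token's character matrix in,
    one fixed-width token vector out.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 cell_type: str = "GRU"):
        self.fwd = make_cell(cell_type, n_in, units, rng)
        self.bwd = make_cell(cell_type, n_in, units, rng)
        self.units = units

    def __call__(self, x: Tensor) -> Tensor:
        _, final_f = RNN(self.fwd)(x)
        _, final_b = RNN(self.bwd)(x, reverse=True)
        return concat([_cell_output(self.fwd, final_f),
                       _cell_output(self.bwd, final_b)], axis=-1)

    @property
    def out_width(self) -> int:
        return 2 * self.units

    def params(self) -> list[Tensor]:
        return self.fwd.params() + self.bwd.params()
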