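"""The per-marker laboratory-progress network and its autoregressive rollout.

Architecture (one network per laboratory marker):

* **LIBC** (longitudinal iterative block): a bidirectional LSTM with 5
  hidden units per direction over the 5-feature monthly rows, ReLU, then a
  fully connected *condensing* layer mapping the concatenated 10-unit
  state back to the 5-feature input width, ReLU.  The condensed output of
  the final step is the latent progress vector (``progress_emb``).
* **Regressor**: two fully connected layers 5 -> 2 -> 1 with ReLU in
  between, mapping a condensed vector to the predicted next-month
  normalized laboratory value (``progress_out``).

`rollout` extends the window month by month for ``g+1`` iterations: each
iteration runs LIBC and the regressor, and the predicted value becomes
the newest month of the next window — the autoregressive closure.
Appended months are marked uncertain (certain_bit 0), keep the patient's
static age and sex, and have their clinical category recomputed from the
denormalized predicted value.  Each sample's representations are read at
its own iteration index ``g``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from .encoding import (AGE, SEX, ThresholdTable,
                       denormalize_value, discrete_code)

__all__ = ["LIBC", "Regressor", "GLPNetwork", "RolloutResult", "rollout"]

INPUT_WIDTH = 5
HIDDEN = 5


def _uniform(rng, shape, k):
    return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)


class _LSTMDirection:
    """One direction of the LSTM: gate order (input, forget, cell, output)."""

    def __init__(self, rng, input_size, hidden_size):
        k = 1.0 / np.sqrt(hidden_size)
        self.Wx = _uniform(rng, (input_size, 4 * hidden_size), k)
        self.Wh = _uniform(rng, (hidden_size, 4 * hidden_size), k)
        self.b = _uniform(rng, (4 * hidden_size,), k)
        self.hidden = hidden_size

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def run(self, xps, n_batch, reverse=False):
        """Recurrence over precomputed input projections xps[t] (B, 4H)."""
        H = self.hidden
        h = Tensor(np.zeros((n_batch, H)))
        c = Tensor(np.zeros((n_batch, H)))
        hs = [None] * len(xps)
        order = range(len(xps) - 1, -1, -1) if reverse else range(len(xps))
        for t in order:
            z = xps[t] + h @ self.Wh + self.b
            i = z[:, 0 * H:1 * H].sigmoid()
            f = z[:, 1 * H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs[t] = h
        return hs


class LIBC:
    """Bidirectional LSTM + condensing layer, both ReLU-terminated."""

    def __init__(self, rng, input_size=INPUT_WIDTH, hidden_size=HIDDEN):
        self.input_size = input_size
        self.hidden = hidden_size
        self.fwd = _LSTMDirection(rng, input_size, hidden_size)
        self.bwd = _LSTMDirection(rng, input_size, hidden_size)
        k = 1.0 / np.sqrt(2 * hidden_size)
        # condensing map back to the input width closes the autoregression
        self.Wc = _uniform(rng, (2 * hidden_size, input_size), k)
        self.bc = _uniform(rng, (input_size,), k)

    def params(self):
        return self.fwd.params() + self.bwd.params() + [self.Wc, self.bc]

    def _project(self, xs, direction):
        """Input projections x_t @ Wx for every step.

        `xs` is either an (B, T, F) ndarray (fast path: one stacked matmul)
        or a list of per-step (B, F) Tensors (rollout path).
        """
        if isinstance(xs, np.ndarray):
            n_batch, n_steps, width = xs.shape
            flat = Tensor(np.ascontiguousarray(
                xs.transpose(1, 0, 2)).reshape(n_steps * n_batch, width))
            proj = flat @ direction.Wx
            return [proj[t * n_batch:(t + 1) * n_batch] for t in range(n_steps)], n_batch
        n_batch = xs[0].shape[0]
        return [x @ direction.Wx for x in xs], n_batch

    def _states(self, xs):
        """ReLU'd bidirectional states stacked over steps: (T*B, 2H)."""
        if isinstance(xs, np.ndarray):
            if xs.ndim != 3 or xs.shape[2] != self.input_size:
                raise ValueError(
                    f"expected (batch, steps, {self.input_size}) input, got {xs.shape}")
        elif xs[0].shape[1] != self.input_size:
            raise ValueError(
                f"expected per-step width {self.input_size}, got {xs[0].shape[1]}")
        xps_f, n_batch = self._project(xs, self.fwd)
        xps_b, _ = self._project(xs, self.bwd)
        hs_f = self.fwd.run(xps_f, n_batch)
        hs_b = self.bwd.run(xps_b, n_batch, reverse=True)
        n_steps = len(hs_f)
        u = concat([concat([hs_f[t], hs_b[t]], axis=1) for t in range(n_steps)],
                   axis=0).relu()
        return u, n_batch, n_steps

    def forward(self, xs):
        """Per-step condensed outputs and the predicted next feature row.

        Returns (condensed, next_step): `condensed` is a list of T (B, 5)
        tensors; `next_step` is the final step's condensed output.
        """
        u, n_batch, n_steps = self._states(xs)
        cond_flat = (u @ self.Wc + self.bc).relu()
        condensed = [cond_flat[t * n_batch:(t + 1) * n_batch]
                     for t in range(n_steps)]
        return condensed, condensed[-1]


class Regressor:
    """Two affine layers 5 -> 2 -> 1 with a ReLU in between."""

    def __init__(self, rng, input_size=INPUT_WIDTH, hidden_size=2):
        k1 = 1.0 / np.sqrt(input_size)
        k2 = 1.0 / np.sqrt(hidden_size)
        self.W1 = _uniform(rng, (input_size, hidden_size), k1)
        self.b1 = _uniform(rng, (hidden_size,), k1)
        self.W2 = _uniform(rng, (hidden_size, 1), k2)
        self.b2 = _uniform(rng, (1,), k2)

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, v):
        if not isinstance(v, Tensor):
            v = Tensor(np.asarray(v, dtype=np.float64))
        if v.shape[-1] != self.W1.shape[0]:
            raise ValueError(f"expected width {self.W1.shape[0]}, got {v.shape[-1]}")
        return (v @ self.W1 + self.b1).relu() @ self.W2 + self.b2


class GLPNetwork:
    """One marker's forecaster: LIBC + regressor and training metadata."""

    def __init__(self, marker: str, seed: int = 0, input_size: int = INPUT_WIDTH):
        self.marker = marker
        self.seed = int(seed)
        self.stage = "init"
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x61)))
        self.libc = LIBC(rng, input_size=input_size)
        self.regressor = Regressor(rng, input_size=input_size)

    def params(self):
        return self.libc.params() + self.regressor.params()

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(p.data.tobytes())
        return h.hexdigest()

    def copy(self) -> "GLPNetwork":
        clone = GLPNetwork(self.marker, self.seed,
                           input_size=self.libc.input_size)
        clone.stage = self.stage
        for dst, src in zip(clone.params(), self.params()):
            dst.data = src.data.copy()
        return clone

    # -- persistence -------------------------------------------------------

    _PARAM_NAMES = ("fwd.Wx", "fwd.Wh", "fwd.b", "bwd.Wx", "bwd.Wh", "bwd.b",
                    "Wc", "bc", "W1", "b1", "W2", "b2")

    def save(self, path) -> None:
        arrays = {name: p.data for name, p in zip(self._PARAM_NAMES, self.params())}
        meta = json.dumps({"marker": self.marker, "seed": self.seed,
                           "stage": self.stage,
                           "input_size": self.libc.input_size})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GLPNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            net = cls(meta["marker"], meta["seed"],
                      input_size=meta.get("input_size", INPUT_WIDTH))
            net.stage = meta["stage"]
            for name, p in zip(cls._PARAM_NAMES, net.params()):
                p.data = np.array(data[name])
        return net


@dataclass
class RolloutResult:
    """Outputs of an autoregressive rollout over a batch of windows."""

    step_outputs: np.ndarray   # (steps, batch) regressor output per step
    step_embs: np.ndarray      # (steps, batch, 5) condensed vector per step
    progress_emb: np.ndarray   # (batch, 5) condensed vector at each sample's g
    progress_out: np.ndarray   # (batch,)  regressor output at each sample's g
    selected: Tensor           # graph node of progress_out (for training loss)


def advance_window(window: list, value: Tensor, marker: str,
                   table: ThresholdTable) -> list:
    """Slide the window one month, appending the predicted feature row.

    `value` is the (B, 1) predicted next-month normalized value (the
    regressor output) and is the only channel carrying gradient; age and
    sex are carried forward unchanged, certainty is 0 (the month is an
    estimate) and the clinical category is recomputed from the
    denormalized predicted value.
    """
    first = window[0].data
    n_batch = first.shape[0]
    age_col = Tensor(first[:, AGE:AGE + 1])
    sex_col = Tensor(first[:, SEX:SEX + 1])
    certain_col = Tensor(np.zeros((n_batch, 1)))
    raw = denormalize_value(value.data[:, 0])
    code_col = Tensor(discrete_code(raw, marker, table).reshape(-1, 1))
    new_row = concat([value, age_col, sex_col, certain_col, code_col], axis=1)
    return window[1:] + [new_row]


def rollout(model: GLPNetwork, features: np.ndarray, g,
            table: ThresholdTable, marker: str | None = None) -> RolloutResult:
    """Iterate the network ``max(g)+1`` times and select per-sample outputs.

    `features` is the (batch, r+1, 5) starting window; `g` the per-sample
    month gap to the prediction target.  Iteration `k` predicts the value
    at `k+1` months past the window, so sample i's prediction is read at
    iteration index ``g[i]``.
    """
    g = np.atleast_1d(np.asarray(g, dtype=np.int64))
    if np.any(g < 0):
        raise ValueError("g must be non-negative")
    marker = marker or model.marker
    n_batch, n_steps_window, width = features.shape
    if len(g) != n_batch:
        raise ValueError("g must have one entry per batch row")
    n_steps = int(g.max()) + 1

    window = None
    embs, outs = [], []
    for step in range(n_steps):
        # first pass over the constant window uses the stacked fast path —
        # the identical op sequence to a stage-1 forward
        _, next_step = model.libc.forward(features if step == 0 else window)
        out = model.regressor.forward(next_step)        # (B, 1)
        embs.append(next_step)
        outs.append(out)
        if step < n_steps - 1:
            if window is None:
                window = [Tensor(np.ascontiguousarray(features[:, t, :]))
                          for t in range(n_steps_window)]
            window = advance_window(window, out, marker, table)

    if n_steps == 1:
        # degenerate branch: one pass through LIBC then the regressor
        selected = outs[0]                              # (B, 1)
        progress_out = outs[0].data[:, 0].copy()
        progress_emb = embs[0].data.copy()
    else:
        grid = concat(outs, axis=1)                     # (B, S)
        mask = np.zeros((n_batch, n_steps))
        mask[np.arange(n_batch), g] = 1.0
        selected = (grid * Tensor(mask)).sum(axis=1)    # (B,)
        progress_out = grid.data[np.arange(n_batch), g].copy()
        progress_emb = np.stack([embs[gi].data[i] for i, gi in enumerate(g)])

    step_outputs = np.stack([o.data[:, 0] for o in outs])
    step_embs = np.stack([e.data for e in embs])
    return RolloutResult(step_outputs, step_embs, progress_emb,
                         progress_out, selected)
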