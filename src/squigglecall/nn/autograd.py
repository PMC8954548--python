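"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tape` records operations as they execute; ``Tape.backward`` replays
them in reverse, accumulating gradients into ``Tensor.grad``.  Recurrent
cells and attention are fused single-node operations with hand-derived
backward passes, which keeps graphs for long sequences small enough to train
on a CPU.  Passing ``tape=None`` runs any op in pure inference mode.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


class Tape:
    """Operation record for one forward pass."""

    def __init__(self):
        self._backward_fns: list = []

    def record(self, fn) -> None:
        self._backward_fns.append(fn)

    def backward(self, loss: Tensor) -> None:
        if loss.data.size != 1:
            raise ValueError("backward requires a scalar loss")
        loss.grad = np.ones_like(loss.data)
        for fn in reversed(self._backward_fns):
            fn()


def _grad_of(t: Tensor):
    return t.grad


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def matmul(tape: Tape | None, a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data)
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            _acc(a, out.grad @ b.data.T)
            _acc(b, a.data.T @ out.grad)
        tape.record(bwd)
    return out


def add_bias(tape: Tape | None, a: Tensor, bias: Tensor) -> Tensor:
    out = Tensor(a.data + bias.data)
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            _acc(a, out.grad)
            _acc(bias, out.grad.sum(axis=tuple(range(out.grad.ndim - 1))))
        tape.record(bwd)
    return out


def add(tape: Tape | None, a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data)
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            _acc(a, out.grad)
            _acc(b, out.grad)
        tape.record(bwd)
    return out


def scale(tape: Tape | None, a: Tensor, k: float) -> Tensor:
    out = Tensor(a.data * k)
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            _acc(a, out.grad * k)
        tape.record(bwd)
    return out


def tanh(tape: Tape | None, a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y)
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            _acc(a, out.grad * (1.0 - y * y))
        tape.record(bwd)
    return out


def concat(tape: Tape | None, parts: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis))
    if tape is not None:
        sizes = [p.data.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]

        def bwd():
            if out.grad is None:
                return
            for p, g in zip(parts, np.split(out.grad, splits, axis=axis)):
                _acc(p, g)
        tape.record(bwd)
    return out


def stack(tape: Tape | None, parts: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.stack([p.data for p in parts], axis=axis))
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            for i, p in enumerate(parts):
                _acc(p, np.take(out.grad, i, axis=axis))
        tape.record(bwd)
    return out


# ---------------------------------------------------------------------------
# fused ops
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def lstm_cell(tape: Tape | None, x: Tensor, h: Tensor, c: Tensor,
              wx: Tensor, wh: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    """One LSTM step.  ``wx``: (input, 4H), ``wh``: (H, 4H), gate order
    [input, forget, cell, output]."""
    H = h.data.shape[1]
    z = x.data @ wx.data + h.data @ wh.data + b.data
    ig = _sigmoid(z[:, :H])
    fg = _sigmoid(z[:, H:2 * H])
    gt = np.tanh(z[:, 2 * H:3 * H])
    og = _sigmoid(z[:, 3 * H:])
    c_new = fg * c.data + ig * gt
    tc = np.tanh(c_new)
    h_out = Tensor(og * tc)
    c_out = Tensor(c_new)
    if tape is not None:
        def bwd():
            dh = h_out.grad
            dc = c_out.grad
            if dh is None and dc is None:
                return
            if dh is None:
                dh = np.zeros_like(h_out.data)
            dct = (np.zeros_like(c_new) if dc is None else dc.copy())
            dct += dh * og * (1.0 - tc * tc)
            dog = dh * tc
            dz = np.empty_like(z)
            dz[:, :H] = dct * gt * ig * (1.0 - ig)
            dz[:, H:2 * H] = dct * c.data * fg * (1.0 - fg)
            dz[:, 2 * H:3 * H] = dct * ig * (1.0 - gt * gt)
            dz[:, 3 * H:] = dog * og * (1.0 - og)
            _acc(c, dct * fg)
            _acc(x, dz @ wx.data.T)
            _acc(h, dz @ wh.data.T)
            _acc(wx, x.data.T @ dz)
            _acc(wh, h.data.T @ dz)
            _acc(b, dz.sum(axis=0))
        tape.record(bwd)
    return h_out, c_out


def lstm_cell_prx(tape: Tape | None, xproj: Tensor, h: Tensor, c: Tensor,
                  wh: Tensor) -> tuple[Tensor, Tensor]:
    """LSTM step with the input projection (x @ wx + b) precomputed for the
    whole sequence — one big matmul instead of one per step."""
    H = h.data.shape[1]
    z = xproj.data + h.data @ wh.data
    ig = _sigmoid(z[:, :H])
    fg = _sigmoid(z[:, H:2 * H])
    gt = np.tanh(z[:, 2 * H:3 * H])
    og = _sigmoid(z[:, 3 * H:])
    c_new = fg * c.data + ig * gt
    tc = np.tanh(c_new)
    h_out = Tensor(og * tc)
    c_out = Tensor(c_new)
    if tape is not None:
        def bwd():
            dh = h_out.grad
            dc = c_out.grad
            if dh is None and dc is None:
                return
            if dh is None:
                dh = np.zeros_like(h_out.data)
            dct = (np.zeros_like(c_new) if dc is None else dc.copy())
            dct += dh * og * (1.0 - tc * tc)
            dog = dh * tc
            dz = np.empty_like(z)
            dz[:, :H] = dct * gt * ig * (1.0 - ig)
            dz[:, H:2 * H] = dct * c.data * fg * (1.0 - fg)
            dz[:, 2 * H:3 * H] = dct * ig * (1.0 - gt * gt)
            dz[:, 3 * H:] = dog * og * (1.0 - og)
            _acc(c, dct * fg)
            _acc(xproj, dz)
            _acc(h, dz @ wh.data.T)
            _acc(wh, h.data.T @ dz)
        tape.record(bwd)
    return h_out, c_out


def seq_input_proj(tape: Tape | None, x_seq: np.ndarray, wx: Tensor,
                   b: Tensor) -> list[Tensor]:
    """Project a whole (B, S, I) input block through (wx, b) at once and
    return per-step (B, 4H) tensors."""
    B, S, _ = x_seq.shape
    proj = x_seq.reshape(B * S, -1) @ wx.data + b.data
    proj = proj.reshape(B, S, -1)
    steps = [Tensor(proj[:, t]) for t in range(S)]
    if tape is not None:
        def bwd():
            grads = [s.grad for s in steps]
            if all(g is None for g in grads):
                return
            g = np.stack([np.zeros_like(steps[0].data) if gr is None else gr
                          for gr in grads], axis=1)
            flat = g.reshape(B * S, -1)
            _acc(wx, x_seq.reshape(B * S, -1).T @ flat)
            _acc(b, flat.sum(axis=0))
        tape.record(bwd)
    return steps


def seq_proj_tensor(tape: Tape | None, steps_in: list[Tensor], wx: Tensor,
                    b: Tensor) -> list[Tensor]:
    """Like :func:`seq_input_proj` but for a list of per-step tensors from a
    previous layer (gradient flows back into them)."""
    S = len(steps_in)
    x = np.stack([s.data for s in steps_in], axis=1)  # (B, S, I)
    B = x.shape[0]
    proj = (x.reshape(B * S, -1) @ wx.data + b.data).reshape(B, S, -1)
    steps = [Tensor(proj[:, t]) for t in range(S)]
    if tape is not None:
        def bwd():
            grads = [s.grad for s in steps]
            if all(g is None for g in grads):
                return
            g = np.stack([np.zeros_like(steps[0].data) if gr is None else gr
                          for gr in grads], axis=1)
            flat = g.reshape(B * S, -1)
            _acc(wx, x.reshape(B * S, -1).T @ flat)
            _acc(b, flat.sum(axis=0))
            dx = (flat @ wx.data.T).reshape(B, S, -1)
            for t, s_in in enumerate(steps_in):
                _acc(s_in, dx[:, t])
        tape.record(bwd)
    return steps


def attend(tape: Tape | None, h_dec: Tensor, wa: Tensor, enc: Tensor,
           mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Multiplicative attention: score_s = h_dec^T W_a h_s, softmax over
    unmasked encoder steps, context = weighted sum of encoder outputs.

    ``enc``: (B, S, E); ``mask``: (B, S) bool.  Returns (context, weights);
    weights carry no gradient (diagnostic output).
    """
    if not mask.any(axis=1).all():
        raise ValueError("every sample needs at least one unmasked encoder step")
    q = h_dec.data @ wa.data                       # (B, E)
    scores = np.einsum("bse,be->bs", enc.data, q)  # (B, S)
    scores = np.where(mask, scores, -np.inf)
    scores -= scores.max(axis=1, keepdims=True)
    ex = np.exp(scores)
    alpha = ex / ex.sum(axis=1, keepdims=True)     # masked entries exactly 0
    ctx = Tensor(np.einsum("bs,bse->be", alpha, enc.data))
    if tape is not None:
        def bwd():
            dctx = ctx.grad
            if dctx is None:
                return
            dalpha = np.einsum("be,bse->bs", dctx, enc.data)
            denc = alpha[:, :, None] * dctx[:, None, :]
            ds = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
            dq = np.einsum("bs,bse->be", ds, enc.data)
            denc += ds[:, :, None] * q[:, None, :]
            _acc(enc, denc)
            _acc(h_dec, dq @ wa.data.T)
            _acc(wa, h_dec.data.T @ dq)
        tape.record(bwd)
    return ctx, alpha


def cross_entropy_logits(tape: Tape | None, logits: Tensor,
                         targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Sum of token cross-entropies over unmasked positions.

    ``logits``: (B, V); ``targets``: (B,) int; ``mask``: (B,) bool.  Padding
    positions contribute nothing, to the value or to the gradient.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    picked = z[np.arange(len(targets)), targets]
    losses = np.where(mask, lse - picked, 0.0)
    out = Tensor(losses.sum())
    if tape is not None:
        def bwd():
            if out.grad is None:
                return
            p = np.exp(z - lse[:, None])
            p[np.arange(len(targets)), targets] -= 1.0
            p *= mask[:, None]
            _acc(logits, float(out.grad) * p)
        tape.record(bwd)
    return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
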