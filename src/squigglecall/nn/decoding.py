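"""Greedy and beam-search decoding.

Both operate over an abstract step function ``step(prev_token, state) ->
(log_probs, state)`` so that small hand-built distributions can be decoded
(and beam search checked against exhaustive enumeration) with the same code
path the model uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..samples import Batch, END, PAD, START
from .autograd import log_softmax


def _mask_control(logp: np.ndarray) -> np.ndarray:
    """PAD and START are never emitted during decoding."""
    out = logp.copy()
    out[PAD] = -np.inf
    out[START] = -np.inf
    return out


def greedy_decode(step_fn, init_state, max_len: int,
                  start: int = START, end: int = END) -> list[int]:
    """Argmax token per step from START until END or the length cap."""
    tokens: list[int] = []
    state = init_state
    prev = start
    for _ in range(max_len):
        logp, state = step_fn(prev, state)
        tok = int(np.argmax(logp))
        if tok == end:
            break
        tokens.append(tok)
        prev = tok
    return tokens


@dataclass
class _Hyp:
    tokens: tuple[int, ...]
    score: float
    state: object
    finished: bool
    finish_step: int

    def sort_key(self):
        # higher score first; ties: lower token ids, then earlier finish
        return (-self.score, self.tokens, self.finish_step)


def beam_decode(step_fn, init_state, max_len: int, width: int,
                start: int = START, end: int = END) -> list[int]:
    """Beam search over summed token log-probabilities.

    Hypotheses are retired when they emit END; the best final hypothesis
    (finished or cap-length) is returned without its END token.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    beam = [_Hyp((), 0.0, init_state, False, max_len + 1)]
    finished: list[_Hyp] = []
    for t in range(max_len):
        candidates: list[_Hyp] = []
        for hyp in beam:
            prev = hyp.tokens[-1] if hyp.tokens else start
            logp, state = step_fn(prev, hyp.state)
            for tok in range(len(logp)):
                sc = hyp.score + float(logp[tok])
                if tok == end:
                    candidates.append(_Hyp(hyp.tokens, sc, None, True, t))
                else:
                    candidates.append(_Hyp(hyp.tokens + (tok,), sc, state,
                                           False, max_len + 1))
        candidates.sort(key=_Hyp.sort_key)
        kept = candidates[:width]
        finished.extend(h for h in kept if h.finished)
        beam = [h for h in kept if not h.finished]
        if not beam:
            break
    finished.extend(beam)  # cap-length hypotheses compete too
    best = min(finished, key=_Hyp.sort_key)
    return list(best.tokens)


def model_step_fn(model, enc_row):
    """Adapt a model + single-sample encoder outputs to the step interface.
    State is (decoder state, last attention row); attention rows are
    collected by the caller via the returned closure."""

    def step(prev_token, state):
        dec_state = state if state is not None else model.init_decoder_state(1)
        logits, new_state, alpha = model.decode_step(
            np.array([prev_token]), dec_state, enc_row, tape=None)
        return _mask_control(log_softmax(logits.data)[0]), new_state
    return step


def decode_batch(model, batch: Batch, width: int = 1,
                 collect_attention: bool = False):
    """Decode every sample of a batch; returns lists of token sequences and
    (optionally) per-sample attention weight matrices (steps x S)."""
    from .model import EncoderOutputs

    enc = model.encode(batch, tape=None)
    results, attentions = [], []
    for i in range(len(batch)):
        row = EncoderOutputs(outputs=_row_tensor(enc.outputs, i),
                             mask=enc.mask[i:i + 1])
        if width == 1:
            tokens, att = _greedy_with_attention(model, row)
        else:
            step = model_step_fn(model, row)
            tokens = beam_decode(step, None, model.config.decode_cap, width)
            att = _replay_attention(model, row, tokens) if collect_attention \
                else None
        results.append(tokens)
        if collect_attention:
            attentions.append(att)
    return (results, attentions) if collect_attention else results


def _row_tensor(outputs, i):
    from .autograd import Tensor

    return Tensor(outputs.data[i:i + 1])


def _greedy_with_attention(model, enc_row):
    state = model.init_decoder_state(1)
    tokens: list[int] = []
    rows = []
    prev = START
    for _ in range(model.config.decode_cap):
        logits, state, alpha = model.decode_step(np.array([prev]), state,
                                                 enc_row, tape=None)
        tok = int(np.argmax(_mask_control(log_softmax(logits.data)[0])))
        if tok == END:
            break
        tokens.append(tok)
        rows.append(alpha[0])
        prev = tok
    att = np.stack(rows) if rows else np.zeros((0, enc_row.mask.shape[1]))
    return tokens, att


def _replay_attention(model, enc_row, tokens):
    state = model.init_decoder_state(1)
    rows = []
    prev = START
    for tok in tokens:
        _, state, alpha = model.decode_step(np.array([prev]), state,
                                            enc_row, tape=None)
        rows.append(alpha[0])
        prev = tok
    return np.stack(rows) if rows else np.zeros((0, enc_row.mask.shape[1]))


def export_attention(model, batch: Batch, width: int = 1) -> list[np.ndarray]:
    """Per-sample attention heat-map matrices: one row per emitted token,
    each row the attention weight vector over the (possibly concatenated)
    encoder step axis."""
    _, attentions = decode_batch(model, batch, width=width,
                                 collect_attention=True)
    return attentions
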