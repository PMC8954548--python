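"""Twin-encoder attention sequence-to-sequence basecalling model.

Two stacked BiLSTM encoders process raw and event inputs in parallel; in
joint mode their per-step outputs are concatenated along the step axis.  A
single-layer LSTM decoder queries the encoder outputs through multiplicative
attention (score = h_dec^T W_a h_s, softmax over unmasked steps, context =
weighted sum) and emits 7-way token logits through an attentional output
layer h~ = tanh(W_c [c; h_dec]).

Training uses masked cross-entropy, scheduled-sampling teacher forcing and
global-norm gradient clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ..samples import Batch, END, PAD, START, VOCAB_SIZE
from . import autograd as ag
from .autograd import Tape, Tensor
from .optim import Adam, clip_by_global_norm

MODES = ("raw", "event", "joint")


@dataclass
class ModelConfig:
    latent_dim: int = 128
    encoder_layers: int = 2
    decoder_layers: int = 1
    vocab_size: int = VOCAB_SIZE
    mode: str = "joint"
    event_features: int = 5
    decode_cap: int = 40
    init_seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.vocab_size != VOCAB_SIZE:
            raise ValueError("vocabulary is fixed at 7 tokens")

    @property
    def encoder_out_dim(self) -> int:
        return 2 * self.latent_dim  # bidirectional concatenation


@dataclass
class TrainConfig:
    clip_norm: float = 1.0
    sampling_ratio: float = 0.5
    epochs: int = 10
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sampling_ratio <= 1.0:
            raise ValueError("sampling_ratio must be in [0, 1]")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")


@dataclass
class EncoderOutputs:
    outputs: Tensor        # (B, S, 2*latent)
    mask: np.ndarray       # (B, S) bool

    @property
    def n_steps(self) -> int:
        return self.outputs.data.shape[1]


class Seq2SeqModel:
    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.init_seed)
        H = config.latent_dim
        E = config.encoder_out_dim

        def mat(name, shape, fan_in):
            self.params[name] = Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                                  size=shape))

        def vec(name, size):
            self.params[name] = Tensor(np.zeros(size))

        for enc, in_dim in (("raw", 1), ("event", config.event_features)):
            if config.mode not in (enc, "joint"):
                continue
            for layer in range(config.encoder_layers):
                d = in_dim if layer == 0 else E
                for dirn in ("f", "b"):
                    mat(f"{enc}_l{layer}{dirn}_wx", (d, 4 * H), d)
                    mat(f"{enc}_l{layer}{dirn}_wh", (H, 4 * H), H)
                    vec(f"{enc}_l{layer}{dirn}_b", 4 * H)
        # decoder: input = one-hot(prev token) + previous attentional vector
        mat("dec_wx", (config.vocab_size + H, 4 * H), config.vocab_size + H)
        mat("dec_wh", (H, 4 * H), H)
        vec("dec_b", 4 * H)
        mat("wa", (H, E), H)                  # attention bilinear form
        mat("wc", (E + H, H), E + H)          # attentional combination
        vec("wc_b", H)
        mat("wout", (H, config.vocab_size), H)
        vec("wout_b", config.vocab_size)

    # -- encoder ------------------------------------------------------------

    def _bilstm_stack(self, tape, prefix: str, x_block: np.ndarray,
                      batch: int) -> list[Tensor]:
        """Stacked BiLSTM over an input block (B, S, I); per-step outputs are
        forward/backward concatenations.  Input projections for a whole
        layer are computed as one matmul."""
        H = self.config.latent_dim
        steps: list[Tensor] | None = None
        for layer in range(self.config.encoder_layers):
            n_steps = x_block.shape[1] if steps is None else len(steps)
            outs_f: list[Tensor] = []
            outs_b: list[Tensor | None] = [None] * n_steps
            for dirn, order in (("f", range(n_steps)),
                                ("b", range(n_steps - 1, -1, -1))):
                wx = self.params[f"{prefix}_l{layer}{dirn}_wx"]
                wh = self.params[f"{prefix}_l{layer}{dirn}_wh"]
                b = self.params[f"{prefix}_l{layer}{dirn}_b"]
                if steps is None:
                    proj = ag.seq_input_proj(tape, x_block, wx, b)
                else:
                    proj = ag.seq_proj_tensor(tape, steps, wx, b)
                h = Tensor(np.zeros((batch, H)))
                c = Tensor(np.zeros((batch, H)))
                for t in order:
                    h, c = ag.lstm_cell_prx(tape, proj[t], h, c, wh)
                    if dirn == "f":
                        outs_f.append(h)
                    else:
                        outs_b[t] = h
            steps = [ag.concat(tape, [f, bwd], axis=1)
                     for f, bwd in zip(outs_f, outs_b)]
        return steps

    def encode(self, batch: Batch, tape: Tape | None = None) -> EncoderOutputs:
        """Run the encoder(s) for the configured mode.  Joint mode returns
        raw steps followed by event steps on the step axis."""
        mode = self.config.mode
        B = len(batch)
        blocks, masks = [], []
        if mode in ("raw", "joint"):
            blocks.append(self._bilstm_stack(tape, "raw", batch.raw[:, :, None], B))
            masks.append(batch.raw_mask)
        if mode in ("event", "joint"):
            blocks.append(self._bilstm_stack(tape, "event", batch.events, B))
            masks.append(batch.event_mask)
        steps = [s for blk in blocks for s in blk]
        out = ag.stack(tape, steps, axis=1)
        return EncoderOutputs(outputs=out, mask=np.concatenate(masks, axis=1))

    # -- decoder ------------------------------------------------------------

    def init_decoder_state(self, batch_size: int):
        H = self.config.latent_dim
        return (Tensor(np.zeros((batch_size, H))),
                Tensor(np.zeros((batch_size, H))),
                Tensor(np.zeros((batch_size, H))))  # h, c, previous h~

    def decode_step(self, prev_tokens: np.ndarray, state, enc: EncoderOutputs,
                    tape: Tape | None = None):
        """One decoder step: LSTM update, attention, attentional output.

        Returns (logits Tensor (B, 7), new state, attention weights (B, S)).
        """
        prev_tokens = np.asarray(prev_tokens, dtype=np.int64)
        if prev_tokens.min() < 0 or prev_tokens.max() >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary")
        h, c, h_tilde = state
        onehot = np.zeros((len(prev_tokens), self.config.vocab_size))
        onehot[np.arange(len(prev_tokens)), prev_tokens] = 1.0
        x = ag.concat(tape, [Tensor(onehot), h_tilde], axis=1)
        h, c = ag.lstm_cell(tape, x, h, c, self.params["dec_wx"],
                            self.params["dec_wh"], self.params["dec_b"])
        ctx, alpha = ag.attend(tape, h, self.params["wa"], enc.outputs, enc.mask)
        comb = ag.concat(tape, [ctx, h], axis=1)
        h_tilde = ag.tanh(tape, ag.add_bias(
            tape, ag.matmul(tape, comb, self.params["wc"]), self.params["wc_b"]))
        logits = ag.add_bias(tape, ag.matmul(tape, h_tilde, self.params["wout"]),
                             self.params["wout_b"])
        return logits, (h, c, h_tilde), alpha

    # -- training -----------------------------------------------------------

    def sequence_loss(self, batch: Batch, tape: Tape | None = None,
                      sampling_ratio: float = 1.0,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Masked mean cross-entropy of the decoded sequence against the
        target, teacher-forced with the given scheduled-sampling ratio
        (1.0 = always feed ground truth)."""
        targets, tmask = batch.targets, batch.target_mask
        if not tmask[:, 1:].any():
            raise ValueError("batch has no unmasked target positions")
        enc = self.encode(batch, tape)
        state = self.init_decoder_state(len(batch))
        prev = targets[:, 0]  # START
        total = None
        prev_logits = None
        for t in range(1, targets.shape[1]):
            if prev_logits is not None and sampling_ratio < 1.0:
                draw = rng.random() if rng is not None else 1.0
                if draw >= sampling_ratio:
                    prev = prev_logits.data.argmax(axis=1)
            logits, state, _ = self.decode_step(prev, state, enc, tape)
            step_loss = ag.cross_entropy_logits(tape, logits, targets[:, t],
                                                tmask[:, t])
            total = step_loss if total is None else ag.add(tape, total, step_loss)
            prev = targets[:, t]
            prev_logits = logits
        return ag.scale(tape, total, 1.0 / tmask[:, 1:].sum())

    def train_step(self, batch: Batch, optimizer: Adam, cfg: TrainConfig,
                   rng: np.random.Generator) -> float:
        tape = Tape()
        loss = self.sequence_loss(batch, tape, sampling_ratio=cfg.sampling_ratio,
                                  rng=rng)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss {loss.data!r}; aborting")
        optimizer.zero_grad()
        tape.backward(loss)
        clip_by_global_norm(list(self.params.values()), cfg.clip_norm)
        optimizer.step()
        return float(loss.data)

    def evaluate_loss(self, batches: list[Batch]) -> float:
        """Teacher-forced mean loss over batches (averaged across batches)."""
        losses = [float(self.sequence_loss(b).data) for b in batches]
        return float(np.mean(losses))

    def fit(self, train_batches: list[Batch], val_batches: list[Batch] | None,
            cfg: TrainConfig, log=None) -> list[dict]:
        optimizer = Adam(self.params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_batches))
            batch_losses = [self.train_step(train_batches[i], optimizer, cfg, rng)
                            for i in order]
            entry = {"epoch": epoch, "train_loss": float(np.mean(batch_losses))}
            if val_batches:
                entry["val_loss"] = self.evaluate_loss(val_batches)
            history.append(entry)
            if log is not None:
                log(entry)
        return history

    # -- persistence --------------------------------------------------------

    def save(self, path, extra: dict | None = None) -> None:
        arrays = {k: p.data for k, p in self.params.items()}
        meta = {"config": asdict(self.config), "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["Seq2SeqModel", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]))
            for k in model.params:
                model.params[k] = Tensor(data[k])
        return model, meta["extra"]
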