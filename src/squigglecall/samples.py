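"""Windowed sample construction, shuffling/splitting, standardization,
tokenization and batching of (raw, event, truth) data for the model.

A sample starts at every ``eventoffset``-th event and greedily gathers
consecutive events while the raw values they cover stay within ``rawmax``
(and the event count within ``eventmax``).  Its target is the bases whose
ground-truth raw range lies fully inside the sample's raw span, wrapped in
START/END markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .events import Event, N_FEATURES, featurize
from .simdata import RawRead

logger = logging.getLogger(__name__)

RAWMAX_DEFAULT = 200
EVENTMAX_DEFAULT = 30
BATCH_SIZE_DEFAULT = 128

PAD, START, END = 0, 1, 2
TOKEN_OF = {"A": 3, "C": 4, "G": 5, "T": 6}
BASE_OF = {v: k for k, v in TOKEN_OF.items()}
VOCAB_SIZE = 7


class Tokenizer:
    """Bijection between the 7-symbol vocabulary and integer ids:
    PAD=0, START=1, END=2, A=3, C=4, G=5, T=6."""

    vocab_size = VOCAB_SIZE
    pad, start, end = PAD, START, END

    def tokenize(self, bases: str) -> list[int]:
        try:
            body = [TOKEN_OF[b] for b in bases]
        except KeyError as exc:
            raise ValueError(f"unknown base symbol {exc.args[0]!r}") from None
        return [START] + body + [END]

    def detokenize(self, tokens) -> str:
        out = []
        for t in tokens:
            t = int(t)
            if t in (PAD, START):
                continue
            if t == END:
                break
            out.append(BASE_OF[t])
        return "".join(out)


@dataclass
class SampleRecord:
    read_id: str
    raw_values: np.ndarray      # (raw_len,)
    event_features: np.ndarray  # (event_count, 5)
    target_tokens: list[int]    # START ... END
    raw_start: int = 0

    @property
    def raw_len(self) -> int:
        return len(self.raw_values)

    @property
    def event_count(self) -> int:
        return len(self.event_features)


def build_samples(read: RawRead, events: list[Event],
                  rawmax: int = RAWMAX_DEFAULT, eventmax: int = EVENTMAX_DEFAULT,
                  eventoffset: int = 1) -> list[SampleRecord]:
    """Stride-``eventoffset`` greedy windowing of a read's events."""
    if eventoffset < 1:
        raise ValueError("eventoffset must be >= 1")
    if events and (events[0].raw_start != 0
                   or events[-1].raw_end != len(read.signal)
                   or any(a.raw_end != b.raw_start
                          for a, b in zip(events, events[1:]))):
        raise ValueError("events must tile the read signal")
    feats = featurize(events)
    samples: list[SampleRecord] = []
    for i in range(0, len(events), eventoffset):
        if events[i].raw_length > rawmax:
            logger.warning("skipping sample at event %d: first event longer "
                           "than rawmax (%d > %d)", i, events[i].raw_length, rawmax)
            continue
        total = 0
        j = i
        while j < len(events) and j - i < eventmax \
                and total + events[j].raw_length <= rawmax:
            total += events[j].raw_length
            j += 1
        span_start = events[i].raw_start
        span_end = events[j - 1].raw_end
        in_span = (read.truth_ranges[:, 0] >= span_start) \
            & (read.truth_ranges[:, 1] <= span_end)
        bases = "".join(read.reference.sequence[k] for k in np.nonzero(in_span)[0])
        samples.append(SampleRecord(
            read_id=read.read_id,
            raw_values=read.signal[span_start:span_end].astype(np.float64),
            event_features=feats[i:j].copy(),
            target_tokens=Tokenizer().tokenize(bases),
            raw_start=span_start))
    return samples


def build_inference_windows(read_id: str, signal: np.ndarray, events: list[Event],
                            rawmax: int = RAWMAX_DEFAULT,
                            eventmax: int = EVENTMAX_DEFAULT,
                            eventoffset: int = 1) -> list[SampleRecord]:
    """Sample windows for basecalling-time input (no ground truth): same
    greedy event gathering as :func:`build_samples`, empty targets."""
    if eventoffset < 1:
        raise ValueError("eventoffset must be >= 1")
    feats = featurize(events)
    samples: list[SampleRecord] = []
    for i in range(0, len(events), eventoffset):
        if events[i].raw_length > rawmax:
            logger.warning("skipping window at event %d: first event longer "
                           "than rawmax", i)
            continue
        total = 0
        j = i
        while j < len(events) and j - i < eventmax \
                and total + events[j].raw_length <= rawmax:
            total += events[j].raw_length
            j += 1
        span_start = events[i].raw_start
        span_end = events[j - 1].raw_end
        samples.append(SampleRecord(
            read_id=read_id,
            raw_values=np.asarray(signal[span_start:span_end], dtype=np.float64),
            event_features=feats[i:j].copy(),
            target_tokens=[START, END],
            raw_start=span_start))
    return samples


def split_dataset(samples: list[SampleRecord],
                  fractions: tuple[float, float, float], seed: int
                  ) -> tuple[list[SampleRecord], list[SampleRecord], list[SampleRecord]]:
    """Shuffle and split into (test, validation, train) by fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_test = int(round(fractions[0] * len(samples)))
    n_val = int(round(fractions[1] * len(samples)))
    test = [samples[i] for i in order[:n_test]]
    val = [samples[i] for i in order[n_test:n_test + n_val]]
    train = [samples[i] for i in order[n_test + n_val:]]
    return test, val, train


@dataclass
class ScalerSet:
    """Six standardizers: one for raw values, one per event feature.
    Fit on the training split only; standard deviations are floored."""

    raw_mean: float
    raw_sd: float
    event_mean: np.ndarray  # (5,)
    event_sd: np.ndarray    # (5,)

    SD_FLOOR = 1e-8

    @classmethod
    def fit(cls, train_samples: list[SampleRecord]) -> "ScalerSet":
        raw = np.concatenate([s.raw_values for s in train_samples])
        ev = np.concatenate([s.event_features for s in train_samples
                             if len(s.event_features)])
        return cls(raw_mean=float(raw.mean()),
                   raw_sd=max(float(raw.std()), cls.SD_FLOOR),
                   event_mean=ev.mean(axis=0),
                   event_sd=np.maximum(ev.std(axis=0), cls.SD_FLOOR))

    def transform(self, samples: list[SampleRecord]) -> list[SampleRecord]:
        out = []
        for s in samples:
            out.append(replace(
                s,
                raw_values=(s.raw_values - self.raw_mean) / self.raw_sd,
                event_features=(s.event_features - self.event_mean) / self.event_sd))
        return out

    def to_dict(self) -> dict:
        return {"raw_mean": self.raw_mean, "raw_sd": self.raw_sd,
                "event_mean": self.event_mean.tolist(),
                "event_sd": self.event_sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerSet":
        return cls(raw_mean=d["raw_mean"], raw_sd=d["raw_sd"],
                   event_mean=np.asarray(d["event_mean"]),
                   event_sd=np.asarray(d["event_sd"]))


@dataclass
class Batch:
    raw: np.ndarray          # (B, rawmax)
    raw_mask: np.ndarray     # (B, rawmax) bool
    events: np.ndarray       # (B, eventmax, 5)
    event_mask: np.ndarray   # (B, eventmax) bool
    targets: np.ndarray      # (B, T) int
    target_mask: np.ndarray  # (B, T) bool

    def __len__(self) -> int:
        return self.raw.shape[0]


def make_batches(samples: list[SampleRecord], batch_size: int = BATCH_SIZE_DEFAULT,
                 rawmax: int = RAWMAX_DEFAULT, eventmax: int = EVENTMAX_DEFAULT
                 ) -> list[Batch]:
    """Pad (truncating only as a safety net) and group samples into batches;
    the last batch may be smaller."""
    batches = []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        b = len(chunk)
        tmax = max(len(s.target_tokens) for s in chunk)
        raw = np.zeros((b, rawmax))
        raw_mask = np.zeros((b, rawmax), dtype=bool)
        ev = np.zeros((b, eventmax, N_FEATURES))
        ev_mask = np.zeros((b, eventmax), dtype=bool)
        tgt = np.full((b, tmax), PAD, dtype=np.int64)
        tgt_mask = np.zeros((b, tmax), dtype=bool)
        for r, s in enumerate(chunk):
            nr = min(s.raw_len, rawmax)
            raw[r, :nr] = s.raw_values[:nr]
            raw_mask[r, :nr] = True
            ne = min(s.event_count, eventmax)
            ev[r, :ne] = s.event_features[:ne]
            ev_mask[r, :ne] = True
            nt = len(s.target_tokens)
            tgt[r, :nt] = s.target_tokens
            tgt_mask[r, :nt] = True
        batches.append(Batch(raw, raw_mask, ev, ev_mask, tgt, tgt_mask))
    return batches
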