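"""Event segmentation of raw signal via sliding-window t-statistics.

A boundary candidate at position p compares the ``window`` samples ending
at p against the ``window`` samples starting at p with a Welch t-statistic;
boundaries are local maxima of |t| above a threshold, with non-maximum
suppression within one window length.  Each resulting segment becomes an
event carrying the 5-feature vector (mean, stdv, length, delta-mean,
mean squared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_FEATURES = 5


@dataclass(frozen=True)
class EventParams:
    window: int = 7
    threshold: float = 4.0
    variance_floor: float = 1e-9

    def __post_init__(self):
        if not 6 <= self.window <= 9:
            raise ValueError("window must be in 6..9")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass(frozen=True)
class Event:
    raw_start: int
    raw_length: int
    features: tuple[float, float, float, float, float]

    @property
    def raw_end(self) -> int:
        return self.raw_start + self.raw_length

    @property
    def mean(self) -> float:
        return self.features[0]


def tstat_trace(signal: np.ndarray, window: int,
                variance_floor: float = 1e-9) -> np.ndarray:
    """Welch t-statistic between the two adjacent length-``window`` blocks at
    every interior position; 0 where two full windows do not fit."""
    signal = np.asarray(signal, dtype=np.float64)
    n = len(signal)
    if n < 2 * window:
        raise ValueError("signal shorter than two windows")
    c1 = np.concatenate([[0.0], np.cumsum(signal)])
    c2 = np.concatenate([[0.0], np.cumsum(signal ** 2)])
    # block [p-w, p) vs [p, p+w) for p in [w, n-w]
    p = np.arange(window, n - window + 1)
    s_l = c1[p] - c1[p - window]
    s_r = c1[p + window] - c1[p]
    q_l = c2[p] - c2[p - window]
    q_r = c2[p + window] - c2[p]
    m_l = s_l / window
    m_r = s_r / window
    v_l = np.maximum(q_l / window - m_l ** 2, variance_floor)
    v_r = np.maximum(q_r / window - m_r ** 2, variance_floor)
    t = (m_l - m_r) / np.sqrt((v_l + v_r) / window)
    out = np.zeros(n)
    out[p] = t
    return out


def _pick_boundaries(trace: np.ndarray, window: int, threshold: float) -> list[int]:
    """Local maxima of |trace| above threshold, greedy non-maximum
    suppression within one window length, deterministic (higher |t| first,
    then lower index)."""
    a = np.abs(trace)
    n = len(a)
    cand = [p for p in range(1, n - 1)
            if a[p] > threshold and a[p] >= a[p - 1] and a[p] >= a[p + 1]]
    cand.sort(key=lambda p: (-a[p], p))
    kept: list[int] = []
    for p in cand:
        if all(abs(p - q) > window for q in kept):
            kept.append(p)
    return sorted(kept)


def detect_events(signal: np.ndarray, params: EventParams = EventParams()) -> list[Event]:
    """Segment a signal at t-statistic peaks and featurize the segments."""
    signal = np.asarray(signal, dtype=np.float64)
    if len(signal) < 2 * params.window:
        raise ValueError("signal shorter than two windows")
    trace = tstat_trace(signal, params.window, params.variance_floor)
    boundaries = _pick_boundaries(trace, params.window, params.threshold)
    edges = [0] + boundaries + [len(signal)]
    events = []
    prev_mean = None
    for start, end in zip(edges[:-1], edges[1:]):
        seg = signal[start:end]
        mean = float(seg.mean())
        stdv = float(seg.std())
        delta = 0.0 if prev_mean is None else prev_mean - mean
        events.append(Event(raw_start=start, raw_length=end - start,
                            features=(mean, stdv, float(end - start),
                                      delta, mean ** 2)))
        prev_mean = mean
    return events


def featurize(events: list[Event]) -> np.ndarray:
    """Stack event feature vectors into an (n_events, 5) matrix."""
    if not events:
        return np.zeros((0, N_FEATURES))
    return np.array([e.features for e in events], dtype=np.float64)


def events_to_tsv(events: list[Event], read_id: str, path) -> None:
    import pandas as pd

    rows = [(read_id, e.raw_start, e.raw_length, *e.features) for e in events]
    pd.DataFrame(rows, columns=["read_id", "start", "length", "mean", "stdv",
                                "len_feature", "delta_mean", "mean_sq"]
                 ).to_csv(path, sep="\t", index=False)
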