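"""Read assembly and accuracy evaluation.

Per-sample predictions are merged into a whole read by pairwise global
alignment against the tail of the growing consensus; accuracy is measured
as exact-match subset accuracy on samples and as alignment identity
(matches over total alignment columns, insertions and deletions included)
on whole reads, averaged with aligned block lengths as weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
MATCH_DEFAULT, MISMATCH_DEFAULT, GAP_DEFAULT = 1, -1, -1


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: int
    matches: int
    alignment_length: int


@dataclass
class AssembledRead:
    read_id: str
    sequence: str
    n_samples: int


@dataclass
class AccuracyReport:
    per_read: list[tuple[str, float, int]]  # (read_id, identity, block_length)
    weighted_identity: float
    subset_accuracy: float | None = None


def needleman_wunsch(a: str, b: str, match: int = MATCH_DEFAULT,
                     mismatch: int = MISMATCH_DEFAULT,
                     gap: int = GAP_DEFAULT) -> AlignmentResult:
    """Optimal global alignment under linear gap scoring.

    Traceback preference is diagonal > up (consume ``a``) > left (consume
    ``b``) for determinism.
    """
    la, lb = len(a), len(b)
    dp = np.empty((la + 1, lb + 1), dtype=np.int64)
    dp[:, 0] = gap * np.arange(la + 1)
    dp[0, :] = gap * np.arange(lb + 1)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, la + 1):
        sub = np.where(aa[i - 1] == bb, match, mismatch)
        row, prev = dp[i], dp[i - 1]
        # dp[i][j] = max(prev[j-1]+sub, prev[j]+gap, dp[i][j-1]+gap)
        best = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        acc = row[0]
        for j in range(1, lb + 1):
            acc = max(best[j - 1], acc + gap)
            row[j] = acc
    # traceback
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            i -= 1; j -= 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y and x != GAP for x, y in zip(aligned_a, aligned_b))
    return AlignmentResult(aligned_a=aligned_a, aligned_b=aligned_b,
                           score=int(dp[la, lb]), matches=matches,
                           alignment_length=len(aligned_a))


def _overlap_consume(window: str, pred: str, match: int, mismatch: int,
                     gap: int, expected: int | None = None) -> int:
    """How many leading characters of ``pred`` are covered by an optimal
    overlap alignment that may skip a prefix of ``window`` for free and must
    consume all of ``window``; the remaining ``pred`` suffix is the overhang
    to append.

    Ties prefer consuming less of ``pred``: for exact overlapping windows the
    true overlap o is the unique maximum among consumptions <= o (every
    consumed character scores at most +1), so this choice makes merging
    invert exact windowing.  The gap penalty must exceed the mismatch
    penalty, otherwise gapped alignments through tandem repeats can
    out-score the true overlap.

    When the caller knows the ``expected`` overlap (sample stride is known
    in the pipeline), consumptions are additionally penalized by their
    distance from it, which resolves the remaining coincidental-repeat
    ambiguity: an alignment at o+k can beat the true one by at most k, so a
    unit distance penalty makes the true overlap optimal and
    closest-to-expected."""
    lw, lp = len(window), len(pred)
    NEG = -(10 ** 9)
    dp = np.full((lw + 1, lp + 1), NEG, dtype=np.int64)
    dp[:, 0] = 0                       # free window prefix skip
    dp[0, 1:] = gap * np.arange(1, lp + 1)
    ww = np.frombuffer(window.encode(), dtype=np.uint8)
    pp = np.frombuffer(pred.encode(), dtype=np.uint8)
    for i in range(1, lw + 1):
        sub = np.where(ww[i - 1] == pp, match, mismatch)
        prev = dp[i - 1]
        best = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        acc = dp[i, 0]
        for j in range(1, lp + 1):
            acc = max(best[j - 1], acc + gap)
            dp[i, j] = acc
    final = dp[lw].astype(np.float64)
    if expected is not None:
        final = final - np.abs(np.arange(lp + 1) - expected)
    return int(np.flatnonzero(final == final.max())[0])


MERGE_GAP_DEFAULT = -2  # must be < mismatch; see _overlap_consume


def merge_samples(predictions: list[str], read_id: str = "read",
                  match: int = MATCH_DEFAULT, mismatch: int = MISMATCH_DEFAULT,
                  gap: int = MERGE_GAP_DEFAULT,
                  expected_overlaps: list[int] | None = None) -> AssembledRead:
    """Merge ordered per-sample predictions into one read.

    Each prediction is aligned to the tail of the growing consensus
    (window of twice its own length); on conflicts inside the overlap the
    earlier consensus wins, and only the part of the prediction extending
    past the consensus end is appended.

    ``expected_overlaps[k]`` (optional, one entry per prediction, entry 0
    ignored) is the anticipated overlap in bases between prediction k and
    the consensus, available in the pipeline from the sample stride.
    """
    if not predictions:
        raise ValueError("no predictions to merge")
    if expected_overlaps is not None and \
            len(expected_overlaps) != len(predictions):
        raise ValueError("need one expected overlap per prediction")
    consensus = ""
    used = 0
    for k, pred in enumerate(predictions):
        if not pred:
            logger.warning("skipping empty prediction %d", k)
            continue
        used += 1
        if not consensus:
            consensus = pred
            continue
        w = min(len(consensus), 2 * len(pred))
        window = consensus[len(consensus) - w:]
        expected = None if expected_overlaps is None \
            else min(expected_overlaps[k], w)
        consumed = _overlap_consume(window, pred, match, mismatch, gap,
                                    expected)
        consensus += pred[consumed:]
    return AssembledRead(read_id=read_id, sequence=consensus, n_samples=used)


def subset_accuracy(pred: str, truth: str) -> float:
    """Fraction of positions matching exactly; denominator is the longer of
    the two lengths.  Two empty sequences count as a perfect match."""
    if not pred and not truth:
        return 1.0
    hits = sum(p == t for p, t in zip(pred, truth))
    return hits / max(len(pred), len(truth))


def read_accuracy(read: AssembledRead | str, reference: str,
                  match: int = MATCH_DEFAULT, mismatch: int = MISMATCH_DEFAULT,
                  gap: int = GAP_DEFAULT) -> tuple[float, int]:
    """Alignment identity of a read against its reference: matching columns
    over total alignment length (insertions and deletions included), plus
    the aligned block length used as averaging weight."""
    seq = read.sequence if isinstance(read, AssembledRead) else read
    if not seq or not reference:
        raise ValueError("read and reference must be nonempty")
    aln = needleman_wunsch(seq, reference, match, mismatch, gap)
    return aln.matches / aln.alignment_length, aln.alignment_length


def weighted_identity(per_read: list[tuple[float, int]]) -> float:
    """Length-weighted mean of per-read identities (weights = block lengths)."""
    ids = np.array([i for i, _ in per_read], dtype=float)
    w = np.array([b for _, b in per_read], dtype=float)
    return float((ids * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# Evaluation-report summarizer over an accuracy table
# ---------------------------------------------------------------------------

def mean_beam_gain(table, wide: int = 5, narrow: int = 1,
                   models: list[str] | None = None, ndigits: int = 2) -> float:
    """Mean accuracy improvement (percentage points) of a wider beam over a
    narrower one, averaged over every (model, dataset) cell present.

    ``table`` has columns dataset, model, beam_width, accuracy (in %).
    """
    import pandas as pd

    df = pd.DataFrame(table, columns=["dataset", "model", "beam_width", "accuracy"]) \
        if not isinstance(table, pd.DataFrame) else table
    if models is not None:
        df = df[df["model"].isin(models)]
    piv = df.pivot_table(index=["dataset", "model"], columns="beam_width",
                         values="accuracy")
    return round(float((piv[wide] - piv[narrow]).mean()), ndigits)


def mean_model_gain(table, better: str, baseline: str,
                    beam_widths: list[int] | None = None, ndigits: int = 2) -> float:
    """Mean accuracy advantage (percentage points) of one model over another,
    averaged over every (dataset, beam width) cell present."""
    import pandas as pd

    df = pd.DataFrame(table, columns=["dataset", "model", "beam_width", "accuracy"]) \
        if not isinstance(table, pd.DataFrame) else table
    if beam_widths is not None:
        df = df[df["beam_width"].isin(beam_widths)]
    piv = df.pivot_table(index=["dataset", "beam_width"], columns="model",
                         values="accuracy")
    return round(float((piv[better] - piv[baseline]).mean()), ndigits)
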