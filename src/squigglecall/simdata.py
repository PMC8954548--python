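"""Synthetic squiggle generation at desk scale.

Builds reduced-complexity reference sequences from a restricted 6-mer
vocabulary, simulates pore-model raw current with per-base ground-truth
alignment, and measures restricted linguistic complexity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
K = 6
NUM_KMERS = 4 ** K  # 4096


def _all_kmers() -> list[str]:
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=K)]


@dataclass(frozen=True)
class KmerBasis:
    """A prefix of a seeded permutation of all 4096 6-mers.

    The nesting property — a smaller basis with the same seed is a prefix
    of a larger one — follows from the permutation depending only on the
    seed, not on the requested size.
    """

    k: int
    members: tuple[str, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ReferenceSequence:
    """A base sequence; generator-produced ones are whole numbers of 6-mer
    blocks, but the type itself also admits externally supplied references."""

    sequence: str
    source_basis_size: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PoreModel:
    """Map from each 6-mer occupying the pore to an expected current level.

    ``levels`` is indexed by the base-4 encoding of the 6-mer
    (A=0, C=1, G=2, T=3, most significant base first).
    """

    levels: np.ndarray  # (4096,) mean pA per 6-mer
    dwell_mean: float = 8.0
    noise_sd: float = 2.0
    seed: int = 0
    # "geometric": minimum 1 (memoryless); "geometric2": shifted to minimum 2
    # so no base is represented by a single raw sample; "constant": exact
    # dwell_mean per base.  All keep the mean at dwell_mean.
    dwell_distribution: str = "geometric"

    def __post_init__(self):
        if self.dwell_distribution not in ("geometric", "geometric2", "constant"):
            raise ValueError(
                "dwell_distribution must be geometric, geometric2 or constant")
        if self.levels.shape != (NUM_KMERS,):
            raise ValueError("levels must cover all 4096 6-mers")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_seed(cls, seed: int = 0, level_mean: float = 100.0,
                  level_sd: float = 15.0, dwell_mean: float = 8.0,
                  noise_sd: float = 2.0,
                  dwell_distribution: str = "geometric") -> "PoreModel":
        rng = np.random.default_rng(seed)
        levels = rng.normal(level_mean, level_sd, size=NUM_KMERS)
        levels = np.clip(levels, 1.0, None)  # current is non-negative
        return cls(levels=levels, dwell_mean=dwell_mean,
                   noise_sd=noise_sd, seed=seed,
                   dwell_distribution=dwell_distribution)

    def level_of(self, kmer: str) -> float:
        return float(self.levels[kmer_index(kmer)])


@dataclass
class RawRead:
    read_id: str
    signal: np.ndarray  # (n,) pA, non-negative
    reference: ReferenceSequence
    truth_ranges: np.ndarray  # (m, 2) half-open raw index ranges per base

    def __post_init__(self):
        m = len(self.reference.sequence)
        r = self.truth_ranges
        if r.shape != (m, 2):
            raise ValueError("one truth range per reference base required")
        if r[0, 0] != 0 or r[-1, 1] != len(self.signal):
            raise ValueError("truth ranges must span [0, n)")
        if np.any(r[1:, 0] != r[:-1, 1]) or np.any(r[:, 1] <= r[:, 0]):
            raise ValueError("truth ranges must partition [0, n)")


_BASE_CODE = {b: i for i, b in enumerate(ALPHABET)}


def kmer_index(kmer: str) -> int:
    """Base-4 integer encoding of a k-mer over ACGT."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + _BASE_CODE[b]
    return idx


def generate_kmer_basis(num_basic: int, seed: int) -> KmerBasis:
    """First ``num_basic`` entries of the seed-determined 6-mer permutation."""
    if not 1 <= num_basic <= NUM_KMERS:
        raise ValueError(f"num_basic must be in 1..{NUM_KMERS}, got {num_basic}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(NUM_KMERS)
    kmers = _all_kmers()
    members = tuple(kmers[i] for i in order[:num_basic])
    return KmerBasis(k=K, members=members, seed=seed)


def generate_reference(basis: KmerBasis, length: int, seed: int) -> ReferenceSequence:
    """Random variation with repetition of basis 6-mers, of defined length."""
    if length <= 0 or length % K != 0:
        raise ValueError(f"length must be a positive multiple of 6, got {length}")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(basis.members), size=length // K)
    seq = "".join(basis.members[i] for i in draws)
    return ReferenceSequence(sequence=seq, source_basis_size=len(basis.members))


def count_appearing_kmers(seq: str, k: int) -> int:
    """Distinct length-k substrings under a stride-1 sliding window."""
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    return len({seq[i:i + k] for i in range(len(seq) - k + 1)})


def linguistic_complexity(seq: str, k: int = K) -> float:
    """Observed distinct k-words over the maximum possible for this length."""
    observed = count_appearing_kmers(seq, k)
    possible = min(4 ** k, len(seq) - k + 1)
    return observed / possible


def de_bruijn_sequence(order: int, alphabet: str = ALPHABET) -> str:
    """Cyclic de Bruijn sequence B(|alphabet|, order): every word of the
    given order appears exactly once per cycle.  Standard Lyndon-word
    concatenation construction."""
    n = len(alphabet)
    seq: list[int] = []
    a = [0] * n * order

    def db(t: int, p: int) -> None:
        if t > order:
            if order % p == 0:
                seq.extend(a[1:p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return "".join(alphabet[i] for i in seq)


def centered_kmer(sequence: str, j: int, k: int = K, offset: int = 2) -> str:
    """The k-mer governing base j: window starting at j-offset, clamped so it
    stays inside the sequence."""
    start = min(max(j - offset, 0), len(sequence) - k)
    return sequence[start:start + k]


def simulate_signal(ref: ReferenceSequence, model: PoreModel, seed: int,
                    read_id: str = "read_0") -> RawRead:
    """Emit raw current for a reference: per base, a geometric dwell (mean
    ``dwell_mean``, minimum 1) of samples at the centered 6-mer's level plus
    Gaussian noise, clipped non-negative.  Truth ranges record each base's
    raw span."""
    m = len(ref.sequence)
    if m == 0:
        raise ValueError("empty reference")
    rng = np.random.default_rng(seed)
    if model.dwell_distribution == "constant":
        if model.dwell_mean != int(model.dwell_mean):
            raise ValueError("constant dwell requires an integer dwell_mean")
        dwells = np.full(m, int(model.dwell_mean), dtype=np.int64)
    elif model.dwell_mean == 1.0:
        dwells = np.ones(m, dtype=np.int64)
    elif model.dwell_distribution == "geometric2":
        if model.dwell_mean <= 2.0:
            raise ValueError("geometric2 requires dwell_mean > 2")
        dwells = 1 + rng.geometric(1.0 / (model.dwell_mean - 1.0), size=m)
    else:
        dwells = rng.geometric(1.0 / model.dwell_mean, size=m)
    ends = np.cumsum(dwells)
    starts = ends - dwells
    n = int(ends[-1])

    level_idx = np.fromiter(
        (kmer_index(centered_kmer(ref.sequence, j)) for j in range(m)),
        dtype=np.int64, count=m)
    per_base_level = model.levels[level_idx]
    signal = np.repeat(per_base_level, dwells)
    if model.noise_sd > 0:
        signal = signal + rng.normal(0.0, model.noise_sd, size=n)
    signal = np.clip(signal, 0.0, None)

    truth_ranges = np.stack([starts, ends], axis=1)
    return RawRead(read_id=read_id, signal=signal, reference=ref,
                   truth_ranges=truth_ranges)


def simulate_reads(basis_size: int, total_length: int, n_reads: int,
                   seed: int, model: PoreModel | None = None) -> list[RawRead]:
    """Convenience: split a total reference length over ``n_reads`` reads
    drawn from one basis, with per-read derived seeds."""
    if model is None:
        model = PoreModel.from_seed(seed)
    basis = generate_kmer_basis(basis_size, seed)
    per = (total_length // n_reads // K) * K
    reads = []
    for i in range(n_reads):
        ref = generate_reference(basis, per, seed=seed * 100003 + 7 * i + 1)
        reads.append(simulate_signal(ref, model, seed=seed * 999983 + 13 * i + 3,
                                     read_id=f"read_{i}"))
    return reads
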