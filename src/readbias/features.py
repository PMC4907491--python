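"""Normalized k-mer composition features and the sequence-complexity score.

A 41-nt window around a genomic position is summarized by the frequencies of
its overlapping k-mers. Each order k contributes a block of 4**k features,
normalized by the total number of k-mers in the window so every block is a
probability vector. Three canonical feature sets are used downstream:

- ``mono``:  the 4 single-nucleotide frequencies,
- ``multi``: the 16 + 64 + 256 di-/tri-/tetra-nucleotide frequencies,
- ``all``:   mono and multi concatenated (340 features).

The module also provides the sequence-complexity score
``sqrt((q/q_max) * (h/h_max))`` combining the transition count q (number of
adjacent unequal base pairs) with the Shannon entropy h of the base
frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

#: orders of k included in each named feature set
FEATURE_ORDERS: dict[str, tuple[int, ...]] = {
    "mono": (1,),
    "multi": (2, 3, 4),
    "all": (1, 2, 3, 4),
}


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0, C=1, G=2, T=3; anything else -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_names(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic A<C<G<T order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of the overlapping k-mers of an encoded sequence.

    Returns an int array of length ``len(codes) - k + 1``; a k-mer touching a
    non-ACGT base gets code -1.
    """
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        out = out * 4 + window
        bad |= window < 0
    out[bad] = -1
    return out


def count_kmers(window: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts of a window as a vector over all 4**k k-mers.

    The counts total ``len(window) - k + 1``. The window must be N-free.
    """
    if not 1 <= k <= len(window):
        raise ValueError(f"k={k} out of range for window of length {len(window)}")
    codes = encode(window)
    if (codes < 0).any():
        raise ValueError("window contains non-ACGT characters")
    kc = kmer_codes(codes, k)
    return np.bincount(kc, minlength=4**k).astype(np.int64)


@dataclass(frozen=True)
class KmerDistribution:
    """Normalized frequency vector over all 4**k k-mers, lexicographic order."""

    k: int
    freqs: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (4**self.k,):
            raise ValueError(
                f"order-{self.k} distribution needs {4 ** self.k} entries, "
                f"got {freqs.shape}"
            )
        total = freqs.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"distribution sums to {total!r}, expected 1")
        object.__setattr__(self, "freqs", freqs)

    @classmethod
    def from_counts(cls, k: int, counts: np.ndarray) -> "KmerDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("no countable k-mers")
        return cls(k=k, freqs=counts / total)

    @classmethod
    def uniform(cls, k: int = 1) -> "KmerDistribution":
        n = 4**k
        return cls(k=k, freqs=np.full(n, 1.0 / n))

    @classmethod
    def from_gc(cls, gc: float) -> "KmerDistribution":
        """Order-1 distribution with the given GC fraction, AT and GC split evenly."""
        if not 0.0 <= gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        at = (1.0 - gc) / 2.0
        return cls(k=1, freqs=np.array([at, gc / 2.0, gc / 2.0, at]))

    def names(self) -> list[str]:
        return kmer_names(self.k)


@dataclass
class FeatureVector:
    """Ordered, per-order-normalized k-mer features of one window."""

    names: list[str]
    values: np.ndarray
    label: int | None = None
    key: tuple[str, int] | None = field(default=None)  # (chrom, pos) provenance

    def __len__(self) -> int:
        return len(self.values)


def feature_names(feature_set: str) -> list[str]:
    orders = _orders(feature_set)
    return [f"{k}:{name}" for k in orders for name in kmer_names(k)]


def _orders(feature_set: str) -> tuple[int, ...]:
    try:
        return FEATURE_ORDERS[feature_set]
    except KeyError:
        raise ValueError(
            f"unknown feature set {feature_set!r}; expected one of "
            f"{sorted(FEATURE_ORDERS)}"
        ) from None


def extract_features(window: str, feature_set: str = "all") -> FeatureVector:
    """Per-order-normalized k-mer frequencies of one window.

    Each order's block is normalized by that order's k-mer total, so the
    blocks are independent probability vectors (lengths 4, 16, 64, 256).
    """
    orders = _orders(feature_set)
    if len(window) < max(orders):
        raise ValueError("window shorter than the highest k-mer order")
    blocks = []
    for k in orders:
        counts = count_kmers(window, k)
        blocks.append(counts / counts.sum())
    return FeatureVector(names=feature_names(feature_set), values=np.concatenate(blocks))


def feature_matrix(windows: list[str], feature_set: str = "all") -> np.ndarray:
    """Stack extract_features over windows into an (n, n_features) matrix."""
    orders = _orders(feature_set)
    n = len(windows)
    width = sum(4**k for k in orders)
    out = np.empty((n, width), dtype=float)
    for i, w in enumerate(windows):
        codes = encode(w)
        if (codes < 0).any():
            raise ValueError("window contains non-ACGT characters")
        offset = 0
        for k in orders:
            kc = kmer_codes(codes, k)
            counts = np.bincount(kc, minlength=4**k)
            out[i, offset : offset + 4**k] = counts / counts.sum()
            offset += 4**k
    return out


def euclidean(u, v) -> float:
    """Euclidean distance between two same-shape feature/distribution vectors."""
    a = u.values if isinstance(u, FeatureVector) else getattr(u, "freqs", u)
    b = v.values if isinstance(v, FeatureVector) else getattr(v, "freqs", v)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def complexity(seq: str) -> float:
    """Composite sequence complexity in [0, 1].

    ``sqrt((q/q_max) * (h/h_max))`` where q is the number of transitions
    (adjacent unequal bases), q_max = len - 1, h the Shannon entropy of the
    within-sequence base frequencies (natural log) and h_max = ln 4 for the
    full 4-letter alphabet. 0 for a homopolymer, 1 for a sequence that
    alternates at every step with equal base usage.
    """
    if len(seq) < 2:
        raise ValueError("complexity needs a sequence of length >= 2")
    codes = encode(seq)
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    q = int(np.count_nonzero(codes[1:] != codes[:-1]))
    q_max = len(seq) - 1
    freqs = np.bincount(codes, minlength=4) / len(seq)
    nz = freqs[freqs > 0]
    h = float(-(nz * np.log(nz)).sum())
    h_max = math.log(4.0)
    return math.sqrt((q / q_max) * (h / h_max)) + 0.0  # avoid -0.0
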