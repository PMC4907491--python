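"""Synthetic references and biased read-start tracks with known ground truth.

The simulator instantiates the pattern the downstream pipeline is built to
recognize: read starts preferentially land where the local window composition
is dissimilar from a global background distribution. Placement weights are an
exponential tilt of the local-vs-global Euclidean distance,

    weight(p) = exp(beta * d(p)),

where d(p) is the Euclidean distance between the order-k k-mer distribution
of the +/-halfwidth window around p and the background distribution. beta = 0
is the exact uniform null; larger beta concentrates reads on compositionally
unusual windows. Reads are drawn multinomially over eligible positions, so a
position can accumulate several read starts, producing the read-frequency
strata the pooling stage samples from.

The exponential-tilt form is this package's own modeling choice: it is the
simplest positive weight that recovers the uniform null exactly at beta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import KmerDistribution, encode, kmer_codes
from .pooling import eligible_mask, global_distribution
from .seqio import ReadStartTrack, ReferenceSequence


@dataclass
class BiasModel:
    """Ground-truth bias: order of the driving composition, strength, window.

    ``background`` is the "global" distribution the local windows are compared
    against; if None, it is computed from the reference itself at placement
    time.
    """

    order: int = 1
    beta: float = 0.0
    halfwidth: int = 20
    background: KmerDistribution | None = None

    def __post_init__(self):
        if self.order not in (1, 2, 3, 4):
            raise ValueError("order must be in {1, 2, 3, 4}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.halfwidth < self.order:
            raise ValueError("halfwidth must be >= order")
        if self.background is not None and self.background.k != self.order:
            raise ValueError("background distribution order must match model order")


def structural_direction(k: int) -> np.ndarray:
    """Unit direction in order-k distribution space invisible to lower orders.

    The k-fold outer product of a = (1,-1,1,-1)/2 over the bases: every
    marginalization to a lower order sums a +/- pattern to zero, so a
    distribution displaced along this direction keeps all of its lower-order
    k-mer marginals unchanged. For k=2 this is the purine/pyrimidine
    correlation contrast.
    """
    if k < 2:
        raise ValueError("structural directions exist only for order >= 2")
    a = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
    u = a
    for _ in range(k - 1):
        u = np.outer(u, a).ravel()
    return u


def structural_background(
    global_dist: KmerDistribution, fraction: float = 0.8
) -> KmerDistribution:
    """The global order-k distribution displaced along the structural direction.

    Used as the default background of an order >= 2 bias model: because the
    displacement is large compared to per-window fluctuations, the distance
    term d(p) is approximately linear in the projection of the local
    deviation onto the (lower-order-neutral) displacement direction, so the
    resulting read-placement bias is specific to order k — invisible to
    mono-nucleotide features by construction. ``fraction`` sets the
    displacement as a fraction of the largest step keeping all entries
    non-negative.
    """
    u = structural_direction(global_dist.k)
    nz = np.abs(u) > 0
    c = fraction * float(np.min(global_dist.freqs[nz] / np.abs(u[nz])))
    return KmerDistribution(k=global_dist.k, freqs=global_dist.freqs - c * u)


def simulate_reference(
    length: int,
    composition: KmerDistribution | None = None,
    seed: int = 0,
    name: str = "sim",
) -> ReferenceSequence:
    """An i.i.d. random sequence with the given mononucleotide composition."""
    if length < 41:
        raise ValueError("sequence shorter than one window")
    if composition is None:
        composition = KmerDistribution.uniform(1)
    if composition.k != 1:
        raise ValueError("reference composition must be an order-1 distribution")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=composition.freqs)
    seq = "".join(np.array(list("ACGT"))[codes])
    return ReferenceSequence(name=name, seq=seq)


def position_distances(
    ref: ReferenceSequence, model: BiasModel
) -> tuple[np.ndarray, np.ndarray]:
    """Eligible positions and their local-vs-background Euclidean distances.

    Eligible positions are window centres in [halfwidth, length-1-halfwidth]
    whose window is N-free. The local distribution is the overlapping order-k
    k-mer frequency vector of the window.
    """
    k, h = model.order, model.halfwidth
    codes = encode(ref.seq)
    positions = np.flatnonzero(eligible_mask(ref, h))
    if positions.size == 0:
        raise ValueError("reference has no eligible positions")
    background = model.background
    if background is None:
        background = global_distribution([ref], k)
        if k >= 2:
            # default order>=2 bias is made specific to that order: displace
            # the background structurally so the tilt is lower-order-neutral
            background = structural_background(background)
    kc = kmer_codes(codes, k)
    # cumulative one-hot counts of k-mer codes -> O(1) window counts
    nk = 4**k
    onehot = np.zeros((kc.shape[0] + 1, nk), dtype=np.int32)
    valid = kc >= 0
    rows = np.flatnonzero(valid) + 1
    onehot[rows, kc[valid]] = 1
    cum = np.cumsum(onehot, axis=0)
    starts = positions - h  # first k-mer index inside each window
    ends = positions + h - k + 2  # one past the last k-mer index
    counts = cum[ends] - cum[starts]
    totals = counts.sum(axis=1, keepdims=True)
    local = counts / totals
    d = np.linalg.norm(local - background.freqs[None, :], axis=1)
    return positions, d


def placement_weights(
    ref: ReferenceSequence, model: BiasModel
) -> tuple[np.ndarray, np.ndarray]:
    """Eligible positions and their normalized multinomial placement weights."""
    positions, d = position_distances(ref, model)
    logw = model.beta * d
    w = np.exp(logw - logw.max())  # stable; normalization removes the shift
    return positions, w / w.sum()


def place_reads(
    ref: ReferenceSequence,
    model: BiasModel,
    n_reads: int,
    seed: int = 0,
) -> ReadStartTrack:
    """Draw read starts multinomially over eligible positions.

    The returned sparse track sums exactly to ``n_reads``; reads land on the
    forward strand only (the downstream pipeline never uses strand).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    positions, probs = placement_weights(ref, model)
    track = ReadStartTrack(name=ref.name)
    if n_reads == 0:
        return track
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs)
    for pos, c in zip(positions[counts > 0], counts[counts > 0]):
        track.counts[int(pos)] = int(c)
    return track
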