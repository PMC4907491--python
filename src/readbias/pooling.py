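"""Sequence data pools: stratified position sampling and composition summaries.

A pool is built by sampling genomic positions stratified by read-start
frequency (classes 0, 1, ..., 10 and "11+") and attaching the +/-20 bp
reference window around each as a 41-character instance. The pool is the
input of every downstream stage: distance tables, GC summaries and the
classification datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import KmerDistribution, count_kmers, encode, euclidean
from .seqio import ReadStartTrack, ReferenceSequence

logger = logging.getLogger(__name__)

#: read-frequency classes, in table order
FREQ_CLASSES: list[int | str] = list(range(11)) + ["11+"]

#: frequency groupings used by the distance and GC summary tables
DEFAULT_GROUPS: list[tuple[str, int, int | None]] = [
    ("0", 0, 0),
    ("1-5", 1, 5),
    ("6-10", 6, 10),
    ("11+", 11, None),
]

#: per-class position counts modeled on a five-chromosome plant genome run
_BASE_STRATA = [5000] + [500] * 10 + [5000]


def default_strata(scale: float = 1.0) -> list[tuple[int | str, int]]:
    """The default stratum sizes (5000/500x10/5000) scaled by a factor."""
    return [
        (cls, max(1, round(n * scale))) for cls, n in zip(FREQ_CLASSES, _BASE_STRATA)
    ]


def freq_class(freq: int) -> int | str:
    """Map a read-start count to its frequency class (0..10 or '11+')."""
    if freq < 0:
        raise ValueError("negative frequency")
    return freq if freq <= 10 else "11+"


@dataclass
class PoolConfig:
    halfwidth: int = 20
    strata: list[tuple[int | str, int]] = field(default_factory=default_strata)
    seed: int = 0

    def __post_init__(self):
        if self.halfwidth < 1:
            raise ValueError("halfwidth must be >= 1")
        for cls, n in self.strata:
            if cls not in FREQ_CLASSES:
                raise ValueError(f"unknown frequency class {cls!r}")
            if n < 0:
                raise ValueError("requested stratum counts must be >= 0")


@dataclass(frozen=True)
class PoolInstance:
    chrom: str
    pos: int  # 0-based
    window: str
    freq: int


@dataclass
class SequencePool:
    instances: list[PoolInstance]
    provenance: dict

    def __len__(self) -> int:
        return len(self.instances)

    def windows(self) -> list[str]:
        return [inst.window for inst in self.instances]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [i.chrom for i in self.instances],
                "pos": [i.pos + 1 for i in self.instances],  # 1-based on output
                "freq": [i.freq for i in self.instances],
                "window": [i.window for i in self.instances],
            }
        )


def write_pool_tsv(pool: SequencePool, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tpos(1-based)\tfreq\twindow\n")
        for inst in pool.instances:
            fh.write(f"{inst.chrom}\t{inst.pos + 1}\t{inst.freq}\t{inst.window}\n")


def read_pool_tsv(path) -> SequencePool:
    instances = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom, pos_s, freq_s, window = parts
            instances.append(
                PoolInstance(
                    chrom=chrom, pos=int(pos_s) - 1, window=window, freq=int(freq_s)
                )
            )
    halfwidth = len(instances[0].window) // 2 if instances else None
    return SequencePool(instances=instances, provenance={"source": str(path), "halfwidth": halfwidth})


def eligible_mask(ref: ReferenceSequence, halfwidth: int) -> np.ndarray:
    """Boolean mask over positions whose +/-halfwidth window fits and is N-free."""
    codes = encode(ref.seq)
    n = codes.shape[0]
    mask = np.zeros(n, dtype=bool)
    if n < 2 * halfwidth + 1:
        return mask
    is_n = (codes < 0).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    centers = np.arange(halfwidth, n - halfwidth)
    n_in_window = cum[centers + halfwidth + 1] - cum[centers - halfwidth]
    mask[centers] = n_in_window == 0
    return mask


def build_pool(
    refs: list[ReferenceSequence],
    tracks: list[ReadStartTrack],
    config: PoolConfig,
) -> SequencePool:
    """Sample positions per frequency stratum and attach their windows.

    Within a stratum, eligible positions whose read-start frequency falls in
    that class are drawn uniformly without replacement, up to the requested
    count (fewer, with a warning, if the class is smaller). Classes are
    disjoint, so a position can enter the pool at most once.
    """
    if not refs:
        raise ValueError("no reference sequences given")
    track_by_chrom = {t.name: t for t in tracks}
    for t in tracks:
        if t.name not in {r.name for r in refs}:
            raise ValueError(f"track chromosome {t.name!r} has no reference")

    # gather (chrom index, position, freq) for all eligible positions
    per_class: dict[int | str, list[tuple[int, int, int]]] = {
        cls: [] for cls in FREQ_CLASSES
    }
    for ri, ref in enumerate(refs):
        mask = eligible_mask(ref, config.halfwidth)
        positions = np.flatnonzero(mask)
        track = track_by_chrom.get(ref.name)
        freqs = np.zeros(ref.length, dtype=np.int64)
        if track is not None:
            for pos, c in track.counts.items():
                if pos < ref.length:
                    freqs[pos] = c
        for pos in positions:
            per_class[freq_class(int(freqs[pos]))].append((ri, int(pos), int(freqs[pos])))

    rng = np.random.default_rng(config.seed)
    instances: list[PoolInstance] = []
    for cls, requested in config.strata:
        candidates = per_class[cls]
        if requested == 0:
            continue
        take = min(requested, len(candidates))
        if take < requested:
            logger.warning(
                "stratum %r: only %d of %d requested positions available",
                cls,
                take,
                requested,
            )
        if take == 0:
            continue
        chosen = rng.choice(len(candidates), size=take, replace=False)
        for idx in sorted(chosen):
            ri, pos, freq = candidates[idx]
            ref = refs[ri]
            instances.append(
                PoolInstance(
                    chrom=ref.name,
                    pos=pos,
                    window=ref.window(pos, config.halfwidth),
                    freq=freq,
                )
            )
    if not instances:
        raise ValueError("all strata are empty; no positions sampled")
    return SequencePool(
        instances=instances,
        provenance={
            "chroms": [r.name for r in refs],
            "seed": config.seed,
            "halfwidth": config.halfwidth,
        },
    )


def global_distribution(refs: list[ReferenceSequence], k: int) -> KmerDistribution:
    """Normalized overlapping k-mer frequencies across whole references.

    k-mers containing an N are skipped.
    """
    if k not in (1, 2, 3, 4):
        raise ValueError("k must be in {1, 2, 3, 4}")
    from .features import kmer_codes

    counts = np.zeros(4**k, dtype=np.int64)
    for ref in refs:
        kc = kmer_codes(encode(ref.seq), k)
        kc = kc[kc >= 0]
        counts += np.bincount(kc, minlength=4**k)
    if counts.sum() == 0:
        raise ValueError("no countable k-mers in the references")
    return KmerDistribution.from_counts(k, counts)


def _group_members(pool: SequencePool, lo: int, hi: int | None) -> list[PoolInstance]:
    return [
        inst
        for inst in pool.instances
        if inst.freq >= lo and (hi is None or inst.freq <= hi)
    ]


def pool_distance_table(
    pool: SequencePool,
    global_mono: KmerDistribution,
    global_di: KmerDistribution,
    groups: list[tuple[str, int, int | None]] | None = None,
    orders: str = "mono+di",
) -> pd.DataFrame:
    """Euclidean distance between local and global composition, per group.

    For each frequency group, all windows in the group are pooled and their
    mono- and di-nucleotide counts are normalized within each order; the two
    blocks are concatenated (``orders='mono+di'``, the default) or the
    di-nucleotide block is used alone (``orders='di'``), and the Euclidean
    distance to the same concatenation of the global distributions is
    reported. Groups with no instances get NaN.
    """
    if orders not in ("mono+di", "di"):
        raise ValueError(f"unknown orders selection {orders!r}")
    groups = groups if groups is not None else DEFAULT_GROUPS
    rows = []
    for label, lo, hi in groups:
        members = _group_members(pool, lo, hi)
        if not members:
            rows.append({"group": label, "n": 0, "distance": np.nan})
            continue
        mono = np.zeros(4, dtype=np.int64)
        di = np.zeros(16, dtype=np.int64)
        for inst in members:
            mono += count_kmers(inst.window, 1)
            di += count_kmers(inst.window, 2)
        local_blocks, global_blocks = [], []
        if orders == "mono+di":
            local_blocks.append(mono / mono.sum())
            global_blocks.append(global_mono.freqs)
        local_blocks.append(di / di.sum())
        global_blocks.append(global_di.freqs)
        dist = euclidean(
            np.concatenate(local_blocks), np.concatenate(global_blocks)
        )
        rows.append({"group": label, "n": len(members), "distance": dist})
    return pd.DataFrame(rows)


def pool_gc_table(
    pool: SequencePool,
    groups: list[tuple[str, int, int | None]] | None = None,
) -> pd.DataFrame:
    """GC fraction of all window bases pooled per frequency group."""
    groups = groups if groups is not None else DEFAULT_GROUPS
    rows = []
    for label, lo, hi in groups:
        members = _group_members(pool, lo, hi)
        if not members:
            rows.append({"group": label, "n": 0, "gc": np.nan})
            continue
        gc = sum(w.count("G") + w.count("C") for w in (m.window for m in members))
        total = sum(len(m.window) for m in members)
        rows.append({"group": label, "n": len(members), "gc": gc / total})
    return pd.DataFrame(rows)
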