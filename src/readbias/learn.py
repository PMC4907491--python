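"""Balanced classification datasets, 3-NN, the pattern effect index, GA selection.

The question asked of the classifier is descriptive, not predictive: can
positions where reads start be told apart from positions with no reads using
only the k-mer composition of the surrounding window? Balanced binary
datasets keep chance performance at 50%; the pattern effect index

    PEI = (accuracy% - 50) / 50

rescales the 3-nearest-neighbor test accuracy so that 0 means read placement
is random with respect to window composition and 1 means it is fully
predictable from it. A PEI above 0.05 (three null standard deviations, see
``AFFECTED_THRESHOLD``) is read as composition-affected positioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .features import feature_matrix, feature_names
from .pooling import PoolConfig, SequencePool, build_pool
from .seqio import ReadStartTrack, ReferenceSequence

logger = logging.getLogger(__name__)

#: PEI above which read positioning is called composition-affected
AFFECTED_THRESHOLD = 0.05


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and per-instance (chrom, pos) keys."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    keys: list[tuple[str, int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.keys):
            raise ValueError("X, y and keys must agree in length")
        labels, counts = np.unique(self.y, return_counts=True)
        if not np.array_equal(labels, [0, 1]):
            raise ValueError("labels must be exactly {0, 1}")
        if counts[0] != counts[1]:
            raise ValueError(f"dataset is unbalanced: {counts[0]} vs {counts[1]}")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class SplitPair:
    train: LabeledDataset
    test: LabeledDataset

    def __post_init__(self):
        overlap = set(self.train.keys) & set(self.test.keys)
        if overlap:
            raise ValueError(f"{len(overlap)} instances shared between train and test")


def make_split(
    pool: SequencePool,
    min_reads: int,
    feature_set: str = "all",
    seed: int = 0,
) -> SplitPair:
    """Balanced train/test pair for the "0 vs min_reads or more" problem.

    Frequency-0 instances are split into equal train/test halves (an odd
    instance goes to train) and labeled 0; the same per-half numbers are drawn
    without replacement from instances with freq >= min_reads and labeled 1.
    If class 1 is too small, both classes shrink to the feasible equal size.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    rng = np.random.default_rng(seed)
    zeros = [i for i in pool.instances if i.freq == 0]
    ones = [i for i in pool.instances if i.freq >= min_reads]
    if not zeros or not ones:
        raise ValueError(
            f"need instances in both classes: {len(zeros)} with freq 0, "
            f"{len(ones)} with freq >= {min_reads}"
        )
    n0 = len(zeros)
    test_half, train_half = n0 // 2, n0 - n0 // 2
    if len(ones) < train_half + test_half:
        feasible = len(ones) // 2
        logger.warning(
            "only %d class-1 instances for %d class-0; shrinking both classes "
            "to %d per half",
            len(ones),
            n0,
            feasible,
        )
        train_half = test_half = feasible
        if feasible == 0:
            raise ValueError("class 1 too small to fill even one instance per half")
        zeros = [zeros[i] for i in rng.choice(n0, size=2 * feasible, replace=False)]
    else:
        zeros = [zeros[i] for i in rng.permutation(n0)]
    chosen1 = rng.choice(len(ones), size=train_half + test_half, replace=False)
    ones = [ones[i] for i in chosen1]

    def build(insts0, insts1, problem) -> LabeledDataset:
        insts = list(insts0) + list(insts1)
        X = feature_matrix([i.window for i in insts], feature_set)
        y = np.array([0] * len(insts0) + [1] * len(insts1))
        return LabeledDataset(
            X=X,
            y=y,
            names=feature_names(feature_set),
            keys=[(i.chrom, i.pos) for i in insts],
            meta={"problem": f"0vs{min_reads}+", "feature_set": feature_set, "seed": seed},
        )

    train = build(zeros[:train_half], ones[:train_half], min_reads)
    test = build(zeros[train_half:], ones[train_half:], min_reads)
    return SplitPair(train=train, test=test)


def shuffle_labels(
    ds: LabeledDataset, times: int = 10, seed: int = 0
) -> list[LabeledDataset]:
    """Label-permutation replicates: the null where composition says nothing."""
    if times < 1:
        raise ValueError("times must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(times):
        perm = rng.permutation(len(ds))
        out.append(
            LabeledDataset(
                X=ds.X, y=ds.y[perm], names=ds.names, keys=ds.keys, meta=dict(ds.meta)
            )
        )
    return out


@dataclass
class ClassifierResult:
    accuracy: float  # percent
    predictions: np.ndarray


def knn_classify(
    train: LabeledDataset, test: LabeledDataset, k: int = 3
) -> ClassifierResult:
    """K-nearest-neighbor majority vote under Euclidean distance.

    Distance ties at the K-th neighbor are broken by lower train-instance
    index, making predictions fully deterministic.
    """
    if len(train) < k:
        raise ValueError(f"train set of {len(train)} smaller than K={k}")
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError("train and test feature spaces differ")
    dists = cdist(test.X, train.X)
    n_train = len(train)
    idx = np.arange(n_train)
    preds = np.empty(len(test), dtype=int)
    for i in range(len(test)):
        order = np.lexsort((idx, dists[i]))[:k]
        votes = train.y[order]
        preds[i] = 1 if votes.sum() * 2 > k else 0
    accuracy = 100.0 * float(np.mean(preds == test.y))
    return ClassifierResult(accuracy=accuracy, predictions=preds)


def compute_pei(accuracy: float) -> float:
    """Pattern effect index of a classification accuracy given in percent."""
    if not 0.0 <= accuracy <= 100.0:
        raise ValueError(f"accuracy {accuracy} outside [0, 100]")
    return (accuracy - 50.0) / 50.0


@dataclass
class PEIResult:
    """Replicate accuracies and the pattern effect index of their mean."""

    replicates: list[float]  # accuracies, percent
    seeds: list[int]
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)
    pei: float = field(init=False)
    affected: bool = field(init=False)

    def __post_init__(self):
        acc = np.asarray(self.replicates, dtype=float)
        self.mean_accuracy = float(acc.mean())
        self.sd_accuracy = float(acc.std(ddof=1)) if acc.size > 1 else 0.0
        self.pei = compute_pei(self.mean_accuracy)
        self.affected = self.pei > AFFECTED_THRESHOLD


def measure_pei(
    refs: list[ReferenceSequence],
    tracks: list[ReadStartTrack],
    min_reads: int,
    feature_set: str = "all",
    pool_config: PoolConfig | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> PEIResult:
    """Repeat pool -> split -> 3-NN and summarize accuracies as a PEI.

    Replicate r uses seed ``seed + r`` for both pooling and splitting, so the
    whole measurement is reproducible from one seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    pool_config = pool_config if pool_config is not None else PoolConfig()
    accuracies, seeds = [], []
    for r in range(replicates):
        s = seed + r
        pool = build_pool(refs, tracks, replace(pool_config, seed=s))
        split = make_split(pool, min_reads, feature_set, seed=s)
        accuracies.append(knn_classify(split.train, split.test).accuracy)
        seeds.append(s)
    return PEIResult(replicates=accuracies, seeds=seeds)


@dataclass
class GAConfig:
    pop_size: int = 50
    generations: int = 20
    p_crossover: float = 0.8
    p_mutation: float = 0.05
    elitism: bool = True
    selection: str = "roulette"  # or "tournament"
    tournament_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.selection not in ("roulette", "tournament"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")


@dataclass
class GAResult:
    mask: np.ndarray  # 1 = feature selected
    best_fitness_per_generation: list[float]
    final_accuracy: float


def _masked(ds: LabeledDataset, mask: np.ndarray) -> LabeledDataset:
    cols = np.flatnonzero(mask)
    return LabeledDataset(
        X=ds.X[:, cols],
        y=ds.y,
        names=[ds.names[c] for c in cols],
        keys=ds.keys,
        meta=dict(ds.meta),
    )


def ga_select(
    split: SplitPair,
    config: GAConfig | None = None,
    initial_population: np.ndarray | None = None,
) -> GAResult:
    """Wrapper feature selection with a generational binary GA.

    Chromosomes are feature masks; the fitness of a mask is the test accuracy
    of the 3-NN classifier trained on the masked train set. Test-set fitness
    is intentional: the search describes which features carry the recognized
    pattern in *this* data, it does not build a predictor. Selection is
    fitness-proportionate (roulette) by default, single-point crossover,
    per-bit mutation, and elitism carries the best individual of a generation
    over the worst of the next.
    """
    config = config if config is not None else GAConfig()
    n_features = split.train.X.shape[1]
    if n_features < 2:
        raise ValueError("feature selection needs at least 2 features")
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = knn_classify(
                _masked(split.train, mask), _masked(split.test, mask)
            ).accuracy
        return cache[key]

    def randomize_empty(pop: np.ndarray) -> np.ndarray:
        # an all-zero chromosome selects nothing and cannot be evaluated
        for i in np.flatnonzero(~pop.any(axis=1)):
            pop[i, rng.integers(n_features)] = 1
        return pop

    if initial_population is not None:
        pop = np.array(initial_population, dtype=np.int64)
        if pop.shape != (config.pop_size, n_features):
            raise ValueError("initial population shape mismatch")
        pop = randomize_empty(pop)
    else:
        pop = randomize_empty(rng.integers(0, 2, size=(config.pop_size, n_features)))
    elite_mask: np.ndarray | None = None
    elite_fit: float = -np.inf
    best_mask: np.ndarray | None = None
    best_fit: float = -np.inf
    history: list[float] = []

    for gen in range(config.generations):
        fits = np.array([fitness(ind) for ind in pop])
        if config.elitism and elite_mask is not None:
            worst = int(np.argmin(fits))
            pop[worst] = elite_mask
            fits[worst] = elite_fit
        gen_best = int(np.argmax(fits))
        elite_mask, elite_fit = pop[gen_best].copy(), float(fits[gen_best])
        if elite_fit > best_fit:
            best_mask, best_fit = elite_mask.copy(), elite_fit
        history.append(float(fits[gen_best]))
        if gen == config.generations - 1:
            break

        if config.selection == "roulette":
            weights = fits / fits.sum() if fits.sum() > 0 else None
            parents = rng.choice(config.pop_size, size=config.pop_size, p=weights)
        else:
            contenders = rng.integers(
                0, config.pop_size, size=(config.pop_size, config.tournament_size)
            )
            parents = contenders[
                np.arange(config.pop_size), np.argmax(fits[contenders], axis=1)
            ]
        nxt = pop[parents].copy()
        for i in range(0, config.pop_size - 1, 2):
            if rng.random() < config.p_crossover and n_features > 1:
                point = int(rng.integers(1, n_features))
                nxt[i, point:], nxt[i + 1, point:] = (
                    nxt[i + 1, point:].copy(),
                    nxt[i, point:].copy(),
                )
        flips = rng.random(nxt.shape) < config.p_mutation
        nxt[flips] ^= 1
        pop = randomize_empty(nxt)

    return GAResult(
        mask=best_mask, best_fitness_per_generation=history, final_accuracy=best_fit
    )
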