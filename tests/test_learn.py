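"""Balanced splits, 3-NN, label-shuffling null, PEI and the GA selector."""

import itertools

import numpy as np
import pytest

import readbias as rb
from readbias.learn import (
    GAConfig,
    LabeledDataset,
    SplitPair,
    compute_pei,
    ga_select,
    knn_classify,
    make_split,
    measure_pei,
    shuffle_labels,
)
from readbias.pooling import PoolInstance, SequencePool


def _pool_with(freqs, seed=0):
    """Pool of random 41-mers carrying the requested frequencies."""
    rng = np.random.default_rng(seed)
    instances = [
        PoolInstance(
            chrom="c",
            pos=100 + i,
            window="".join(rng.choice(list("ACGT"), size=41)),
            freq=f,
        )
        for i, f in enumerate(freqs)
    ]
    return SequencePool(instances=instances, provenance={})


def test_make_split_balanced_halves():
    pool = _pool_with([0] * 10 + [3] * 20)
    split = make_split(pool, min_reads=1, feature_set="mono", seed=0)
    for ds in (split.train, split.test):
        assert len(ds) == 10
        assert (ds.y == 0).sum() == 5 and (ds.y == 1).sum() == 5


def test_make_split_shrinks_when_class1_scarce(caplog):
    pool = _pool_with([0] * 10 + [12] * 7)
    with caplog.at_level("WARNING"):
        split = make_split(pool, min_reads=11, feature_set="mono", seed=0)
    assert len(split.train) == 6 and len(split.test) == 6
    assert any("shrinking" in rec.message for rec in caplog.records)


def test_make_split_no_position_overlap():
    pool = _pool_with([0] * 21 + [1] * 40)
    split = make_split(pool, min_reads=1, feature_set="mono", seed=4)
    train_keys = set(split.train.keys)
    test_keys = set(split.test.keys)
    assert not train_keys & test_keys
    # odd class-0 count: the extra instance goes to train
    assert (split.train.y == 0).sum() == 11 and (split.test.y == 0).sum() == 10


def test_make_split_requires_both_classes():
    with pytest.raises(ValueError):
        make_split(_pool_with([0] * 10), min_reads=1)
    with pytest.raises(ValueError):
        make_split(_pool_with([2] * 10), min_reads=1)


def test_split_pair_rejects_shared_instances():
    pool = _pool_with([0] * 4 + [1] * 4)
    split = make_split(pool, min_reads=1, feature_set="mono", seed=0)
    with pytest.raises(ValueError, match="shared"):
        SplitPair(train=split.train, test=split.train)


def test_shuffle_labels_preserves_multiset_and_is_seeded():
    pool = _pool_with([0] * 20 + [1] * 40)
    ds = make_split(pool, 1, "mono", seed=1).train
    reps = shuffle_labels(ds, times=10, seed=2)
    assert len(reps) == 10
    for rep in reps:
        assert (rep.y == 0).sum() == (ds.y == 0).sum()
    again = shuffle_labels(ds, times=10, seed=2)
    assert all(np.array_equal(a.y, b.y) for a, b in zip(reps, again))


def _toy_dataset(X, y):
    return LabeledDataset(
        X=np.asarray(X, dtype=float),
        y=np.asarray(y),
        names=[f"f{i}" for i in range(np.asarray(X).shape[1])],
        keys=[("c", i) for i in range(len(y))],
    )


def test_knn_majority_beats_proximity():
    train = _toy_dataset([[1.0], [2.0], [2.0], [9.0]], [0, 1, 1, 0])
    test = _toy_dataset([[0.0], [0.0]], [1, 0])
    result = knn_classify(train, test, k=3)
    # nearest three are 0@1, 1@2, 1@2 -> majority label 1
    assert list(result.predictions) == [1, 1]
    assert result.accuracy == pytest.approx(50.0)


def test_knn_coincident_points():
    train = _toy_dataset(
        [[5.0], [5.0], [5.0], [0.0], [0.0], [0.0]], [1, 1, 1, 0, 0, 0]
    )
    test = _toy_dataset([[5.0], [1.0]], [1, 0])
    assert list(knn_classify(train, test).predictions) == [1, 0]
    assert knn_classify(train, test).accuracy == 100.0


def test_knn_train_smaller_than_k():
    ds = _toy_dataset([[0.0], [1.0]], [0, 1])
    with pytest.raises(ValueError):
        knn_classify(ds, ds, k=3)


def _brute_force_knn(train, test, k=3):
    """Oracle: exhaustively sort all (distance, index) pairs per test point."""
    preds = []
    for x in test.X:
        pairs = sorted(
            (float(np.linalg.norm(x - t)), i) for i, t in enumerate(train.X)
        )
        votes = [train.y[i] for _, i in pairs[:k]]
        preds.append(1 if sum(votes) > k / 2 else 0)
    return np.array(preds)


def test_knn_matches_brute_force_oracle_on_random_data():
    rng = np.random.default_rng(42)
    for trial in range(100):
        n_train = int(rng.integers(4, 30))
        n_test = int(rng.integers(1, 15))
        dim = int(rng.integers(1, 6))
        half = n_train // 2
        Xtr = np.vstack(
            [rng.normal(0, 1, (half, dim)), rng.normal(1.5, 1, (n_train - 2 * half + half, dim))]
        )
        ytr = np.array([0] * half + [1] * (n_train - half))
        train = LabeledDataset(
            X=Xtr[: 2 * half],
            y=ytr[: 2 * half],
            names=[f"f{i}" for i in range(dim)],
            keys=[("c", i) for i in range(2 * half)],
        )
        test = LabeledDataset(
            X=rng.normal(0.7, 1.5, (2 * (n_test // 2 + 1), dim)),
            y=np.array([0, 1] * (n_test // 2 + 1)),
            names=train.names,
            keys=[("d", i) for i in range(2 * (n_test // 2 + 1))],
        )
        got = knn_classify(train, test).predictions
        assert np.array_equal(got, _brute_force_knn(train, test))


def test_knn_agrees_with_sklearn_on_tie_free_data():
    """Independent cross-check against scikit-learn where no distance ties
    exist (continuous Gaussian features make ties measure-zero)."""
    from sklearn.neighbors import KNeighborsClassifier

    rng = np.random.default_rng(7)
    Xtr = rng.normal(size=(40, 5))
    ytr = np.array([0, 1] * 20)
    Xte = rng.normal(size=(20, 5))
    train = _toy_dataset(Xtr, ytr)
    test = _toy_dataset(Xte, [0, 1] * 10)
    sk = KNeighborsClassifier(n_neighbors=3).fit(Xtr, ytr).predict(Xte)
    assert np.array_equal(knn_classify(train, test).predictions, sk)


@pytest.mark.parametrize(
    "accuracy,expected", [(52.41, 0.0482), (100.0, 1.0), (50.0, 0.0)]
)
def test_compute_pei_values(accuracy, expected):
    assert compute_pei(accuracy) == pytest.approx(expected)


@pytest.mark.parametrize("accuracy", [-0.1, 100.1])
def test_compute_pei_range_check(accuracy):
    with pytest.raises(ValueError):
        compute_pei(accuracy)


def test_pei_strictly_increasing_in_accuracy():
    grid = np.linspace(0, 100, 21)
    values = [compute_pei(a) for a in grid]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_null_calibration_mean_accuracy_near_50(small_ref):
    """With labels shuffled, 3-NN accuracy must straddle chance: the mean
    over 10 permutation replicates stays within 3 standard errors of 50%."""
    track = rb.place_reads(small_ref, rb.BiasModel(order=2, beta=0.0), 5000, seed=40)
    pool = rb.build_pool(
        [small_ref], [track], rb.PoolConfig(strata=rb.default_strata(0.05), seed=41)
    )
    split = make_split(pool, 1, "all", seed=41)
    accs = []
    for strain, stest in zip(
        shuffle_labels(split.train, 10, seed=42), shuffle_labels(split.test, 10, seed=43)
    ):
        accs.append(knn_classify(strain, stest).accuracy)
    accs = np.array(accs)
    se = accs.std(ddof=1) / np.sqrt(len(accs))
    assert abs(accs.mean() - 50.0) <= 3 * max(se, 1e-9)


def test_measure_pei_replicate_bookkeeping(small_ref, biased_track):
    result = measure_pei(
        [small_ref],
        [biased_track],
        min_reads=1,
        feature_set="mono",
        pool_config=rb.PoolConfig(strata=rb.default_strata(0.02)),
        replicates=5,
        seed=10,
    )
    assert len(result.replicates) == 5
    assert result.seeds == [10, 11, 12, 13, 14]
    assert result.pei == pytest.approx((result.mean_accuracy - 50) / 50)
    assert result.affected == (result.pei > 0.05)


def _separable_split(n_noise=5, n=40, seed=0):
    """Feature 0 determines the class exactly; the rest is noise."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 1 + n_noise))
    X[:, 0] = y * 2.0 + rng.normal(0, 0.05, n)
    train = _toy_dataset(X[: n // 2], y[: n // 2])
    test = LabeledDataset(
        X=X[n // 2 :],
        y=y[n // 2 :],
        names=train.names,
        keys=[("d", i) for i in range(n // 2)],
    )
    return SplitPair(train=train, test=test)


def test_ga_no_variation_keeps_seeded_optimum():
    split = _separable_split()
    n_feat = split.train.X.shape[1]
    optimal = np.zeros(n_feat, dtype=np.int64)
    optimal[0] = 1
    population = np.tile(optimal, (10, 1))
    config = GAConfig(pop_size=10, generations=5, p_crossover=0.0, p_mutation=0.0, seed=1)
    result = ga_select(split, config, initial_population=population)
    assert np.array_equal(result.mask, optimal)
    trace = result.best_fitness_per_generation
    assert len(set(trace)) == 1


def test_ga_elitism_trace_non_decreasing():
    split = _separable_split(seed=3)
    result = ga_select(split, GAConfig(pop_size=12, generations=10, seed=5))
    trace = result.best_fitness_per_generation
    assert all(b >= a for a, b in zip(trace, trace[1:]))
    assert result.mask.sum() >= 1


def test_ga_finds_informative_feature_vs_exhaustive_oracle():
    """On a toy problem with one decisive feature among noise, the GA's best
    mask must match the exhaustively-found optimal fitness."""
    split = _separable_split(n_noise=5, n=60, seed=8)
    n_feat = split.train.X.shape[1]

    def fitness(mask):
        cols = np.flatnonzero(mask)
        train = LabeledDataset(
            X=split.train.X[:, cols],
            y=split.train.y,
            names=[split.train.names[c] for c in cols],
            keys=split.train.keys,
        )
        test = LabeledDataset(
            X=split.test.X[:, cols],
            y=split.test.y,
            names=train.names,
            keys=split.test.keys,
        )
        return knn_classify(train, test).accuracy

    best_fit = max(
        fitness(np.array(bits))
        for bits in itertools.product([0, 1], repeat=n_feat)
        if any(bits)
    )
    result = ga_select(split, GAConfig(pop_size=20, generations=15, seed=9))
    assert result.mask[0] == 1
    assert result.final_accuracy == pytest.approx(best_fit, abs=1.0)


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GAConfig(pop_size=1)
    with pytest.raises(ValueError):
        GAConfig(p_crossover=1.5)
    with pytest.raises(ValueError):
        GAConfig(selection="rank")
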