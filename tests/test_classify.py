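"""SVM workflow and the inheritable-GA feature selector."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hcsneurons.classify import (
    Chromosome,
    IBCGAConfig,
    SVM_PARAM_GRID,
    SVMParams,
    aggregate_runs,
    cv_accuracy,
    evaluate_independent,
    grid_search_svm,
    ibcga_run,
    oa_crossover,
    orthogonal_array,
    prepare_feature_table,
    stratified_split,
)


def make_table(n_per_class=36, classes=(0, 10, 50, 100, 200, 1000), seed=0, sep=2.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, d in enumerate(classes):
        for _ in range(n_per_class):
            rows.append(
                {"dose_ng_per_ml": d, "a": sep * i + rng.normal(), "b": rng.normal()}
            )
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_216_rows_gives_144_72(self):
        table = make_table()
        train, test = stratified_split(table, seed=0)
        assert len(train) == 144 and len(test) == 72
        assert (train.groupby("dose_ng_per_ml").size() == 24).all()
        assert (test.groupby("dose_ng_per_ml").size() == 12).all()

    def test_partition_is_exact(self):
        table = make_table(n_per_class=5)
        train, test = stratified_split(table, seed=1)
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(table.index)

    def test_seven_row_class_round_half_up(self):
        table = make_table(n_per_class=7, classes=(0, 10))
        train, test = stratified_split(table, seed=2)
        assert (train.groupby("dose_ng_per_ml").size() == 5).all()
        assert (test.groupby("dose_ng_per_ml").size() == 2).all()

    def test_single_row_class_rejected(self):
        table = make_table(n_per_class=1, classes=(0, 10))
        with pytest.raises(ValueError):
            stratified_split(table)

    def test_deterministic_per_seed(self):
        table = make_table()
        a, _ = stratified_split(table, seed=3)
        b, _ = stratified_split(table, seed=3)
        assert a.index.equals(b.index)


class TestCVAccuracy:
    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        assert cv_accuracy(X, y, SVMParams(1, 1), folds=5, seed=0) == 100.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (180, 4))
        y = np.repeat(np.arange(6), 30)
        rng.shuffle(y)
        acc = cv_accuracy(X, y, SVMParams(1, 0.1), folds=6, seed=0)
        assert acc == pytest.approx(100 / 6, abs=8)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 3))
        y = np.repeat([0, 1], 20)
        a = cv_accuracy(X, y, SVMParams(2, 0.5), folds=4, seed=5)
        b = cv_accuracy(X, y, SVMParams(2, 0.5), folds=4, seed=5)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cv_accuracy(np.zeros((10, 2)), np.zeros(10), SVMParams(1, 1))


class TestGridSearch:
    def test_returns_grid_member_and_max(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(2, 1, (10, 2))])
        y = np.repeat([0, 1], 10)
        params, acc = grid_search_svm(X, y, folds=2, seed=0)
        assert params.C in SVM_PARAM_GRID and params.gamma in SVM_PARAM_GRID
        # independent brute-force sweep
        best = max(
            cv_accuracy(X, y, SVMParams(c, g), folds=2, seed=0)
            for c in SVM_PARAM_GRID
            for g in SVM_PARAM_GRID
        )
        assert acc == best

    def test_separable_reaches_100(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.05, (12, 2)), rng.normal(9, 0.05, (12, 2))])
        y = np.repeat([0, 1], 12)
        _, acc = grid_search_svm(X, y, folds=3, seed=0)
        assert acc == 100.0


class TestIndependentEvaluation:
    def test_confusion_matrix_reconciles(self):
        table = make_table(n_per_class=12)
        train, test = stratified_split(table, seed=0)
        Xtr, ytr, _ = prepare_feature_table(train)
        Xte, yte, _ = prepare_feature_table(test)
        acc, cm = evaluate_independent(Xtr, ytr, Xte, yte, SVMParams(4, 0.5))
        counts = pd.Series(yte).value_counts()
        for label in cm.index:
            assert cm.loc[label].sum() == counts[label]
        assert acc == pytest.approx(100 * np.trace(cm.values) / len(yte))

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_independent(
                np.zeros((4, 3)), np.array([0, 0, 1, 1]),
                np.zeros((2, 2)), np.array([0, 1]), SVMParams(1, 1),
            )

    def test_nan_rows_dropped_with_warning(self, caplog):
        table = make_table(n_per_class=4, classes=(0, 10))
        table.loc[0, "a"] = np.nan
        with caplog.at_level("WARNING"):
            X, y, names = prepare_feature_table(table)
        assert len(X) == len(table) - 1
        assert "dropped 1" in caplog.text


class TestOACrossover:
    def test_orthogonal_array_is_balanced_and_orthogonal(self):
        for k in (2, 3, 5, 7):
            oa = orthogonal_array(k)
            assert oa.shape[1] == k and oa.shape[0] <= 2 * k + 2
            for col in oa.T:
                assert col.sum() == len(col) // 2
            for i, j in itertools.combinations(range(k), 2):
                pairs = list(zip(oa[:, i], oa[:, j]))
                for combo in itertools.product([0, 1], repeat=2):
                    assert pairs.count(combo) == len(oa) // 4

    def test_identical_parents_copied_without_evaluation(self):
        bits = np.array([1, 0, 1, 0], dtype=np.uint8)
        p = Chromosome(bits, 3, 4)
        calls = []
        c1, c2 = oa_crossover(p, p.copy(), lambda ch: calls.append(1) or 0.0)
        assert not calls
        assert np.array_equal(c1.feature_bits, bits) and np.array_equal(c2.feature_bits, bits)

    @pytest.mark.parametrize("k", [2, 4])
    def test_main_effect_child_matches_exhaustive_optimum(self, k):
        # parents share popcount and differ in k bits (k/2 swapped pairs);
        # weights make the unconstrained optimum keep that popcount, so
        # repair is a no-op and the main-effect child must equal the
        # exhaustive argmax over all 2^k level combinations
        n = 8
        bits1 = np.zeros(n, np.uint8)
        bits2 = np.zeros(n, np.uint8)
        bits1[[0, 1]] = 1
        bits2[[2, 3]] = 1
        if k == 4:
            diff = [0, 1, 2, 3]
        else:
            bits1[[2]] = 1
            bits2[[0]] = 1  # now differ only in bits 1 and 3
            diff = [1, 3]
        common = np.array([6, 7])
        bits1[common] = bits2[common] = 1
        w = np.array([-1.0, -2.0, 3.0, 4.0, 0, 0, 0.5, 0.5])
        p1, p2 = Chromosome(bits1, 2, 2), Chromosome(bits2, 2, 2)

        def fitness(ch):
            return float(w @ ch.feature_bits)

        _, child2 = oa_crossover(p1, p2, fitness, np.random.default_rng(0))
        best = -np.inf
        for combo in itertools.product([0, 1], repeat=len(diff)):
            v = bits1.copy()
            for pos, lvl in zip(diff, combo):
                v[pos] = bits2[pos] if lvl else bits1[pos]
            if v.sum() == p1.r:
                best = max(best, float(w @ v))
        assert fitness(child2) == best

    def test_children_preserve_popcount(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            bits1 = (rng.random(10) < 0.5).astype(np.uint8)
            if bits1.sum() in (0, 10):
                continue
            bits2 = bits1.copy()
            rng.shuffle(bits2)
            p1 = Chromosome(bits1, int(rng.integers(16)), int(rng.integers(16)))
            p2 = Chromosome(bits2, int(rng.integers(16)), int(rng.integers(16)))
            c1, c2 = oa_crossover(p1, p2, lambda ch: float(ch.feature_bits.sum()), rng)
            assert c1.r == p1.r and c2.r == p1.r

    def test_evaluation_budget_l8(self):
        # k <= 7 differing factors fit in an L8 array: at most 8 trials
        bits1 = np.array([1, 1, 1, 0, 0, 0, 1, 0], np.uint8)
        bits2 = np.array([0, 0, 0, 1, 1, 1, 1, 0], np.uint8)
        calls = []
        oa_crossover(
            Chromosome(bits1, 0, 5),  # 6 bit factors + the C gene = 7 factors
            Chromosome(bits2, 1, 5),
            lambda ch: calls.append(1) or 0.0,
            np.random.default_rng(0),
        )
        assert len(calls) <= 8  # one evaluation per L8 row


@pytest.fixture(scope="module")
def planted_table():
    """Six ordinal classes; features 0-2 informative, 3-12 pure noise."""
    rng = np.random.default_rng(42)
    y = np.repeat(np.arange(6), 13)
    X = rng.normal(0, 1, (len(y), 13))
    for f in range(3):
        X[:, f] += 1.4 * y
    return X, y


class TestIBCGA:
    def test_degenerate_single_stage_full_features(self, planted_table):
        X, y = planted_table
        cfg = IBCGAConfig(r_start=13, r_end=13, generations_per_stage=2,
                          population_size=6, cv_folds=3)
        run = ibcga_run(X, y, cfg, seed=0)
        assert len(run.per_r) == 1
        assert run.best.chromosome.r == 13

    def test_popcount_invariant_and_elitism(self, planted_table):
        X, y = planted_table
        cfg = IBCGAConfig(r_start=6, r_end=3, generations_per_stage=3,
                          population_size=6, cv_folds=3)
        run = ibcga_run(X, y, cfg, seed=1)
        for stage in run.per_r:
            assert stage.chromosome.r == stage.r
        # elitism: best fitness non-decreasing across generations within one r
        for r in {h[0] for h in run.history}:
            fits = [f for (rr, g, f) in run.history if rr == r]
            assert all(b >= a - 1e-9 for a, b in zip(fits, fits[1:]))

    def test_deterministic_per_seed(self, planted_table):
        X, y = planted_table
        cfg = IBCGAConfig(r_start=5, r_end=4, generations_per_stage=2,
                          population_size=5, cv_folds=3)
        a = ibcga_run(X, y, cfg, seed=7)
        b = ibcga_run(X, y, cfg, seed=7)
        assert a.best.accuracy == b.best.accuracy
        assert np.array_equal(a.best.chromosome.feature_bits, b.best.chromosome.feature_bits)

    def test_r_start_above_feature_count_rejected(self, planted_table):
        X, y = planted_table
        with pytest.raises(ValueError):
            ibcga_run(X, y, IBCGAConfig(r_start=14), seed=0)

    def test_informative_features_outrank_noise(self, planted_table):
        X, y = planted_table
        cfg = IBCGAConfig(r_start=13, r_end=1, generations_per_stage=3,
                          population_size=8, cv_folds=3)
        runs = [ibcga_run(X, y, cfg, seed=s) for s in range(5)]
        report = aggregate_runs(runs, [f"f{i}" for i in range(13)])
        counts = report.selection_counts
        assert min(counts[:3]) > max(counts[3:])

    def test_aggregate_counts_bounded(self, planted_table):
        X, y = planted_table
        cfg = IBCGAConfig(r_start=4, r_end=3, generations_per_stage=2,
                          population_size=5, cv_folds=3)
        runs = [ibcga_run(X, y, cfg, seed=s) for s in range(3)]
        report = aggregate_runs(runs, [f"f{i}" for i in range(13)])
        assert report.selection_counts.min() >= 0
        assert report.selection_counts.max() <= 3
        d = report.to_dict()
        assert d["best"]["C"] in SVM_PARAM_GRID and d["best"]["gamma"] in SVM_PARAM_GRID
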