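"""Multi-class dose classification and GA-wrapped feature selection.

An RBF-kernel support vector machine (one-vs-one multi-class, features
z-scored on the training data only) classifies images into dose classes;
10-fold stratified cross-validation accuracy is the universal fitness.
Feature selection runs an inheritable bi-objective combinatorial genetic
algorithm (IBCGA): at each stage every chromosome carries exactly r
feature bits set plus two 4-bit genes indexing the SVM cost C and kernel
width gamma on the grid {2^-7 .. 2^8}; the population evolves for a
fixed number of generations with tournament selection, orthogonal-array
crossover and popcount-preserving swap mutation, then r decreases by one
(each chromosome drops one randomly chosen selected feature) and
evolution continues.  The best 10-CV solution over all stages is the
final answer; repeated seeded runs are aggregated into per-feature
selection frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SVM_PARAM_GRID",
    "SVMParams",
    "Chromosome",
    "IBCGAConfig",
    "SelectionReport",
    "prepare_feature_table",
    "stratified_split",
    "cv_accuracy",
    "grid_search_svm",
    "evaluate_independent",
    "orthogonal_array",
    "oa_crossover",
    "ibcga_run",
    "aggregate_runs",
]

#: 16-value exponential grid shared by C and gamma: 2^-7 .. 2^8.
SVM_PARAM_GRID = tuple(2.0**e for e in range(-7, 9))


@dataclass(frozen=True)
class SVMParams:
    C: float
    gamma: float


@dataclass
class Chromosome:
    """Feature bits plus two 4-bit genes indexing the C / gamma grid."""

    feature_bits: np.ndarray  # (n,) uint8
    c_gene: int
    gamma_gene: int

    def __post_init__(self) -> None:
        self.feature_bits = np.asarray(self.feature_bits, dtype=np.uint8)
        if not (0 <= self.c_gene < 16 and 0 <= self.gamma_gene < 16):
            raise ValueError("4-bit genes must lie in [0, 16)")

    @property
    def params(self) -> SVMParams:
        return SVMParams(SVM_PARAM_GRID[self.c_gene], SVM_PARAM_GRID[self.gamma_gene])

    @property
    def r(self) -> int:
        return int(self.feature_bits.sum())

    def key(self) -> tuple:
        return (self.feature_bits.tobytes(), self.c_gene, self.gamma_gene)

    def copy(self) -> "Chromosome":
        return Chromosome(self.feature_bits.copy(), self.c_gene, self.gamma_gene)


def prepare_feature_table(
    table: pd.DataFrame, dose_column: str = "dose_ng_per_ml"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, feature_names), dropping NaN rows.

    Rows with undefined per-soma averages (no soma detected) cannot enter
    the classifier; they are dropped with a logged count.
    """
    features = [
        c for c in table.columns if c != dose_column and pd.api.types.is_numeric_dtype(table[c])
    ]
    clean = table.dropna(subset=features)
    dropped = len(table) - len(clean)
    if dropped:
        logger.warning("dropped %d rows with missing feature values", dropped)
    X = clean[features].to_numpy(dtype=float)
    y = clean[dose_column].to_numpy()
    return X, y, features


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    dose_column: str = "dose_ng_per_ml",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class random split; train size = round-half-up(fraction x class size).

    A 6x36 table at fraction 2/3 gives 24 train / 12 test per class.
    Classes with a single row cannot be split and raise.
    """
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for _, sub in table.groupby(dose_column, sort=True):
        if len(sub) < 2:
            raise ValueError("every class needs >= 2 rows to split")
        n_train = int(math.floor(train_fraction * len(sub) + 0.5))  # round half up
        n_train = min(max(n_train, 1), len(sub) - 1)
        perm = rng.permutation(sub.index.to_numpy())
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]


def _svm(params: SVMParams) -> SVC:
    # one-vs-one is sklearn's internal multi-class scheme for SVC
    return SVC(kernel="rbf", C=params.C, gamma=params.gamma)


def cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold accuracy (percent) of the z-scored RBF SVM.

    Standardization is fit inside each training fold (no leakage).
    """
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = make_pipeline(StandardScaler(), _svm(params))
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return 100.0 * float(np.mean(accs))


def grid_search_svm(
    X: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0
) -> tuple[SVMParams, float]:
    """Exhaustive 16x16 sweep of (C, gamma); ties go to smaller C, then gamma."""
    best: tuple[SVMParams, float] | None = None
    for c in SVM_PARAM_GRID:
        for g in SVM_PARAM_GRID:
            params = SVMParams(c, g)
            acc = cv_accuracy(X, y, params, folds=folds, seed=seed)
            if best is None or acc > best[1]:
                best = (params, acc)
    return best


def evaluate_independent(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    params: SVMParams,
) -> tuple[float, pd.DataFrame]:
    """Fit on the full training set; accuracy and confusion matrix on test.

    The confusion matrix has true classes on rows, predictions on
    columns; row sums equal the per-class test counts.
    """
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    model = make_pipeline(StandardScaler(), _svm(params))
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    labels = np.unique(np.concatenate([y_train, y_test]))
    cm = _sk_confusion(y_test, pred, labels=labels)
    acc = 100.0 * float(np.trace(cm)) / len(y_test)
    frame = pd.DataFrame(cm, index=labels, columns=labels)
    return acc, frame


# ---------------------------------------------------------------------------
# orthogonal-array crossover


def orthogonal_array(k: int) -> np.ndarray:
    """Two-level orthogonal array L_m(2^(m-1)) with m-1 >= k columns.

    Sylvester-Hadamard construction: entry (i, j) = popcount(i & j) mod 2
    for rows i = 0..m-1 and columns j = 1..m-1; the first k columns are
    returned.  m is the smallest power of two exceeding k.
    """
    m = 2
    while m - 1 < k:
        m *= 2
    rows = np.arange(m)
    cols = np.arange(1, m)
    arr = np.zeros((m, m - 1), dtype=np.uint8)
    for jj, j in enumerate(cols):
        arr[:, jj] = [bin(int(i) & int(j)).count("1") % 2 for i in rows]
    return arr[:, :k]


def _gene_vector(ch: Chromosome) -> np.ndarray:
    return np.concatenate([ch.feature_bits, [ch.c_gene, ch.gamma_gene]])


def _from_gene_vector(v: np.ndarray, n: int) -> Chromosome:
    return Chromosome(v[:n].astype(np.uint8), int(v[n]), int(v[n + 1]))


def _repair_popcount(ch: Chromosome, r: int, effect: np.ndarray | None, rng) -> None:
    """Flip bits (lowest main-effect first when known) until popcount = r."""
    bits = ch.feature_bits
    n = len(bits)
    pri = effect[:n] if effect is not None else rng.random(n)
    while bits.sum() > r:
        ones = np.flatnonzero(bits)
        bits[ones[np.argmin(pri[ones])]] = 0
    while bits.sum() < r:
        zeros = np.flatnonzero(bits == 0)
        bits[zeros[np.argmax(pri[zeros])]] = 1


def oa_crossover(
    p1: Chromosome,
    p2: Chromosome,
    fitness,
    rng: np.random.Generator | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Orthogonal-array crossover over the genes where the parents differ.

    Each differing gene (a feature bit, or one whole 4-bit SVM gene) is a
    two-level factor: level 0 takes parent 1's value, level 1 parent 2's.
    The OA rows are evaluated with ``fitness`` (at most m <= 2k trials
    instead of 2^k); child 1 is the best evaluated row, child 2 is
    composed from each factor's main-effect winner.  Genes shared by both
    parents pass through unchanged; children are repaired to parent 1's
    popcount by flipping lowest-main-effect bits.
    """
    rng = rng or np.random.default_rng()
    n = len(p1.feature_bits)
    v1, v2 = _gene_vector(p1), _gene_vector(p2)
    diff = np.flatnonzero(v1 != v2)
    if len(diff) == 0:
        return p1.copy(), p2.copy()
    r = p1.r
    oa = orthogonal_array(len(diff))
    m = oa.shape[0]

    trials, scores = [], []
    for row in oa:
        v = v1.copy()
        v[diff[row == 1]] = v2[diff[row == 1]]
        ch = _from_gene_vector(v, n)
        _repair_popcount(ch, r, None, rng)
        trials.append(ch)
        scores.append(fitness(ch))
    scores = np.asarray(scores, dtype=float)

    # main effects: mean fitness at level 1 minus level 0, per factor
    main = np.array(
        [scores[oa[:, f] == 1].mean() - scores[oa[:, f] == 0].mean() for f in range(len(diff))]
    )
    v_best = v1.copy()
    winners = diff[main > 0]
    v_best[winners] = v2[winners]
    child2 = _from_gene_vector(v_best, n)
    # repair priority: effect magnitude per gene position (unknown -> 0)
    effect_by_pos = np.zeros(n + 2)
    effect_by_pos[diff] = np.abs(main)
    _repair_popcount(child2, r, effect_by_pos, rng)

    child1 = trials[int(np.argmax(scores))].copy()
    return child1, child2


# ---------------------------------------------------------------------------
# IBCGA


@dataclass
class IBCGAConfig:
    r_start: int = 13
    r_end: int = 1
    generations_per_stage: int = 20
    population_size: int = 50
    tournament_size: int = 2
    mutation_rate: float = 0.05
    n_runs: int = 30
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not (self.r_start >= self.r_end >= 1):
            raise ValueError("need r_start >= r_end >= 1")
        if self.generations_per_stage < 1:
            raise ValueError("generations_per_stage must be >= 1")


@dataclass
class StageBest:
    r: int
    chromosome: Chromosome
    accuracy: float


@dataclass
class RunResult:
    per_r: list[StageBest]
    best: StageBest
    n_evaluations: int
    history: list[tuple[int, int, float]] = field(default_factory=list)  # (r, gen, best fitness)


@dataclass
class SelectionReport:
    feature_names: list[str]
    selection_counts: np.ndarray  # per-feature count over runs
    best: StageBest
    per_run_best: list[StageBest] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selection_counts": dict(
                zip(self.feature_names, self.selection_counts.astype(int).tolist())
            ),
            "best": {
                "features": [
                    f
                    for f, b in zip(self.feature_names, self.best.chromosome.feature_bits)
                    if b
                ],
                "C": self.best.chromosome.params.C,
                "gamma": self.best.chromosome.params.gamma,
                "cv_accuracy": self.best.accuracy,
                "r": self.best.r,
            },
            "per_run_best": [
                {
                    "r": s.r,
                    "cv_accuracy": s.accuracy,
                    "features": [
                        f
                        for f, b in zip(self.feature_names, s.chromosome.feature_bits)
                        if b
                    ],
                }
                for s in self.per_run_best
            ],
        }


def ibcga_run(
    X: np.ndarray,
    y: np.ndarray,
    config: IBCGAConfig | None = None,
    seed: int = 0,
) -> RunResult:
    """One inheritable GA run over subset sizes r_start down to r_end.

    Fitness is the stratified CV accuracy of the SVM restricted to the
    chromosome's feature subset at its (C, gamma).  CV folds are fixed
    per run (the fold seed derives from ``seed``) so fitness is
    deterministic and cacheable.  Elitism keeps the stage best, so
    per-stage best fitness never decreases within a stage.
    """
    config = config or IBCGAConfig()
    n = X.shape[1]
    if config.r_start > n:
        raise ValueError(f"r_start={config.r_start} exceeds feature count {n}")
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    cache: dict[tuple, float] = {}
    n_evals = 0

    def fitness(ch: Chromosome) -> float:
        nonlocal n_evals
        key = ch.key()
        if key not in cache:
            cols = np.flatnonzero(ch.feature_bits)
            if len(cols) == 0:
                cache[key] = 0.0
            else:
                cache[key] = cv_accuracy(
                    X[:, cols], y, ch.params, folds=config.cv_folds, seed=fold_seed
                )
                n_evals += 1
        return cache[key]

    def random_chromosome(r: int) -> Chromosome:
        bits = np.zeros(n, dtype=np.uint8)
        bits[rng.choice(n, size=r, replace=False)] = 1
        return Chromosome(bits, int(rng.integers(16)), int(rng.integers(16)))

    def tournament(pop, fits) -> Chromosome:
        idx = rng.integers(len(pop), size=config.tournament_size)
        return pop[idx[np.argmax(np.asarray(fits)[idx])]].copy()

    def swap_mutate(ch: Chromosome) -> None:
        # exchange a 1-bit and a 0-bit (popcount preserved); jitter SVM genes
        bits = ch.feature_bits
        for _ in range(max(1, int(round(config.mutation_rate * n)))):
            if rng.random() < 0.5 and 0 < bits.sum() < n:
                ones = np.flatnonzero(bits)
                zeros = np.flatnonzero(bits == 0)
                bits[rng.choice(ones)] = 0
                bits[rng.choice(zeros)] = 1
        if rng.random() < config.mutation_rate * 4:
            ch.c_gene = int(rng.integers(16))
        if rng.random() < config.mutation_rate * 4:
            ch.gamma_gene = int(rng.integers(16))

    pop = [random_chromosome(config.r_start) for _ in range(config.population_size)]
    per_r: list[StageBest] = []
    history: list[tuple[int, int, float]] = []

    for r in range(config.r_start, config.r_end - 1, -1):
        fits = [fitness(ch) for ch in pop]
        history.append((r, 0, max(fits)))
        for gen in range(config.generations_per_stage):
            elite = pop[int(np.argmax(fits))].copy()
            nxt = [elite]
            while len(nxt) < config.population_size:
                a = tournament(pop, fits)
                b = tournament(pop, fits)
                c1, c2 = oa_crossover(a, b, fitness, rng)
                swap_mutate(c1)
                nxt.append(c1)
                if len(nxt) < config.population_size:
                    swap_mutate(c2)
                    nxt.append(c2)
            pop = nxt
            fits = [fitness(ch) for ch in pop]
            history.append((r, gen + 1, max(fits)))
        best_i = int(np.argmax(fits))
        per_r.append(StageBest(r, pop[best_i].copy(), fits[best_i]))
        if r > config.r_end:
            # inheritance: drop one randomly chosen selected feature each
            for ch in pop:
                ones = np.flatnonzero(ch.feature_bits)
                ch.feature_bits[rng.choice(ones)] = 0

    best = max(per_r, key=lambda s: (s.accuracy, -s.r))
    return RunResult(per_r, best, n_evals, history)


def aggregate_runs(
    runs: list[RunResult], feature_names: list[str]
) -> SelectionReport:
    """Per-feature selection frequencies over the runs' final solutions."""
    if not runs:
        raise ValueError("need at least one run")
    n = len(feature_names)
    counts = np.zeros(n, dtype=int)
    for run in runs:
        counts += run.best.chromosome.feature_bits.astype(int)
    best_run = max(runs, key=lambda r: r.best.accuracy)
    return SelectionReport(
        feature_names=feature_names,
        selection_counts=counts,
        best=best_run.best,
        per_run_best=[r.best for r in runs],
    )
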