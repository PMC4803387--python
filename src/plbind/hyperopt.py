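"""Hyperparameter search by genetic algorithm or grid, with a persistent cache.

The objective is mean cross-validated AUC.  GA defaults follow the tuning
protocol: 100 generations of 20 individuals, tournament selection (size 2),
single-point crossover at rate 0.8, per-gene point mutation at rate 0.05,
elitism of 1.  Every evaluated genotype is cached in an SQLite key-value
store so re-evaluations never retrain.
"""

from __future__ import annotations

import dataclasses
import itertools
import sqlite3
import time
from collections.abc import Callable, Sequence

import numpy as np

from . import evaluate, learners
from .profiles import LabeledDataset, vectorize_dataset

__all__ = [
    "GeneSpec",
    "SearchSpace",
    "SearchPoint",
    "EvalCache",
    "Objective",
    "ConfigError",
    "default_space",
    "fitness",
    "run_ga",
    "run_grid",
    "write_trace_tsv",
]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GeneSpec:
    name: str
    low: float
    high: float
    integer: bool = False
    odd: bool = False  # decode to the nearest odd integer (window size)

    def sample(self, rng: np.random.Generator) -> float:
        if self.integer or self.odd:
            v = float(rng.integers(int(self.low), int(self.high) + 1))
        else:
            v = float(rng.uniform(self.low, self.high))
        return self.clip(v)

    def clip(self, v: float) -> float:
        v = float(min(max(v, self.low), self.high))
        if self.odd:
            v = float(int(round(v)) | 1)  # nearest odd, rounding up
            v = float(min(max(v, self.low), self.high))
        elif self.integer:
            v = float(int(round(v)))
        return v


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    algorithm: str
    genes: tuple[GeneSpec, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def decode(self, genotype: Sequence[float]) -> learners.HyperParams:
        genotype = list(genotype)
        if len(genotype) != len(self.genes):
            raise ConfigError(
                f"genotype length {len(genotype)} != {len(self.genes)} genes"
            )
        fields: dict = {}
        for spec, v in zip(self.genes, genotype):
            v = spec.clip(v)
            fields[spec.name] = int(v) if (spec.integer or spec.odd) else v
        return learners.HyperParams(algorithm=self.algorithm, **fields)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([g.sample(rng) for g in self.genes])


# bounds envelope the parameter values reported for the reference predictors
_DEFAULT_GENES = {
    "svm": (
        GeneSpec("C", 0.1, 30.0),
        GeneSpec("sigma", 0.05, 5.0),
        GeneSpec("w", 3, 21, odd=True),
    ),
    "nn": (
        GeneSpec("hidden_nodes", 5, 50, integer=True),
        GeneSpec("learning_rate", 0.01, 5.0),
        GeneSpec("w", 3, 21, odd=True),
    ),
    "rf": (
        GeneSpec("n_trees", 100, 2500, integer=True),
        GeneSpec("mtry", 1, 40, integer=True),
        GeneSpec("w", 3, 21, odd=True),
    ),
}


def default_space(algorithm: str) -> SearchSpace:
    if algorithm not in _DEFAULT_GENES:
        raise ConfigError(f"unknown algorithm {algorithm!r}")
    return SearchSpace(algorithm, _DEFAULT_GENES[algorithm])


@dataclasses.dataclass
class SearchPoint:
    genotype: np.ndarray
    fitness: float  # mean CV AUC
    fitness_se: float  # standard error across folds
    step: int  # generation / grid-cell index


class EvalCache:
    """SQLite-backed map: canonical genotype key -> (fitness, fitness_se).

    Keys round real genes to 4 decimals in a fixed field order, so lookups
    never miss on float formatting; a hit never retrains.
    """

    def __init__(self, path: str = ":memory:"):
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS evals (key TEXT PRIMARY KEY, fitness REAL, se REAL)"
        )
        self.hits = 0
        self.misses = 0

    @staticmethod
    def key(algorithm: str, names: Sequence[str], genotype: Sequence[float]) -> str:
        parts = [algorithm] + [f"{n}={float(v):.4f}" for n, v in zip(names, genotype)]
        return "|".join(parts)

    def get(self, key: str) -> tuple[float, float] | None:
        row = self._conn.execute("SELECT fitness, se FROM evals WHERE key = ?", (key,)).fetchone()
        if row is None:
            self.misses += 1
            return None
        self.hits += 1
        return float(row[0]), float(row[1])

    def put(self, key: str, fit: float, se: float) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO evals (key, fitness, se) VALUES (?, ?, ?)", (key, fit, se)
        )
        self._conn.commit()

    def __len__(self) -> int:
        return int(self._conn.execute("SELECT COUNT(*) FROM evals").fetchone()[0])

    def close(self) -> None:
        self._conn.close()


class Objective:
    """CV-AUC fitness of a genotype; counts real trainings for cache audits.

    ``data_for_w`` maps a window size to the (already vectorized) dataset at
    that w, so the window gene re-windows features.  Fold assignment uses one
    fixed seed for every evaluation of a run, so fitness differences reflect
    parameters rather than fold luck.
    """

    def __init__(
        self,
        space: SearchSpace,
        data_for_w: Callable[[int], LabeledDataset],
        folds: int = 5,
        seed: int = 0,
        cache: EvalCache | None = None,
    ):
        if folds < 2:
            raise ConfigError("folds must be >= 2")
        self.space = space
        self.data_for_w = data_for_w
        self.folds = folds
        self.seed = seed
        self.cache = cache if cache is not None else EvalCache()
        self.train_count = 0

    @classmethod
    def from_features(
        cls, labelsets, profiles, algorithm: str, scale: float = 0.1, **kw
    ) -> "Objective":
        space = kw.pop("space", None) or default_space(algorithm)
        cache_fn: dict[int, LabeledDataset] = {}

        def data_for_w(w: int) -> LabeledDataset:
            if w not in cache_fn:
                cache_fn[w] = vectorize_dataset(labelsets, profiles, w, scale=scale)
            return cache_fn[w]

        return cls(space, data_for_w, **kw)

    @classmethod
    def from_fixed(cls, data: LabeledDataset, space: SearchSpace, **kw) -> "Objective":
        return cls(space, lambda w: data, **kw)

    def __call__(self, genotype: Sequence[float]) -> tuple[float, float]:
        key = EvalCache.key(self.space.algorithm, self.space.names, genotype)
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        params = self.space.decode(genotype)
        data = self.data_for_w(params.w)
        y = np.asarray(data.y, dtype=int)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        aucs = []
        for train_idx, test_idx in skf.split(data.X, y):
            model = learners.train((data.X[train_idx], y[train_idx]), params, seed=self.seed)
            self.train_count += 1
            s = learners.score(model, data.X[test_idx])
            _, auc = evaluate.roc_auc(s, y[test_idx])
            aucs.append(auc)
        mean = float(np.mean(aucs))
        se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs)))
        self.cache.put(key, mean, se)
        return mean, se


def fitness(genotype, objective: Objective) -> tuple[float, float]:
    """Mean CV AUC and its standard error for one genotype (cache-aware)."""
    return objective(genotype)


def run_ga(
    objective: Objective,
    seed: int = 0,
    generations: int = 100,
    pop: int = 20,
    p_mut: float = 0.05,
    p_cross: float = 0.8,
    tournament: int = 2,
    elitism: int = 1,
) -> tuple[SearchPoint, list[dict]]:
    """Generational GA over the objective's search space.

    Returns the best point ever evaluated and a per-generation trace of the
    best-so-far individual (generation, runtime_s, genes, mean_auc, se_auc);
    elitism makes the trace non-decreasing in fitness.
    """
    space = objective.space
    rng = np.random.default_rng(seed)
    t0 = time.perf_counter()

    population = [space.sample(rng) for _ in range(pop)]
    scores = [objective(g) for g in population]

    def best_of(pop_, scores_):
        i = int(np.argmax([s[0] for s in scores_]))
        return pop_[i].copy(), scores_[i]

    best_g, (best_f, best_se) = best_of(population, scores)
    trace = [_trace_row(0, t0, space, best_g, best_f, best_se)]

    for gen in range(1, generations + 1):
        new_pop = [best_g.copy()] if elitism else []
        while len(new_pop) < pop:
            pa = _tournament(population, scores, rng, tournament)
            pb = _tournament(population, scores, rng, tournament)
            ca, cb = pa.copy(), pb.copy()
            if len(space.genes) > 1 and rng.random() < p_cross:
                point = int(rng.integers(1, len(space.genes)))
                ca = np.concatenate([pa[:point], pb[point:]])
                cb = np.concatenate([pb[:point], pa[point:]])
            for child in (ca, cb):
                for i, spec in enumerate(space.genes):
                    if rng.random() < p_mut:
                        child[i] = spec.sample(rng)
                if len(new_pop) < pop:
                    new_pop.append(child)
        population = new_pop
        scores = [objective(g) for g in population]
        gen_best_g, (gen_best_f, gen_best_se) = best_of(population, scores)
        if gen_best_f > best_f:
            best_g, best_f, best_se = gen_best_g, gen_best_f, gen_best_se
        trace.append(_trace_row(gen, t0, space, best_g, best_f, best_se))

    return SearchPoint(best_g, best_f, best_se, len(trace) - 1), trace


def _tournament(population, scores, rng, k: int) -> np.ndarray:
    idx = rng.integers(0, len(population), size=k)
    winner = max(idx, key=lambda i: scores[i][0])
    return population[winner]


def _trace_row(gen, t0, space, genotype, fit, se) -> dict:
    row = {"generation": gen, "runtime_s": round(time.perf_counter() - t0, 3)}
    for name, v in zip(space.names, genotype):
        row[name] = float(v)
    row["mean_auc"] = fit
    row["se_auc"] = se
    return row


def run_grid(
    objective: Objective,
    grid: dict[str, Sequence[float]],
    seed: int = 0,
) -> tuple[SearchPoint, list[SearchPoint]]:
    """Exhaustive evaluation of the Cartesian product of per-gene value lists.

    Best by mean AUC; ties broken by smaller w, then lexicographic gene
    order.  Previously cached genotypes are not retrained.
    """
    space = objective.space
    names = space.names
    unknown = set(grid) - set(names)
    if unknown:
        raise ConfigError(f"grid axes not in search space: {sorted(unknown)}")
    axes = []
    for name in names:
        values = list(grid.get(name, ()))
        if not values:
            raise ConfigError(f"empty grid axis for gene {name!r}")
        axes.append(values)

    table: list[SearchPoint] = []
    for step, combo in enumerate(itertools.product(*axes)):
        genotype = np.array([float(v) for v in combo])
        fit, se = objective(genotype)
        table.append(SearchPoint(genotype, fit, se, step))

    w_pos = names.index("w") if "w" in names else None

    def sort_key(pt: SearchPoint):
        w = pt.genotype[w_pos] if w_pos is not None else 0.0
        return (-pt.fitness, w, tuple(pt.genotype))

    best = min(table, key=sort_key)
    return best, table


def write_trace_tsv(trace: list[dict], path) -> None:
    import csv

    if not trace:
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        keys = list(trace[0].keys())
        w.writerow(keys)
        for row in trace:
            w.writerow([row[k] for k in keys])
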