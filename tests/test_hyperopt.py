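import numpy as np
import pytest

from plbind import fixtures as fx
from plbind.hyperopt import (
    ConfigError,
    EvalCache,
    GeneSpec,
    Objective,
    SearchSpace,
    default_space,
    fitness,
    run_ga,
    run_grid,
    write_trace_tsv,
)

# SVM space on the separable fixture: sigma is the gene that controls
# separability (tiny sigma collapses the kernel), C is mostly inert
TUNABLE_SPACE = SearchSpace(
    "svm",
    (
        GeneSpec("C", 0.1, 30.0),
        GeneSpec("sigma", 0.01, 20.0),
        GeneSpec("w", 3, 3, odd=True),
    ),
)


@pytest.fixture(scope="module")
def objective():
    data, _ = fx.gen_labeled_features(21, n_pos=50, n_neg=50, w=3, separation_sigma=4.0)
    return Objective.from_fixed(data, TUNABLE_SPACE, folds=3, seed=0)


class TestSearchSpace:
    def test_decode_rounds_and_clips(self):
        space = default_space("svm")
        params = space.decode([100.0, 0.5, 8.0])
        assert params.C == 30.0  # clipped to bound
        assert params.w == 9  # nearest odd
        assert params.algorithm == "svm"

    def test_w_gene_always_odd(self):
        space = default_space("rf")
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = space.sample(rng)
            assert space.decode(g).w % 2 == 1

    def test_genotype_length_checked(self):
        with pytest.raises(ConfigError):
            default_space("nn").decode([1.0])

    def test_unknown_algorithm(self):
        with pytest.raises(ConfigError):
            default_space("boost")

    def test_default_bounds_envelope_reported_values(self):
        # reported tuned values: C up to 25.27, sigma down to 0.16, nodes up
        # to 49, lr up to 3.26, trees up to 2023, tries up to 29, w 3..19
        svm = {g.name: g for g in default_space("svm").genes}
        assert svm["C"].low <= 0.159 and svm["C"].high >= 25.27
        assert svm["sigma"].low <= 0.16 and svm["sigma"].high >= 0.78
        nn = {g.name: g for g in default_space("nn").genes}
        assert nn["hidden_nodes"].high >= 49 and nn["learning_rate"].high >= 3.26
        rf = {g.name: g for g in default_space("rf").genes}
        assert rf["n_trees"].high >= 2023 and rf["mtry"].high >= 29
        w = svm["w"]
        assert w.low <= 3 and w.high >= 19


class TestFitness:
    def test_separable_genotype_hits_ceiling(self, objective):
        fit, se = fitness(np.array([1.0, 8.0, 3.0]), objective)
        assert fit >= 0.99
        assert se < 0.02

    def test_shuffled_labels_near_half(self):
        data, _ = fx.gen_labeled_features(22, n_pos=50, n_neg=50, w=3, separation_sigma=0.0)
        obj = Objective.from_fixed(data, TUNABLE_SPACE, folds=3, seed=0)
        fits = []
        for s in range(10):
            rng = np.random.default_rng(s)
            y = rng.permutation(data.y)
            from plbind.profiles import LabeledDataset

            shuffled = LabeledDataset(X=data.X, y=y, meta=data.meta, w=data.w)
            o = Objective.from_fixed(shuffled, TUNABLE_SPACE, folds=3, seed=0)
            fits.append(o(np.array([1.0, 8.0, 3.0]))[0])
        assert 0.4 <= float(np.mean(fits)) <= 0.6

    def test_cache_hit_returns_identical_without_training(self, objective):
        g = np.array([2.0, 5.0, 3.0])
        first = objective(g)
        trained = objective.train_count
        second = objective(g)
        assert second == first
        assert objective.train_count == trained
        assert objective.cache.hits >= 1

    def test_cache_key_rounding(self):
        k1 = EvalCache.key("svm", ("C", "sigma"), [1.00001, 2.0])
        k2 = EvalCache.key("svm", ("C", "sigma"), [1.000011, 2.0])
        assert k1 == k2

    def test_undecodable_genotype(self, objective):
        with pytest.raises(ConfigError):
            objective(np.array([1.0]))


class TestGA:
    def test_trace_monotone_and_final_at_least_initial(self, objective):
        best, trace = run_ga(objective, seed=3, generations=5, pop=6)
        fits = [row["mean_auc"] for row in trace]
        assert all(a <= b for a, b in zip(fits, fits[1:]))
        assert best.fitness >= fits[0]
        assert best.fitness == fits[-1]

    def test_scaled_down_run_reaches_ceiling(self, objective):
        best, _ = run_ga(objective, seed=1, generations=10, pop=10)
        assert best.fitness >= 0.95

    def test_deterministic_traces(self, objective):
        b1, t1 = run_ga(objective, seed=11, generations=4, pop=6)
        b2, t2 = run_ga(objective, seed=11, generations=4, pop=6)
        assert [r["mean_auc"] for r in t1] == [r["mean_auc"] for r in t2]
        np.testing.assert_array_equal(b1.genotype, b2.genotype)

    def test_zero_generations_returns_initial_best(self, objective):
        best, trace = run_ga(objective, seed=2, generations=0, pop=5)
        assert len(trace) == 1
        assert best.fitness == trace[0]["mean_auc"]

    def test_beats_random_search_on_budget(self):
        # GA vs random search with the same distinct-evaluation budget (the
        # cache defines what counts as an evaluation), on the fixture whose
        # separability is controlled by the w gene
        from conftest import make_w_ramp_objective

        wins = 0
        for seed in range(10):
            obj = make_w_ramp_objective()
            best, _ = run_ga(obj, seed=seed, generations=20, pop=16, p_mut=0.2)
            budget = len(obj.cache)
            rng = np.random.default_rng(seed + 1000)
            rand_best = max(obj(obj.space.sample(rng))[0] for _ in range(budget))
            if best.fitness >= rand_best:
                wins += 1
        assert wins >= 8

    def test_w_ramp_improvement_trace(self):
        # scaled-down analogue of the published tuning run: pop 10, 10
        # generations; best-so-far is non-decreasing and strictly improves
        from conftest import make_w_ramp_objective

        obj = make_w_ramp_objective()
        best, trace = run_ga(obj, seed=0, generations=10, pop=10)
        fits = [row["mean_auc"] for row in trace]
        assert all(a <= b for a, b in zip(fits, fits[1:]))
        assert best.fitness >= 0.95
        assert best.fitness > fits[0]


class TestGrid:
    def test_one_by_one_grid(self, objective):
        best, table = run_grid(objective, {"C": [1.0], "sigma": [8.0], "w": [3]})
        assert len(table) == 1
        np.testing.assert_array_equal(best.genotype, [1.0, 8.0, 3.0])

    def test_best_is_argmax_of_cells(self, objective):
        grid = {"C": [0.5, 1.0, 5.0], "sigma": [0.05, 1.0, 8.0], "w": [3]}
        best, table = run_grid(objective, grid)
        assert len(table) == 9
        assert best.fitness == max(pt.fitness for pt in table)

    def test_cache_shared_with_ga(self, objective):
        g = np.array([1.0, 8.0, 3.0])
        objective(g)
        trained = objective.train_count
        best, _ = run_grid(objective, {"C": [1.0], "sigma": [8.0], "w": [3]})
        assert objective.train_count == trained  # pure cache hit
        assert best.fitness == objective(g)[0]

    def test_empty_axis_rejected(self, objective):
        with pytest.raises(ConfigError):
            run_grid(objective, {"C": [], "sigma": [1.0], "w": [3]})

    def test_tie_broken_by_smaller_w(self):
        # constant stub objective: every cell ties, so the smaller w wins
        space = SearchSpace(
            "svm",
            (GeneSpec("C", 0.1, 30.0), GeneSpec("sigma", 0.05, 20.0), GeneSpec("w", 3, 21, odd=True)),
        )

        class Stub:
            def __init__(self):
                self.space = space

            def __call__(self, genotype):
                return 0.7, 0.0

        best, table = run_grid(Stub(), {"C": [1.0], "sigma": [1.0], "w": [9, 3, 5]})
        assert len(table) == 3
        assert best.genotype[2] == 3.0


def test_trace_tsv_writer(tmp_path, objective):
    _, trace = run_ga(objective, seed=5, generations=2, pop=4)
    path = tmp_path / "trace.tsv"
    write_trace_tsv(trace, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == ["generation", "runtime_s", "C", "sigma", "w", "mean_auc", "se_auc"]
    assert len(lines) == len(trace) + 1


def test_cache_persistence(tmp_path):
    path = str(tmp_path / "cache.sqlite")
    c1 = EvalCache(path)
    key = EvalCache.key("svm", ("C",), [1.0])
    c1.put(key, 0.9, 0.01)
    c1.close()
    c2 = EvalCache(path)
    assert c2.get(key) == (0.9, 0.01)
    assert len(c2) == 1
    c2.close()
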