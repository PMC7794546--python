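"""Random search, history bookkeeping, and the TPE suggestion machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spectune.objective import ObjectiveValue
from spectune.optimizers import (
    History,
    TPEParams,
    Trial,
    _CategoricalDensity,
    _NumericParzen,
    density_estimators,
    random_search,
    split_history,
    tpe_optimize,
    tpe_suggest,
)
from spectune.space import Configuration, HyperparameterDef, SearchSpace, validate
from spectune.surrogates import cnn_proxy_objective, quadratic_objective, quadratic_space


def _history_1d_cat(categories, cats, objs, space=None):
    space = space or SearchSpace([HyperparameterDef("c", "categorical", categories)])
    trials = [
        Trial(i, Configuration({"c": c}), ObjectiveValue(o, [o]))
        for i, (c, o) in enumerate(zip(cats, objs))
    ]
    return History(space=space, trials=trials)


class TestRandomSearch:
    def test_contract(self):
        space = quadratic_space()
        h = random_search(space, quadratic_objective, 5, seed=0)
        assert len(h) == 5
        assert all(t.origin == "random" for t in h.trials)

    def test_constant_objective(self):
        h = random_search(quadratic_space(), lambda c: 1.25, 4, seed=1)
        assert h.best_trial.objective.mean_rmse == 1.25

    def test_same_seed_same_configs(self):
        a = random_search(quadratic_space(), quadratic_objective, 6, seed=3)
        b = random_search(quadratic_space(), quadratic_objective, 6, seed=3)
        assert [t.config.values for t in a.trials] == [t.config.values for t in b.trials]

    def test_objective_exception_recorded_as_failed(self):
        def bad(cfg):
            raise RuntimeError("boom")

        h = random_search(quadratic_space(), bad, 3, seed=0)
        assert len(h) == 3
        assert all(t.objective.status == "failed" for t in h.trials)

    def test_running_best_non_increasing(self):
        h = random_search(quadratic_space(), quadratic_objective, 40, seed=5)
        rb = h.running_best()
        assert all(a >= b for a, b in zip(rb, rb[1:]))


class TestHistoryIO:
    def test_jsonl_round_trip(self, tmp_path):
        h = random_search(quadratic_space(), quadratic_objective, 5, seed=2)
        p = tmp_path / "history.jsonl"
        h.save_jsonl(p)
        back = History.load_jsonl(p, h.space)
        assert [t.to_record() for t in back.trials] == [t.to_record() for t in h.trials]

    def test_best_index_points_to_minimum(self):
        h = random_search(quadratic_space(), quadratic_objective, 10, seed=4)
        objs = [t.objective.mean_rmse for t in h.trials]
        assert h.best_index == int(np.argmin(objs))


class TestSplitHistory:
    def test_quantile_counts(self):
        h = _history_1d_cat(("A", "B"), ["A", "B"] * 5, list(range(10)))
        good, bad = split_history(h, 0.2)
        assert len(good) == 2 and len(bad) == 8

    def test_ties_broken_by_index(self):
        h = _history_1d_cat(("A", "B"), ["A", "B", "A", "B"], [1.0] * 4)
        good, _ = split_history(h, 0.5)
        assert [t.index for t in good] == [0, 1]

    def test_two_trials_one_good(self):
        h = _history_1d_cat(("A", "B"), ["A", "B"], [2.0, 1.0])
        good, bad = split_history(h, 0.25)
        assert len(good) == 1 and good[0].index == 1


class TestDensities:
    def test_categorical_laplace_smoothing(self):
        d = _CategoricalDensity(("A", "B"), [3, 0], prior_weight=1.0)
        assert d.pdf("A") == pytest.approx(4 / 5)
        assert d.pdf("B") == pytest.approx(1 / 5)

    def test_single_observation_peaks_at_midpoint(self):
        d = _NumericParzen([0.5], 0.0, 1.0, False, 1.0, 0.01)
        xs = np.linspace(0.0, 1.0, 101)
        pdfs = [d.pdf(x) for x in xs]
        assert xs[int(np.argmax(pdfs))] == pytest.approx(0.5, abs=0.01)

    def test_uniform_history_gives_similar_l_and_g(self):
        """Objectives independent of the hyperparameter: l and g should be
        close (small KS distance between their samples)."""
        rng = np.random.default_rng(0)
        space = SearchSpace([HyperparameterDef("x", "continuous", (0.0, 1.0))])
        trials = []
        for i in range(500):
            x = float(rng.uniform())
            o = float(rng.normal())  # unrelated to x
            trials.append(Trial(i, Configuration({"x": x}), ObjectiveValue(o, [o])))
        h = History(space=space, trials=trials)
        good, bad = split_history(h, 0.25)
        dens = density_estimators(good, bad, space, TPEParams())
        l_d, g_d = dens["x"]
        ls = [l_d.sample(rng) for _ in range(600)]
        gs = [g_d.sample(rng) for _ in range(600)]
        # l and g use different sample sizes, hence slightly different
        # bandwidths; the distributions agree up to that smoothing.
        assert stats.ks_2samp(ls, gs).statistic < 0.2

    def test_integer_samples_stay_on_lattice(self):
        rng = np.random.default_rng(1)
        d = _NumericParzen([3, 4, 5], 1, 10, True, 1.0, 0.01)
        draws = [d.sample(rng) for _ in range(200)]
        assert all(isinstance(v, int) and 1 <= v <= 10 for v in draws)


class TestTpeSuggest:
    def test_matches_bruteforce_lg_ratio_on_1d_categorical(self):
        """On a finite 1-D space the suggestion must equal direct
        maximisation of the Laplace-smoothed l/g ratio (computed here from
        raw counts, independently of the density classes)."""
        gen = np.random.default_rng(99)
        categories = ("A", "B", "C", "D")
        params = TPEParams(n_startup=2, gamma=0.3, seed=0)
        space = SearchSpace([HyperparameterDef("c", "categorical", categories)])
        for rep in range(50):
            n = int(gen.integers(5, 30))
            cats = [categories[i] for i in gen.integers(0, 4, n)]
            objs = gen.normal(size=n).tolist()
            h = _history_1d_cat(categories, cats, objs, space)
            suggestion = tpe_suggest(space, h, params, np.random.default_rng(rep))["c"]

            order = sorted(range(n), key=lambda i: (objs[i], i))
            n_good = max(1, int(np.ceil(params.gamma * n)))
            good = set(order[:n_good])
            k = len(categories)

            def smoothed(idx_set, c):
                cnt = sum(1 for i in idx_set if cats[i] == c)
                return (cnt + 1.0) / (len(idx_set) + k)

            bad = [i for i in range(n) if i not in good]
            ratios = [smoothed(good, c) / smoothed(bad, c) for c in categories]
            assert suggestion == categories[int(np.argmax(ratios))]

    def test_startup_phase_uniform(self):
        space = SearchSpace([HyperparameterDef("c", "categorical", tuple("ABCDE"))])
        empty = History(space=space)
        counts = {c: 0 for c in "ABCDE"}
        for i in range(2000):
            counts[tpe_suggest(space, empty, TPEParams(), np.random.default_rng(i))["c"]] += 1
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_concentrates_on_quadratic_optimum(self):
        space = SearchSpace([HyperparameterDef("x", "continuous", (0.0, 1.0))])
        for seed in (1, 2, 3):
            params = TPEParams(seed=seed)
            h = tpe_optimize(space, quadratic_objective, 100, params)
            sugs = [
                tpe_suggest(space, h, params, np.random.default_rng([seed, 10_000 + i]))["x"]
                for i in range(50)
            ]
            assert abs(np.mean(sugs) - 0.3) < abs(0.5 - 0.3)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_suggestions_valid_on_tree_structured_space(self, full_space, seed):
        h = random_search(full_space, cnn_proxy_objective, 15, seed=7)
        cfg = tpe_suggest(full_space, h, TPEParams(n_startup=12),
                          np.random.default_rng(seed))
        assert validate(full_space, cfg) == []

    def test_huge_prior_weight_approaches_uniform(self, full_space):
        """With an overwhelming uniform prior the suggestion distribution
        loses its dependence on the history."""
        h = random_search(full_space, cnn_proxy_objective, 30, seed=11)
        params = TPEParams(prior_weight=1e18)
        draws = [
            tpe_suggest(full_space, h, params, np.random.default_rng(i))["epochs"]
            for i in range(300)
        ]
        # epochs domain [100, 1500]; uniform mean 800
        assert abs(np.mean(draws) - 800) < 120


class TestTpeOptimize:
    def test_budget_equal_to_startup_is_all_uniform(self):
        h = tpe_optimize(quadratic_space(), quadratic_objective, 12,
                         TPEParams(n_startup=12, seed=0))
        assert all(t.origin == "startup" for t in h.trials)

    def test_resume_reproduces_uninterrupted_run(self, tmp_path):
        space = quadratic_space()
        params = TPEParams(n_startup=5, seed=8)
        full = tpe_optimize(space, quadratic_objective, 25, params)
        part = tpe_optimize(space, quadratic_objective, 14, params)
        p = tmp_path / "h.jsonl"
        part.save_jsonl(p)
        resumed = tpe_optimize(space, quadratic_objective, 25, params,
                               history=History.load_jsonl(p, space))
        assert len(resumed) == len(full) == 25
        assert [t.config.values for t in resumed.trials] == [
            t.config.values for t in full.trials
        ]

    def test_running_best_non_increasing(self):
        h = tpe_optimize(quadratic_space(), quadratic_objective, 40, TPEParams(seed=2))
        rb = h.running_best()
        assert all(a >= b for a, b in zip(rb, rb[1:]))

    def test_histories_schema_identical_across_optimisers(self):
        space = quadratic_space()
        ht = tpe_optimize(space, quadratic_objective, 15, TPEParams(n_startup=5, seed=0))
        hr = random_search(space, quadratic_objective, 15, seed=0)
        keys_t = set(ht.trials[0].to_record())
        keys_r = set(hr.trials[0].to_record())
        assert keys_t == keys_r
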