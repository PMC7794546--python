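"""fANOVA: exact tree marginals, variance fractions, history encoding."""

import numpy as np
import pytest

from spectune.importance import (
    Dim,
    FanovaSettings,
    TreeNode,
    encode_history,
    fanova,
    single_tree_marginal,
    tree_total_variance,
)
from spectune.objective import ObjectiveValue
from spectune.optimizers import History, Trial
from spectune.space import HyperparameterDef, SearchSpace, sample_uniform
from spectune.surrogates import cnn_proxy_objective


def _synthetic_history(space, objective, n, seed):
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        cfg = sample_uniform(space, rng)
        y = float(objective(cfg))
        trials.append(Trial(i, cfg, ObjectiveValue(y, [y])))
    return History(space=space, trials=trials)


def _nuisance_space():
    defs = [HyperparameterDef("x1", "continuous", (0.0, 1.0))]
    defs += [HyperparameterDef(f"n{i}", "continuous", (0.0, 1.0)) for i in range(2, 7)]
    defs += [HyperparameterDef(f"i{i}", "integer", (1, 10)) for i in range(3)]
    defs += [HyperparameterDef("c", "categorical", ("a", "b", "c"))]
    return SearchSpace(defs)


UNIT_DIMS = [Dim("x0", "num", 0, 1), Dim("x1", "num", 0, 1)]


class TestSingleTreeMarginal:
    def test_stump_marginals_by_hand(self):
        """Stump on x0 at 0.5 with leaves {1, 3}: the x0 marginal is the leaf
        values, every other marginal is the volume-weighted mean 2."""
        stump = TreeNode(feature=0, threshold=0.5,
                         left=TreeNode(value=1.0), right=TreeNode(value=3.0))
        m0 = single_tree_marginal(stump, UNIT_DIMS, 0)
        m1 = single_tree_marginal(stump, UNIT_DIMS, 1)
        assert m0(0.25) == 1.0 and m0(0.75) == 3.0
        assert m1(0.1) == 2.0 and m1(0.99) == 2.0
        assert m1.variance() == 0.0
        assert tree_total_variance(stump, UNIT_DIMS) == pytest.approx(1.0)

    def test_constant_tree_zero_variance(self):
        const = TreeNode(value=5.0)
        for j in range(2):
            assert single_tree_marginal(const, UNIT_DIMS, j).variance() == 0.0
        assert tree_total_variance(const, UNIT_DIMS) == 0.0

    def test_depth_two_tree_matches_grid_integration(self):
        tree = TreeNode(
            feature=0, threshold=0.4,
            left=TreeNode(feature=1, threshold=0.6,
                          left=TreeNode(value=0.0), right=TreeNode(value=2.0)),
            right=TreeNode(feature=0, threshold=0.7,
                           left=TreeNode(value=1.0), right=TreeNode(value=5.0)),
        )
        g = np.linspace(0.0005, 0.9995, 1000)
        x0, x1 = np.meshgrid(g, g, indexing="ij")
        f = np.where(x0 <= 0.4, np.where(x1 <= 0.6, 0.0, 2.0),
                     np.where(x0 <= 0.7, 1.0, 5.0))
        total = tree_total_variance(tree, UNIT_DIMS)
        assert total == pytest.approx(f.var(), abs=1e-6)
        assert single_tree_marginal(tree, UNIT_DIMS, 0).variance() == pytest.approx(
            f.mean(axis=1).var(), abs=1e-6
        )
        assert single_tree_marginal(tree, UNIT_DIMS, 1).variance() == pytest.approx(
            f.mean(axis=0).var(), abs=1e-6
        )

    def test_lattice_dimension_marginal(self):
        dims = [Dim("k", "lat", 1, 4), Dim("x", "num", 0, 1)]
        stump = TreeNode(feature=0, threshold=2.5,
                         left=TreeNode(value=0.0), right=TreeNode(value=4.0))
        m = single_tree_marginal(stump, dims, 0)
        assert m(1) == 0.0 and m(2) == 0.0 and m(3) == 4.0 and m(4) == 4.0
        # half the lattice at 0, half at 4 -> variance 4
        assert m.variance() == pytest.approx(4.0)


class TestEncodeHistory:
    def test_drops_conditionals_keeps_block_one(self, full_space):
        h = _synthetic_history(full_space, cnn_proxy_objective, 40, seed=0)
        enc = encode_history(h)
        names = [d.name for d in enc.dims]
        assert "conv1_pool_size" not in names
        assert "conv2_filters" not in names
        assert "conv1_filters" in names  # block 1 always exists
        assert "optimiser" in names and "batch_size" in names
        assert enc.n_trials == 40

    def test_row_count_matches_trials(self, full_space):
        h = _synthetic_history(full_space, cnn_proxy_objective, 50, seed=1)
        assert encode_history(h).X.shape[0] == 50

    def test_constant_column_flagged(self):
        space = SearchSpace([
            HyperparameterDef("x", "continuous", (0.0, 1.0)),
            HyperparameterDef("c", "categorical", ("only",)),
        ])
        h = _synthetic_history(space, lambda cfg: cfg["x"], 35, seed=2)
        enc = encode_history(h)
        flags = {d.name: d.is_constant for d in enc.dims}
        assert flags == {"x": False, "c": True}

    def test_too_few_trials_rejected(self, full_space):
        h = _synthetic_history(full_space, cnn_proxy_objective, 10, seed=3)
        with pytest.raises(ValueError):
            encode_history(h)


class TestFanova:
    def test_recovers_single_active_dimension(self):
        """Objective depends only on x1 among 10 dims: x1 captures > 0.8 of
        the variance and every nuisance < 0.05, across 3 surrogate seeds."""
        space = _nuisance_space()
        for seed in (0, 1, 2):
            h = _synthetic_history(space, lambda c: 10 * (c["x1"] - 0.3) ** 2, 500, seed)
            rep = fanova(encode_history(h), FanovaSettings(seed=seed))
            assert rep.importances["x1"] > 0.8
            for name, frac in rep.importances.items():
                if name != "x1":
                    assert frac < 0.05
            total = sum(rep.importances.values()) + rep.higher_order
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_additive_dimensions(self):
        space = SearchSpace([
            HyperparameterDef("x1", "continuous", (0.0, 1.0)),
            HyperparameterDef("x2", "continuous", (0.0, 1.0)),
        ])
        h = _synthetic_history(space, lambda c: c["x1"] + c["x2"], 400, seed=5)
        rep = fanova(encode_history(h), FanovaSettings(seed=5))
        assert abs(rep.importances["x1"] - rep.importances["x2"]) < 0.1

    def test_constant_objective_degenerate(self):
        space = _nuisance_space()
        h = _synthetic_history(space, lambda c: 42.0, 50, seed=6)
        rep = fanova(encode_history(h), FanovaSettings(seed=6))
        assert rep.degenerate
        assert all(v == 0.0 for v in rep.importances.values())

    def test_affine_objective_rescaling_invariant(self):
        space = _nuisance_space()
        h1 = _synthetic_history(space, lambda c: 10 * (c["x1"] - 0.3) ** 2, 300, seed=7)
        h2 = History(space=space, trials=[
            Trial(t.index, t.config,
                  ObjectiveValue(5.0 * t.objective.mean_rmse + 3.0,
                                 [5.0 * t.objective.mean_rmse + 3.0]))
            for t in h1.trials
        ])
        r1 = fanova(encode_history(h1), FanovaSettings(seed=0))
        r2 = fanova(encode_history(h2), FanovaSettings(seed=0))
        # variance fractions are scale-free; forest refits may break split
        # ties differently under rescaling, hence the small tolerance
        for name in r1.importances:
            assert r1.importances[name] == pytest.approx(r2.importances[name], abs=0.01)

    def test_trial_order_permutation_invariant(self):
        space = _nuisance_space()
        h = _synthetic_history(space, lambda c: 10 * (c["x1"] - 0.3) ** 2, 200, seed=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(h.trials))
        hp = History(space=space, trials=[h.trials[i] for i in perm])
        r1 = fanova(encode_history(h), FanovaSettings(seed=1))
        r2 = fanova(encode_history(hp), FanovaSettings(seed=1))
        assert r1.importances == r2.importances

    def test_report_dataframe_has_groups(self, full_space):
        h = _synthetic_history(full_space, cnn_proxy_objective, 60, seed=9)
        rep = fanova(encode_history(h), FanovaSettings(seed=9))
        df = rep.to_dataframe()
        assert set(df.columns) == {"hyperparameter", "group", "fraction"}
        assert (df["fraction"] >= 0).all()
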