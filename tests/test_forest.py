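"""Forest training, OOB bookkeeping and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from rvimp import (
    CLASSIFICATION,
    REGRESSION,
    DataValidationError,
    ForestSpec,
    TabularDataset,
    all_vimps,
    oob_error,
    permutation_vimp,
    train_forest,
)
from rvimp._tree import forest_vimp_kernel, predict_tree

from conftest import make_classification, make_regression


class TestTraining:
    def test_deterministic_under_seed(self):
        data = make_regression(n=50, seed=7)
        spec = ForestSpec(n_trees=20, rng_seed=7)
        f1 = train_forest(data, spec)
        f2 = train_forest(data, spec)
        for a, b in zip(f1.inbag, f2.inbag):
            assert np.array_equal(a, b)
        v1 = permutation_vimp(f1, data, "X1", seed=3)
        v2 = permutation_vimp(f2, data, "X1", seed=3)
        assert v1 == v2

    def test_inbag_oob_partition(self):
        data = make_regression(n=60, seed=1)
        forest = train_forest(data, ForestSpec(n_trees=5, rng_seed=0))
        for bag, o in zip(forest.inbag, forest.oob):
            support = set(bag.tolist())
            assert support.isdisjoint(o.tolist())
            assert support | set(o.tolist()) == set(range(60))

    def test_expected_oob_fraction(self):
        """With a size-n bootstrap each row is OOB with probability
        (1 - 1/n)^n; the mean OOB fraction over many trees must sit
        within 5 standard errors of it."""
        n, T = 100, 600
        data = make_regression(n=n, seed=2)
        forest = train_forest(data, ForestSpec(n_trees=T, rng_seed=5))
        p_oob = (1 - 1 / n) ** n
        fractions = forest._oob_mask.mean(axis=1)
        se = np.sqrt(p_oob * (1 - p_oob) / n) / np.sqrt(T)
        assert abs(fractions.mean() - p_oob) < 5 * se

    def test_subsampling_without_replacement(self):
        data = make_regression(n=40, seed=3)
        forest = train_forest(
            data, ForestSpec(n_trees=4, bootstrap_fraction=0.632, replace=False, rng_seed=1)
        )
        for bag, o in zip(forest.inbag, forest.oob):
            assert len(bag) == 25  # round(0.632 * 40)
            assert len(np.unique(bag)) == len(bag)
            assert len(o) == 40 - 25

    def test_rejects_bad_inputs(self):
        data = make_regression(n=30, seed=0)
        with pytest.raises(DataValidationError, match="values in \\{0, 1\\}"):
            TabularDataset(data.features, np.arange(30, dtype=float), CLASSIFICATION)
        with pytest.raises(DataValidationError, match="missing or non-finite"):
            TabularDataset(data.features.assign(X1=np.nan), data.y, REGRESSION)


class TestOobError:
    def test_perfect_classification_zero_loss(self):
        # outcome is a wide-margin threshold of X1; with both features
        # candidate at the root the pure X1 split always wins, so every
        # tree classifies its OOB rows correctly
        rng = np.random.default_rng(4)
        x1 = rng.uniform(0.5, 2.0, 200) * rng.choice([-1.0, 1.0], 200)
        X = np.column_stack([x1, rng.normal(size=200)])
        y = (x1 > 0).astype(float)
        data = TabularDataset(pd.DataFrame(X, columns=["X1", "X2"]), y, CLASSIFICATION)
        forest = train_forest(data, ForestSpec(n_trees=30, mtry=2, rng_seed=0))
        assert oob_error(forest, data) == 0.0

    def test_constant_outcome_zero_loss(self):
        data = make_regression(n=40, seed=5)
        const = TabularDataset(data.features, np.full(40, 3.14), REGRESSION)
        forest = train_forest(const, ForestSpec(n_trees=10, rng_seed=0))
        assert oob_error(forest, const) == 0.0

    def test_matches_per_tree_recomputation(self):
        """Aggregation rule: mean over trees of the tree-wise OOB loss."""
        data = make_regression(n=60, seed=6)
        forest = train_forest(data, ForestSpec(n_trees=8, rng_seed=2))
        X, y = data.X, data.y
        expected = np.mean(
            [
                np.mean((y[o] - predict_tree(*tr, np.ascontiguousarray(X[o]))) ** 2)
                for tr, o in zip(forest.trees, forest.oob)
                if len(o)
            ]
        )
        assert oob_error(forest, data) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        data = make_regression(n=60, seed=6)
        forest = train_forest(data, ForestSpec(n_trees=3, rng_seed=2))
        with pytest.raises(ValueError):
            oob_error(forest, make_regression(n=50, seed=6))


class TestPermutationVimp:
    def test_constant_column_exactly_zero(self):
        data = make_regression(n=80, seed=8)
        const = data.replace_column("X3", np.full(80, 1.0))
        forest = train_forest(const, ForestSpec(n_trees=25, rng_seed=1))
        assert permutation_vimp(forest, const, "X3", seed=9) == 0.0

    def test_identity_permutation_zero(self):
        """Feeding identity permutations into the kernel yields exactly
        zero loss difference for every tree."""
        data = make_regression(n=60, seed=9)
        forest = train_forest(data, ForestSpec(n_trees=6, rng_seed=3))
        n_oob = forest._oob_mask.sum(axis=1).astype(np.int64)
        offsets = np.concatenate([[0], np.cumsum(n_oob)[:-1]])
        perms = np.concatenate([np.arange(k) for k in n_oob])
        diffs = forest_vimp_kernel(
            forest._feature, forest._threshold, forest._left, forest._right,
            forest._value, forest._oob_mask, data.X, data.y,
            0, perms, offsets, 1, False,
        )
        assert np.all(diffs == 0.0)

    @pytest.mark.parametrize("task", ["regression", "classification"])
    def test_single_tree_brute_force(self, task):
        """Engine output equals an independent recomputation of the two
        OOB losses for a known permutation."""
        data = (
            make_regression(n=40, seed=10) if task == "regression"
            else make_classification(n=40, seed=10)
        )
        forest = train_forest(data, ForestSpec(n_trees=1, rng_seed=4))
        seed = 13
        col = 1
        got = permutation_vimp(forest, data, col, n_perm=1, seed=seed)

        # replicate the documented seed schedule, then recompute by hand
        rng = np.random.default_rng(np.random.SeedSequence((seed, col)))
        o = forest.oob[0]
        pi = rng.permutation(len(o))
        X, y = data.X, data.y
        Xo = np.ascontiguousarray(X[o])
        Xp = Xo.copy()
        Xp[:, col] = Xo[pi, col]

        def loss(Xmat):
            pred = predict_tree(*forest.trees[0], Xmat)
            if task == "classification":
                return np.mean((pred > 0.5) != (y[o] > 0.5))
            return np.mean((y[o] - pred) ** 2)

        assert got == pytest.approx(loss(Xp) - loss(Xo), rel=1e-12, abs=1e-15)

    def test_signal_dominates_noise(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(300, 2))
        y = X[:, 0].copy()  # Y = X1 exactly
        data = TabularDataset(pd.DataFrame(X, columns=["X1", "X2"]), y, REGRESSION)
        forest = train_forest(data, ForestSpec(n_trees=60, rng_seed=0))
        vv = all_vimps(forest, data, seed=0)
        assert vv["X1"] > vv["X2"]

    def test_null_feature_within_noise_band(self):
        """A feature independent of the outcome has VIMP within 3
        standard errors of zero (SE from the per-tree differences)."""
        rng = np.random.default_rng(15)
        X = rng.normal(size=(600, 3))
        y = 2 * X[:, 0] + rng.normal(size=600)
        data = TabularDataset(pd.DataFrame(X, columns=["X1", "X2", "X3"]), y, REGRESSION)
        forest = train_forest(data, ForestSpec(n_trees=300, rng_seed=1))
        vv = all_vimps(forest, data, seed=2)
        diffs = vv.per_tree[:, 2]
        se = np.nanstd(diffs) / np.sqrt(np.sum(~np.isnan(diffs)))
        assert abs(vv["X3"]) < 3 * se

    def test_errors(self, small_regression):
        forest = train_forest(small_regression, ForestSpec(n_trees=3, rng_seed=0))
        with pytest.raises(KeyError):
            permutation_vimp(forest, small_regression, "nope")
        with pytest.raises(ValueError):
            permutation_vimp(forest, small_regression, "X1", n_perm=0)


class TestAllVimps:
    def test_single_column_consistency(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(50, 1))
        y = X[:, 0] + rng.normal(size=50)
        data = TabularDataset(pd.DataFrame(X, columns=["X1"]), y, REGRESSION)
        forest = train_forest(data, ForestSpec(n_trees=10, rng_seed=5))
        vv = all_vimps(forest, data, seed=21)
        assert vv["X1"] == permutation_vimp(forest, data, "X1", seed=21)

    def test_per_tree_mean_invariant(self, small_regression):
        forest = train_forest(small_regression, ForestSpec(n_trees=15, rng_seed=6))
        vv = all_vimps(forest, small_regression, seed=0)
        np.testing.assert_allclose(vv.values, np.nanmean(vv.per_tree, axis=0), rtol=1e-12)

    def test_zero_oob_trees_skipped(self):
        # n=3 with replacement: some trees see every row in-bag
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"X1": rng.normal(size=3), "X2": rng.normal(size=3)})
        data = TabularDataset(df, rng.normal(size=3), REGRESSION)
        with pytest.warns(UserWarning, match="no out-of-bag"):
            forest = train_forest(data, ForestSpec(n_trees=80, rng_seed=3))
        vv = all_vimps(forest, data, seed=0)
        n_contributing = np.sum(~np.isnan(vv.per_tree[:, 0]))
        assert 0 < n_contributing < 80
        assert np.isfinite(vv.values).all()
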