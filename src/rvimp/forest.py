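"""Random-forest engine with explicit in-bag/out-of-bag bookkeeping.

Breiman's permutation variable importance (VIMP) is the increase in
out-of-bag (OOB) prediction error caused by randomly permuting one
feature's values:

    VIMP(X_i) = E[L(Y, f(pi_i(X)))] - E[L(Y, f(X))]

estimated here tree by tree: for every tree the feature is permuted among
that tree's OOB rows only, the tree's OOB loss is recomputed, and the loss
differences are averaged over trees (and optionally over several
permutations per tree).  The loss is squared error for regression and 0-1
loss for classification.

The trees are standard CART: bootstrap sample per tree, best variance-
reduction split among ``mtry`` randomly drawn candidate features at every
node (for a 0/1 outcome this coincides with the Gini criterion), growth
until node purity or the minimum node size.  Induction runs through the
compiled kernels in :mod:`rvimp._tree`; their split rules reproduce
scikit-learn's ``DecisionTreeRegressor`` exactly up to the order in which
exactly-tied splits are broken (asserted in the test-suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
import numpy as np

from . import _tree
from .datasets import CLASSIFICATION, REGRESSION, DataValidationError, TabularDataset

__all__ = [
    "ForestSpec",
    "LossFunction",
    "FittedForest",
    "VimpVector",
    "train_forest",
    "oob_error",
    "permutation_vimp",
    "all_vimps",
]


def _squared_error(observed: np.ndarray, predicted: np.ndarray) -> float:
    return float(np.mean((observed - predicted) ** 2))


def _zero_one(observed: np.ndarray, predicted: np.ndarray) -> float:
    # predicted holds leaf class-1 fractions; majority vote with ties
    # broken toward class 0
    return float(np.mean((predicted > 0.5) != (observed > 0.5)))


@dataclass(frozen=True)
class LossFunction:
    name: str
    evaluator: "callable"

    def __call__(self, observed: np.ndarray, predicted: np.ndarray) -> float:
        return self.evaluator(observed, predicted)


SQUARED_ERROR = LossFunction("squared_error", _squared_error)
ZERO_ONE = LossFunction("zero_one", _zero_one)


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters.

    ``mtry`` and ``min_node_size`` default to the conventions of the
    reference forest implementations: mtry = max(floor(p/3), 1) for
    regression and floor(sqrt(p)) for classification; minimum terminal
    node size 5 for regression and 1 for classification.  Bootstrap
    samples are of size ``round(bootstrap_fraction * n)``, with
    replacement by default.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int | None = None
    bootstrap_fraction: float = 1.0
    replace: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size is not None and self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def resolve(self, task: str, p: int) -> tuple[int, int]:
        """Concrete (mtry, min_node_size) for a given task and width."""
        if self.mtry is not None:
            mtry = min(self.mtry, p)
        elif task == REGRESSION:
            mtry = max(p // 3, 1)
        else:
            mtry = max(int(np.sqrt(p)), 1)
        if self.min_node_size is not None:
            min_node = self.min_node_size
        else:
            min_node = 5 if task == REGRESSION else 1
        return mtry, min_node

    def with_seed(self, seed: int) -> "ForestSpec":
        return replace(self, rng_seed=int(seed))


@dataclass
class VimpVector:
    """Per-feature permutation importances with per-tree detail."""

    values: np.ndarray
    per_tree: np.ndarray  # (n_trees, p); NaN for trees without OOB rows
    feature_names: list[str]

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.feature_names.index(name)])

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.feature_names, self.values)}


class FittedForest:
    """Trained ensemble plus the per-tree bootstrap bookkeeping.

    ``inbag[t]`` is the multiset (as drawn, with duplicates) of row
    indices used to grow tree ``t``; ``oob[t]`` the sorted indices absent
    from it.  Every VIMP computation permutes within ``oob[t]`` only.

    The trees live in packed parallel arrays (one row per tree) produced
    by the compiled training kernel; ``trees`` exposes the per-tree
    array views.
    """

    def __init__(
        self,
        packed: tuple,
        draws: np.ndarray,
        oob_mask: np.ndarray,
        task: str,
        n_rows: int,
        feature_names: list[str],
        spec: ForestSpec,
    ):
        (self._feature, self._threshold, self._left, self._right,
         self._value, self._n_nodes) = packed
        self._draws = draws
        self._oob_mask = oob_mask
        self.task = task
        self.n_rows = n_rows
        self.feature_names = feature_names
        self.spec = spec
        self.loss: LossFunction = SQUARED_ERROR if task == REGRESSION else ZERO_ONE
        n_empty = int((oob_mask.sum(axis=1) == 0).sum())
        if n_empty:
            warnings.warn(
                f"{n_empty} tree(s) have no out-of-bag rows and are skipped "
                "in OOB error and VIMP aggregation",
                stacklevel=2,
            )

    @property
    def n_trees(self) -> int:
        return self._feature.shape[0]

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def tree(self, t: int) -> tuple:
        """Parallel-array encoding of tree ``t``."""
        k = self._n_nodes[t]
        return (
            self._feature[t, :k],
            self._threshold[t, :k],
            self._left[t, :k],
            self._right[t, :k],
            self._value[t, :k],
        )

    @property
    def trees(self) -> list[tuple]:
        return [self.tree(t) for t in range(self.n_trees)]

    @property
    def inbag(self) -> list[np.ndarray]:
        return [self._draws[t] for t in range(self.n_trees)]

    @property
    def oob(self) -> list[np.ndarray]:
        return [np.flatnonzero(self._oob_mask[t]) for t in range(self.n_trees)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble prediction: mean of tree values (class-1 probability
        for classification)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        acc = np.zeros(X.shape[0])
        for tr in self.trees:
            acc += _tree.predict_tree(*tr, X)
        return acc / self.n_trees

    def _check_data(self, data: TabularDataset) -> None:
        if data.n != self.n_rows:
            raise ValueError(
                f"forest was trained on {self.n_rows} rows, got {data.n}"
            )
        if data.p != self.p:
            raise ValueError(
                f"forest was trained on {self.p} features, got {data.p}"
            )


def train_forest(data: TabularDataset, spec: ForestSpec) -> FittedForest:
    """Train a forest on ``data`` with full in-bag/OOB bookkeeping.

    Deterministic: the same (data, spec) pair always yields the same
    forest.  A single generator seeded from ``spec.rng_seed`` drives, in a
    fixed order, the bootstrap draw matrix and one split-search seed per
    tree.
    """
    if not isinstance(data, TabularDataset):
        raise TypeError("data must be a TabularDataset")
    n, p = data.n, data.p
    mtry, min_node = spec.resolve(data.task, p)
    XC = data.X
    XF = np.asfortranarray(XC)
    y = data.y
    if data.task == CLASSIFICATION:
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise DataValidationError("classification outcome must be 0/1")

    k = int(np.floor(spec.bootstrap_fraction * n + 0.5))
    if k < 1:
        raise ValueError("bootstrap_fraction too small: empty bootstrap sample")

    order = np.empty((p, n), np.int32)
    for j in range(p):
        order[j] = np.argsort(XC[:, j], kind="stable")

    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    if spec.replace:
        draws = rng.integers(0, n, size=(spec.n_trees, k))
    else:
        draws = np.empty((spec.n_trees, k), dtype=np.int64)
        for t in range(spec.n_trees):
            draws[t] = rng.choice(n, size=k, replace=False)
    split_seeds = rng.integers(0, 2**63, size=spec.n_trees).astype(np.uint64)

    out = _tree.train_forest_kernel(XF, y, order, draws, split_seeds, mtry, min_node)
    feature, threshold, left, right, value, n_nodes, oob_mask = out
    packed = (feature, threshold, left, right, value, n_nodes)
    return FittedForest(packed, draws, oob_mask, data.task, n, data.columns, spec)


def oob_error(forest: FittedForest, data: TabularDataset) -> float:
    """Mean over trees of each tree's loss on its own OOB rows."""
    forest._check_data(data)
    X, y = data.X, data.y
    losses = []
    for tr, o in zip(forest.trees, forest.oob):
        if len(o) == 0:
            continue
        pred = _tree.predict_tree(*tr, X[o])
        losses.append(forest.loss(y[o], pred))
    if not losses:
        raise ValueError("no tree has out-of-bag rows; cannot compute OOB error")
    return float(np.mean(losses))


def _vimp_single(
    forest: FittedForest,
    X: np.ndarray,
    y: np.ndarray,
    col: int,
    n_perm: int,
    seed_entropy: tuple,
) -> np.ndarray:
    """Per-tree OOB loss differences for one column (NaN for OOB-less
    trees).  One generator per column drives the (tree, permutation)
    draws in fixed order; the loss evaluations run in a compiled kernel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed_entropy))
    n_oob = forest._oob_mask.sum(axis=1).astype(np.int64)
    offsets = np.zeros(forest.n_trees, dtype=np.int64)
    perm_parts = []
    pos = 0
    for t in range(forest.n_trees):
        offsets[t] = pos
        if n_oob[t] == 0:
            # keep the seed stream aligned regardless of skipped trees
            for _ in range(n_perm):
                rng.permutation(1)
            continue
        for _ in range(n_perm):
            perm_parts.append(rng.permutation(n_oob[t]))
        pos += n_perm * n_oob[t]
    perms = (
        np.concatenate(perm_parts).astype(np.int64)
        if perm_parts
        else np.empty(0, np.int64)
    )
    return _tree.forest_vimp_kernel(
        forest._feature, forest._threshold, forest._left, forest._right,
        forest._value, forest._oob_mask,
        np.ascontiguousarray(X), y, col, perms, offsets, n_perm,
        forest.task == CLASSIFICATION,
    )


def permutation_vimp(
    forest: FittedForest,
    data: TabularDataset,
    feature: str | int,
    n_perm: int = 1,
    seed: int = 0,
) -> float:
    """OOB permutation importance of one feature.

    For each tree the feature is permuted among that tree's OOB rows, the
    tree OOB loss recomputed and the un-permuted loss subtracted; the
    differences are averaged over trees and permutations.  May be
    negative in finite samples; reported as-is.
    """
    forest._check_data(data)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    col = feature if isinstance(feature, int) else data.column_index(feature)
    if not 0 <= col < data.p:
        raise KeyError(f"feature index {col} out of range")
    diffs = _vimp_single(forest, data.X, data.y, col, n_perm, (seed, col))
    if np.isnan(diffs).all():
        raise ValueError("no tree has out-of-bag rows; cannot compute VIMP")
    return float(np.nanmean(diffs))


def all_vimps(
    forest: FittedForest,
    data: TabularDataset,
    n_perm: int = 1,
    seed: int = 0,
) -> VimpVector:
    """Permutation VIMP of every feature, column order preserved.

    Each column uses the same seed schedule as a direct
    :func:`permutation_vimp` call with the same ``seed``.
    """
    forest._check_data(data)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = data.X, data.y
    per_tree = np.empty((forest.n_trees, data.p))
    values = np.empty(data.p)
    for j in range(data.p):
        diffs = _vimp_single(forest, X, y, j, n_perm, (seed, j))
        per_tree[:, j] = diffs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values[j] = np.nanmean(diffs)
    return VimpVector(values, per_tree, data.columns)
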