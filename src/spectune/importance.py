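"""Hyperparameter importance by functional ANOVA on a tree-ensemble surrogate.

A random-forest regressor is fitted to (configuration -> mean objective)
records of a search history. For each tree, the marginal predictor of each
hyperparameter is computed *exactly* by integrating the tree's piecewise-
constant function over all other dimensions, weighting each partition cell
by its volume fraction under independent uniform inputs (uniform over the
domain for numerics, uniform over the category/lattice points otherwise).
The first-order importance of a hyperparameter is the variance of its
marginal divided by the tree's total variance, averaged over trees; the
remaining fraction is interaction/higher-order variance.

Only independent hyperparameters — those active in every configuration —
are encoded, since conditional ones do not exist in all records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .optimizers import History

__all__ = [
    "Dim",
    "TreeNode",
    "PiecewiseMarginal",
    "EncodedHistory",
    "FanovaSettings",
    "ImportanceReport",
    "encode_history",
    "tree_from_sklearn",
    "single_tree_marginal",
    "tree_total_variance",
    "fanova",
]


@dataclass(frozen=True)
class Dim:
    """One encoded dimension: continuous interval or integer/category lattice."""

    name: str
    kind: str  # "num" (continuous interval) | "lat" (integer lattice)
    lo: float
    hi: float
    group: str = "other"
    categories: tuple | None = None  # original labels for categorical dims
    is_constant: bool = False

    def total_measure(self) -> float:
        if self.kind == "num":
            return max(self.hi - self.lo, 1e-300)
        return math.floor(self.hi) - math.floor(self.lo - 1.0)

    def init_bounds(self) -> tuple[float, float]:
        # half-open (a, b]; for lattices a starts just below the first point
        return (self.lo - 1.0, self.hi) if self.kind == "lat" else (self.lo, self.hi)

    def measure(self, a: float, b: float) -> float:
        """Fraction of the domain inside (a, b]."""
        if self.kind == "num":
            return max(b - a, 0.0) / self.total_measure()
        return max(math.floor(b) - math.floor(a), 0) / self.total_measure()


@dataclass
class TreeNode:
    """A regression-tree node; leaf iff feature < 0."""

    feature: int = -1
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    value: float = 0.0


def tree_from_sklearn(sk_tree) -> TreeNode:
    """Convert a fitted sklearn tree (estimator.tree_) into TreeNode form."""
    t = sk_tree

    def rec(i: int) -> TreeNode:
        if t.children_left[i] == -1:
            return TreeNode(value=float(t.value[i].ravel()[0]))
        return TreeNode(
            feature=int(t.feature[i]),
            threshold=float(t.threshold[i]),
            left=rec(t.children_left[i]),
            right=rec(t.children_right[i]),
        )

    return rec(0)


def _leaves(root: TreeNode, dims: list[Dim]):
    """Yield (bounds, value) for every leaf; bounds are (a, b] per dimension."""
    out: list[tuple[list[tuple[float, float]], float]] = []

    def rec(node: TreeNode, bounds):
        if node.feature < 0:
            out.append(([tuple(b) for b in bounds], node.value))
            return
        a, b = bounds[node.feature]
        t = node.threshold
        left_b = (a, min(b, t))
        right_b = (max(a, t), b)
        d = dims[node.feature]
        if d.measure(*left_b) > 0:
            bounds[node.feature] = list(left_b)
            rec(node.left, bounds)
        if d.measure(*right_b) > 0:
            bounds[node.feature] = list(right_b)
            rec(node.right, bounds)
        bounds[node.feature] = [a, b]

    rec(root, [list(d.init_bounds()) for d in dims])
    return out


def tree_total_variance(root: TreeNode, dims: list[Dim]) -> float:
    """Variance of the tree function under independent uniform inputs."""
    leaves = _leaves(root, dims)
    w = np.array([np.prod([d.measure(a, b) for d, (a, b) in zip(dims, bounds)])
                  for bounds, _ in leaves])
    v = np.array([value for _, value in leaves])
    mean = float(np.sum(w * v))
    return float(np.sum(w * v * v) - mean * mean)


@dataclass
class PiecewiseMarginal:
    """Exact marginal of a tree along one dimension: piecewise constant on
    (a, b] segments that tile the dimension's domain."""

    dim: Dim
    segments: list[tuple[float, float, float]]  # (a, b, value)

    def __call__(self, x: float) -> float:
        for a, b, v in self.segments:
            if a < x <= b or (x == self.dim.lo and a <= x <= b):
                return v
        raise ValueError(f"{x} outside the domain of {self.dim.name}")

    def mean(self) -> float:
        return sum(self.dim.measure(a, b) * v for a, b, v in self.segments)

    def variance(self) -> float:
        mu = self.mean()
        return sum(self.dim.measure(a, b) * (v - mu) ** 2 for a, b, v in self.segments)


def single_tree_marginal(root: TreeNode, dims: list[Dim], dimension: int) -> PiecewiseMarginal:
    """Integrate the tree over all dimensions except `dimension` (exact
    cell-volume weighting, no Monte Carlo)."""
    d = dims[dimension]
    leaves = _leaves(root, dims)
    pieces = []
    for bounds, value in leaves:
        w_other = 1.0
        for j, (a, b) in enumerate(bounds):
            if j != dimension:
                w_other *= dims[j].measure(a, b)
        pieces.append((bounds[dimension][0], bounds[dimension][1], w_other * value))
    cuts = sorted({p[0] for p in pieces} | {p[1] for p in pieces})
    segments = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if d.measure(a, b) <= 0:
            continue
        v = sum(pv for pa, pb, pv in pieces if pa <= a and pb >= b)
        segments.append((a, b, v))
    return PiecewiseMarginal(dim=d, segments=segments)


# ---------------------------------------------------------------------------
# history encoding and the ensemble
# ---------------------------------------------------------------------------


@dataclass
class EncodedHistory:
    """Design matrix over independent hyperparameters plus mean objectives."""

    X: np.ndarray
    y: np.ndarray
    dims: list[Dim]

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]


def encode_history(history: History, min_trials: int = 30,
                   include_penalised: bool = True) -> EncodedHistory:
    """Encode a history for fANOVA.

    Conditional hyperparameters (not active in every configuration, e.g. pool
    size behind the pooling state) are dropped. Categoricals and flags are
    encoded as category indices; numerics are used raw. Penalised
    (infeasible/failed) trials keep their penalty objective unless excluded.
    """
    trials = [t for t in history.trials
              if include_penalised or t.objective.status == "ok"]
    trials = [t for t in trials if np.isfinite(t.objective.mean_rmse)]
    trials.sort(key=lambda t: t.index)  # row order independent of storage order
    if len(trials) < min_trials:
        raise ValueError(f"need at least {min_trials} completed trials, have {len(trials)}")
    space = history.space
    names = [d.name for d in space if space.is_always_active(d.name)]
    dims: list[Dim] = []
    cols = []
    for name in names:
        d = space.get(name)
        raw = [t.config.values[name] for t in trials]
        if d.kind == "continuous":
            col = np.array(raw, dtype=float)
            dim = Dim(name, "num", float(d.domain[0]), float(d.domain[1]), d.group,
                      is_constant=len(set(raw)) <= 1)
        elif d.kind == "integer":
            col = np.array(raw, dtype=float)
            dim = Dim(name, "lat", float(d.domain[0]), float(d.domain[1]), d.group,
                      is_constant=len(set(raw)) <= 1)
        else:
            col = np.array([d.domain.index(v) for v in raw], dtype=float)
            dim = Dim(name, "lat", 0.0, float(len(d.domain) - 1), d.group,
                      categories=tuple(d.domain), is_constant=len(set(raw)) <= 1)
        dims.append(dim)
        cols.append(col)
    X = np.column_stack(cols)
    y = np.array([t.objective.mean_rmse for t in trials])
    return EncodedHistory(X=X, y=y, dims=dims)


@dataclass(frozen=True)
class FanovaSettings:
    n_trees: int = 64
    min_leaf: int = 3
    max_features: float = 0.8
    seed: int = 0


@dataclass
class ImportanceReport:
    importances: dict[str, float]
    higher_order: float
    groups: dict[str, str]
    oob_r2: float | None = None
    degenerate: bool = False
    constant_dims: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"hyperparameter": k, "group": self.groups[k], "fraction": v}
                for k, v in self.importances.items()]
        rows.append({"hyperparameter": "(higher-order)", "group": "interactions",
                     "fraction": self.higher_order})
        return pd.DataFrame(rows)


def fanova(encoded: EncodedHistory, settings: FanovaSettings | None = None) -> ImportanceReport:
    """First-order variance fractions per hyperparameter, averaged over the
    forest; fractions plus the higher-order remainder sum to one (unless the
    history is degenerate, in which case all are zero and flagged)."""
    settings = settings or FanovaSettings()
    dims = encoded.dims
    names = [d.name for d in dims]
    groups = {d.name: d.group for d in dims}
    constant = [d.name for d in dims if d.is_constant]

    if float(np.var(encoded.y)) < 1e-24:
        return ImportanceReport({n: 0.0 for n in names}, 0.0, groups,
                                degenerate=True, constant_dims=constant)

    forest = RandomForestRegressor(
        n_estimators=settings.n_trees,
        min_samples_leaf=settings.min_leaf,
        max_features=settings.max_features,
        bootstrap=True,
        oob_score=True,
        random_state=settings.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small histories may lack full OOB coverage
        forest.fit(encoded.X, encoded.y)
    oob = float(forest.oob_score_) if hasattr(forest, "oob_score_") else None

    frac_sum = np.zeros(len(dims))
    resid_sum = 0.0
    kept = 0
    for est in forest.estimators_:
        root = tree_from_sklearn(est.tree_)
        total = tree_total_variance(root, dims)
        if total < 1e-18:
            continue
        fracs = np.array([
            single_tree_marginal(root, dims, j).variance() / total for j in range(len(dims))
        ])
        frac_sum += fracs
        resid_sum += max(1.0 - float(fracs.sum()), 0.0)
        kept += 1
    if kept == 0:
        return ImportanceReport({n: 0.0 for n in names}, 0.0, groups, oob_r2=oob,
                                degenerate=True, constant_dims=constant)
    fracs = frac_sum / kept
    return ImportanceReport(
        importances={n: float(f) for n, f in zip(names, fracs)},
        higher_order=float(resid_sum / kept),
        groups=groups,
        oob_r2=oob,
        degenerate=False,
        constant_dims=constant,
    )
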