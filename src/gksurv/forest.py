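"""Random survival forest for right-censored time to local failure.

Each tree is grown on a bootstrap sample of the training rows.  At every
internal node a random subset of features is considered; candidate thresholds
are the midpoints of consecutive sorted unique values, and the chosen split
maximizes the standardized two-group log-rank statistic (ties broken by
lowest feature index, then lowest threshold, so fitting is reproducible bit
for bit given the seed).  Leaves carry the Nelson-Aalen cumulative hazard
H(t) = sum_{t_i <= t} d_i / n_i of their bootstrap rows, evaluated on the
shared grid of unique training event times; ensemble aggregation averages
cumulative hazards across trees, and S(t) = exp(-H_bar(t)).

The risk score is ensemble mortality — the averaged cumulative hazard summed
over the whole grid — so a higher score means predicted earlier failure.
Forests serialize to a JSON document (grid, node arrays, leaf hazards) that
reconstructs the exact predictor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .curves import SurvivalCurve
from .preprocessing import FeatureMatrix

__all__ = [
    "Hyperparams",
    "SurvivalTree",
    "SurvivalForest",
    "logrank_split_statistic",
    "fit_forest",
    "predict_survival",
    "predict_risk",
    "DEFAULT_TUNING_GRID",
]


@dataclass(frozen=True)
class Hyperparams:
    """Forest hyperparameters; ``max_features`` is a fraction or a rule name."""

    n_trees: int = 200
    max_depth: Optional[int] = None
    min_samples_split: int = 6
    min_samples_leaf: int = 3
    max_features: Union[float, str] = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive or None")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if isinstance(self.max_features, str):
            if self.max_features not in ("sqrt", "all"):
                raise ValueError("max_features rule must be 'sqrt' or 'all'")
        elif not 0.0 < self.max_features <= 1.0:
            raise ValueError("max_features fraction must lie in (0,1]")

    def n_candidate_features(self, p: int) -> int:
        if self.max_features == "sqrt":
            return min(p, max(1, math.ceil(math.sqrt(p))))
        if self.max_features == "all":
            return p
        return min(p, max(1, math.ceil(self.max_features * p)))


#: Default hyperparameter search grid for inner-loop tuning.  The tuned
#: dimensions are tree count, depth, leaf size and feature subsampling; the
#: values span shallow, regularized forests through fully grown ones.
DEFAULT_TUNING_GRID: list[Hyperparams] = [
    Hyperparams(
        n_trees=nt,
        max_depth=md,
        min_samples_leaf=msl,
        min_samples_split=max(2 * msl, 2),
        max_features=mf,
    )
    for nt in (200, 500)
    for md in (3, 5, None)
    for msl in (3, 5, 10)
    for mf in (0.33, 0.58, 1.0)
]


def logrank_split_statistic(
    times: np.ndarray, events: np.ndarray, left_mask: np.ndarray
) -> float:
    """Standardized two-group log-rank statistic |O - E| / sqrt(V).

    O is the observed number of left-group events summed over event times,
    E the hypergeometric expectation and V the hypergeometric variance.
    Degenerate configurations (a side with nobody at risk, or zero variance)
    return 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    left_mask = np.asarray(left_mask, dtype=bool)
    if left_mask.sum() == 0 or left_mask.sum() == left_mask.size:
        return 0.0
    ut = np.unique(times[events == 1])
    if ut.size == 0:
        return 0.0
    O = E = V = 0.0
    for t in ut:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & left_mask).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & left_mask).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0.0:
        return 0.0
    return abs(O - E) / math.sqrt(V)


@dataclass
class SurvivalTree:
    """Flat-array survival tree; node 0 is the root, feature -1 marks a leaf."""

    feature: list[int]
    threshold: list[float]
    left: list[int]
    right: list[int]
    hazard: list[Optional[list[float]]]  # leaf cumulative hazard on the grid
    bootstrap_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def predict_hazard(self, X: np.ndarray, n_grid: int) -> np.ndarray:
        """Route rows to leaves; returns (n_rows, n_grid) cumulative hazards."""
        n = X.shape[0]
        out = np.empty((n, n_grid), dtype=float)
        stack = [(0, np.arange(n))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            f = self.feature[node]
            if f < 0:
                out[rows] = np.asarray(self.hazard[node], dtype=float)
                continue
            go_left = X[rows, f] <= self.threshold[node]
            stack.append((self.left[node], rows[go_left]))
            stack.append((self.right[node], rows[~go_left]))
        return out


def _nelson_aalen_on_grid(
    times: np.ndarray, events: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Nelson-Aalen cumulative hazard of (times, events) at each grid time."""
    inc = np.zeros(grid.size)
    for gi, g in enumerate(grid):
        n_at = int(np.sum(times >= g))
        if n_at > 0:
            d = int(np.sum((times == g) & (events == 1)))
            inc[gi] = d / n_at
    return np.cumsum(inc)


def _scan_feature(
    xf: np.ndarray,
    tb: np.ndarray,
    eb: np.ndarray,
    min_leaf: int,
) -> tuple[float, float]:
    """Best (statistic^2-scaled, threshold) for one feature at one node.

    Vectorizes the log-rank scan over all admissible midpoint thresholds via
    prefix sums over the node's event-time columns.  Returns (-inf, nan)
    when no admissible split exists.
    """
    n = xf.size
    ut = np.unique(tb[eb == 1])
    if ut.size == 0:
        return -np.inf, math.nan
    order = np.argsort(xf, kind="stable")
    xs, ts, es = xf[order], tb[order], eb[order]

    at_risk = ts[:, None] >= ut[None, :]
    death = (ts[:, None] == ut[None, :]) & (es[:, None] == 1)
    n1 = np.cumsum(at_risk, axis=0)
    d1 = np.cumsum(death, axis=0)
    n_t = n1[-1]
    d_t = d1[-1]

    ratio = n1 / n_t
    O = d1.sum(axis=1)
    E = (d_t * ratio).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vcol = d_t * ratio * (1.0 - ratio) * (n_t - d_t) / np.maximum(n_t - 1, 1)
    vcol[:, n_t <= 1] = 0.0
    V = vcol.sum(axis=1)

    sizes = np.arange(1, n + 1)
    boundary = np.zeros(n, dtype=bool)
    boundary[:-1] = xs[:-1] < xs[1:]
    admissible = boundary & (sizes >= min_leaf) & ((n - sizes) >= min_leaf) & (V > 0)
    if not admissible.any():
        return -np.inf, math.nan
    stat = np.full(n, -np.inf)
    stat[admissible] = (O[admissible] - E[admissible]) ** 2 / V[admissible]
    best = int(np.argmax(stat))  # argmax takes the first (lowest threshold) on ties
    thr = 0.5 * (xs[best] + xs[best + 1])
    return float(stat[best]), thr


def _grow_tree(
    Xb: np.ndarray,
    tb: np.ndarray,
    eb: np.ndarray,
    grid: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
    bootstrap_indices: np.ndarray,
) -> SurvivalTree:
    p = Xb.shape[1]
    m_try = hp.n_candidate_features(p)
    tree = SurvivalTree([], [], [], [], [], bootstrap_indices)

    def new_node() -> int:
        tree.feature.append(-1)
        tree.threshold.append(math.nan)
        tree.left.append(-1)
        tree.right.append(-1)
        tree.hazard.append(None)
        return len(tree.feature) - 1

    def make_leaf(node: int, rows: np.ndarray) -> None:
        tree.hazard[node] = _nelson_aalen_on_grid(tb[rows], eb[rows], grid).tolist()

    def build(node: int, rows: np.ndarray, depth: int) -> None:
        n_events = int(eb[rows].sum())
        if (
            (hp.max_depth is not None and depth >= hp.max_depth)
            or rows.size < hp.min_samples_split
            or n_events == 0
        ):
            make_leaf(node, rows)
            return
        candidates = np.sort(rng.choice(p, size=m_try, replace=False))
        best_stat, best_f, best_thr = -np.inf, -1, math.nan
        for f in candidates:
            stat, thr = _scan_feature(
                Xb[rows, f], tb[rows], eb[rows], hp.min_samples_leaf
            )
            if stat > best_stat:  # strict: first (lowest index/threshold) wins ties
                best_stat, best_f, best_thr = stat, int(f), thr
        if best_f < 0:
            make_leaf(node, rows)
            return
        go_left = Xb[rows, best_f] <= best_thr
        tree.feature[node] = best_f
        tree.threshold[node] = best_thr
        lnode, rnode = new_node(), new_node()
        tree.left[node], tree.right[node] = lnode, rnode
        build(lnode, rows[go_left], depth + 1)
        build(rnode, rows[~go_left], depth + 1)

    root = new_node()
    build(root, np.arange(Xb.shape[0]), 0)
    return tree


@dataclass
class SurvivalForest:
    """Ensemble of survival trees sharing one event-time grid."""

    trees: list[SurvivalTree]
    grid: np.ndarray
    hp: Hyperparams
    columns: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": self.grid.tolist(),
                "columns": self.columns,
                "hyperparams": {
                    "n_trees": self.hp.n_trees,
                    "max_depth": self.hp.max_depth,
                    "min_samples_split": self.hp.min_samples_split,
                    "min_samples_leaf": self.hp.min_samples_leaf,
                    "max_features": self.hp.max_features,
                    "seed": self.hp.seed,
                },
                "trees": [
                    {
                        "feature": t.feature,
                        "threshold": t.threshold,
                        "left": t.left,
                        "right": t.right,
                        "hazard": t.hazard,
                        "bootstrap_indices": t.bootstrap_indices.tolist(),
                    }
                    for t in self.trees
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SurvivalForest":
        d = json.loads(text)
        hp = Hyperparams(**d["hyperparams"])
        trees = [
            SurvivalTree(
                t["feature"],
                t["threshold"],
                t["left"],
                t["right"],
                t["hazard"],
                np.asarray(t["bootstrap_indices"], dtype=int),
            )
            for t in d["trees"]
        ]
        return cls(trees, np.asarray(d["grid"], dtype=float), hp, d["columns"])


def fit_forest(X: FeatureMatrix, hp: Hyperparams = Hyperparams()) -> SurvivalForest:
    """Fit the forest on a feature matrix with right-censored outcomes.

    The shared grid is the sorted unique training event times; training data
    without a single observed failure cannot anchor the grid and raise.
    """
    if int(X.event.sum()) == 0:
        raise ValueError("cannot fit a survival forest with zero observed events")
    grid = np.unique(X.time[X.event == 1])
    n = X.n
    ss = np.random.SeedSequence(hp.seed)
    trees: list[SurvivalTree] = []
    for child in ss.spawn(hp.n_trees):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, n, size=n)
        trees.append(
            _grow_tree(
                X.X[boot], X.time[boot], X.event[boot], grid, hp, rng, boot
            )
        )
    return SurvivalForest(trees, grid, hp, list(X.columns))


def _as_matrix(forest: SurvivalForest, rows: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(rows, FeatureMatrix):
        if list(rows.columns) != list(forest.columns):
            raise ValueError(
                "feature columns do not match the training layout: "
                f"{rows.columns} vs {forest.columns}"
            )
        return rows.X
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    if arr.shape[1] != len(forest.columns):
        raise ValueError(
            f"expected {len(forest.columns)} feature columns, got {arr.shape[1]}"
        )
    return arr


def _mean_hazard(forest: SurvivalForest, X: np.ndarray) -> np.ndarray:
    m = forest.grid.size
    acc = np.zeros((X.shape[0], m))
    for tree in forest.trees:
        acc += tree.predict_hazard(X, m)
    return acc / len(forest.trees)


def predict_survival(
    forest: SurvivalForest, rows: Union[FeatureMatrix, np.ndarray]
) -> list[SurvivalCurve]:
    """Per-row ensemble survival curves S(t) = exp(-mean cumulative hazard)."""
    X = _as_matrix(forest, rows)
    H = _mean_hazard(forest, X)
    S = np.exp(-H)
    return [SurvivalCurve(forest.grid.copy(), S[i]) for i in range(X.shape[0])]


def predict_risk(
    forest: SurvivalForest, rows: Union[FeatureMatrix, np.ndarray]
) -> np.ndarray:
    """Ensemble mortality: averaged cumulative hazard summed over the grid."""
    X = _as_matrix(forest, rows)
    return _mean_hazard(forest, X).sum(axis=1)
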