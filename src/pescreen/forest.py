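"""Random-forest variable importance for binary risk factors.

Purpose-built for screening tables where every predictor is a 0/1 flag:
bootstrap-resampled CART trees, Gini-impurity splits over a random
feature subset at each node, and mean-decrease-in-Gini importance.  The
forest here only ranks variables (to guide combination subgroups); it is
not used as the risk predictor itself.

With two classes the Gini impurity is G = 1 - p^2 - (1-p)^2 = 2p(1-p).
A split's contribution to a feature's importance is the impurity decrease
weighted by the fraction of the tree's samples reaching the node, summed
over splits and averaged over trees.  Permutation importance (mean
increase of the out-of-bag Brier score after permuting one feature) is
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    mtry: int | None = None      # default: ceil(sqrt(p))
    max_depth: int | None = None
    min_leaf: int = 50
    seed: int = 0
    importance: str = "gini"     # or "permutation"

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else math.ceil(math.sqrt(p))
        if not 1 <= m <= p:
            raise ValueError(f"mtry must lie in [1, {p}], got {m}")
        return m


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-variable importance scores; rank 1 is the most important.

    Ties are broken lexicographically on the variable name so the ranking
    is stable across runs with the same seed.
    """

    table: pd.DataFrame  # columns: variable, importance, rank

    def top_k(self, k: int) -> list[str]:
        if k > len(self.table):
            raise ValueError(f"k={k} exceeds the {len(self.table)} ranked variables")
        return self.table["variable"].head(k).tolist()


def _gini(n_pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


class _Tree:
    """CART tree over binary features, stored as flat node arrays."""

    __slots__ = ("feature", "left", "right", "value")

    def __init__(self) -> None:
        self.feature: list[int] = []   # -1 for leaves
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []   # P(y=1) at the node

    def add_node(self) -> int:
        self.feature.append(-1)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        stack = [(0, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] < 0 or len(idx) == 0:
                out[idx] = self.value[node]
                continue
            mask = X[idx, self.feature[node]]
            stack.append((self.right[node], idx[mask]))
            stack.append((self.left[node], idx[~mask]))
        return out


def _grow_tree(X: np.ndarray, y: np.ndarray, sample: np.ndarray,
               config: ForestConfig, mtry: int, rng: np.random.Generator,
               importance: np.ndarray) -> _Tree:
    n_root = len(sample)
    p = X.shape[1]
    tree = _Tree()
    root = tree.add_node()
    stack = [(root, sample, 0)]
    while stack:
        node, idx, depth = stack.pop()
        n = len(idx)
        n_pos = int(y[idx].sum())
        tree.value[node] = n_pos / n
        g_parent = _gini(n_pos, n)
        if (g_parent == 0.0 or n < 2 * config.min_leaf
                or (config.max_depth is not None and depth >= config.max_depth)):
            continue
        feats = rng.choice(p, size=mtry, replace=False)
        Xs = X[idx][:, feats]
        n_right = Xs.sum(axis=0)                       # feature == 1 branch
        n_left = n - n_right
        pos_right = (Xs & y[idx, None]).sum(axis=0)
        pos_left = n_pos - pos_right
        valid = (n_left >= config.min_leaf) & (n_right >= config.min_leaf)
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            g_left = np.where(n_left > 0, 2 * (pos_left / n_left) * (1 - pos_left / n_left), 0.0)
            g_right = np.where(n_right > 0, 2 * (pos_right / n_right) * (1 - pos_right / n_right), 0.0)
        gain = g_parent - (n_left * g_left + n_right * g_right) / n
        gain[~valid] = -np.inf
        best = int(np.argmax(gain))
        if gain[best] <= 0:
            continue
        feat = int(feats[best])
        importance[feat] += (n / n_root) * gain[best]
        tree.feature[node] = feat
        mask = X[idx, feat]
        left, right = tree.add_node(), tree.add_node()
        tree.left[node], tree.right[node] = left, right
        stack.append((left, idx[~mask], depth + 1))
        stack.append((right, idx[mask], depth + 1))
    return tree


def fit_forest(X: pd.DataFrame, y, config: ForestConfig = ForestConfig()
               ) -> ImportanceRanking:
    """Fit the forest and return the variable-importance ranking.

    ``X`` holds binary features (the caller should already have reduced
    the data to one record per mother when independence matters); ``y``
    is the binary outcome.  Deterministic under ``config.seed``.
    """
    names = list(X.columns)
    Xb = X.to_numpy(dtype=bool)
    yb = np.asarray(y, dtype=bool)
    if yb.all() or not yb.any():
        raise ValueError("outcome is constant; forest cannot be grown")
    n, p = Xb.shape
    mtry = config.resolved_mtry(p)
    rng = np.random.default_rng(config.seed)

    total = np.zeros(p)
    for _ in range(config.n_trees):
        sample = rng.integers(0, n, size=n)
        imp = np.zeros(p)
        tree = _grow_tree(Xb, yb, sample, config, mtry, rng, imp)
        if config.importance == "permutation":
            oob = np.setdiff1d(np.arange(n), sample)
            if len(oob) == 0:
                continue
            base = np.mean((tree.predict_proba(Xb[oob]) - yb[oob]) ** 2)
            for j in range(p):
                Xperm = Xb[oob].copy()
                Xperm[:, j] = Xperm[rng.permutation(len(oob)), j]
                err = np.mean((tree.predict_proba(Xperm) - yb[oob]) ** 2)
                total[j] += err - base
        else:
            total += imp
    scores = total / config.n_trees

    order = sorted(range(p), key=lambda j: (-scores[j], names[j]))
    table = pd.DataFrame({
        "variable": [names[j] for j in order],
        "importance": [scores[j] for j in order],
        "rank": np.arange(1, p + 1),
    })
    return ImportanceRanking(table=table)


def top_k(ranking: ImportanceRanking, k: int = 4) -> list[str]:
    """The k most important variables, in rank order."""
    return ranking.top_k(k)
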