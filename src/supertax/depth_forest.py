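"""Chi-square-split random forests and per-OTU depth-importance ranking.

Each tree is grown without pruning on a random subset of the OTUs in one
taxonomic block.  At every node the (OTU, threshold) pair maximising the
Pearson chi-square statistic of (abundance > threshold) x disease label
is chosen.  The depth importance of OTU j in tree T is

    V_T(j) = sum over nodes t split by j of 2^(-L_t) * G_t,

with L_t the node depth (root = 1) and G_t the chi-square statistic of
the chosen split, and the forest score is the average of V_T over trees.
Deep in the tree a split acts on few samples, hence the geometric
down-weighting; a root split with statistic G contributes G/2.

Within a block, OTUs are ranked by descending forest score; this ranking
drives super-taxon aggregation (see :mod:`supertax.supertaxon`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from supertax._tree_kernel import (grow_tree_arrays, forest_importance_kernel,
                                   accumulate_depth_importance)

__all__ = [
    "ForestParams", "TreeNode", "ImportanceScores", "ImportanceRanking",
    "chi_square_stat", "grow_tree", "tree_depth_importance",
    "forest_importance", "rank_otus",
]

_UNLIMITED_DEPTH = 2**31


@dataclass(frozen=True)
class ForestParams:
    """Forest configuration.

    otus_per_tree
        Number of OTUs sampled (without replacement) per tree; ``None``
        resolves to ceil(J/2) for a block of J OTUs, a float in (0, 1)
        to that fraction of J.
    min_node_size
        Nodes with fewer samples are leaves.
    max_depth
        ``None`` = unlimited.
    binarize
        Pre-threshold abundances at zero (presence/absence) before tree
        growth.
    bootstrap
        Resample rows with replacement per tree (off by default: only
        feature subsetting is part of the core procedure).
    """

    n_trees: int = 100
    otus_per_tree: Optional[float] = None
    min_node_size: int = 10
    max_depth: Optional[int] = None
    seed: int = 0
    binarize: bool = False
    bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_size < 2:
            raise ValueError("min_node_size must be >= 2")

    def resolve_subset_size(self, n_otus: int) -> int:
        if self.otus_per_tree is None:
            m = math.ceil(n_otus / 2)
        elif isinstance(self.otus_per_tree, float) and 0 < self.otus_per_tree <= 1:
            m = math.ceil(self.otus_per_tree * n_otus)
        else:
            m = int(self.otus_per_tree)
        if m < 1:
            raise ValueError("otus_per_tree resolves to < 1")
        return min(m, n_otus)


@dataclass
class TreeNode:
    """One node of a grown tree; leaves have ``split_otu is None``."""

    depth: int
    node_samples: int
    split_otu: Optional[int] = None
    split_threshold: Optional[float] = None
    chi_square: float = 0.0
    children: Optional[tuple["TreeNode", "TreeNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.split_otu is None

    def walk(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            if node.children is not None:
                stack.extend(node.children)


@dataclass
class ImportanceScores:
    """Per-OTU forest depth-importance scores for one block."""

    block_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be a vector")
        if np.any(self.scores < 0):
            raise ValueError("depth-importance scores are non-negative")


@dataclass
class ImportanceRanking:
    """Descending-importance order of the OTUs in one block.

    ``order[j]`` is the 0-based block-column position of the OTU with
    the (j+1)-th largest score; score ties break by ascending position.
    """

    block_id: str
    order: np.ndarray
    scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if sorted(self.order.tolist()) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of 0..J-1")

    def ranks_one_based(self) -> np.ndarray:
        """The ordering as 1-based OTU positions (field convention)."""
        return self.order + 1

    def to_frame(self, otu_ids: Optional[list[str]] = None) -> pd.DataFrame:
        ids = otu_ids if otu_ids is not None else [str(i) for i in self.order]
        rows = []
        for rank0, pos in enumerate(self.order):
            rows.append({
                "block_id": self.block_id,
                "otu_id": ids[pos],
                "score": float(self.scores[pos]) if self.scores is not None else np.nan,
                "rank": rank0 + 1,
            })
        return pd.DataFrame(rows)


def chi_square_stat(left_case: float, left_ctrl: float,
                    right_case: float, right_ctrl: float) -> float:
    """Pearson chi-square of a 2x2 table, without continuity correction.

    Returns 0 when any margin is zero (a degenerate split carries no
    information).
    """
    cells = (left_case, left_ctrl, right_case, right_ctrl)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    a, b, c, d = map(float, cells)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    n = r1 + r2
    diff = a * d - b * c
    return n * diff * diff / (r1 * r2 * c1 * c2)


def _prepare(features: np.ndarray, labels: np.ndarray,
             params: ForestParams) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(np.asarray(features, dtype=np.float64))
    if X.ndim != 2:
        raise ValueError("features must be a 2-d matrix")
    y = np.asarray(labels)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must align with feature rows")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if params.binarize:
        X = (X > 0).astype(np.float64)
    return X, y.astype(np.int8)


def _build_tree_node(arrays) -> TreeNode:
    feat, thr, chi, depth, n_node, left, right = arrays
    nodes = [TreeNode(depth=int(depth[t]), node_samples=int(n_node[t]))
             for t in range(len(feat))]
    for t in range(len(feat)):
        if feat[t] >= 0:
            nodes[t].split_otu = int(feat[t])
            nodes[t].split_threshold = float(thr[t])
            nodes[t].chi_square = float(chi[t])
            nodes[t].children = (nodes[int(left[t])], nodes[int(right[t])])
    return nodes[0]


def grow_tree(features: np.ndarray, labels: np.ndarray, params: ForestParams,
              rng: Optional[np.random.Generator] = None) -> TreeNode:
    """Grow a single unpruned chi-square tree on one block.

    The tree's OTU subset is drawn from ``rng`` (all OTUs when the
    resolved subset size equals the block size).  Split indices refer to
    columns of ``features``.
    """
    X, y = _prepare(features, labels, params)
    n, p = X.shape
    if p == 0:
        raise ValueError("empty feature subset")
    if y.sum() in (0, n):
        raise ValueError("labels must contain both classes at the root")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m = params.resolve_subset_size(p)
    subset = np.sort(rng.choice(p, size=m, replace=False)).astype(np.int64)
    rows = np.arange(n)
    if params.bootstrap:
        rows = rng.integers(0, n, size=n)
    max_depth = params.max_depth if params.max_depth is not None else _UNLIMITED_DEPTH
    arrays = grow_tree_arrays(X[rows], y[rows], subset,
                              params.min_node_size, max_depth)
    return _build_tree_node(arrays)


def tree_depth_importance(tree: TreeNode, otu: int) -> float:
    """Sum of 2^(-depth) * chi-square over nodes split by ``otu``."""
    total = 0.0
    for node in tree.walk():
        if node.split_otu == otu:
            total += 2.0 ** (-node.depth) * node.chi_square
    return total


def forest_importance(features: np.ndarray, labels: np.ndarray,
                      params: ForestParams,
                      block_id: str = "") -> ImportanceScores:
    """Average depth importance over ``params.n_trees`` trees.

    Deterministic given ``params.seed``: feature subsets (and bootstrap
    rows, if enabled) are drawn from a single seeded generator in tree
    order.
    """
    X, y = _prepare(features, labels, params)
    n, p = X.shape
    if p == 0:
        raise ValueError("empty feature subset")
    if y.sum() in (0, n):
        raise ValueError("labels must contain both classes")
    rng = np.random.default_rng(params.seed)
    m = params.resolve_subset_size(p)
    max_depth = params.max_depth if params.max_depth is not None else _UNLIMITED_DEPTH
    if not params.bootstrap:
        subsets = np.empty((params.n_trees, m), dtype=np.int64)
        for t in range(params.n_trees):
            subsets[t] = np.sort(rng.choice(p, size=m, replace=False))
        ids_sorted = np.ascontiguousarray(
            np.argsort(X, axis=0, kind="stable").T).astype(np.int64)
        vals_sorted = np.ascontiguousarray(
            np.take_along_axis(X, np.argsort(X, axis=0, kind="stable"),
                               axis=0).T)
        scores = forest_importance_kernel(vals_sorted, ids_sorted, y, subsets,
                                          params.min_node_size, max_depth)
    else:
        scores = np.zeros(p)
        for _ in range(params.n_trees):
            subset = np.sort(rng.choice(p, size=m, replace=False)).astype(np.int64)
            rows = rng.integers(0, n, size=n)
            Xb, yb = np.ascontiguousarray(X[rows]), y[rows]
            if yb.sum() in (0, n):
                continue    # degenerate bootstrap draw contributes nothing
            feat, thr, chi, depth, n_node, left, right = grow_tree_arrays(
                Xb, yb, subset, params.min_node_size, max_depth)
            accumulate_depth_importance(feat, chi, depth, scores)
    scores /= params.n_trees
    return ImportanceScores(block_id=block_id, scores=scores)


def rank_otus(scores: ImportanceScores) -> ImportanceRanking:
    """Order block OTUs by descending score, ties by ascending position."""
    s = scores.scores
    order = np.lexsort((np.arange(len(s)), -s))
    return ImportanceRanking(block_id=scores.block_id, order=order, scores=s)
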