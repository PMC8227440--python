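"""Classification trees by recursive partitioning with cost-complexity pruning.

This is a from-scratch binary CART for the two-class RR/SP problem:

* growth — greedy search over axis-aligned splits maximising the decrease in
  Gini impurity, with candidate thresholds at midpoints between consecutive
  distinct feature values; growth stops at pure nodes, below
  ``min_node_size``, or when no split yields a positive improvement;
* pruning — weakest-link cost-complexity pruning, with the per-split
  improvement scaled by the root impurity so a complexity parameter (cp) of
  0.0001 means "keep a split only if it recovers more than 0.01% of the
  total impurity per leaf it adds";
* cp selection — stratified k-fold cross-validation over the pruning
  sequence of the tree grown on the full data, picking the cp with the
  smallest mean misclassification error (ties go to the larger cp, i.e.
  the simpler tree).

Trees are deterministic: ties between equally good splits are broken toward
the smaller threshold, then the earlier feature in ``feature_names``.
Records with missing features are rejected rather than handled by surrogate
splits.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CohortError

DEFAULT_FEATURES = ("edss", "age")


class FitError(CohortError):
    pass


@dataclass
class FitConfig:
    complexity_parameter: float = 0.0001
    cv_folds: int = 10
    min_node_size: int = 20
    impurity: str = "gini"
    rng_seed: int = 0

    def __post_init__(self):
        if self.complexity_parameter < 0:
            raise FitError("complexity_parameter must be >= 0")
        if self.cv_folds < 2:
            raise FitError("cv_folds must be >= 2")
        if self.impurity != "gini":
            raise FitError("only gini impurity is supported")


def gini_impurity(n_sp: int, n_rr: int) -> float:
    """Gini impurity ``1 - p^2 - (1-p)^2`` of a two-class node."""
    n = n_sp + n_rr
    if n < 1:
        raise FitError("empty node has no impurity")
    p = n_sp / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


@dataclass
class TreeNode:
    n: int
    n_sp: int
    split_variable: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    #: count-scale impurity decrease of this node's split (n * delta-Gini)
    improvement: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def sp_fraction(self) -> float:
        return self.n_sp / self.n

    @property
    def label(self) -> str:
        return "SP" if self.sp_fraction > 0.5 else "RR"

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict:
        d = {"n": self.n, "n_sp": self.n_sp, "sp_fraction": self.sp_fraction, "label": self.label}
        if not self.is_leaf:
            d.update(
                split_variable=self.split_variable,
                split_threshold=self.split_threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n=d["n"], n_sp=d["n_sp"])
        if "split_variable" in d:
            node.split_variable = d["split_variable"]
            node.split_threshold = d["split_threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def save_tree(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1)


def load_tree(path) -> TreeNode:
    with open(path) as fh:
        return TreeNode.from_dict(json.load(fh))


def _as_matrix(features, feature_names) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[list(feature_names)].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _best_split(X: np.ndarray, y: np.ndarray, feature_names) -> tuple[int, float, float] | None:
    """Best (feature index, threshold, count-scale improvement) or None.

    Improvement is ``n*G(node) - n_l*G(l) - n_r*G(r)`` with unnormalised
    Gini counts; ties break toward the smaller threshold then earlier
    feature.
    """
    n = len(y)
    n_sp = int(y.sum())
    parent = n * gini_impurity(n_sp, n - n_sp)
    best = None
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # candidate cut positions: between consecutive distinct values
        cut = np.nonzero(np.diff(xs) > 0)[0]
        if cut.size == 0:
            continue
        left_n = cut + 1
        left_sp = np.cumsum(ys)[cut]
        right_n = n - left_n
        right_sp = n_sp - left_sp
        pl = left_sp / left_n
        pr = right_sp / right_n
        child = left_n * 2 * pl * (1 - pl) + right_n * 2 * pr * (1 - pr)
        gains = parent - child
        k = int(np.argmax(gains))  # first (smallest threshold) among ties
        gain = float(gains[k])
        if gain <= 1e-12:
            continue
        thr = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
        if best is None or gain > best[2] + 1e-12:
            best = (j, float(thr), gain)
    return best


def grow_tree(features, labels, config: FitConfig | None = None,
              feature_names=DEFAULT_FEATURES) -> TreeNode:
    """Grow a full tree (no cp applied during growth; prune afterwards).

    *labels* may be "RR"/"SP" strings or 0/1 integers (1 = SP).
    """
    config = config or FitConfig()
    X = _as_matrix(features, feature_names)
    y = _encode_labels(labels)
    if len(y) < 1 or len(y) != len(X):
        raise FitError("features and labels must be non-empty and aligned")
    if np.isnan(X).any():
        raise FitError("missing feature values are not supported (no surrogate splits)")

    def build(idx: np.ndarray) -> TreeNode:
        yy = y[idx]
        node = TreeNode(n=len(idx), n_sp=int(yy.sum()))
        if node.n < config.min_node_size or node.n_sp in (0, node.n):
            return node
        found = _best_split(X[idx], yy, feature_names)
        if found is None:
            return node
        j, thr, gain = found
        node.split_variable = feature_names[j]
        node.split_threshold = thr
        node.improvement = gain
        mask = X[idx, j] < thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return build(np.arange(len(y)))


def _encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "SP").astype(np.int64)
    return arr.astype(np.int64)


def predict(tree: TreeNode, features, feature_names=DEFAULT_FEATURES,
            return_probability: bool = False) -> np.ndarray:
    X = _as_matrix(features, feature_names)
    name_to_idx = {nm: i for i, nm in enumerate(feature_names)}
    out = np.empty(len(X), dtype=float)

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.sp_fraction
            return
        mask = X[idx, name_to_idx[node.split_variable]] < node.split_threshold
        walk(node.left, idx[mask])
        walk(node.right, idx[~mask])

    walk(tree, np.arange(len(X)))
    if return_probability:
        return out
    return np.where(out > 0.5, "SP", "RR")


# ---------------------------------------------------------------------------
# Cost-complexity pruning

def _weakest_link(root: TreeNode, root_risk: float) -> tuple[float, TreeNode] | None:
    """Internal node with minimal per-leaf scaled improvement g(t).

    Single post-order pass; each recursion returns (subtree leaf risk,
    n_leaves, best candidate) so pruning a tree of m nodes is O(m) per
    collapse. On ties the shallowest (first-visited) node wins.
    """

    def walk(node: TreeNode):
        own_risk = node.n * gini_impurity(node.n_sp, node.n - node.n_sp)
        if node.is_leaf:
            return own_risk, 1, None
        rl, ll, bl = walk(node.left)
        rr, lr, br = walk(node.right)
        sub_risk, leaves = rl + rr, ll + lr
        g = (own_risk - sub_risk) / (leaves - 1) / root_risk
        best = (g, node)
        for cand in (bl, br):
            if cand is not None and cand[0] < best[0] - 1e-15:
                best = cand
        return sub_risk, leaves, best

    return walk(root)[2]


def _collapse(node: TreeNode) -> None:
    node.split_variable = None
    node.split_threshold = None
    node.left = None
    node.right = None
    node.improvement = 0.0


def cost_complexity_prune(tree: TreeNode, cp: float) -> TreeNode:
    """Weakest-link pruning: retain a split only if its scaled per-leaf
    improvement strictly exceeds *cp*.

    Improvements are scaled by the root's total impurity, matching the
    convention under which the final published model used cp = 0.0001.
    The input tree is not modified; pruned subtrees are nested across cp.
    """
    pruned = copy.deepcopy(tree)
    root_risk = pruned.n * gini_impurity(pruned.n_sp, pruned.n - pruned.n_sp)
    return _prune_in_place(pruned, cp, root_risk)


def pruning_path(tree: TreeNode) -> list[tuple[float, int]]:
    """Sequence of (critical cp, n_leaves) from the full tree to the stump.

    Successive weakest links are collapsed; each critical cp is the g value
    at which the tree first shrinks to the given size.
    """
    work = copy.deepcopy(tree)
    root_risk = work.n * gini_impurity(work.n_sp, work.n - work.n_sp)
    path = [(0.0, work.n_leaves())]
    if root_risk <= 0:
        return path
    while not work.is_leaf:
        g, node = _weakest_link(work, root_risk)
        _collapse(node)
        path.append((max(g, path[-1][0]), work.n_leaves()))
    return path


def select_cp_by_cv(features, labels, config: FitConfig | None = None,
                    feature_names=DEFAULT_FEATURES) -> tuple[float, pd.DataFrame]:
    """Choose cp by stratified k-fold CV over the full tree's pruning path.

    Candidate cp values are geometric means of consecutive critical cps
    (plus the endpoints), so each candidate indexes one distinct subtree of
    the full-data tree. Returns the cp of minimal mean misclassification
    error, with ties broken toward the larger cp, and the CV error table.
    """
    config = config or FitConfig()
    X = _as_matrix(features, feature_names)
    y = _encode_labels(labels)
    n = len(y)
    if config.cv_folds > n:
        raise FitError("more folds than records")

    full = grow_tree(X, y, config, feature_names)
    alphas = sorted({a for a, _ in pruning_path(full)})
    candidates = [0.0]
    for a, b in zip(alphas, alphas[1:]):
        candidates.append(float(np.sqrt(max(a, 1e-300) * b)) if a > 0 else b / 2)
    candidates.append(alphas[-1] * 2 + 1e-12)
    candidates = sorted(set(candidates))

    rng = np.random.default_rng(config.rng_seed)
    folds = _stratified_folds(y, config.cv_folds, rng)

    errors = np.zeros((len(folds), len(candidates)))
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        work = grow_tree(X[train_mask], y[train_mask], config, feature_names)
        # candidates are ascending and pruned subtrees are nested, so the
        # fold tree is pruned incrementally instead of from scratch per cp
        root_risk = work.n * gini_impurity(work.n_sp, work.n - work.n_sp)
        for ci, cp in enumerate(candidates):
            work = _prune_in_place(work, cp, root_risk)
            pred = predict(work, X[test_idx], feature_names)
            errors[fi, ci] = float(np.mean((pred == "SP") != (y[test_idx] == 1)))
    mean_err = errors.mean(axis=0)
    best_err = mean_err.min()
    # ties (within float fuzz) broken toward the larger cp → simpler tree
    best_ci = max(i for i, e in enumerate(mean_err) if e <= best_err + 1e-12)
    work = copy.deepcopy(full)
    full_risk = work.n * gini_impurity(work.n_sp, work.n - work.n_sp)
    n_leaves = []
    for cp in candidates:
        work = _prune_in_place(work, cp, full_risk)
        n_leaves.append(work.n_leaves())
    table = pd.DataFrame(
        {
            "cp": candidates,
            "mean_cv_error": mean_err,
            "se_cv_error": errors.std(axis=0, ddof=1) / np.sqrt(len(folds)),
            "n_leaves": n_leaves,
        }
    )
    return float(candidates[best_ci]), table


def _prune_in_place(tree: TreeNode, cp: float, root_risk: float) -> TreeNode:
    if root_risk <= 0:
        _collapse(tree)
        return tree
    while not tree.is_leaf:
        g, node = _weakest_link(tree, root_risk)
        if g > cp:
            break
        _collapse(node)
    return tree


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold assignment; errors if a class cannot reach
    every fold at least... strata are interleaved so folds stay balanced."""
    assign = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % k
    return [np.nonzero(assign == f)[0] for f in range(k)]


def fit(features, labels, config: FitConfig | None = None,
        feature_names=DEFAULT_FEATURES, cp: float | str = "auto") -> tuple[TreeNode, pd.DataFrame | None]:
    """Grow, select cp (or take a fixed one), and prune.

    ``cp="auto"`` runs :func:`select_cp_by_cv`; a float prunes at that
    value directly (the published model used 0.0001).
    """
    config = config or FitConfig()
    table = None
    if cp == "auto":
        cp_value, table = select_cp_by_cv(features, labels, config, feature_names)
    else:
        cp_value = float(cp)
    full = grow_tree(features, labels, config, feature_names)
    return cost_complexity_prune(full, cp_value), table


def variable_importance(tree: TreeNode, feature_names=DEFAULT_FEATURES) -> dict[str, float]:
    """Per-variable sums of impurity improvement, normalised to sum to 1.

    A stump yields an all-zero report.
    """
    raw = {nm: 0.0 for nm in feature_names}

    def walk(node: TreeNode):
        if node.is_leaf:
            return
        raw[node.split_variable] = raw.get(node.split_variable, 0.0) + node.improvement
        walk(node.left)
        walk(node.right)

    walk(tree)
    total = sum(raw.values())
    if total <= 0:
        return {nm: 0.0 for nm in raw}
    return {nm: v / total for nm, v in raw.items()}
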