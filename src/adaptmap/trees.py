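"""Bootstrapped pruned regression trees as a main-effect/interaction selector.

A least-squares binary tree is grown (depth cap, minimum leaf size) and then
cost-complexity pruned, with the penalty chosen by internal K-fold
cross-validation and the 1-SE rule — the classic CART default.  Candidate
model terms are read off root-to-leaf paths of the pruned tree: every
splitting feature is a main effect, features at adjacent internal
(parent, child) nodes form 2-way terms, and (grandparent, parent, child)
internal runs form 3-way terms.  Repeating the fit on bootstrap resamples of
subjects and thresholding term occurrence counts yields a stable candidate
set despite the variance of single trees.

Weakest-link pruning is implemented directly on the grown sklearn tree so
that every pruned subtree along the penalty path can be evaluated on held-out
data without regrowing; sklearn's ``cost_complexity_pruning_path`` recovers
the same penalty sequence and is used as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .terms import ModelTermSet, OccurrenceTable, TermKey

__all__ = [
    "TreeNode",
    "PrunedTree",
    "fit_pruned_tree",
    "enumerate_terms",
    "bootstrap_term_occurrences",
    "threshold_terms",
]

_MAX_ALPHA_CANDIDATES = 24


# ---------------------------------------------------------------------------
# feature encoding

def _target_mean_codes(col: pd.Series, y: np.ndarray) -> dict[object, float]:
    means = pd.Series(y, index=col.index).groupby(col.astype("object")).mean()
    return means.to_dict()


def _encode_matrix(
    X, y: np.ndarray | None = None, maps: dict[str, dict] | None = None
) -> tuple[np.ndarray, list[str], dict[str, dict]]:
    """Numeric matrix for tree fitting.

    Categorical (non-numeric) columns are ordinal-coded by the mean response
    of each level, which makes the best binary split on the coded column
    coincide with CART's optimal subset split for a least-squares criterion.
    The learned level->code maps are reused when predicting on new data
    (unseen levels fall back to the overall mean code).
    """
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    names = list(X.columns)
    out = np.empty((len(X), len(names)), dtype=float)
    new_maps: dict[str, dict] = {}
    for j, c in enumerate(names):
        col = X[c]
        if col.dtype.kind in "fiub":
            out[:, j] = col.to_numpy(dtype=float)
        else:
            if maps is not None and c in maps:
                codes = maps[c]
            elif y is not None:
                codes = _target_mean_codes(col, np.asarray(y, dtype=float))
            else:
                codes = {lev: k for k, lev in enumerate(sorted(col.dropna().unique()))}
            new_maps[c] = codes
            default = float(np.mean(list(codes.values()))) if codes else 0.0
            out[:, j] = col.map(codes).astype(float).fillna(default).to_numpy()
    return out, names, (maps if maps is not None else new_maps)


# ---------------------------------------------------------------------------
# weakest-link pruning machinery


def _weakest_link_alphas(tree) -> np.ndarray:
    """Penalty at which each internal node collapses into a leaf.

    Returns per-node alpha values (``inf`` for original leaves).  Collapse
    alphas are non-increasing along any root-to-leaf path, so the subtree
    retained at penalty ``a`` is exactly the nodes with collapse alpha > a.
    Risk is normalized by total sample weight, matching sklearn's
    ``ccp_alphas`` convention.
    """
    n = tree.node_count
    left, right = tree.children_left, tree.children_right
    is_leaf = left == -1
    w = tree.weighted_n_node_samples
    r = tree.impurity * w / w[0]

    collapse = np.full(n, np.inf)
    alive = ~is_leaf
    last_alpha = 0.0
    while alive.any() and alive[0]:
        sub_r = r.copy()
        n_lv = np.ones(n)
        # children have larger ids (preorder), so one reverse pass suffices
        for i in range(n - 1, -1, -1):
            if alive[i]:
                sub_r[i] = sub_r[left[i]] + sub_r[right[i]]
                n_lv[i] = n_lv[left[i]] + n_lv[right[i]]
        with np.errstate(invalid="ignore"):
            g = np.where(alive & (n_lv > 1), (r - sub_r) / np.maximum(n_lv - 1, 1), np.inf)
        alpha = max(float(g.min()), last_alpha)
        last_alpha = alpha
        for i in np.flatnonzero(g <= alpha + 1e-15):
            if not alive[i]:
                continue
            stack = [i]
            while stack:
                j = stack.pop()
                if j == -1 or is_leaf[j]:
                    continue
                if alive[j]:
                    alive[j] = False
                    collapse[j] = alpha
                    stack.append(left[j])
                    stack.append(right[j])
    return collapse


def _path_predict(tree, collapse: np.ndarray, X_enc: np.ndarray, alphas) -> np.ndarray:
    """Predictions of the pruned subtree at each penalty in ``alphas``.

    For a sample, the effective leaf at penalty ``a`` is the shallowest node
    on its decision path whose collapse alpha is <= a (node ids are preorder,
    so the shallowest such node has the smallest id), falling back to the
    sample's original leaf.  Returns an array of shape (len(alphas), n).
    """
    P = tree.decision_path(np.ascontiguousarray(X_enc, dtype=np.float32))
    ids = P.indices
    starts = P.indptr[:-1]
    last = ids[P.indptr[1:] - 1]
    values = tree.value[:, 0, 0]
    big = tree.node_count

    out = np.empty((len(alphas), X_enc.shape[0]))
    for k, a in enumerate(alphas):
        collapsed = collapse <= a
        data = np.where(collapsed[ids], ids, big)
        first = np.minimum.reduceat(data, starts)
        node = np.where(first < big, first, last)
        out[k] = values[node]
    return out


def _candidate_alphas(collapse: np.ndarray) -> np.ndarray:
    finite = np.unique(collapse[np.isfinite(collapse)])
    finite = finite[finite > 0]
    if finite.size == 0:
        return np.array([0.0])
    cands = [0.0]
    if finite.size > 1:
        cands.extend(np.sqrt(finite[:-1] * finite[1:]))
    cands.append(finite[-1] * 1.0000001)  # collapses the root: intercept model
    cands = np.asarray(cands)
    if cands.size > _MAX_ALPHA_CANDIDATES:
        pick = np.linspace(0, cands.size - 1, _MAX_ALPHA_CANDIDATES).round().astype(int)
        cands = cands[np.unique(pick)]
    return cands


# ---------------------------------------------------------------------------
# public tree objects


@dataclass
class TreeNode:
    """Plain binary-tree node; ``feature`` is None at leaves."""

    feature: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class PrunedTree:
    """A grown sklearn regression tree plus its chosen pruning penalty."""

    def __init__(self, sk_tree, alpha: float, collapse: np.ndarray,
                 feature_names: list[str], cat_maps: dict[str, dict],
                 cv_curve: pd.DataFrame | None = None):
        self._sk = sk_tree
        self.alpha = float(alpha)
        self.collapse = collapse
        self.feature_names = feature_names
        self.cat_maps = cat_maps
        self.cv_curve = cv_curve

    def _encode(self, X) -> np.ndarray:
        enc, names, _ = _encode_matrix(X, maps=self.cat_maps)
        if names != self.feature_names:
            raise ValueError("feature columns do not match the fitted tree")
        return enc

    def predict(self, X) -> np.ndarray:
        return _path_predict(self._sk.tree_, self.collapse, self._encode(X),
                             [self.alpha])[0]

    def _kept(self) -> np.ndarray:
        t = self._sk.tree_
        return (t.children_left != -1) & (self.collapse > self.alpha)

    @property
    def n_internal(self) -> int:
        return int(self._kept().sum())

    def to_nodes(self) -> TreeNode:
        """Materialize the pruned subtree as plain TreeNodes."""
        t = self._sk.tree_
        kept = self._kept()
        values = t.value[:, 0, 0]

        def build(i: int) -> TreeNode:
            if not kept[i]:
                return TreeNode(value=float(values[i]))
            return TreeNode(
                feature=self.feature_names[t.feature[i]],
                left=build(t.children_left[i]),
                right=build(t.children_right[i]),
                value=float(values[i]),
            )

        return build(0)


def _choose_alpha_one_se(cands: np.ndarray, mean: np.ndarray, se: np.ndarray,
                         one_se: bool) -> float:
    i_min = int(np.argmin(mean))
    if not one_se:
        return float(cands[i_min])
    thr = mean[i_min] + se[i_min]
    return float(cands[np.flatnonzero(mean <= thr).max()])


def _fit_pruned_encoded(
    X_enc: np.ndarray,
    y: np.ndarray,
    names: list[str],
    maps: dict[str, dict],
    *,
    min_leaf: int,
    max_depth: int,
    inner_cv: int,
    one_se: bool,
    rng: np.random.Generator,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> PrunedTree:
    def grow(Xe, yy):
        est = DecisionTreeRegressor(
            min_samples_leaf=min_leaf,
            max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        est.fit(Xe, yy)
        return est

    full = grow(X_enc, y)
    collapse = _weakest_link_alphas(full.tree_)
    cands = _candidate_alphas(collapse)
    if cands.size == 1 or full.tree_.node_count == 1:
        return PrunedTree(full, 0.0, collapse, names, maps)

    if validation is not None:
        X_val, y_val = validation
        preds = _path_predict(full.tree_, collapse, X_val, cands)
        sq = (preds - y_val) ** 2
        mean = sq.mean(axis=1)
        se = sq.std(axis=1, ddof=1) / np.sqrt(sq.shape[1])
        alpha = _choose_alpha_one_se(cands, mean, se, one_se)
        curve = pd.DataFrame({"alpha": cands, "cv_mse": mean})
        return PrunedTree(full, alpha, collapse, names, maps, cv_curve=curve)

    k = min(inner_cv, len(y) // (2 * min_leaf))
    if k < 2:
        return PrunedTree(full, 0.0, collapse, names, maps)
    folds = KFold(n_splits=k, shuffle=True,
                  random_state=int(rng.integers(2**31 - 1)))
    errs = np.empty((k, cands.size))
    for f, (tr, va) in enumerate(folds.split(X_enc)):
        sub = grow(X_enc[tr], y[tr])
        sub_collapse = _weakest_link_alphas(sub.tree_)
        preds = _path_predict(sub.tree_, sub_collapse, X_enc[va], cands)
        errs[f] = np.mean((preds - y[va]) ** 2, axis=1)

    mean = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(k)
    alpha = _choose_alpha_one_se(cands, mean, se, one_se)
    curve = pd.DataFrame({"alpha": cands, "cv_mse": mean, "se": se})
    return PrunedTree(full, alpha, collapse, names, maps, cv_curve=curve)


def fit_pruned_tree(
    X,
    y,
    *,
    min_leaf: int = 20,
    max_depth: int = 10,
    inner_cv: int = 10,
    one_se: bool = True,
    seed: int | None = None,
) -> PrunedTree:
    """Grow a least-squares tree and prune by CV cost-complexity.

    The penalty grid is taken from the weakest-link sequence of the full
    tree; each internal CV fold grows its own tree and scores every candidate
    penalty on the held-out part.  With ``one_se`` the largest penalty within
    one standard error of the CV minimum is chosen, otherwise the minimizer.
    A constant response yields a root-only tree.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * min_leaf:
        raise ValueError("need at least 2*min_leaf samples")
    X_enc, names, maps = _encode_matrix(X, y=y)
    rng = np.random.default_rng(seed)
    return _fit_pruned_encoded(
        X_enc, y, names, maps, min_leaf=min_leaf, max_depth=max_depth,
        inner_cv=inner_cv, one_se=one_se, rng=rng,
    )


# ---------------------------------------------------------------------------
# term extraction


def enumerate_terms(tree: PrunedTree | TreeNode) -> set[TermKey]:
    """Terms from root-to-leaf paths of a pruned tree.

    Mains: every splitting feature.  2-way: features of adjacent internal
    (parent, child) nodes.  3-way: features of internal
    (grandparent, parent, child) runs.  A pair or triple containing a
    repeated feature is not a distinct term (a self-interaction is just a
    main effect) and is skipped.  Duplicates across paths collapse.
    """
    root = tree.to_nodes() if isinstance(tree, PrunedTree) else tree
    out: set[TermKey] = set()

    def walk(node: TreeNode, path: tuple[str, ...]) -> None:
        if node.is_leaf:
            return
        path = path + (node.feature,)
        out.add(TermKey((node.feature,)))
        if len(path) >= 2 and path[-2] != path[-1]:
            out.add(TermKey(path[-2:]))
        if len(path) >= 3 and len(set(path[-3:])) == 3:
            out.add(TermKey(path[-3:]))
        walk(node.left, path)
        walk(node.right, path)

    walk(root, ())
    return out


def bootstrap_term_occurrences(
    X,
    y,
    B: int = 300,
    seed: int | None = None,
    **tree_params,
) -> OccurrenceTable:
    """Fit one pruned tree per bootstrap resample of subjects; tally terms.

    Subjects are resampled with replacement ``B`` times (default 300); each
    resample gets an independently seeded tree fit, and the incidence of each
    extracted term is recorded once per tree.  Within the bootstrap, the
    cost-complexity penalty of each tree is chosen by the 1-SE rule on the
    subjects left out of that resample (about 37% of the sample), which
    validates the pruning honestly without regrowing trees; categorical
    encodings are computed once on the full table.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    params = dict(min_leaf=20, max_depth=10, inner_cv=10, one_se=True)
    params.update(tree_params)
    n = len(X)
    X_enc, names, maps = _encode_matrix(X, y=y)
    X_enc = np.ascontiguousarray(X_enc, dtype=np.float32)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    term_sets: list[set[TermKey]] = []
    for b in range(B):
        rng = np.random.default_rng(children[b])
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        validation = (X_enc[oob], y[oob]) if oob.size >= 20 else None
        tree = _fit_pruned_encoded(
            X_enc[idx], y[idx], names, maps, rng=rng, validation=validation,
            **params,
        )
        term_sets.append(enumerate_terms(tree))
    return OccurrenceTable.from_term_sets(term_sets)


def threshold_terms(occ: OccurrenceTable, cutoff_fraction: float) -> ModelTermSet:
    """Keep terms occurring in strictly more than cutoff_fraction * B trees.

    The survivors are closed under marginality: component main effects of any
    kept interaction are added even when below the cutoff.
    """
    if not 0.0 < cutoff_fraction < 1.0:
        raise ValueError("cutoff_fraction must lie in (0, 1)")
    bar = cutoff_fraction * occ.B
    kept = [t for t, c in zip(occ.terms, occ.counts) if c > bar]
    return ModelTermSet.from_terms(kept).close_marginality()
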