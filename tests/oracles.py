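"""Independent brute-force reference implementations used only by tests.

These deliberately take the most literal route (explicit path enumeration,
naive O(n^3) agglomeration, exhaustive prefix search) so that agreement with
the package implementations is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from adaptmap import TermKey, TreeNode


def random_tree(rng: np.random.Generator, features: list[str], max_depth: int = 5,
                p_leaf: float = 0.35) -> TreeNode:
    """A random binary tree with random split features."""
    if max_depth == 0 or rng.random() < p_leaf:
        return TreeNode(value=float(rng.normal()))
    return TreeNode(
        feature=str(rng.choice(features)),
        left=random_tree(rng, features, max_depth - 1, p_leaf),
        right=random_tree(rng, features, max_depth - 1, p_leaf),
    )


def all_root_to_leaf_paths(node: TreeNode) -> list[list[str]]:
    """Explicit list of internal-node feature sequences, one per leaf."""
    if node.is_leaf:
        return [[]]
    return [
        [node.feature] + rest
        for child in (node.left, node.right)
        for rest in all_root_to_leaf_paths(child)
    ]


def brute_force_terms(node: TreeNode) -> set[TermKey]:
    """Terms via exhaustive path enumeration (mains, adjacent pairs, runs of 3)."""
    out: set[TermKey] = set()
    for path in all_root_to_leaf_paths(node):
        for f in path:
            out.add(TermKey((f,)))
        for a, b in zip(path, path[1:]):
            if a != b:
                out.add(TermKey((a, b)))
        for a, b, c in zip(path, path[1:], path[2:]):
            if len({a, b, c}) == 3:
                out.add(TermKey((a, b, c)))
    return out


def brute_force_average_linkage(d: np.ndarray, cut: float) -> list[set[int]]:
    """Naive agglomerative average-linkage clustering, merged below ``cut``.

    Average inter-cluster dissimilarity is recomputed from the original
    matrix at every step (unweighted pair-group average, as scipy's
    ``average`` method defines it).
    """
    clusters: list[set[int]] = [{i} for i in range(d.shape[0])]
    while len(clusters) > 1:
        best, pair = None, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            vals = [d[a, b] for a in clusters[i] for b in clusters[j]]
            avg = float(np.mean(vals))
            if best is None or avg < best:
                best, pair = avg, (i, j)
        if best > cut:
            break
        i, j = pair
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def brute_force_stepup(fdr: np.ndarray, q: float) -> int:
    """Largest k over all prefixes of the sorted fdr with mean <= q."""
    s = np.sort(fdr)
    best = 0
    for k in range(1, len(s) + 1):
        if s[:k].mean() <= q:
            best = k
    return best
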