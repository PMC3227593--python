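"""Merging competing features via co-occurrence clustering.

Near-collinear features compete inside a tree: a bootstrap run tends to use
one or the other but rarely both, so competitors show low *simultaneous*
occurrence across the bootstrap trees.  The default dissimilarity between
features i and j is therefore the normalized co-occurrence rate

    d_ij = #ij / min(#i, #j)

where #ij counts trees containing both features and #i, #j trees containing
each one: disjointly occurring features (pure competitors) get d = 0 and are
clustered together, while features that always appear jointly (independently
informative) get d = 1 and stay apart.  Each cluster is then represented by
its minimax centroid — the member whose largest dissimilarity to the other
members is smallest, i.e. the member that most consistently substitutes for
the rest — and the candidate term set is rewritten onto the centroids.

The complementary convention (1 - #ij/min(#i,#j)) is available via
``formula="complement"`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .terms import ModelTermSet, OccurrenceTable, TermKey

__all__ = [
    "DissimilarityMatrix",
    "cooccurrence_dissimilarity",
    "cluster_features",
    "minimax_centroid",
    "centroid_assignment",
    "reduce_term_set",
    "cooccurrence_reduce",
]


@dataclass
class DissimilarityMatrix:
    features: list[str]
    d: np.ndarray              # symmetric, zero diagonal, in [0, 1]
    marginals: np.ndarray      # #i, per-tree occurrence count per feature
    joints: np.ndarray         # #ij, simultaneous occurrence counts

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.features), len(self.features)):
            raise ValueError("dissimilarity matrix shape mismatch")
        if self.d.size and (not np.allclose(self.d, self.d.T)
                            or np.abs(np.diag(self.d)).max() > 1e-12):
            raise ValueError("dissimilarity must be symmetric with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.features)

    def value(self, a: str, b: str) -> float:
        i, j = self.features.index(a), self.features.index(b)
        return float(self.d[i, j])

    def marginal(self, a: str) -> int:
        return int(self.marginals[self.features.index(a)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.features, columns=self.features)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def cooccurrence_dissimilarity(
    occ: OccurrenceTable,
    features: Iterable[str] | None = None,
    formula: str = "cooccurrence",
) -> DissimilarityMatrix:
    """Pairwise feature dissimilarity from main-effect tree incidence.

    Features with zero occurrences are dropped.  With fewer than two
    surviving features the matrix is empty and clustering is skipped
    downstream.
    """
    inc = occ.main_incidence(features)
    counts = inc.sum(axis=0)
    inc = inc.loc[:, counts > 0]
    names = list(inc.columns)
    if len(names) < 2:
        m = np.asarray(inc.sum(axis=0), dtype=float)
        return DissimilarityMatrix(names, np.zeros((len(names), len(names))),
                                   m, np.outer(m, m) * 0)
    mat = inc.to_numpy(dtype=float)
    joint = mat.T @ mat
    marg = np.diag(joint).copy()
    denom = np.minimum.outer(marg, marg)
    rate = joint / denom
    if formula == "cooccurrence":
        d = rate
    elif formula == "complement":
        d = 1.0 - rate
    else:
        raise ValueError(f"unknown dissimilarity formula {formula!r}")
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(names, d, marg.astype(int), joint.astype(int))


def cluster_features(
    D: DissimilarityMatrix, cut_height: float = 0.5, linkage: str = "average"
) -> dict[str, int]:
    """Agglomerative clustering of the dissimilarity, cut at ``cut_height``."""
    if D.n == 0:
        return {}
    if D.n == 1:
        return {D.features[0]: 1}
    Z = hierarchy.linkage(squareform(D.d, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    return {f: int(l) for f, l in zip(D.features, labels)}


def minimax_centroid(D: DissimilarityMatrix, cluster: Iterable[str]) -> str:
    """Member minimizing its maximum dissimilarity to the other members.

    Ties break toward the larger marginal occurrence count, then the
    lexicographically smaller feature name.
    """
    members = sorted(set(cluster))
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    best = None
    for f in members:
        worst = max(D.value(f, g) for g in members if g != f)
        key = (worst, -D.marginal(f), f)
        if best is None or key < best[0]:
            best = (key, f)
    return best[1]


def centroid_assignment(
    D: DissimilarityMatrix, labels: Mapping[str, int]
) -> dict[str, str]:
    """Map each feature to the minimax centroid of its cluster."""
    clusters: dict[int, list[str]] = {}
    for f, l in labels.items():
        clusters.setdefault(l, []).append(f)
    out: dict[str, str] = {}
    for members in clusters.values():
        c = minimax_centroid(D, members)
        for f in members:
            out[f] = c
    return out


def reduce_term_set(
    terms: ModelTermSet, centroid_map: Mapping[str, str]
) -> ModelTermSet:
    """Rewrite a term set onto cluster centroids.

    Main effects are replaced by their centroid; interactions have each
    component mapped, and any interaction whose components collapse onto a
    shared centroid is dropped (it would become a self-interaction).  The
    result is re-closed under marginality.  Features absent from the map
    (e.g. SNPs screened separately) pass through unchanged.
    """
    mains = {centroid_map.get(f, f) for f in terms.mains}
    inters: set[TermKey] = set()
    for t in terms.interactions:
        mapped = tuple(centroid_map.get(f, f) for f in t.features)
        if len(set(mapped)) == len(mapped):
            inters.add(TermKey(mapped))
    return ModelTermSet(mains, inters).close_marginality()


def cooccurrence_reduce(
    occ: OccurrenceTable,
    terms: ModelTermSet,
    cut_height: float = 0.5,
    linkage: str = "average",
    formula: str = "cooccurrence",
) -> tuple[ModelTermSet, DissimilarityMatrix, dict[str, str]]:
    """Full reduction chain: dissimilarity, clustering, centroid remapping.

    Clustering is computed on the main-effect occurrences of the selected
    features only; interaction terms are remapped, not clustered.
    """
    D = cooccurrence_dissimilarity(occ, features=terms.mains, formula=formula)
    if D.n < 2:
        return terms, D, {f: f for f in D.features}
    labels = cluster_features(D, cut_height=cut_height, linkage=linkage)
    cmap = centroid_assignment(D, labels)
    return reduce_term_set(terms, cmap), D, cmap
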