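"""Symbolic model terms: main effects and low-order interactions.

A term is an unordered tuple of one to three distinct feature names.  Order-1
terms are main effects; orders 2 and 3 are interactions discovered from
adjacent splits in regression trees.  SNP identifiers are valid feature names,
so terms may mix clinical features and SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["TermKey", "ModelTermSet", "OccurrenceTable"]


@dataclass(frozen=True, order=True)
class TermKey:
    """An order-insensitive set of 1-3 distinct feature names."""

    features: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = tuple(sorted(str(f) for f in self.features))
        if not 1 <= len(feats) <= 3:
            raise ValueError(f"term order must be 1-3, got {len(feats)}")
        if len(set(feats)) != len(feats):
            raise ValueError(f"repeated feature in term: {feats}")
        object.__setattr__(self, "features", feats)

    @property
    def order(self) -> int:
        return len(self.features)

    def __str__(self) -> str:
        return ":".join(self.features)

    @classmethod
    def parse(cls, text: str) -> "TermKey":
        return cls(tuple(text.split(":")))


@dataclass
class ModelTermSet:
    """Main effects plus interactions, kept closed under marginality.

    Marginality closure: every feature appearing in an interaction must also be
    present as a main effect.  ``close_marginality`` enforces this; selection
    code calls it after every thresholding or remapping step.
    """

    mains: set[str] = field(default_factory=set)
    interactions: set[TermKey] = field(default_factory=set)

    @classmethod
    def from_terms(cls, terms: Iterable[TermKey]) -> "ModelTermSet":
        out = cls()
        for t in terms:
            if t.order == 1:
                out.mains.add(t.features[0])
            else:
                out.interactions.add(t)
        return out

    def terms(self) -> Iterator[TermKey]:
        for m in sorted(self.mains):
            yield TermKey((m,))
        for t in sorted(self.interactions):
            yield t

    def close_marginality(self) -> "ModelTermSet":
        mains = set(self.mains)
        for t in self.interactions:
            mains.update(t.features)
        return ModelTermSet(mains, set(self.interactions))

    def is_closed(self) -> bool:
        return all(f in self.mains for t in self.interactions for f in t.features)

    def features(self) -> set[str]:
        out = set(self.mains)
        for t in self.interactions:
            out.update(t.features)
        return out

    def __len__(self) -> int:
        return len(self.mains) + len(self.interactions)

    def __contains__(self, term: TermKey) -> bool:
        if term.order == 1:
            return term.features[0] in self.mains
        return term in self.interactions


class OccurrenceTable:
    """Per-bootstrap-tree incidence of candidate terms.

    Rows are bootstrap trees, columns are terms; a cell is True when the term
    was extracted from that tree (a term recurring on several paths of one
    tree still counts once).  ``counts`` are column sums, bounded by ``B``.
    """

    def __init__(self, terms: list[TermKey], incidence: np.ndarray):
        incidence = np.asarray(incidence, dtype=bool)
        if incidence.ndim != 2 or incidence.shape[1] != len(terms):
            raise ValueError("incidence must be B x n_terms")
        self.terms = list(terms)
        self.incidence = incidence
        self._index = {t: j for j, t in enumerate(self.terms)}

    @classmethod
    def from_term_sets(cls, term_sets: list[set[TermKey]]) -> "OccurrenceTable":
        all_terms = sorted(set().union(*term_sets)) if term_sets else []
        inc = np.zeros((len(term_sets), len(all_terms)), dtype=bool)
        idx = {t: j for j, t in enumerate(all_terms)}
        for b, ts in enumerate(term_sets):
            for t in ts:
                inc[b, idx[t]] = True
        return cls(all_terms, inc)

    @property
    def B(self) -> int:
        return self.incidence.shape[0]

    @property
    def counts(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    def count(self, term: TermKey) -> int:
        j = self._index.get(term)
        return 0 if j is None else int(self.incidence[:, j].sum())

    def main_incidence(self, features: Iterable[str] | None = None) -> pd.DataFrame:
        """B x n_features boolean frame of main-effect occurrences."""
        mains = [t for t in self.terms if t.order == 1]
        if features is not None:
            want = set(features)
            mains = [t for t in mains if t.features[0] in want]
        cols = {t.features[0]: self.incidence[:, self._index[t]] for t in mains}
        return pd.DataFrame(cols, index=range(self.B))

    def to_frame(self) -> pd.DataFrame:
        counts = self.counts
        return pd.DataFrame(
            {
                "term": [str(t) for t in self.terms],
                "order": [t.order for t in self.terms],
                "count": counts,
                "fraction": counts / max(self.B, 1),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
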