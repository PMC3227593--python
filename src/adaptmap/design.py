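"""Numeric encoding of a symbolic term set.

Numeric covariates enter as-is; categorical covariates are reference-coded
(the lexicographically first level is dropped) with columns named
``feature.LEVEL``; SNP main effects are 0/1/2 dosage columns.  Interaction
columns are elementwise products of the encoded component columns — for
categorical components, one column per combination of retained dummy levels —
and products are always computed on the raw (pre-standardization) encodings.
Column order is deterministic: sorted mains, then sorted interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix
from .terms import ModelTermSet, TermKey

__all__ = ["DesignMatrix", "build_design"]


@dataclass
class DesignMatrix:
    X: pd.DataFrame
    column_terms: dict[str, TermKey]
    levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def means(self) -> pd.Series:
        return self.X.mean()

    @property
    def scales(self) -> pd.Series:
        return self.X.std(ddof=0)


def _main_columns(
    name: str,
    covariates: pd.DataFrame,
    dosage: pd.DataFrame | None,
    levels: dict[str, list[str]],
) -> dict[str, np.ndarray]:
    if name in covariates.columns:
        col = covariates[name]
        if col.isna().any():
            raise ValueError(f"feature {name!r} has missing values; impute first")
        if col.dtype.kind in "fiub":
            return {name: col.to_numpy(dtype=float)}
        vals = col.astype(str)
        if name in levels:
            levs = levels[name]
        else:
            levs = sorted(vals.unique())
            levels[name] = levs
        return {
            f"{name}.{lev}": (vals == lev).to_numpy(dtype=float)
            for lev in levs[1:]
        }
    if dosage is not None and name in dosage.columns:
        col = dosage[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        return {name: col}
    raise KeyError(f"unknown feature {name!r} in term set")


def build_design(
    covariates: pd.DataFrame,
    terms: ModelTermSet,
    geno: GenotypeMatrix | pd.DataFrame | None = None,
    levels: dict[str, list[str]] | None = None,
) -> DesignMatrix:
    """Encode a marginality-closed term set as a numeric design matrix.

    ``levels`` pins the categorical level sets (as recorded on a training
    design) so that test-set encodings align column-for-column.
    """
    dosage = geno.to_frame() if isinstance(geno, GenotypeMatrix) else geno
    if dosage is not None:
        dosage = dosage.reset_index(drop=True)
    covariates = covariates.reset_index(drop=True)
    levels = dict(levels) if levels else {}

    cols: dict[str, np.ndarray] = {}
    column_terms: dict[str, TermKey] = {}

    encoded: dict[str, dict[str, np.ndarray]] = {}
    for f in sorted(terms.features()):
        encoded[f] = _main_columns(f, covariates, dosage, levels)

    for f in sorted(terms.mains):
        for cname, arr in encoded[f].items():
            cols[cname] = arr
            column_terms[cname] = TermKey((f,))

    for t in sorted(terms.interactions):
        parts = [sorted(encoded[f].items()) for f in t.features]
        combos = [[]]
        for group in parts:
            combos = [c + [item] for c in combos for item in group]
        for combo in combos:
            cname = ":".join(name for name, _ in combo)
            arr = np.ones(len(covariates))
            for _, a in combo:
                arr = arr * a
            cols[cname] = arr
            column_terms[cname] = t

    X = pd.DataFrame(cols, index=range(len(covariates)))
    return DesignMatrix(X, column_terms, levels)
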