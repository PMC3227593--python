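"""Phenotype construction and covariate imputation.

Mean arterial pressure is defined as the convex combination
``MAP = 2/3 DBP + 1/3 SBP``.  For subjects on anti-hypertensive medication
the conventional treatment correction adds 10 mmHg to SBP and 5 mmHg to DBP
before MAP is computed ("adjusted" phenotype); the "unadjusted" phenotype
uses the raw readings.  Missing covariates are imputed with pruned trees
trained on the observed values of each column, the other covariates serving
as predictors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .simulate import Cohort, RESERVED_COLS
from .trees import fit_pruned_tree

__all__ = [
    "compute_map",
    "medication_adjust",
    "map_values",
    "CartImputer",
    "cart_impute",
]


def compute_map(sbp, dbp):
    """MAP = (2*DBP + SBP) / 3, elementwise; inputs must be finite."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if not (np.isfinite(sbp).all() and np.isfinite(dbp).all()):
        raise ValueError("non-finite blood pressure value")
    out = (2.0 * dbp + sbp) / 3.0
    return out if out.ndim else float(out)


def medication_adjust(sbp, dbp, medicated):
    """Treatment correction: +10 mmHg SBP, +5 mmHg DBP for medicated subjects."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if not (np.isfinite(sbp).all() and np.isfinite(dbp).all()):
        raise ValueError("non-finite blood pressure value")
    med = np.asarray(medicated, dtype=bool)
    sbp_adj = sbp + 10.0 * med
    dbp_adj = dbp + 5.0 * med
    if sbp_adj.ndim:
        return sbp_adj, dbp_adj
    return float(sbp_adj), float(dbp_adj)


def map_values(cohort: Cohort, adjusted: bool = True) -> np.ndarray:
    """Cohort phenotype vector, medication-adjusted or raw."""
    d = cohort.data
    if (d["sbp"] < d["dbp"]).any():
        warnings.warn("some subjects have SBP < DBP", stacklevel=2)
    if adjusted:
        sbp, dbp = medication_adjust(d["sbp"], d["dbp"], d["medicated"])
    else:
        sbp, dbp = d["sbp"].to_numpy(float), d["dbp"].to_numpy(float)
    return compute_map(sbp, dbp)


# ---------------------------------------------------------------------------
# tree-based imputation


def _is_categorical(col: pd.Series) -> bool:
    return col.dtype.kind not in "fiu"


def _encode_predictors(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric matrix for imputation trees: median/mode fill + ordinal codes."""
    out = {}
    for c in df.columns:
        col = df[c]
        if _is_categorical(col):
            codes = pd.Categorical(col.astype("object")).codes.astype(float)
            codes[codes < 0] = np.nan
            col = pd.Series(codes, index=col.index)
            fill = col.mode().iloc[0] if col.notna().any() else 0.0
        else:
            col = col.astype(float)
            fill = col.median() if col.notna().any() else 0.0
        out[c] = col.fillna(fill)
    return pd.DataFrame(out, index=df.index)


class CartImputer:
    """Per-column pruned-tree imputation of missing covariates.

    Columns are processed in increasing order of missing count, each tree
    trained on the rows where the column is observed, with all other
    covariates (simple-filled, ordinal-coded) as predictors.  Numeric columns
    use a cost-complexity CV-pruned regression tree; categorical columns use
    a depth-capped classification tree with majority-vote leaves.  Observed
    cells are never altered, so the transform is idempotent on complete
    tables.
    """

    def __init__(self, min_leaf: int = 20, max_depth: int = 5, inner_cv: int = 5,
                 seed: int | None = None):
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.inner_cv = inner_cv
        self.seed = seed
        self._models: dict[str, tuple[str, object, list[str]]] = {}
        self._fills: dict[str, object] = {}
        self._columns: list[str] | None = None

    def fit(self, covariates: pd.DataFrame) -> "CartImputer":
        df = covariates.copy()
        n = len(df)
        n_missing = df.isna().sum()
        for c in df.columns:
            if n_missing[c] == n:
                raise ValueError(f"covariate {c!r} has no observed values")
            if n_missing[c] > n / 2:
                raise ValueError(f"covariate {c!r} is more than 50% missing")
        self._columns = list(df.columns)
        for c in df.columns:
            col = df[c]
            if _is_categorical(col):
                self._fills[c] = col.dropna().mode().iloc[0]
            else:
                self._fills[c] = float(col.dropna().median())
        order = n_missing.sort_values(kind="stable").index

        rng = np.random.default_rng(self.seed)
        for c in order:
            col = df[c]
            obs = col.notna()
            predictors = [p for p in df.columns if p != c]
            if n_missing[c] == 0 or not predictors:
                continue
            X = _encode_predictors(df[predictors])
            state = int(rng.integers(2**31 - 1))
            if _is_categorical(col):
                model = DecisionTreeClassifier(
                    min_samples_leaf=self.min_leaf,
                    max_depth=self.max_depth,
                    random_state=state,
                )
                model.fit(X[obs], col[obs].astype(str))
                pred = pd.Series(model.predict(X[~obs]), index=col.index[~obs])
                kind = "cat"
            else:
                model = fit_pruned_tree(
                    X[obs], col[obs].to_numpy(float),
                    min_leaf=self.min_leaf, max_depth=self.max_depth,
                    inner_cv=self.inner_cv, seed=state,
                )
                pred = pd.Series(model.predict(X[~obs]), index=col.index[~obs])
                kind = "num"
            self._models[c] = (kind, model, predictors)
            # later columns see this column's imputed values as predictors
            df.loc[~obs, c] = pred
        return self

    def transform(self, covariates: pd.DataFrame) -> pd.DataFrame:
        if self._columns is None:
            raise RuntimeError("imputer is not fitted")
        df = covariates.copy()
        for c in self._columns:
            if c not in df.columns:
                raise ValueError(f"covariate {c!r} missing from table")
            miss = df[c].isna()
            if not miss.any():
                continue
            if c not in self._models:
                # column was complete at fit time: fall back to the training
                # median/mode so held-out rows can still be scored
                if _is_categorical(df[c]):
                    df.loc[miss, c] = self._fills[c]
                else:
                    df[c] = df[c].astype(float)
                    df.loc[miss, c] = self._fills[c]
                continue
            kind, model, predictors = self._models[c]
            X = _encode_predictors(df[predictors])
            pred = model.predict(X[miss])
            if kind == "num":
                df[c] = df[c].astype(float)
            df.loc[miss, c] = pred
        return df

    def fit_transform(self, covariates: pd.DataFrame) -> pd.DataFrame:
        return self.fit(covariates).transform(covariates)


def cart_impute(cohort: Cohort, seed: int | None = None, **kwargs) -> Cohort:
    """Impute all covariate gaps in a cohort; reserved columns untouched."""
    imputed = CartImputer(seed=seed, **kwargs).fit_transform(cohort.covariates)
    data = cohort.data.copy()
    for c in imputed.columns:
        data[c] = imputed[c]
    return Cohort(data)
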