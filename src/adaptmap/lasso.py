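"""L1-penalized fitting of the selected terms and R² scoring.

The design is standardized internally (zero mean, unit variance per column);
the penalty is chosen by inner K-fold cross-validation minimizing squared
error on the training data only, and coefficients are reported back on the
original scale.  Terms whose coefficient is driven to zero are considered
eliminated by the adaptive fit.  Predictive quality is the squared Pearson
correlation between predictions and observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .design import DesignMatrix

__all__ = ["LassoFit", "fit_lasso", "predict", "r_squared"]


@dataclass
class LassoFit:
    intercept: float
    coef: pd.Series                 # original-scale coefficients by column
    penalty: float
    cv_curve: pd.DataFrame | None = None
    dropped: list[str] = field(default_factory=list)

    @property
    def active(self) -> pd.Series:
        return self.coef[self.coef != 0.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.coef.index, "coefficient": self.coef.values})


def fit_lasso(
    design: DesignMatrix,
    y,
    inner_folds: int = 10,
    seed: int | None = None,
    penalty: float | None = None,
    n_alphas: int = 100,
    max_iter: int = 20000,
) -> LassoFit:
    """LASSO with internally cross-validated penalty.

    ``penalty=None`` selects the penalty on a 100-point path by
    ``inner_folds``-fold CV; ``penalty=0`` is ordinary least squares
    (requires p < n); any positive value fixes the penalty.  Zero-variance
    columns are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    if design.n != len(y):
        raise ValueError("design/response length mismatch")
    if design.n <= 10:
        raise ValueError("need more than 10 samples")
    if design.p < 1:
        raise ValueError("design has no columns")

    X = design.X.to_numpy(dtype=float)
    names = list(design.X.columns)
    m = X.mean(axis=0)
    s = X.std(axis=0)
    keep = s > 1e-12
    dropped = [n_ for n_, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance design columns: {dropped}")
    if not keep.any():
        return LassoFit(float(y.mean()), pd.Series(0.0, index=names),
                        0.0, dropped=dropped)
    Xs = (X[:, keep] - m[keep]) / s[keep]
    kept_names = [n_ for n_, k in zip(names, keep) if k]

    cv_curve = None
    if penalty is None:
        folds = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = LassoCV(alphas=n_alphas, cv=folds, max_iter=max_iter).fit(Xs, y)
        coef_s = est.coef_
        alpha = float(est.alpha_)
        cv_curve = pd.DataFrame(
            {"alpha": est.alphas_, "cv_mse": est.mse_path_.mean(axis=1)}
        )
    elif penalty == 0:
        if Xs.shape[1] >= len(y):
            raise ValueError("penalty=0 requires p < n")
        A = np.column_stack([np.ones(len(y)), Xs])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        coef_s = sol[1:]
        alpha = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = Lasso(alpha=float(penalty), max_iter=max_iter, tol=1e-8).fit(Xs, y)
        coef_s = est.coef_
        alpha = float(penalty)

    coef = pd.Series(0.0, index=names)
    coef[kept_names] = coef_s / s[keep]
    intercept = float(y.mean() - (coef.to_numpy() * m).sum())
    return LassoFit(intercept, coef, alpha, cv_curve=cv_curve, dropped=dropped)


def predict(fit: LassoFit, design: DesignMatrix) -> np.ndarray:
    """Intercept plus linear combination on the raw design scale."""
    active = fit.active
    missing = [c for c in active.index if c not in design.X.columns]
    if missing:
        raise KeyError(f"design lacks required columns: {missing}")
    if len(active) == 0:
        return np.full(design.n, fit.intercept)
    return fit.intercept + design.X[active.index].to_numpy(float) @ active.to_numpy()


def r_squared(pred, actual) -> float:
    """Squared Pearson correlation; constant predictions score 0."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("length mismatch between predictions and observations")
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    if pred.std() < 1e-12 or actual.std() < 1e-12:
        warnings.warn("constant predictions or observations; R^2 defined as 0")
        return 0.0
    r = np.corrcoef(pred, actual)[0, 1]
    return float(r * r)
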