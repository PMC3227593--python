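"""Genome-wide SNP screening: marginal scan, local fdr, step-up selection.

Each SNP is tested one at a time in a least-squares model of the phenotype
on an intercept, the selected clinical covariates, and the SNP's additive
dosage.  The two-sided t-test p-value for the dosage coefficient is mapped
to a z-value through the probit of the t CDF.  The z-ensemble is then fed to
an empirical-Bayes local false discovery rate fit (Lindsey-method Poisson
density estimate, central-matching empirical null), and SNPs are selected by
the step-up rule that keeps the running mean of the sorted fdr values below
a marginal-FDR bound q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import interpolate, special, stats

from .simulate import GenotypeMatrix

__all__ = ["ScanResult", "LocfdrFit", "SnpSelection",
           "marginal_snp_scan", "fit_locfdr", "stepup_select"]

_Z_CLIP = 37.0  # probit of the smallest positive double


@dataclass
class ScanResult:
    """Per-SNP association statistics from the covariate-adjusted scan."""

    table: pd.DataFrame  # snp_id, beta, t, p, z, flagged

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _covariate_matrix(Z: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept plus dummy-coded covariates (reference level dropped)."""
    cols = [np.ones(n)]
    if Z is not None and Z.shape[1] > 0:
        if len(Z) != n:
            raise ValueError("covariate row count mismatch")
        for c in Z.columns:
            col = Z[c]
            if col.isna().any():
                raise ValueError(f"missing values in covariate {c!r}")
            if col.dtype.kind in "fiub":
                cols.append(col.to_numpy(dtype=float))
            else:
                levels = sorted(col.astype(str).unique())
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def marginal_snp_scan(
    y, Z: pd.DataFrame | None, geno: GenotypeMatrix
) -> ScanResult:
    """Per-SNP additive association, adjusted for selected covariates.

    Missing dosages are mean-imputed per SNP before the regression.  SNPs
    whose dosage is constant or collinear with the covariates are flagged and
    reported with p = 1, z = 0.  The scan is computed by residualizing both
    phenotype and dosages on the covariates (Frisch-Waugh-Lovell), so the
    per-SNP t statistics match the full least-squares fits exactly.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if geno.n != n:
        raise ValueError("genotype row count mismatch")
    C = _covariate_matrix(Z, n)
    k = C.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    G = geno.dosages.copy()
    if np.isnan(G).any():
        means = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = means[idx[1]]

    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    scale = np.maximum(np.einsum("ij,ij->j", G, G), 1.0)
    flagged = gg <= 1e-10 * scale

    gg_safe = np.where(flagged, 1.0, gg)
    beta = gy / gg_safe
    sse = np.maximum(y_r @ y_r - beta**2 * gg_safe, 0.0)
    sigma2 = sse / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / gg_safe)
    t = np.where(flagged | ~np.isfinite(t), 0.0, t)

    # two-sided p and probit z, computed tail-stably
    sf = stats.t.sf(np.abs(t), df)
    p = np.minimum(2.0 * sf, 1.0)
    z_mag = -special.ndtri(np.clip(sf, 1e-300, None))
    z = np.clip(np.sign(t) * z_mag, -_Z_CLIP, _Z_CLIP)
    z = np.where(flagged, 0.0, z)
    p = np.where(flagged, 1.0, p)
    beta = np.where(flagged, 0.0, beta)

    table = pd.DataFrame(
        {"snp_id": geno.snp_ids, "beta": beta, "t": t, "p": p, "z": z,
         "flagged": flagged}
    )
    return ScanResult(table)


# ---------------------------------------------------------------------------
# local false discovery rate


@dataclass
class LocfdrFit:
    """Empirical-Bayes two-group fit: fdr(z) = min(1, p0 f0(z) / f(z))."""

    z_grid: np.ndarray
    f_grid: np.ndarray            # estimated mixture density on the grid
    p0: float
    null_mean: float
    null_sd: float
    null: str = "empirical"
    _interp: interpolate.interp1d | None = field(default=None, repr=False)

    def fdr(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        f = np.exp(np.interp(z, self.z_grid, np.log(self.f_grid)))
        f0 = stats.norm.pdf(z, loc=self.null_mean, scale=self.null_sd)
        out = np.clip(self.p0 * f0 / np.maximum(f, 1e-300), None, 1.0)
        return np.maximum(out, 1e-12)


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with df columns (knots at quantile positions)."""
    k = 3
    n_inner = df - k
    inner = np.quantile(x, np.linspace(0, 1, n_inner + 2)[1:-1]) if n_inner > 0 else []
    t = np.concatenate([[x.min()] * (k + 1), inner, [x.max()] * (k + 1)])
    return interpolate.BSpline.design_matrix(x, t, k).toarray()


def fit_locfdr(
    z,
    null: str = "empirical",
    n_bins: int = 120,
    df: int = 7,
    central_fraction: float = 0.5,
) -> LocfdrFit:
    """Estimate the z-ensemble mixture density and the null component.

    The mixture density f is fitted by Lindsey's method: a Poisson GLM of
    histogram counts on a smooth (cubic B-spline, ``df`` degrees of freedom)
    basis in z.  With ``null="empirical"`` the null N(delta, sigma^2) and its
    proportion p0 come from central matching — a quadratic fit to log f over
    the central ``central_fraction`` of the z-values; ``null="theoretical"``
    uses N(0,1) with p0 capped at 1.  Fewer than 200 z-values trigger the
    theoretical null with p0 = 1.
    """
    z = np.asarray(z, dtype=float)
    if z.std() < 0.1:
        raise ValueError(
            "degenerate z spread (sd < 0.1); use the theoretical null on raw p-values"
        )
    if len(z) < 200 and null == "empirical":
        warnings.warn("fewer than 200 z-values; falling back to the theoretical null")
        null = "theoretical"

    lo, hi = z.min() - 0.1, z.max() + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    width = edges[1] - edges[0]
    counts, _ = np.histogram(z, bins=edges)

    X = _spline_basis(mids, df)
    glm = sm.GLM(counts, X, family=sm.families.Poisson())
    res = glm.fit()
    mu = np.maximum(res.predict(X), 1e-12)
    f_grid = np.maximum(mu / (len(z) * width), 1e-300)

    if null == "empirical":
        qlo, qhi = np.quantile(z, [(1 - central_fraction) / 2,
                                   (1 + central_fraction) / 2])
        sel = (mids >= qlo) & (mids <= qhi)
        if sel.sum() < 5:
            sel = np.argsort(np.abs(mids))[:max(5, n_bins // 4)]
        xs, ls = mids[sel], np.log(f_grid[sel])
        coef = np.polyfit(xs, ls, 2)  # c2 z^2 + c1 z + c0
        c2, c1, c0 = coef
        if c2 >= -1e-8:
            # log-density not concave at the center; fall back
            delta, sigma = 0.0, 1.0
            p0 = 1.0
        else:
            sigma = float(np.sqrt(-1.0 / (2.0 * c2)))
            delta = float(-c1 / (2.0 * c2))
            log_peak = c0 - c1**2 / (4.0 * c2)
            p0 = float(np.exp(log_peak) * sigma * np.sqrt(2 * np.pi))
        p0 = min(p0, 1.0)
    elif null == "theoretical":
        delta, sigma, p0 = 0.0, 1.0, 1.0
    else:
        raise ValueError(f"unknown null {null!r}")

    return LocfdrFit(mids, f_grid, p0, delta, max(sigma, 1e-6), null=null)


# ---------------------------------------------------------------------------
# step-up selection


@dataclass
class SnpSelection:
    selected: list[str]
    q: float
    fdr: pd.Series  # per-SNP fdr values indexed by snp_id

    def __len__(self) -> int:
        return len(self.selected)


def stepup_select(fdr_values, q: float, snp_ids=None) -> SnpSelection:
    """Step-up rule bounding the marginal false discovery rate.

    Sort fdr values ascending; the selection size k* is the largest k whose
    prefix mean fdr is <= q, and the k* smallest-fdr SNPs are selected.  The
    sort is stable on (fdr, snp_id), so boundary ties resolve
    deterministically.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    fdr = np.asarray(fdr_values, dtype=float)
    if ((fdr <= 0) | (fdr > 1)).any():
        raise ValueError("fdr values must lie in (0, 1]")
    if snp_ids is None:
        snp_ids = [str(i) for i in range(len(fdr))]
    snp_ids = list(snp_ids)

    order = sorted(range(len(fdr)), key=lambda i: (fdr[i], snp_ids[i]))
    sorted_fdr = fdr[order]
    prefix_mean = np.cumsum(sorted_fdr) / np.arange(1, len(fdr) + 1)
    # tolerance keeps exact boundary cases (prefix mean == q) selected
    # despite floating-point accumulation
    ok = np.flatnonzero(prefix_mean <= q * (1 + 1e-12) + 1e-12)
    k_star = int(ok.max() + 1) if ok.size else 0
    selected = [snp_ids[i] for i in order[:k_star]]
    return SnpSelection(selected, q, pd.Series(fdr, index=snp_ids))
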