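"""Cross-validated orchestration of the full adaptive pipeline.

Every selection step — covariate imputation, bootstrapped-tree term
discovery, co-occurrence reduction, SNP screening, LASSO penalty choice —
is re-run inside each training fold, and only the resulting fitted model
touches the held-out fold.  The same fold partition is reused across stages
of a variant, so stage-to-stage ΔR² comparisons are paired.

Variants:

* ``non_snp_first`` — clinical terms are discovered first; SNP main effects
  (screened by locfdr + step-up) are added next; a second tree pass with the
  chosen SNPs included as candidate splitters adds SNP interactions.
* ``snp_first`` — SNPs are screened with no covariate adjustment and fitted
  alone; clinical main effects and then clinical interactions are added.
* ``candidate_snps`` — like ``non_snp_first`` but a user-supplied candidate
  SNP list is forced into the design alongside the screened SNPs (still
  penalized, so the fit may drop them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooccur import cooccurrence_reduce
from .design import DesignMatrix, build_design
from .lasso import LassoFit, fit_lasso, predict, r_squared
from .phenotype import CartImputer, map_values
from .screen import fit_locfdr, marginal_snp_scan, stepup_select
from .simulate import Cohort, GenotypeMatrix
from .terms import ModelTermSet
from .trees import bootstrap_term_occurrences, threshold_terms

__all__ = ["PipelineConfig", "StageResult", "FoldResult", "CVReport",
           "run_fold", "cross_validate", "summarize"]

VARIANT_STAGES = {
    "non_snp_first": ("non_snp_only", "plus_snp_main", "plus_snp_interactions"),
    "snp_first": ("snp_only", "plus_nonsnp_main", "plus_nonsnp_interactions"),
    "candidate_snps": ("non_snp_only", "plus_snp_main", "plus_snp_interactions"),
}


@dataclass
class PipelineConfig:
    variant: str = "non_snp_first"
    phenotype: str = "adjusted"          # or "unadjusted"
    B: int = 300
    cutoff_fraction: float = 0.05
    mfdr_q: float = 0.2
    stages: tuple[str, ...] | None = None
    K: int = 10
    seed: int = 0
    candidate_snps: list[str] | None = None
    cut_height: float = 0.5
    null: str = "empirical"
    min_leaf: int = 20
    max_depth: int = 10
    tree_inner_cv: int = 10
    lasso_inner_folds: int = 10

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_STAGES:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.phenotype not in ("adjusted", "unadjusted"):
            raise ValueError("phenotype must be 'adjusted' or 'unadjusted'")
        allowed = VARIANT_STAGES[self.variant]
        if self.stages is None:
            self.stages = allowed
        else:
            self.stages = tuple(self.stages)
            bad = [s for s in self.stages if s not in allowed]
            if bad:
                raise ValueError(f"stages {bad} not valid for variant {self.variant!r}")
        if self.variant == "candidate_snps" and not self.candidate_snps:
            raise ValueError("candidate_snps variant needs a candidate SNP list")


@dataclass
class StageResult:
    r2: float
    coef: dict[str, float]               # nonzero coefficients by design column
    terms: ModelTermSet
    snps: list[str]                      # SNPs with nonzero fitted coefficient
    screened_snps: list[str] = field(default_factory=list)


@dataclass
class FoldResult:
    fold: int
    stages: dict[str, StageResult]


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(np.random.default_rng(ss).integers(2**31 - 1))


def _fit_and_score(
    cov_tr: pd.DataFrame,
    cov_te: pd.DataFrame,
    geno_tr: GenotypeMatrix | None,
    geno_te: GenotypeMatrix | None,
    terms: ModelTermSet,
    y_tr: np.ndarray,
    y_te: np.ndarray,
    config: PipelineConfig,
    seed: int,
    snp_ids: set[str],
    screened: list[str],
) -> StageResult:
    if len(terms) == 0:
        warnings.warn("empty term set; intercept-only model, R^2 = 0")
        return StageResult(0.0, {}, terms, [], screened)
    dm_tr = build_design(cov_tr, terms, geno_tr)
    fit = fit_lasso(dm_tr, y_tr, inner_folds=config.lasso_inner_folds, seed=seed)
    dm_te = build_design(cov_te, terms, geno_te, levels=dm_tr.levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = r_squared(predict(fit, dm_te), y_te)
    coef = {k: float(v) for k, v in fit.active.items()}
    snps = sorted({c for c in coef if c in snp_ids})
    return StageResult(r2, coef, terms, snps, screened)


def _discover_clinical_terms(cov_tr, y_tr, config, seed):
    occ = bootstrap_term_occurrences(
        cov_tr, y_tr, B=config.B, seed=seed,
        min_leaf=config.min_leaf, max_depth=config.max_depth,
        inner_cv=config.tree_inner_cv,
    )
    terms0 = threshold_terms(occ, config.cutoff_fraction)
    terms, _, _ = cooccurrence_reduce(occ, terms0, cut_height=config.cut_height)
    return occ, terms


def _screen_snps(y_tr, Z, geno_tr, config):
    scan = marginal_snp_scan(y_tr, Z, geno_tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_locfdr(scan.z, null=config.null)
    fdr = fit.fdr(scan.z)
    sel = stepup_select(fdr, config.mfdr_q, scan.snp_ids)
    return sel.selected


def run_fold(
    cohort: Cohort,
    geno: GenotypeMatrix | None,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
    fold: int = 0,
    seed_seq: np.random.SeedSequence | None = None,
) -> FoldResult:
    """Run the configured variant on one train/test split.

    All selection happens on the training rows; the held-out rows are only
    transformed (imputation) and scored.
    """
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test rows overlap")
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(config.seed)
    s_imp, s_boot1, s_boot2, s_l1, s_l2, s_l3 = ss.spawn(6)

    y = map_values(cohort, adjusted=(config.phenotype == "adjusted"))
    y_tr, y_te = y[train_idx], y[test_idx]
    cov = cohort.covariates
    imputer = CartImputer(seed=_int_seed(s_imp))
    cov_tr = imputer.fit_transform(cov.iloc[train_idx].reset_index(drop=True))
    cov_te = imputer.transform(cov.iloc[test_idx].reset_index(drop=True))

    geno_tr = geno.subset_rows(train_idx) if geno is not None else None
    geno_te = geno.subset_rows(test_idx) if geno is not None else None
    snp_ids = set(geno.snp_ids) if geno is not None else set()

    stages: dict[str, StageResult] = {}
    need = set(config.stages)

    if config.variant in ("non_snp_first", "candidate_snps"):
        occ, cterms = _discover_clinical_terms(cov_tr, y_tr, config,
                                               _int_seed(s_boot1))
        if "non_snp_only" in need:
            stages["non_snp_only"] = _fit_and_score(
                cov_tr, cov_te, None, None, cterms, y_tr, y_te, config,
                _int_seed(s_l1), snp_ids, [])

        if need & {"plus_snp_main", "plus_snp_interactions"}:
            if geno is None:
                raise ValueError("SNP stages need genotypes")
            z_cols = sorted(f for f in cterms.mains if f in cov_tr.columns)
            screened = _screen_snps(y_tr, cov_tr[z_cols] if z_cols else None,
                                    geno_tr, config)
            forced = []
            if config.variant == "candidate_snps":
                forced = [s for s in config.candidate_snps if s in snp_ids]
            in_design = sorted(set(screened) | set(forced))

            if "plus_snp_main" in need:
                terms_m = ModelTermSet(set(cterms.mains) | set(in_design),
                                       set(cterms.interactions))
                stages["plus_snp_main"] = _fit_and_score(
                    cov_tr, cov_te, geno_tr, geno_te, terms_m, y_tr, y_te,
                    config, _int_seed(s_l2), snp_ids, in_design)

            if "plus_snp_interactions" in need:
                aug_tr = cov_tr.copy()
                aug_te = cov_te.copy()
                for s in in_design:
                    j = geno.snp_ids.index(s)
                    aug_tr[s] = geno_tr.dosages[:, j]
                    aug_te[s] = geno_te.dosages[:, j]
                occ2 = bootstrap_term_occurrences(
                    aug_tr, y_tr, B=config.B, seed=_int_seed(s_boot2),
                    min_leaf=config.min_leaf, max_depth=config.max_depth,
                    inner_cv=config.tree_inner_cv,
                )
                terms2 = threshold_terms(occ2, config.cutoff_fraction)
                terms2, _, _ = cooccurrence_reduce(occ2, terms2,
                                                   cut_height=config.cut_height)
                # screened SNP mains stay as penalized candidates (model keeps
                # the chosen SNPs' additive effects alongside discovered terms)
                terms_i = ModelTermSet(
                    set(terms2.mains) | set(in_design),
                    set(terms2.interactions),
                ).close_marginality()
                stages["plus_snp_interactions"] = _fit_and_score(
                    aug_tr, aug_te, geno_tr, geno_te, terms_i, y_tr, y_te,
                    config, _int_seed(s_l3), snp_ids, in_design)

    else:  # snp_first
        if geno is None:
            raise ValueError("snp_first variant needs genotypes")
        screened = _screen_snps(y_tr, None, geno_tr, config)
        if "snp_only" in need:
            terms_s = ModelTermSet(set(screened), set())
            stages["snp_only"] = _fit_and_score(
                cov_tr, cov_te, geno_tr, geno_te, terms_s, y_tr, y_te,
                config, _int_seed(s_l1), snp_ids, screened)
        if need & {"plus_nonsnp_main", "plus_nonsnp_interactions"}:
            occ, cterms = _discover_clinical_terms(cov_tr, y_tr, config,
                                                   _int_seed(s_boot1))
            if "plus_nonsnp_main" in need:
                terms_m = ModelTermSet(set(cterms.mains) | set(screened), set())
                stages["plus_nonsnp_main"] = _fit_and_score(
                    cov_tr, cov_te, geno_tr, geno_te, terms_m, y_tr, y_te,
                    config, _int_seed(s_l2), snp_ids, screened)
            if "plus_nonsnp_interactions" in need:
                terms_f = ModelTermSet(set(cterms.mains) | set(screened),
                                       set(cterms.interactions))
                stages["plus_nonsnp_interactions"] = _fit_and_score(
                    cov_tr, cov_te, geno_tr, geno_te, terms_f, y_tr, y_te,
                    config, _int_seed(s_l3), snp_ids, screened)

    return FoldResult(fold, stages)


@dataclass
class CVReport:
    config: PipelineConfig
    folds: list[FoldResult]

    @property
    def K(self) -> int:
        return len(self.folds)

    def fold_r2(self, stage: str) -> np.ndarray:
        return np.array([f.stages[stage].r2 for f in self.folds])

    def stage_summary(self) -> pd.DataFrame:
        rows = []
        base = self.config.stages[0]
        for stage in self.config.stages:
            r2 = self.fold_r2(stage)
            d = r2 - self.fold_r2(base)
            rows.append({
                "stage": stage,
                "mean_r2": r2.mean(),
                "se_r2": r2.std(ddof=1) / np.sqrt(self.K) if self.K > 1 else np.nan,
                "delta_r2": d.mean(),
                "se_delta": d.std(ddof=1) / np.sqrt(self.K) if self.K > 1 else np.nan,
            })
        return pd.DataFrame(rows)

    def delta_r2(self, stage: str, baseline: str | None = None) -> float:
        base = baseline if baseline is not None else self.config.stages[0]
        return float(np.mean(self.fold_r2(stage) - self.fold_r2(base)))

    def term_stats(self, stage: str) -> pd.DataFrame:
        """Per-design-column CV count and average coefficient."""
        per_fold = [f.stages[stage].coef for f in self.folds]
        cols = sorted({c for coefs in per_fold for c in coefs})
        rows = []
        for c in cols:
            vals = [coefs[c] for coefs in per_fold if c in coefs]
            rows.append({"term": c, "avg_coef": float(np.mean(vals)),
                         "cv_count": len(vals)})
        return pd.DataFrame(rows, columns=["term", "avg_coef", "cv_count"])

    def snp_union(self, stage: str) -> list[str]:
        out: set[str] = set()
        for f in self.folds:
            out.update(f.stages[stage].snps)
        return sorted(out)

    def snp_intersection(self, stage: str) -> list[str]:
        sets = [set(f.stages[stage].snps) for f in self.folds]
        return sorted(set.intersection(*sets)) if sets else []


def cross_validate(
    cohort: Cohort, geno: GenotypeMatrix | None, config: PipelineConfig
) -> CVReport:
    """K-fold cross-validation of the whole adaptive procedure.

    Folds come from a seeded permutation split into K nearly equal blocks;
    the same partition serves every stage, so ΔR² between stages is a paired
    per-fold comparison.
    """
    n = cohort.n
    if n < 10 * config.K:
        raise ValueError("need at least 10*K subjects")
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(7,))
    rng = np.random.default_rng(ss)
    perm = rng.permutation(n)
    blocks = np.array_split(perm, config.K)
    fold_seeds = np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(8,)
    ).spawn(config.K)

    folds = []
    for k in range(config.K):
        test_idx = np.sort(blocks[k])
        train_idx = np.sort(np.concatenate([b for i, b in enumerate(blocks) if i != k]))
        folds.append(run_fold(cohort, geno, train_idx, test_idx, config,
                              fold=k, seed_seq=fold_seeds[k]))
    return CVReport(config, folds)


def summarize(reports: list[CVReport], outdir) -> dict[str, pd.DataFrame]:
    """Write Table-style TSV summaries for one or more CV runs.

    Produces an R² grid (variant x phenotype x stage x cutoff, with per-fold
    SE), per-stage term tables (avg coef + CV count per cutoff, 'NA' where a
    term was never selected), and per-stage SNP-union lists.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    grid_rows = []
    for rep in reports:
        cfg = rep.config
        for _, row in rep.stage_summary().iterrows():
            grid_rows.append({
                "variant": cfg.variant, "phenotype": cfg.phenotype,
                "mfdr_q": cfg.mfdr_q, "cutoff": cfg.cutoff_fraction,
                "stage": row["stage"], "r2": row["mean_r2"],
                "se": row["se_r2"], "delta_r2": row["delta_r2"],
            })
    grid = pd.DataFrame(grid_rows)
    grid.to_csv(outdir / "r2_grid.tsv", sep="\t", index=False, na_rep="NA")

    out = {"r2_grid": grid}
    stages = sorted({s for rep in reports for s in rep.config.stages})
    for stage in stages:
        pieces = []
        for rep in reports:
            if stage not in rep.config.stages:
                continue
            t = rep.term_stats(stage).set_index("term")
            t.columns = pd.MultiIndex.from_product(
                [[f"cutoff_{rep.config.cutoff_fraction}"], t.columns]
            )
            pieces.append(t)
        if not pieces:
            continue
        table = pd.concat(pieces, axis=1).sort_index()
        flat = table.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        flat.to_csv(outdir / f"terms_{stage}.tsv", sep="\t", na_rep="NA")
        out[f"terms_{stage}"] = flat

        snp_rows = []
        for rep in reports:
            if stage in rep.config.stages:
                for s in rep.snp_union(stage):
                    snp_rows.append({"cutoff": rep.config.cutoff_fraction,
                                     "snp_id": s})
        if snp_rows:
            pd.DataFrame(snp_rows).to_csv(
                outdir / f"snp_union_{stage}.tsv", sep="\t", index=False)
    return out
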