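"""Operating-characteristic studies of the SNP screening rule.

The main entry point replicates a synthetic covariate-adjusted genome scan
many times and reports the realized marginal false discovery rate
E[false selections] / E[selections] of the locfdr + step-up rule, the
quantity the mFDR bound q is supposed to control.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phenotype import map_values
from .screen import fit_locfdr, marginal_snp_scan, stepup_select
from .simulate import SimConfig, simulate_covariates, simulate_genotypes, simulate_phenotype

__all__ = ["MfdrStudy", "mfdr_simulation"]


@dataclass
class MfdrStudy:
    realized_mfdr: float
    n_replicates: int
    total_selected: int
    total_false: int
    mean_selected: float
    mean_true_found: float


def mfdr_simulation(
    n_replicates: int = 50,
    n_subjects: int = 1000,
    n_snps: int = 5000,
    n_causal: int = 200,
    effect: float = 1.5,
    noise_sd: float = 8.0,
    q: float = 0.2,
    null: str = "empirical",
    seed: int = 1,
) -> MfdrStudy:
    """Realized mFDR of the screen over replicated synthetic cohorts.

    Each replicate simulates a cohort with two planted clinical covariate
    effects plus ``n_causal`` SNPs of ``effect`` mmHg per allele, runs the
    covariate-adjusted scan, fits the local fdr, and applies the step-up
    rule at bound ``q``.  Replicate r uses generator seed ``seed + r``.  The
    realized mFDR is the ratio of total false selections to total selections
    across replicates (0 if nothing was ever selected).
    """
    total_selected = total_false = total_true = 0
    for r in range(n_replicates):
        cfg = SimConfig(
            n_subjects=n_subjects,
            n_features=2,
            n_categorical=0,
            block_structure=[],
            n_snps=n_snps,
            n_causal_snps=n_causal,
            snp_effect_size=effect,
            planted_main_terms=[(0, 2.0), (1, 1.5)],
            planted_interaction_terms=[],
            noise_sd=noise_sd,
            missing_rate=0.0,
            seed=seed + r,
        )
        cov = simulate_covariates(cfg)
        geno = simulate_genotypes(cfg)
        cohort, truth = simulate_phenotype(cov, geno, cfg)
        y = map_values(cohort, adjusted=False)
        scan = marginal_snp_scan(y, cohort.covariates, geno)
        fit = fit_locfdr(scan.z, null=null)
        sel = stepup_select(fit.fdr(scan.z), q, scan.snp_ids)
        causal = set(truth.causal_snp_ids)
        chosen = set(sel.selected)
        total_selected += len(chosen)
        total_false += len(chosen - causal)
        total_true += len(chosen & causal)
    mfdr = total_false / total_selected if total_selected else 0.0
    return MfdrStudy(
        realized_mfdr=mfdr,
        n_replicates=n_replicates,
        total_selected=total_selected,
        total_false=total_false,
        mean_selected=total_selected / n_replicates,
        mean_true_found=total_true / n_replicates,
    )
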