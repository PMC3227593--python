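"""Synthetic blood-pressure cohorts with planted effects and known truth.

The generator emulates the statistical structure of a population cohort used
for quantitative blood-pressure genetics: correlated blocks of numeric
clinical covariates, a few categorical factors (e.g. field center), additive
SNP dosages with a minor-allele-frequency spectrum, a latent mean arterial
pressure (MAP) that is linear in planted main effects, low-order interactions
and per-allele SNP effects plus Gaussian noise, an anti-hypertensive
medication indicator, and a small MCAR missingness rate in the covariates.

The latent phenotype is decomposed into systolic/diastolic pressure through
an independent pulse-pressure draw so that MAP == 2/3 DBP + 1/3 SBP holds
exactly by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .terms import ModelTermSet, TermKey

__all__ = [
    "SimConfig",
    "TruthRecord",
    "GenotypeMatrix",
    "Cohort",
    "simulate_covariates",
    "simulate_genotypes",
    "simulate_phenotype",
    "inject_missingness",
    "simulate_cohort",
]

# "map" is the derived phenotype a prepped table may carry; never a covariate
RESERVED_COLS = ("subject_id", "sbp", "dbp", "medicated", "map")

#: Baseline (intercept) MAP in mmHg around which effects are planted.
BASELINE_MAP = 90.0
#: Pulse pressure distribution (mmHg) used to split MAP into SBP/DBP.
PULSE_MEAN, PULSE_SD, PULSE_MIN = 45.0, 8.0, 5.0


@dataclass
class Cohort:
    """Subject-level table: sbp/dbp/medicated plus named covariates.

    ``data`` holds one row per subject with the reserved columns
    ``subject_id, sbp, dbp, medicated`` followed by covariates (numeric or
    string-valued categorical; NaN marks missingness).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("subject_id",):
            if c not in self.data.columns:
                raise ValueError(f"cohort table lacks required column {c!r}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_cols(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLS]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_cols]

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy())


@dataclass
class GenotypeMatrix:
    """n x m additive dosage matrix: 0/1/2 copies of the minor allele."""

    snp_ids: list[str]
    dosages: np.ndarray  # float to allow NaN for missing calls

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosages must be n x len(snp_ids)")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.snp_ids)

    def subset_rows(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.snp_ids), self.dosages[np.asarray(idx)])


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults reflect the cohort this generator emulates: n=3138 women, a few
    dozen clinical covariates with correlated subgroups, per-feature
    missingness at most 2%, a 26% medicated fraction, and planted effects
    sized so that the signal explains roughly a quarter of phenotypic
    variance on a residual noise SD of 8.3 mmHg.
    """

    n_subjects: int = 3138
    n_features: int = 44          # total covariates, including categorical
    n_categorical: int = 4
    block_structure: Sequence[tuple[int, float]] = ((4, 0.7), (4, 0.5), (3, 0.3))
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_snps: int = 5
    snp_effect_size: float = 1.5  # mmHg per minor allele
    planted_main_terms: Sequence[tuple[int, float]] = ((12, 3.0), (13, 2.5), (14, 2.0))
    planted_interaction_terms: Sequence[tuple[tuple[int, ...], float]] = (((12, 13), 1.5),)
    noise_sd: float = 8.3         # mmHg
    medicated_fraction: float = 0.26
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categorical > self.n_features:
            raise ValueError("n_categorical exceeds n_features")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps exceeds n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.medicated_fraction <= 1.0:
            raise ValueError("medicated_fraction must lie in [0, 1]")
        if sum(s for s, _ in self.block_structure) > self.n_numeric:
            raise ValueError("block sizes exceed the number of numeric features")
        for _, rho in self.block_structure:
            if not 0.0 <= rho < 1.0:
                raise ValueError("within-block correlation must lie in [0, 1)")

    @property
    def n_numeric(self) -> int:
        return self.n_features - self.n_categorical

    def numeric_name(self, i: int) -> str:
        if not 0 <= i < self.n_numeric:
            raise ValueError(f"no numeric feature with index {i}")
        return f"x{i:02d}"

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for parameter-recovery checks."""

    true_terms: ModelTermSet
    true_coefficients: dict[str, float]
    oracle_r2: float
    causal_snp_ids: list[str]

    def to_json(self, path) -> None:
        payload = {
            "true_terms": [str(t) for t in self.true_terms.terms()],
            "true_coefficients": self.true_coefficients,
            "oracle_r2": self.oracle_r2,
            "causal_snp_ids": self.causal_snp_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        terms = ModelTermSet.from_terms(TermKey.parse(t) for t in payload["true_terms"])
        return cls(
            terms,
            {k: float(v) for k, v in payload["true_coefficients"].items()},
            float(payload["oracle_r2"]),
            list(payload["causal_snp_ids"]),
        )


# ---------------------------------------------------------------------------
# covariates

_CATEGORICAL_LEVELS = {
    0: ("center", ["A", "B", "C", "D"], [0.3, 0.25, 0.25, 0.2]),
}


def simulate_covariates(config: SimConfig) -> Cohort:
    """Draw block-correlated numeric covariates plus categorical factors.

    Numeric features are standard Gaussians; the leading features are grouped
    into equicorrelated blocks per ``config.block_structure`` and the rest are
    independent.  Categorical factors are drawn multinomially and are
    independent of the numeric features.
    """
    rng = config._rng(0)
    n, p = config.n_subjects, config.n_numeric

    x = rng.standard_normal((n, p))
    pos = 0
    for size, rho in config.block_structure:
        if rho > 0 and size > 1:
            shared = rng.standard_normal((n, 1))
            x[:, pos : pos + size] = (
                np.sqrt(rho) * shared + np.sqrt(1 - rho) * x[:, pos : pos + size]
            )
        pos += size

    cols: dict[str, object] = {"subject_id": [f"S{i:06d}" for i in range(n)]}
    for j in range(p):
        cols[config.numeric_name(j)] = x[:, j]
    for k in range(config.n_categorical):
        name, levels, probs = _CATEGORICAL_LEVELS.get(
            k, (f"cat{k}", ["1", "2", "3"], [0.5, 0.3, 0.2])
        )
        cols[name] = rng.choice(levels, size=n, p=probs)
    return Cohort(pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Independent SNPs: dosage ~ Binomial(2, MAF), MAF ~ Uniform(maf_range)."""
    rng = config._rng(1)
    n, m = config.n_subjects, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    snp_ids = [f"rs{i + 1:06d}" for i in range(m)]
    return GenotypeMatrix(snp_ids, dosages)


# ---------------------------------------------------------------------------
# phenotype


def _planted_signal(
    cohort: Cohort, geno: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, ModelTermSet, dict[str, float], list[str]]:
    cov = cohort.data
    signal = np.zeros(cohort.n)
    terms = ModelTermSet()
    coefs: dict[str, float] = {}

    for idx, beta in config.planted_main_terms:
        name = config.numeric_name(idx)
        if name not in cov.columns:
            raise ValueError(f"planted main term references missing feature {name!r}")
        signal += beta * cov[name].to_numpy(float)
        terms.mains.add(name)
        coefs[name] = float(beta)

    for idxs, beta in config.planted_interaction_terms:
        names = tuple(config.numeric_name(i) for i in idxs)
        for name in names:
            if name not in cov.columns:
                raise ValueError(f"planted interaction references missing feature {name!r}")
        key = TermKey(names)
        prod = np.ones(cohort.n)
        for name in names:
            prod *= cov[name].to_numpy(float)
        signal += beta * prod
        terms.interactions.add(key)
        coefs[str(key)] = float(beta)

    causal_ids: list[str] = []
    if config.n_causal_snps > 0:
        picks = rng.choice(geno.m, size=config.n_causal_snps, replace=False)
        for j in sorted(picks):
            sid = geno.snp_ids[j]
            signal += config.snp_effect_size * geno.dosages[:, j]
            terms.mains.add(sid)
            coefs[sid] = float(config.snp_effect_size)
            causal_ids.append(sid)

    terms = terms.close_marginality()
    return signal, terms, coefs, causal_ids


def simulate_phenotype(
    cohort: Cohort, geno: GenotypeMatrix, config: SimConfig
) -> tuple[Cohort, TruthRecord]:
    """Add SBP/DBP/medication to a covariate table; return the ground truth.

    Latent MAP* = baseline + planted mains + planted interactions + per-allele
    SNP effects + N(0, noise_sd^2).  A pulse-pressure draw PP ~ N(45, 8^2)
    (floored at 5 mmHg) then sets DBP = MAP* - PP/3 and SBP = DBP + PP, so
    that 2/3 DBP + 1/3 SBP reconstructs MAP* exactly.  The medication flag is
    Bernoulli(medicated_fraction), independent of the phenotype.
    """
    if geno.n != cohort.n:
        raise ValueError("cohort and genotype row counts differ")
    rng = config._rng(2)

    signal, terms, coefs, causal_ids = _planted_signal(cohort, geno, config, rng)
    eps = rng.normal(0.0, config.noise_sd, size=cohort.n)
    map_star = BASELINE_MAP + signal + eps

    var_sig = float(np.var(signal))
    oracle_r2 = var_sig / (var_sig + config.noise_sd**2) if var_sig > 0 else 0.0

    pp = np.maximum(rng.normal(PULSE_MEAN, PULSE_SD, size=cohort.n), PULSE_MIN)
    dbp = map_star - pp / 3.0
    sbp = dbp + pp
    medicated = rng.random(cohort.n) < config.medicated_fraction

    data = cohort.data.copy()
    data.insert(1, "sbp", sbp)
    data.insert(2, "dbp", dbp)
    data.insert(3, "medicated", medicated.astype(int))
    truth = TruthRecord(terms, coefs, oracle_r2, causal_ids)
    return Cohort(data), truth


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(cohort: Cohort, config: SimConfig) -> Cohort:
    """Mask each covariate cell independently with probability missing_rate.

    SBP, DBP and the medication flag are never masked.
    """
    if config.missing_rate == 0:
        return cohort.copy()
    rng = config._rng(3)
    data = cohort.data.copy()
    cols = [c for c in data.columns if c not in RESERVED_COLS]
    mask = rng.random((len(data), len(cols))) < config.missing_rate
    for j, c in enumerate(cols):
        col = data[c]
        if col.dtype.kind in "iub":
            col = col.astype(float)
        col = col.mask(mask[:, j])
        data[c] = col
    return Cohort(data)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GenotypeMatrix, TruthRecord]:
    """Full generator: covariates, genotypes, phenotype, missingness."""
    cov = simulate_covariates(config)
    geno = simulate_genotypes(config)
    cohort, truth = simulate_phenotype(cov, geno, config)
    cohort = inject_missingness(cohort, config)
    return cohort, geno, truth
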