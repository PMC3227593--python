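"""Readers and writers for cohort tables and genotype matrices.

Cohort tables are TSV, one row per subject, with ``NA`` marking missing
covariates.  Genotypes use the PLINK ``.raw`` additive-recoding layout
(FID/IID bookkeeping columns followed by one ``rsid_ALLELE`` column of
0/1/2 dosages per SNP).  An optional VCF reader converts GT fields to
minor-allele dosages.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .simulate import Cohort, GenotypeMatrix, RESERVED_COLS

__all__ = [
    "read_cohort", "write_cohort",
    "read_plink_raw", "write_plink_raw",
    "read_vcf", "read_snp_list",
]

log = logging.getLogger(__name__)

_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def write_cohort(cohort: Cohort, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path) -> Cohort:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True,
                     dtype={"subject_id": str})
    # categorical covariates round-trip as strings; numeric parse wins otherwise
    for c in df.columns:
        if c in RESERVED_COLS:
            continue
        if df[c].dtype == object:
            df[c] = df[c].astype("object")
    if "medicated" in df.columns:
        df["medicated"] = df["medicated"].astype(int)
    return Cohort(df)


def write_plink_raw(geno: GenotypeMatrix, path, iids=None, alleles=None) -> None:
    n = geno.n
    iids = list(iids) if iids is not None else [f"S{i:06d}" for i in range(n)]
    alleles = list(alleles) if alleles is not None else ["A"] * geno.m
    out = pd.DataFrame({"FID": iids, "IID": iids})
    dos = pd.DataFrame(
        geno.dosages,
        columns=[f"{s}_{a}" for s, a in zip(geno.snp_ids, alleles)],
    )
    pd.concat([out, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    cols = [c for c in df.columns if c not in _RAW_META]
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in cols]
    dosages = df[cols].to_numpy(dtype=float)
    return GenotypeMatrix(snp_ids, dosages)


def read_snp_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_vcf(path) -> GenotypeMatrix:
    """Biallelic sites from a VCF as minor-allele dosages.

    Requires cyvcf2.  Multi-allelic sites are skipped with a warning.  The
    ALT dosage is flipped wherever ALT is the major allele so entries count
    copies of the minor allele.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc

    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            log.warning("skipping multi-allelic site %s", var.ID or var.POS)
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dos = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alt_freq = np.nanmean(dos) / 2.0
        if alt_freq > 0.5:
            dos = 2.0 - dos
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dos)
    dosages = np.column_stack(rows) if rows else np.empty((0, 0))
    return GenotypeMatrix(snp_ids, dosages)
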