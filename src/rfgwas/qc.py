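"""Genotype quality control and naive median imputation.

Filters mirror standard array QC: sample call rate, SNP call rate, minor
allele frequency, and a heterozygosity outlier screen.  Order is fixed and
recorded: (1) samples below the call-rate threshold, (2) SNPs below the
call-rate or MAF thresholds (allele frequencies recomputed after the sample
removals), (3) samples whose heterozygosity deviates from the cohort mean by
more than ``het_sd_limit`` standard deviations.  The heterozygosity screen
is per-sample by default; a per-SNP variant is available behind a flag.
The three-stage pass is iterated until no further removal occurs (removals
shift the statistics later thresholds depend on), so the filter is
idempotent; the report records the exact removal sequence across passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["QCError", "QCReport", "qc_filter", "impute_median"]


class QCError(ValueError):
    """QC cannot proceed (empty input, all samples removed...)."""


@dataclass
class QCReport:
    """Record of every QC removal with its reason and offending value."""

    removed_samples: pd.DataFrame  # columns: sample, reason, value
    removed_snps: pd.DataFrame  # columns: snp, reason, value
    thresholds: dict = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0

    def summary(self) -> str:
        return (
            f"samples {self.n_samples_before} -> {self.n_samples_after} "
            f"({len(self.removed_samples)} removed); "
            f"SNPs {self.n_snps_before} -> {self.n_snps_after} "
            f"({len(self.removed_snps)} removed)"
        )

    def to_tsv(self, path) -> None:
        rows = [self.removed_samples.rename(columns={"sample": "item"}).assign(kind="sample"),
                self.removed_snps.rename(columns={"snp": "item"}).assign(kind="snp")]
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def qc_filter(
    genotypes: GenotypeMatrix,
    sample_call_rate_min: float = 0.90,
    snp_call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    het_sd_limit: float = 3.0,
    het_axis: str = "samples",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample/SNP call-rate, MAF and heterozygosity filters.

    Returns the filtered matrix and a :class:`QCReport` listing every
    removal (one primary reason each, in application order).
    """
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise QCError("empty genotype matrix")
    if het_axis not in {"samples", "snps"}:
        raise QCError(f"het_axis must be 'samples' or 'snps', got {het_axis!r}")

    thresholds = {
        "sample_call_rate_min": sample_call_rate_min,
        "snp_call_rate_min": snp_call_rate_min,
        "maf_min": maf_min,
        "het_sd_limit": het_sd_limit,
        "het_axis": het_axis,
    }
    sample_rows: list[tuple[str, str, float]] = []
    snp_rows: list[tuple[str, str, float]] = []
    g = genotypes

    # the three stages are applied in fixed order, and the whole pass is
    # iterated to a fixed point (removals change the cohort statistics the
    # later thresholds are computed from), which makes the filter idempotent
    changed = True
    while changed:
        n_removed = len(sample_rows) + len(snp_rows)

        # 1. sample call rate
        cr = g.sample_call_rate()
        bad = cr < sample_call_rate_min
        for i in np.flatnonzero(bad):
            sample_rows.append((g.samples[i], "sample_call_rate", float(cr[i])))
        g = g.subset_samples(list(~bad))
        if g.n_samples == 0:
            raise QCError("all samples removed by the call-rate filter")

        # 2. SNP call rate then MAF (frequencies from post-sample-filter calls)
        cr_snp = g.snp_call_rate()
        maf = g.maf()
        ids = g.snps["snp"].to_numpy(str)
        bad_cr = cr_snp < snp_call_rate_min
        bad_maf = (~bad_cr) & (np.nan_to_num(maf, nan=0.0) < maf_min)
        for j in np.flatnonzero(bad_cr):
            snp_rows.append((ids[j], "snp_call_rate", float(cr_snp[j])))
        for j in np.flatnonzero(bad_maf):
            snp_rows.append((ids[j], "maf", float(0.0 if np.isnan(maf[j]) else maf[j])))
        keep = ~(bad_cr | bad_maf)
        g = g.subset_snps(list(keep))
        if g.n_snps == 0:
            raise QCError("all SNPs removed by call-rate/MAF filters")

        # 3. heterozygosity outliers
        het = g.heterozygosity(axis=het_axis)
        mu, sd = float(np.nanmean(het)), float(np.nanstd(het))
        if sd > 0:
            out = np.abs(het - mu) > het_sd_limit * sd
            out &= ~np.isnan(het)
            if het_axis == "samples":
                for i in np.flatnonzero(out):
                    sample_rows.append((g.samples[i], "heterozygosity", float(het[i])))
                g = g.subset_samples(list(~out))
            else:
                ids = g.snps["snp"].to_numpy(str)
                for j in np.flatnonzero(out):
                    snp_rows.append((ids[j], "heterozygosity", float(het[j])))
                g = g.subset_snps(list(~out))
        if g.n_samples == 0:
            raise QCError("all samples removed by the heterozygosity filter")
        changed = len(sample_rows) + len(snp_rows) > n_removed

    report = QCReport(
        removed_samples=pd.DataFrame(sample_rows, columns=["sample", "reason", "value"]),
        removed_snps=pd.DataFrame(snp_rows, columns=["snp", "reason", "value"]),
        thresholds=thresholds,
        n_samples_before=genotypes.n_samples,
        n_samples_after=g.n_samples,
        n_snps_before=genotypes.n_snps,
        n_snps_after=g.n_snps,
    )
    return g, report


def impute_median(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by its SNP's median of non-missing calls.

    The median of an even-sized set is the midpoint, so imputed values may
    be half-integers (0.5/1.5).  Non-missing entries are untouched.  A SNP
    with no observed calls raises :class:`QCError` naming the SNP.
    """
    g = genotypes.copy()
    miss = np.isnan(g.dosages)
    if not miss.any():
        return g
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = g.snps["snp"].to_numpy(str)[all_missing]
        raise QCError(f"SNP(s) with no observed genotypes: {list(bad[:5])}")
    med = np.nanmedian(g.dosages, axis=0)
    jj = np.where(miss)[1]
    g.dosages[miss] = med[jj]
    return g
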