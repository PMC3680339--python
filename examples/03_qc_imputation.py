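"""Genotype quality control and naive median imputation.

Applies the call-rate (0.90 for samples and SNPs), MAF (0.01) and
heterozygosity (3 SD) filters, then fills remaining missing calls with the
per-SNP median — the imputation the downstream forest expects.
"""

import numpy as np

from rfgwas import SimConfig, impute_median, qc_filter
from rfgwas.simulate import simulate_genotypes, simulate_pedigree

config = SimConfig(
    n_sires=20, offspring_per_sire_range=(5, 20), n_dams=120, n_other_sires=0,
    n_extra_pedigree_generations=1, n_chromosomes=3, snps_per_chromosome=150,
    missing_genotype_rate=0.01, seed=3,
)
herd = simulate_pedigree(config)
genotypes = simulate_genotypes(herd, config).subset_samples(herd.cohort)

# degrade two samples and one SNP so the filters have something to catch
rng = np.random.default_rng(0)
genotypes.dosages[0, rng.random(genotypes.n_snps) < 0.2] = np.nan
genotypes.dosages[1, rng.random(genotypes.n_snps) < 0.15] = np.nan
genotypes.dosages[:, 5] = 0.0  # monomorphic -> MAF 0

filtered, report = qc_filter(genotypes)
print(report.summary())
for _, row in report.removed_samples.iterrows():
    print(f"  removed sample {row['sample']}: {row['reason']} = {row['value']:.3f}")
for _, row in report.removed_snps.head(5).iterrows():
    print(f"  removed SNP {row['snp']}: {row['reason']} = {row['value']:.3f}")

imputed = impute_median(filtered)
n_imputed = int(np.isnan(filtered.dosages).sum())
print(f"imputed {n_imputed} missing calls with per-SNP medians "
      f"({np.isnan(imputed.dosages).sum()} missing remain)")
# Median imputation may produce half-integer dosages when a SNP has an even
# number of observed calls; the forest treats them as ordinary numeric values.
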