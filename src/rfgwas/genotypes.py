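"""Genotype dosage matrix with SNP map metadata and PLINK/VCF text I/O.

Genotypes are held as an animals x SNPs float matrix of B-allele dosages
(0 = AA, 1 = AB, 2 = BB, NaN = missing) alongside a per-SNP map (id,
chromosome, bp position, alleles).  PLINK PED/MAP is the primary on-disk
format; a minimal GT-only VCF (v4.2) writer/reader is provided as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "GenotypeFormatError", "encode_genotypes"]

MISSING = np.nan


class GenotypeFormatError(ValueError):
    """Malformed genotype data (unknown allele, inconsistent map...)."""


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage table with per-SNP map metadata.

    ``dosages``: float array, entries in {0, 1, 2} or NaN (missing); median
    imputation may later introduce half-integer values.
    ``snps``: DataFrame with columns snp, chrom, pos (1-based bp), a1, a2.
    """

    dosages: np.ndarray
    samples: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        self.snps = self.snps.reset_index(drop=True)

    # -- basic queries -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def heterozygosity(self, axis: str = "samples") -> np.ndarray:
        """Fraction of heterozygous calls per sample (or per SNP)."""
        het = self.dosages == 1
        ok = ~np.isnan(self.dosages)
        ax = 1 if axis == "samples" else 0
        with np.errstate(invalid="ignore"):
            return het.sum(axis=ax) / ok.sum(axis=ax)

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([pos[str(s)] for s in keep], dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx].copy(),
            samples=[self.samples[i] for i in idx],
            snps=self.snps.copy(),
        )

    def subset_snps(self, keep) -> "GenotypeMatrix":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.snps["snp"])}
            idx = np.array([pos[str(s)] for s in keep], dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].copy(),
            samples=list(self.samples),
            snps=self.snps.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), list(self.samples), self.snps.copy())

    # -- PLINK PED/MAP -----------------------------------------------------

    def to_plink(self, prefix) -> None:
        """Write ``prefix``.ped / ``prefix``.map (white-space delimited)."""
        prefix = str(prefix)
        map_df = self.snps[["chrom", "snp", "pos"]].copy()
        map_df.insert(2, "cm", 0)
        map_df.to_csv(prefix + ".map", sep="\t", header=False, index=False)
        a1 = self.snps["a1"].to_numpy(str)
        a2 = self.snps["a2"].to_numpy(str)
        with open(prefix + ".ped", "w") as fh:
            for i, sid in enumerate(self.samples):
                row = self.dosages[i]
                alleles = []
                for j, dose in enumerate(row):
                    if np.isnan(dose):
                        alleles.append("0 0")
                    elif dose == 0:
                        alleles.append(f"{a1[j]} {a1[j]}")
                    elif dose == 1:
                        alleles.append(f"{a1[j]} {a2[j]}")
                    else:
                        alleles.append(f"{a2[j]} {a2[j]}")
                fh.write(f"FAM {sid} 0 0 0 -9 " + " ".join(alleles) + "\n")

    @classmethod
    def from_plink(cls, prefix) -> "GenotypeMatrix":
        prefix = str(prefix)
        map_df = pd.read_csv(
            prefix + ".map",
            sep=r"\s+",
            header=None,
            names=["chrom", "snp", "cm", "pos"],
            dtype={"chrom": str, "snp": str},
        )
        p = len(map_df)
        samples: list[str] = []
        dose_rows: list[np.ndarray] = []
        a1 = np.array([""] * p, dtype=object)  # first-seen allele per SNP
        a2 = np.array([""] * p, dtype=object)
        with open(prefix + ".ped") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) != 6 + 2 * p:
                    raise GenotypeFormatError(
                        f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                        f"{len(parts) - 6} allele fields, expected {2 * p}"
                    )
                samples.append(parts[1])
                row = np.full(p, np.nan)
                for j in range(p):
                    x, y = parts[6 + 2 * j], parts[7 + 2 * j]
                    if x == "0" or y == "0":
                        continue
                    for al in (x, y):
                        if al not in (a1[j], a2[j]):
                            if a1[j] == "":
                                a1[j] = al
                            elif a2[j] == "":
                                a2[j] = al
                            else:
                                raise GenotypeFormatError(
                                    f"SNP {map_df['snp'][j]}: third allele {al!r} "
                                    f"for sample {parts[1]}"
                                )
                    row[j] = (x == a2[j]) + (y == a2[j])
                dose_rows.append(row)
        # monomorphic SNPs may never reveal a second allele
        a2[a2 == ""] = "B"
        a1[a1 == ""] = "A"
        snps = map_df[["snp", "chrom", "pos"]].copy()
        snps["a1"] = a1
        snps["a2"] = a2
        return cls(np.array(dose_rows), samples, snps)

    # -- VCF (GT only) -----------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a minimal VCF v4.2 with GT-only genotype fields."""
        with open(str(path), "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, rec in self.snps.iterrows():
                col = self.dosages[:, j]
                gts = "\t".join(
                    "./." if np.isnan(x) else gt_codes[float(x)] for x in col
                )
                fh.write(
                    f"{rec['chrom']}\t{rec['pos']}\t{rec['snp']}\t{rec['a1']}\t"
                    f"{rec['a2']}\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a biallelic VCF via cyvcf2 (GT field only)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        snp_rows = []
        dose_cols = []
        for var in vcf:
            if len(var.ALT) != 1:
                raise GenotypeFormatError(
                    f"SNP {var.ID}: multiallelic ALT {var.ALT!r}"
                )
            gts = np.asarray(var.genotype.array())[:, :2].astype(float)
            gts[gts < 0] = np.nan  # -1 encodes a missing allele
            doses = gts.sum(axis=1)
            snp_rows.append(
                (var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0])
            )
            dose_cols.append(doses)
        snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "a1", "a2"])
        return cls(np.array(dose_cols).T, samples, snps)


def encode_genotypes(calls: pd.DataFrame, snps: pd.DataFrame) -> np.ndarray:
    """Encode allele-pair calls to B-allele dosages 0/1/2.

    ``calls``: animals x SNPs table of two-character strings such as "AA",
    "AB", "BA", "BB"; "00"/"--"/NaN mean missing.  ``snps`` declares the
    alleles (columns snp, a1, a2) in the column order of ``calls``.  AA -> 0,
    AB/BA -> 1, BB -> 2; an undeclared allele raises
    :class:`GenotypeFormatError` naming the SNP and animal.
    """
    out = np.full(calls.shape, np.nan)
    a1 = snps["a1"].astype(str).to_numpy()
    a2 = snps["a2"].astype(str).to_numpy()
    ids = snps["snp"].astype(str).to_numpy()
    for j, col in enumerate(calls.columns):
        for i, (animal, val) in enumerate(calls[col].items()):
            if val is None or (isinstance(val, float) and np.isnan(val)):
                continue
            s = str(val).strip()
            if s in {"00", "--", "..", "NA", ""}:
                continue
            if len(s) != 2:
                raise GenotypeFormatError(
                    f"SNP {ids[j]}, animal {animal}: malformed call {s!r}"
                )
            dose = 0
            for al in s:
                if al == a2[j]:
                    dose += 1
                elif al != a1[j]:
                    raise GenotypeFormatError(
                        f"SNP {ids[j]}, animal {animal}: allele {al!r} not in "
                        f"declared alleles {{{a1[j]}, {a2[j]}}}"
                    )
            out[i, j] = dose
    return out
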