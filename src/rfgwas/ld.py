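"""Linkage disequilibrium from unphased dosages, genomic windows, and
interval annotation.

r² between two SNPs is the squared Pearson correlation of their 0/1/2
dosage vectors (composite LD; equivalent to haplotype r² under
Hardy-Weinberg equilibrium, and computable without phasing).  Windows of
+/- 250 kb around selected SNPs are intersected with gene/QTL intervals to
produce a candidate-region report.  Coordinates are 1-based inclusive
throughout; BED input (0-based half-open) is converted at the reader.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "pairwise_r2",
    "ld_decay",
    "snp_windows",
    "annotate_windows",
    "read_bed",
    "read_gff3",
    "normalise_chrom",
]


def normalise_chrom(label) -> str:
    """Normalise a chromosome label: strip 'chr' prefix, lowercase."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.lower()


def pairwise_r2(
    genotypes: GenotypeMatrix,
    max_distance_bp: int | None = None,
) -> pd.DataFrame:
    """r² for every same-chromosome SNP pair within ``max_distance_bp``.

    Returns a DataFrame (snp1, snp2, chrom, dist_bp, r2).  Monomorphic SNPs
    are skipped with a warning; pairs with no overlapping non-missing calls
    are skipped and counted in the warning.
    """
    X = genotypes.dosages
    snps = genotypes.snps
    out_rows: list[tuple] = []
    n_mono = 0
    n_nodata = 0
    for chrom, sub in snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy(int)
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        ids = sub["snp"].to_numpy(str)[order]
        for a in range(len(idx)):
            if max_distance_bp is None:
                hi = len(idx)
            else:
                hi = int(np.searchsorted(pos, pos[a] + max_distance_bp, side="right"))
            for b in range(a + 1, hi):
                xa, xb = X[:, idx[a]], X[:, idx[b]]
                ok = ~(np.isnan(xa) | np.isnan(xb))
                if ok.sum() < 2:
                    n_nodata += 1
                    continue
                va, vb = xa[ok], xb[ok]
                if np.var(va) == 0 or np.var(vb) == 0:
                    n_mono += 1
                    continue
                r = np.corrcoef(va, vb)[0, 1]
                out_rows.append(
                    (ids[a], ids[b], str(chrom), int(pos[b] - pos[a]), float(r * r))
                )
    if n_mono or n_nodata:
        warnings.warn(
            f"skipped {n_mono} monomorphic and {n_nodata} no-overlap SNP pairs",
            stacklevel=2,
        )
    return pd.DataFrame(out_rows, columns=["snp1", "snp2", "chrom", "dist_bp", "r2"])


def ld_decay(records: pd.DataFrame, bin_width_bp: int) -> pd.DataFrame:
    """Mean r² per distance bin, with pair counts and the cumulative mean.

    ``cum_mean_r2`` is the mean over all pairs at distances up to the bin's
    upper edge (the alternative reading of "average r² at a distance").
    """
    if records.empty:
        raise ValueError("no LD records to bin")
    d = records["dist_bp"].to_numpy(int)
    r2 = records["r2"].to_numpy(float)
    b = d // bin_width_bp
    out = []
    csum, cn = 0.0, 0
    for k in sorted(np.unique(b)):
        m = b == k
        csum += r2[m].sum()
        cn += int(m.sum())
        out.append(
            (
                int(k * bin_width_bp),
                int((k + 1) * bin_width_bp),
                float(r2[m].mean()),
                int(m.sum()),
                csum / cn,
            )
        )
    return pd.DataFrame(
        out, columns=["bin_start_bp", "bin_end_bp", "mean_r2", "n_pairs", "cum_mean_r2"]
    )


def snp_windows(
    snps: pd.DataFrame,
    half_width_bp: int = 250_000,
) -> pd.DataFrame:
    """+/- ``half_width_bp`` windows around SNPs (1-based inclusive).

    ``snps`` needs columns snp, chrom, pos.  Start is clamped at 1.
    Returns (snp, chrom, start, end).
    """
    for col in ("snp", "chrom", "pos"):
        if col not in snps:
            raise ValueError(f"snp table lacks column {col!r}")
    pos = snps["pos"].to_numpy(int)
    return pd.DataFrame(
        {
            "snp": snps["snp"].astype(str).to_numpy(),
            "chrom": snps["chrom"].astype(str).to_numpy(),
            "start": np.maximum(1, pos - half_width_bp),
            "end": pos + half_width_bp,
        }
    )


def annotate_windows(windows: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Intersect query windows with feature intervals (overlap >= 1 bp).

    ``features`` columns: feature, kind, chrom, start, end (1-based
    inclusive).  Output: one row per (window, feature) intersection with
    the overlap length in bp.
    """
    bad = features[features["start"] > features["end"]]
    if len(bad):
        raise ValueError(
            f"feature interval(s) with start > end: {bad['feature'].tolist()[:5]}"
        )
    out = []
    feats = {c: f for c, f in features.assign(
        _chrom=features["chrom"].map(normalise_chrom)
    ).groupby("_chrom")}
    for row in windows.itertuples(index=False):
        f = feats.get(normalise_chrom(row.chrom))
        if f is None:
            continue
        lo = np.maximum(f["start"].to_numpy(int), int(row.start))
        hi = np.minimum(f["end"].to_numpy(int), int(row.end))
        ov = hi - lo + 1
        for k in np.flatnonzero(ov >= 1):
            rec = f.iloc[k]
            out.append(
                (
                    row.snp,
                    str(rec["feature"]),
                    str(rec["kind"]),
                    str(row.chrom),
                    int(ov[k]),
                )
            )
    return pd.DataFrame(out, columns=["snp", "feature", "kind", "chrom", "overlap_bp"])


# ---------------------------------------------------------------------------
# feature interval readers


def read_bed(path, kind: str = "gene") -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    rows = []
    with open(str(path)) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has < 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            if start >= end:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            rows.append((name, kind, chrom, start + 1, end, str(path)))
    return pd.DataFrame(
        rows, columns=["feature", "kind", "chrom", "start", "end", "source"]
    )


def read_gff3(path, kinds: dict[str, str] | None = None) -> pd.DataFrame:
    """Read GFF3 (1-based inclusive) feature intervals.

    ``kinds`` maps GFF3 ``type`` values to report kinds (default: 'gene'
    types -> gene, anything containing 'QTL' -> QTL); unmapped types are
    kept with their own type label.
    """
    rows = []
    with open(str(path)) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line has < 9 fields")
            chrom, _, ftype, start, end = parts[0], parts[1], parts[2], int(parts[3]), int(parts[4])
            if start > end:
                raise ValueError(f"{path}:{ln}: inverted interval")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"feature_{ln}"
            if kinds and ftype in kinds:
                kind = kinds[ftype]
            elif ftype.lower() == "gene":
                kind = "gene"
            elif "qtl" in ftype.lower():
                kind = "QTL"
            else:
                kind = ftype
            rows.append((name, kind, chrom, start, end, str(path)))
    return pd.DataFrame(
        rows, columns=["feature", "kind", "chrom", "start", "end", "source"]
    )
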