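"""Random-forest SNP importance and the two-step top-fraction selection.

A regression forest is fitted to a pseudo-phenotype (dEBV) with a per-split
candidate fraction (mtry) of 10% of the SNPs being evaluated.  Importance is
out-of-bag permutation importance (mean increase in OOB squared error when a
SNP's column is permuted, averaged over trees), the default importance of
the classic R implementation; mean decrease in impurity is available behind
a flag.

Selection is two-step: step 1 keeps the top 1% of SNPs *per chromosome*;
step 2 refits the forest on the surviving SNPs, pooled across chromosomes,
and keeps the top 1% of those.  With the floor rounding rule
max(1, floor(fraction * n)) the candidate counts are fully determined by the
per-chromosome SNP counts.

To tame unbalanced half-sib family structure, the analysis is repeated on
subsamples built by a greedy rule that adds, at each step, the animal least
related (numerator relationship) to the animals already chosen; candidate
SNPs supported by both the full run and the subsample runs form the
"common SNP" strategy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .genotypes import GenotypeMatrix
from .pedigree import RelationshipMatrix

__all__ = [
    "ImportanceTable",
    "CandidateSet",
    "SubsamplePlan",
    "rf_importance",
    "select_top_fraction_by_chromosome",
    "select_top_fraction",
    "top_fraction_count",
    "two_step_select",
    "build_subsamples",
    "common_snp_strategy",
]


@dataclass
class ImportanceTable:
    """Per-SNP importance scores plus the forest parameters that made them."""

    table: pd.DataFrame  # columns: snp, chrom, importance
    n_trees: int
    mtry_fraction: float
    seed: int | None = None
    measure: str = "permutation"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CandidateSet:
    """Ordered SNP selection with provenance (which selection stage)."""

    snps: list[str]
    provenance: str  # stage-1 | stage-2 | common | highest-1%
    scores: pd.DataFrame | None = None  # columns: snp, score (selection-time)
    stage1: list[str] | None = None

    def __len__(self) -> int:
        return len(self.snps)

    def __contains__(self, snp) -> bool:
        return str(snp) in set(self.snps)

    def to_tsv(self, path) -> None:
        df = (
            self.scores.copy()
            if self.scores is not None
            else pd.DataFrame({"snp": self.snps})
        )
        df["provenance"] = self.provenance
        df.to_csv(path, sep="\t", index=False)


@dataclass
class SubsamplePlan:
    """Animal subsets built by the low-relationship greedy rule."""

    subsamples: list[list[str]]
    subsample_size: int
    seed: int | None = None
    mean_relationships: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# importance


def _oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-tree OOB permutation importance, averaged over trees.

    For every tree: baseline OOB MSE, then for each SNP actually used in
    that tree, the OOB MSE after permuting that SNP's column; the increase
    is accumulated.  SNPs a tree never splits on contribute 0 for that tree,
    matching the convention of averaging over all trees.
    """
    n, p = X.shape
    imp = np.zeros(p)
    in_bag = forest.estimators_samples_
    for tree, bag in zip(forest.estimators_, in_bag):
        oob = np.setdiff1d(np.arange(n), bag, assume_unique=False)
        if oob.size < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        feats = np.unique(tree.tree_.feature)
        feats = feats[feats >= 0]
        for f in feats:
            saved = Xo[:, f].copy()
            Xo[:, f] = saved[rng.permutation(oob.size)]
            mse = np.mean((tree.predict(Xo) - yo) ** 2)
            Xo[:, f] = saved
            imp[f] += mse - base
    return imp / forest.n_estimators


def rf_importance(
    genotypes: GenotypeMatrix | np.ndarray,
    response: np.ndarray,
    n_trees: int = 5000,
    mtry_fraction: float = 0.10,
    seed: int | None = None,
    measure: str = "permutation",
    min_samples_leaf: int = 5,
    snps: pd.DataFrame | None = None,
) -> ImportanceTable:
    """Score SNPs by random-forest variable importance.

    Parameters
    ----------
    genotypes
        Imputed dosage matrix (no missing values); a :class:`GenotypeMatrix`
        or a plain array (then ``snps`` supplies the map).
    response
        Per-animal pseudo-phenotype (dEBV), same row order.
    n_trees, mtry_fraction
        Forest size and per-split candidate fraction; mtry =
        max(1, floor(mtry_fraction * p)).
    measure
        'permutation' (OOB, default) or 'impurity'.
    """
    if isinstance(genotypes, GenotypeMatrix):
        X = genotypes.dosages
        snps = genotypes.snps
    else:
        X = np.asarray(genotypes, dtype=float)
        if snps is None:
            snps = pd.DataFrame(
                {"snp": [f"snp{j}" for j in range(X.shape[1])], "chrom": "1"}
            )
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if p == 0 or n < 2:
        raise ValueError(f"need at least 2 animals and 1 SNP, got n={n}, p={p}")
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != {n} animals")
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; impute first")
    if measure not in {"permutation", "impurity"}:
        raise ValueError(f"unknown importance measure {measure!r}")

    mtry = max(1, math.floor(mtry_fraction * p))
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_samples_leaf,
        bootstrap=True,
        random_state=None if seed is None else int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    if measure == "impurity":
        scores = forest.feature_importances_
    else:
        rng = np.random.default_rng(None if seed is None else seed)
        scores = _oob_permutation_importance(forest, np.ascontiguousarray(X), y, rng)
    table = pd.DataFrame(
        {
            "snp": snps["snp"].astype(str).to_numpy(),
            "chrom": snps["chrom"].astype(str).to_numpy()
            if "chrom" in snps
            else "1",
            "importance": scores,
        }
    )
    return ImportanceTable(
        table=table,
        n_trees=n_trees,
        mtry_fraction=mtry_fraction,
        seed=seed,
        measure=measure,
    )


# ---------------------------------------------------------------------------
# selection rules


def top_fraction_count(n: int, fraction: float) -> int:
    """Number of SNPs kept from n by the top-fraction rule: max(1, floor(f*n))."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, math.floor(fraction * n))


def _top_rows(df: pd.DataFrame, k: int) -> pd.DataFrame:
    # ties: higher score first, then lexicographic SNP id
    return df.sort_values(
        ["importance", "snp"], ascending=[False, True], kind="mergesort"
    ).head(k)


def select_top_fraction(table: ImportanceTable, fraction: float = 0.01) -> CandidateSet:
    """Keep the top fraction of SNPs pooled across chromosomes."""
    df = table.table
    k = top_fraction_count(len(df), fraction)
    top = _top_rows(df, k)
    return CandidateSet(
        snps=top["snp"].tolist(),
        provenance="stage-2",
        scores=top.rename(columns={"importance": "score"})[["snp", "score"]].reset_index(drop=True),
    )


def select_top_fraction_by_chromosome(
    table: ImportanceTable, fraction: float = 0.01
) -> CandidateSet:
    """Keep, per chromosome with n_c SNPs, the max(1, floor(fraction*n_c))
    highest-importance SNPs; return the union."""
    df = table.table
    if "chrom" not in df:
        raise ValueError("importance table lacks chromosome labels")
    parts = []
    for _, sub in df.groupby("chrom", sort=True):
        parts.append(_top_rows(sub, top_fraction_count(len(sub), fraction)))
    top = pd.concat(parts, ignore_index=True)
    return CandidateSet(
        snps=top["snp"].tolist(),
        provenance="stage-1",
        scores=top.rename(columns={"importance": "score"})[["snp", "score"]].reset_index(drop=True),
    )


def two_step_select(
    genotypes: GenotypeMatrix,
    response: np.ndarray,
    fraction: float = 0.01,
    n_trees: int = 5000,
    mtry_fraction: float = 0.10,
    seed: int | None = None,
    measure: str = "permutation",
    n_trees_stage2: int | None = None,
) -> CandidateSet:
    """Two-step top-fraction selection with a stage-2 forest refit.

    Step 1 scores all SNPs and keeps the top fraction per chromosome; step 2
    refits the forest on the step-1 SNPs only (mtry recomputed as 10% of the
    reduced set) and keeps the top fraction pooled across chromosomes.
    ``n_trees_stage2`` lets the cheap reduced-panel refit keep a full-size
    forest when stage 1 has been scaled down (default: same as stage 1).
    """
    seed = None if seed is None else int(seed)
    imp1 = rf_importance(
        genotypes, response, n_trees=n_trees, mtry_fraction=mtry_fraction,
        seed=seed, measure=measure,
    )
    stage1 = select_top_fraction_by_chromosome(imp1, fraction)
    g1 = genotypes.subset_snps(stage1.snps)
    imp2 = rf_importance(
        g1, response, n_trees=n_trees_stage2 or n_trees,
        mtry_fraction=mtry_fraction,
        seed=None if seed is None else seed + 1, measure=measure,
    )
    stage2 = select_top_fraction(imp2, fraction)
    stage2.stage1 = list(stage1.snps)
    return stage2


# ---------------------------------------------------------------------------
# subsampling


def build_subsamples(
    A: RelationshipMatrix,
    genotyped,
    n_subsamples: int = 10,
    size: int = 198,
    seed: int | None = None,
) -> SubsamplePlan:
    """Build low-kinship subsamples by the greedy rule.

    Each subsample starts from a random animal; every further animal is the
    unselected one with the lowest mean relationship to the selected set,
    ties broken by the highest mean relationship to the remaining unselected
    animals (most representative of the rest), then by id.
    """
    ids = [str(a) for a in genotyped]
    if size > len(ids):
        raise ValueError(f"subsample size {size} > {len(ids)} genotyped animals")
    sub = A.submatrix(ids).values
    n = len(ids)
    order = np.argsort(ids)  # for id tie-breaks
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    rng = np.random.default_rng(seed)
    rowsum = sub.sum(axis=1)

    plans: list[list[str]] = []
    means: list[float] = []
    for _ in range(n_subsamples):
        selected = np.zeros(n, dtype=bool)
        start = int(rng.integers(n))
        selected[start] = True
        rel_to_sel = sub[:, start].copy()  # sum of relationships to selected
        while selected.sum() < size:
            k = selected.sum()
            mean_sel = np.where(selected, np.inf, rel_to_sel / k)
            n_unsel = n - k
            if n_unsel > 1:
                mean_unsel = (rowsum - rel_to_sel - np.diag(sub)) / (n_unsel - 1)
            else:
                mean_unsel = np.zeros(n)
            # lexicographic: min mean-to-selected, then max mean-to-unselected,
            # then smallest id
            best = np.lexsort((rank, -mean_unsel, mean_sel))[0]
            selected[best] = True
            rel_to_sel += sub[:, best]
        idx = np.flatnonzero(selected)
        plans.append([ids[i] for i in idx])
        off = sub[np.ix_(idx, idx)]
        means.append(float((off.sum() - np.trace(off)) / (size * (size - 1))))
    return SubsamplePlan(
        subsamples=plans, subsample_size=size, seed=seed, mean_relationships=means
    )


# ---------------------------------------------------------------------------
# strategies


def common_snp_strategy(
    full_run: CandidateSet,
    subsample_runs: list[CandidateSet],
    min_subsample_hits: int = 1,
    full_stage: str = "stage1",
) -> CandidateSet:
    """SNPs supported by both the full-sample run and the subsample runs.

    Keeps SNPs present in the full-sample run (its stage-1 set by default;
    ``full_stage='stage2'`` uses the final set) and in the stage-2 sets of at
    least ``min_subsample_hits`` subsamples.  Ordered by number of
    supporting subsamples, then by full-run score, then id.
    """
    if not full_run.snps or not subsample_runs:
        raise ValueError("common_snp_strategy needs a full run and subsample runs")
    if full_stage == "stage1" and full_run.stage1 is not None:
        base = list(full_run.stage1)
    else:
        base = list(full_run.snps)
    hits: dict[str, int] = {s: 0 for s in base}
    for run in subsample_runs:
        for s in set(run.snps):
            if s in hits:
                hits[s] += 1
    kept = [s for s in base if hits[s] >= min_subsample_hits]
    if not kept:
        warnings.warn(
            "common-SNP strategy: no SNP shared between the full run and the "
            "subsample runs", stacklevel=2,
        )
    score = {}
    if full_run.scores is not None:
        score = dict(zip(full_run.scores["snp"], full_run.scores["score"]))
    kept.sort(key=lambda s: (-hits[s], -score.get(s, 0.0), s))
    return CandidateSet(
        snps=kept,
        provenance="common",
        scores=pd.DataFrame(
            {"snp": kept, "score": [float(hits[s]) for s in kept]}
        ),
    )
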