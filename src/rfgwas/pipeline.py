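"""End-to-end orchestration: simulate or ingest, BLUP, deregress, QC,
random-forest selection, stepwise regression with the permutation bias
test, and LD-window annotation.

Every stage persists its artifact under the output directory, so any stage
can be re-run from its predecessor's files.  All randomness derives from a
single master seed: stage k uses ``np.random.default_rng([seed, k])`` (or
the first 31 bits of ``SeedSequence([seed, k])`` where an integer seed is
required), so runs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import forest, ld
from .blup import AnimalModelDesign, deregress_ebv, solve_animal_model
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, build_a_matrix
from .qc import impute_median, qc_filter
from .simulate import (
    HerdPedigree,
    SimConfig,
    sample_architecture,
    select_genotyping_subset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from .stepwise import forward_stepwise, permutation_r2

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

log = logging.getLogger("rfgwas")

_S_SUBSET = 11
_S_RF_FULL = 12
_S_SUBSAMPLES = 13
_S_PERM = 14


def _int_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one input mode is active: ``sim`` (synthetic herd) or the three
    ``*_path`` fields (PLINK prefix, pedigree TSV, phenotype TSV).  Forest
    size defaults to a desk-scale 500 trees; raise ``n_trees`` to 5000 for
    a full-scale run.
    """

    # inputs
    sim: SimConfig | None = None
    genotypes_prefix: str | None = None
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    genotyped_animals: list[str] | None = None
    features_path: str | None = None  # BED (genes) or GFF3 intervals
    # model
    heritability: float = 0.16
    factors: list[str] = field(
        default_factory=lambda: ["sex", "year", "herd", "genetic_group"]
    )
    covariates: list[str] = field(default_factory=lambda: ["age_days"])
    deregression_c: float = 0.5
    reliability_floor: float = 0.1
    # genotyping subset (simulation mode)
    n_genotyped: int = 400
    sex_split: tuple[int, int] | None = None
    family_cap: int = 30
    # QC
    sample_call_rate_min: float = 0.90
    snp_call_rate_min: float = 0.90
    maf_min: float = 0.01
    het_sd_limit: float = 3.0
    # random forest selection
    n_trees: int = 500
    mtry_fraction: float = 0.10
    selection_fraction: float = 0.01
    importance_measure: str = "permutation"
    # subsampling / strategies
    strategy: str = "both"  # 'highest1' | 'common' | 'both'
    n_subsamples: int = 10
    subsample_size: int | None = None  # default: half the genotyped animals
    min_subsample_hits: int = 1
    # stepwise + permutation
    sl_entry: float = 0.15
    sl_stay: float = 0.15
    n_permutations: int = 1000
    permutation_statistic: str = "adjusted"
    # annotation
    window_half_width_bp: int = 250_000
    # bookkeeping
    out_dir: str = "rfgwas_run"
    seed: int = 0

    def validate(self) -> None:
        sim_mode = self.sim is not None
        path_mode = self.genotypes_prefix is not None
        if sim_mode == path_mode:
            raise ValueError("exactly one of sim config or input paths must be set")
        if path_mode and (self.pedigree_path is None or self.phenotypes_path is None):
            raise ValueError("path mode needs pedigree_path and phenotypes_path")
        if self.strategy not in {"highest1", "common", "both"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.heritability < 1:
            raise ValueError("heritability must be in (0, 1)")


@dataclass
class RunReport:
    """Structured results of one pipeline run."""

    stage_counts: dict
    parameters: dict
    strategy_results: pd.DataFrame  # strategy, n_candidates, n_final, pct_debv_variance, perm_mean, perm_sd
    snp_table: pd.DataFrame  # strategy, snp, chrom, pos, pct_debv, features
    out_dir: str


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        log.info("stage simulate: generating synthetic herd")
        herd = simulate_pedigree(config.sim)
        genotypes = simulate_genotypes(herd, config.sim)
        arch = sample_architecture(genotypes, config.sim)
        phenotypes = simulate_phenotypes(herd, genotypes, arch, config.sim)
        return herd, genotypes, phenotypes, arch
    log.info("stage ingest: reading %s", config.genotypes_prefix)
    genotypes = GenotypeMatrix.from_plink(config.genotypes_prefix)
    ped = Pedigree.from_tsv(config.pedigree_path)
    phenotypes = pd.read_csv(config.phenotypes_path, sep="\t", dtype={"animal": str})
    meta = ped.to_frame()
    meta["role"] = "other"
    meta.loc[meta["animal"].isin(phenotypes["animal"]), "role"] = "cohort"
    for col in ("sex", "year", "herd", "genetic_group"):
        meta[col] = "-"
    meta["age_days"] = np.nan
    herd = HerdPedigree(pedigree=ped, meta=meta)
    return herd, genotypes, phenotypes, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis under one configuration.

    Stage order: inputs -> A matrix & animal-model BLUP -> deregression ->
    genotype QC -> median imputation -> two-step random-forest selection
    (full sample, plus low-kinship subsamples for the common-SNP strategy)
    -> stepwise regression with sequential partial R² -> permutation bias
    test -> LD windows and interval annotation.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    counts: dict = {}

    herd, genotypes, phenotypes, arch = _load_inputs(config)
    ped = herd.pedigree
    counts["pedigree_animals"] = len(ped)
    counts["phenotyped"] = len(phenotypes)
    ped.to_tsv(out / "pedigree.tsv")
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if arch is not None:
        arch.to_tsv(out / "truth_qtl.tsv")

    # --- BLUP ------------------------------------------------------------
    log.info("stage blup: solving the animal model (h2=%.2f)", config.heritability)
    lam = (1.0 - config.heritability) / config.heritability
    design = AnimalModelDesign(
        factors=config.factors, covariates=config.covariates,
        animal_col="animal", value_col="phenotype",
    )
    bvs = solve_animal_model(phenotypes, design, ped, variance_ratio=lam)
    bvs.to_tsv(out / "ebv.tsv")

    # --- genotyping subset ----------------------------------------------
    if config.genotyped_animals is not None:
        genotyped = [str(a) for a in config.genotyped_animals]
    elif config.sim is not None:
        cohort = herd.cohort
        n = min(config.n_genotyped, len(cohort))
        split = config.sex_split or (n // 2, n - n // 2)
        genotyped = select_genotyping_subset(
            cohort, bvs, herd, n=n, sex_split=split, family_cap=config.family_cap
        )
    else:
        genotyped = list(genotypes.samples)
    counts["genotyped_selected"] = len(genotyped)

    # --- deregression -----------------------------------------------------
    log.info("stage deregress: %d genotyped animals", len(genotyped))
    dereg = deregress_ebv(
        bvs, ped, c=config.deregression_c, heritability=config.heritability,
        reliability_floor=config.reliability_floor, animals=genotyped,
    )
    dereg.to_tsv(out / "debv.tsv")
    kept = dereg.included()
    debv = kept.set_index("animal")["debv"]

    # --- QC and imputation ------------------------------------------------
    g = genotypes.subset_samples([a for a in genotyped if a in set(kept["animal"])])
    g, qc_report = qc_filter(
        g,
        sample_call_rate_min=config.sample_call_rate_min,
        snp_call_rate_min=config.snp_call_rate_min,
        maf_min=config.maf_min,
        het_sd_limit=config.het_sd_limit,
    )
    qc_report.to_tsv(out / "qc_report.tsv")
    log.info("stage qc: %s", qc_report.summary())
    counts["qc_samples"] = g.n_samples
    counts["qc_snps"] = g.n_snps
    g = impute_median(g)
    g.to_plink(out / "genotypes_qc")
    y = debv.loc[g.samples].to_numpy(float)

    # --- random-forest selection -----------------------------------------
    log.info(
        "stage select: two-step RF on %d animals x %d SNPs (%d trees)",
        g.n_samples, g.n_snps, config.n_trees,
    )
    full_run = forest.two_step_select(
        g, y,
        fraction=config.selection_fraction,
        n_trees=config.n_trees,
        mtry_fraction=config.mtry_fraction,
        seed=_int_seed(config.seed, _S_RF_FULL),
        measure=config.importance_measure,
    )
    full_run.provenance = "highest-1%"
    full_run.to_tsv(out / "candidates_highest1.tsv")
    counts["stage1_snps"] = len(full_run.stage1 or [])
    counts["highest1_candidates"] = len(full_run)

    strategies: dict[str, forest.CandidateSet] = {}
    if config.strategy in {"highest1", "both"}:
        strategies["highest1"] = full_run
    if config.strategy in {"common", "both"}:
        A = build_a_matrix(ped)
        size = config.subsample_size or max(2, len(g.samples) // 2)
        plan = forest.build_subsamples(
            A, g.samples, n_subsamples=config.n_subsamples, size=size,
            seed=_int_seed(config.seed, _S_SUBSAMPLES),
        )
        runs = []
        for k, animals in enumerate(plan.subsamples):
            gs = g.subset_samples(animals)
            ys = debv.loc[gs.samples].to_numpy(float)
            runs.append(
                forest.two_step_select(
                    gs, ys,
                    fraction=config.selection_fraction,
                    n_trees=config.n_trees,
                    mtry_fraction=config.mtry_fraction,
                    seed=_int_seed(config.seed, 100 + k),
                    measure=config.importance_measure,
                )
            )
        common = forest.common_snp_strategy(
            full_run, runs, min_subsample_hits=config.min_subsample_hits
        )
        common.to_tsv(out / "candidates_common.tsv")
        strategies["common"] = common
        counts["common_candidates"] = len(common)

    # --- stepwise + permutation + annotation ------------------------------
    features = None
    if config.features_path:
        fp = str(config.features_path)
        features = (
            ld.read_gff3(fp) if fp.endswith((".gff", ".gff3")) else ld.read_bed(fp)
        )

    strat_rows = []
    snp_rows = []
    for name, cand in strategies.items():
        if len(cand) == 0:
            log.warning("strategy %s: empty candidate set; skipping model fit", name)
            strat_rows.append((name, 0, 0, 0.0, np.nan, np.nan))
            continue
        sub = g.subset_snps(cand.snps)
        X = pd.DataFrame(sub.dosages, columns=sub.snps["snp"].astype(str))
        model = forward_stepwise(y, X, sl_entry=config.sl_entry, sl_stay=config.sl_stay)
        perm = permutation_r2(
            y, X[model.entered] if model.entered else np.empty((len(y), 0)),
            n_permutations=config.n_permutations,
            statistic=config.permutation_statistic,
            seed=_int_seed(config.seed, _S_PERM),
        )
        strat_rows.append(
            (
                name, len(cand), len(model.entered),
                100.0 * model.total_r2, perm.mean, perm.sd,
            )
        )
        if model.entered:
            sel = sub.snps.set_index("snp").loc[model.entered]
            windows = ld.snp_windows(
                sel.reset_index()[["snp", "chrom", "pos"]],
                half_width_bp=config.window_half_width_bp,
            )
            windows.to_csv(out / f"windows_{name}.tsv", sep="\t", index=False)
            ann = (
                ld.annotate_windows(windows, features)
                if features is not None
                else pd.DataFrame(columns=["snp", "feature", "kind", "chrom", "overlap_bp"])
            )
            feat_by_snp = ann.groupby("snp")["feature"].apply(
                lambda s: ",".join(sorted(set(s)))
            )
            for snp, r2_inc in zip(model.entered, model.partial_r2):
                snp_rows.append(
                    (
                        name, snp, str(sel.at[snp, "chrom"]), int(sel.at[snp, "pos"]),
                        100.0 * r2_inc, feat_by_snp.get(snp, ""),
                    )
                )
        log.info(
            "strategy %s: %d candidates -> %d final SNPs, %.2f%% of dEBV "
            "variance, permutation %s",
            name, len(cand), len(model.entered), 100.0 * model.total_r2, perm,
        )

    strategy_results = pd.DataFrame(
        strat_rows,
        columns=["strategy", "n_candidates", "n_final", "pct_debv_variance",
                 "perm_mean", "perm_sd"],
    )
    snp_table = pd.DataFrame(
        snp_rows, columns=["strategy", "snp", "chrom", "pos", "pct_debv", "features"]
    ).sort_values(["strategy", "pct_debv"], ascending=[True, False]).reset_index(drop=True)

    counts["runtime_s"] = round(time.time() - t0, 2)
    params = asdict(config)
    params["sim"] = asdict(config.sim) if config.sim is not None else None
    report = RunReport(
        stage_counts=counts,
        parameters=params,
        strategy_results=strategy_results,
        snp_table=snp_table,
        out_dir=str(out),
    )
    write_report(report, out)
    return report


def write_report(report: RunReport, out_dir) -> None:
    """Write the summary TSV, per-SNP TSV, and the machine-readable manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.strategy_results.to_csv(out / "summary.tsv", sep="\t", index=False)
    report.snp_table.to_csv(out / "snp_report.tsv", sep="\t", index=False)
    manifest = {
        "parameters": report.parameters,
        "stage_counts": report.stage_counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
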