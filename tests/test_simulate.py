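"""Generator contracts: pedigree structure, Mendelian gene dropping,
heritability realisation, and the genotyping-subset rule."""

import numpy as np
import pandas as pd
import pytest

from rfgwas import SimConfig
from rfgwas.blup import BreedingValueSet
from rfgwas.simulate import (
    TraitArchitecture,
    sample_architecture,
    select_genotyping_subset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def test_cohort_size_bounds(small_herd, small_config):
    """Each cohort animal has a sire among the main sires; sizes in range."""
    lo, hi = small_config.offspring_per_sire_range
    meta = small_herd.meta
    sires = set(meta.loc[meta["role"] == "sire", "animal"])
    cohort = meta[meta["role"] == "cohort"]
    assert sires == set(cohort["sire"].unique()) or set(cohort["sire"]) <= sires
    counts = cohort.groupby("sire").size()
    assert counts.between(lo, hi).all()
    assert small_config.n_sires * lo <= len(cohort) <= small_config.n_sires * hi


def test_degenerate_single_offspring():
    cfg = SimConfig(
        n_sires=1, offspring_per_sire_range=(1, 1), n_dams=2, n_other_sires=0,
        n_extra_pedigree_generations=0, n_chromosomes=1, snps_per_chromosome=100,
        seed=1,
    )
    herd = simulate_pedigree(cfg)
    assert len(herd.cohort) == 1


def test_pedigree_determinism(small_config):
    h1 = simulate_pedigree(small_config)
    h2 = simulate_pedigree(small_config)
    assert h1.pedigree.ids == h2.pedigree.ids
    pd.testing.assert_frame_equal(h1.meta, h2.meta)


def test_invalid_config_raises():
    with pytest.raises(ValueError):
        SimConfig(n_sires=0).validate()
    with pytest.raises(ValueError):
        SimConfig(heritability=1.2).validate()
    with pytest.raises(ValueError):
        SimConfig(snps_per_chromosome=50).validate()
    with pytest.raises(ValueError):
        SimConfig(offspring_per_sire_range=(5, 2)).validate()


def test_mendelian_consistency(small_herd, small_genotypes):
    """No offspring dosage is impossible given its parents, at any SNP."""
    ped = small_herd.pedigree
    D = small_genotypes.dosages
    for i in range(len(ped)):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0 or di < 0:
            continue
        o, s, d = D[i], D[si], D[di]
        ok = ~(np.isnan(o) | np.isnan(s) | np.isnan(d))
        mn = (s[ok] == 2).astype(int) + (d[ok] == 2).astype(int)
        mx = 2 - ((s[ok] == 0).astype(int) + (d[ok] == 0).astype(int))
        assert ((o[ok] >= mn) & (o[ok] <= mx)).all()


def test_founder_maf_bound(small_herd, small_genotypes, small_config):
    """Founder minor allele frequencies respect the configured bound."""
    founders = np.flatnonzero(small_herd.pedigree.founder_mask)
    dos = small_genotypes.dosages[founders]
    p = np.nanmean(dos, axis=0) / 2
    assert np.minimum(p, 1 - p).min() >= small_config.maf_lower_bound - 1e-9


def test_no_recombination_limit():
    """Zero recombination, pool of one haplotype pair: every animal carries
    the founder patterns up to whole-chromosome Mendelian sampling."""
    cfg = SimConfig(
        n_sires=2, offspring_per_sire_range=(3, 3), n_dams=4, n_other_sires=0,
        n_extra_pedigree_generations=0, n_chromosomes=1, snps_per_chromosome=100,
        founder_haplotype_pool_size=2, recombination_rate_morgan_per_bp=0.0,
        missing_genotype_rate=0.0, maf_lower_bound=0.0, seed=5,
    )
    herd = simulate_pedigree(cfg)
    g = simulate_genotypes(herd, cfg)
    # with a 2-haplotype pool and no crossovers, every chromosome copy is one
    # of the two pool haplotypes, so each animal's dosage column pattern is a
    # sum of two pool haplotypes
    from rfgwas.simulate import _founder_pool

    rng = np.random.default_rng([cfg.seed, 2])
    pool, *_ = _founder_pool(cfg, rng)
    allowed = {
        tuple((pool[a] + pool[b]).tolist()) for a in range(2) for b in range(2)
    }
    for row in g.dosages:
        assert tuple(row.tolist()) in allowed


def test_parent_offspring_dosage_correlation():
    """Mean parent-offspring dosage correlation over >= 1,000 SNPs ~ 0.5."""
    cfg = SimConfig(
        n_sires=40, offspring_per_sire_range=(10, 25), n_dams=400, n_other_sires=10,
        n_extra_pedigree_generations=1, n_chromosomes=5, snps_per_chromosome=200,
        missing_genotype_rate=0.0, seed=11,
    )
    herd = simulate_pedigree(cfg)
    g = simulate_genotypes(herd, cfg)
    ped = herd.pedigree
    pairs = [(i, ped.sire_idx[i]) for i in range(len(ped)) if ped.sire_idx[i] >= 0]
    o = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    cors = []
    for j in range(g.n_snps):
        x, y = g.dosages[o, j], g.dosages[s, j]
        if x.std() > 0 and y.std() > 0:
            cors.append(np.corrcoef(x, y)[0, 1])
    assert len(cors) >= 1000
    assert np.mean(cors) == pytest.approx(0.5, abs=0.05)


def test_realized_heritability():
    """Realized h2 (var TBV / var of phenotype net of fixed effects) within
    +/- 0.05 of the 0.16 target at n >= 1,000 phenotyped animals."""
    cfg = SimConfig(
        n_sires=50, offspring_per_sire_range=(10, 30), n_dams=600, n_other_sires=20,
        n_extra_pedigree_generations=1, n_chromosomes=5, snps_per_chromosome=200,
        seed=11,
    )
    herd = simulate_pedigree(cfg)
    g = simulate_genotypes(herd, cfg)
    arch = sample_architecture(g, cfg)
    ph = simulate_phenotypes(herd, g, arch, cfg)
    assert len(ph) >= 1000
    vg = ph["tbv"].var()
    vp = (ph["tbv"] + ph["residual"]).var()
    assert vg / vp == pytest.approx(cfg.heritability, abs=0.05)


def test_null_genetics_limit(small_herd, small_genotypes, small_config):
    """No QTL, no polygenic variance: phenotypic variance = residual variance."""
    arch = TraitArchitecture(
        qtl_snp_ids=[], qtl_effects=np.array([]), polygenic_variance=0.0,
        residual_variance=2.0,
    )
    ph = simulate_phenotypes(small_herd, small_genotypes, arch, small_config)
    assert (ph["tbv"] == 0).all()
    resid_var = ph["residual"].var()
    assert resid_var == pytest.approx(2.0, rel=0.35)  # sampling at small n
    net = ph["phenotype"] - ph["cg_effect"] - small_config.age_covariate_slope * (
        ph["age_days"] - small_config.age_mean_days
    )
    assert net.var() == pytest.approx(resid_var, rel=1e-9)


def test_phenotype_determinism(small_herd, small_genotypes, small_config):
    arch = sample_architecture(small_genotypes, small_config)
    p1 = simulate_phenotypes(small_herd, small_genotypes, arch, small_config)
    p2 = simulate_phenotypes(small_herd, small_genotypes, arch, small_config)
    pd.testing.assert_frame_equal(p1, p2)


def test_unknown_qtl_raises(small_herd, small_genotypes, small_config):
    arch = TraitArchitecture(
        qtl_snp_ids=["nope"], qtl_effects=np.array([1.0]), polygenic_variance=0.5,
        residual_variance=5.25,
    )
    with pytest.raises(KeyError, match="nope"):
        simulate_phenotypes(small_herd, small_genotypes, arch, small_config)


def test_missingness_rate():
    cfg = SimConfig(
        n_sires=5, offspring_per_sire_range=(10, 10), n_dams=20, n_other_sires=0,
        n_extra_pedigree_generations=0, n_chromosomes=2, snps_per_chromosome=200,
        missing_genotype_rate=0.05, seed=9,
    )
    herd = simulate_pedigree(cfg)
    g = simulate_genotypes(herd, cfg)
    assert np.isnan(g.dosages).mean() == pytest.approx(0.05, abs=0.01)


# ---------------------------------------------------------------------------
# genotyping subset


def _fake_bvs(animals, rng):
    acc = rng.uniform(0.3, 0.9, len(animals))
    return BreedingValueSet(
        table=pd.DataFrame(
            {
                "animal": animals,
                "ebv": rng.normal(0, 1, len(animals)),
                "pev": 1 - acc**2,
                "accuracy": acc,
            }
        ),
        sigma_a=1.0,
        sigma_e=5.25,
    )


def test_subset_sex_split(small_herd):
    rng = np.random.default_rng(0)
    cohort = small_herd.cohort
    bvs = _fake_bvs(cohort, rng)
    meta = small_herd.meta.set_index("animal")
    n_m = int((meta.loc[cohort, "sex"] == "M").sum())
    n_f = len(cohort) - n_m
    want_m, want_f = min(20, n_m), min(20, n_f)
    out = select_genotyping_subset(
        cohort, bvs, small_herd, n=want_m + want_f, sex_split=(want_m, want_f)
    )
    sexes = meta.loc[out, "sex"]
    assert (sexes == "M").sum() == want_m
    assert (sexes == "F").sum() == want_f
    assert len(set(out)) == len(out)


def test_subset_identity(small_herd):
    """Selecting all candidates returns all candidates."""
    rng = np.random.default_rng(1)
    cohort = small_herd.cohort
    bvs = _fake_bvs(cohort, rng)
    meta = small_herd.meta.set_index("animal")
    n_m = int((meta.loc[cohort, "sex"] == "M").sum())
    out = select_genotyping_subset(
        cohort, bvs, small_herd, n=len(cohort), sex_split=(n_m, len(cohort) - n_m)
    )
    assert sorted(out) == sorted(cohort)


def test_subset_family_cap_one(small_herd):
    """Cap 1 forces at most one offspring per sire."""
    rng = np.random.default_rng(2)
    cohort = small_herd.cohort
    bvs = _fake_bvs(cohort, rng)
    meta = small_herd.meta.set_index("animal")
    by_sex = meta.loc[cohort, "sex"]
    sires_m = meta.loc[[a for a in cohort if by_sex[a] == "M"], "sire"].nunique()
    sires_f = meta.loc[[a for a in cohort if by_sex[a] == "F"], "sire"].nunique()
    k_m, k_f = min(3, sires_m), min(3, sires_f)
    out = select_genotyping_subset(
        cohort, bvs, small_herd, n=k_m + k_f, sex_split=(k_m, k_f), family_cap=1
    )
    assert meta.loc[out, "sire"].is_unique


def test_subset_infeasible_split_raises(small_herd):
    rng = np.random.default_rng(3)
    cohort = small_herd.cohort
    bvs = _fake_bvs(cohort, rng)
    with pytest.raises(ValueError, match="[Ii]nfeasible|sum"):
        select_genotyping_subset(cohort, bvs, small_herd, n=10, sex_split=(5, 4))
    with pytest.raises(ValueError, match="infeasible sex split"):
        select_genotyping_subset(
            cohort, bvs, small_herd, n=len(cohort), sex_split=(len(cohort), 0)
        )
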