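"""Shared fixtures: small synthetic herds and toy genotype matrices.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from rfgwas import GenotypeMatrix, Pedigree, SimConfig
from rfgwas.simulate import (
    sample_architecture,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_config():
    """Small herd: 10 sire families, 3 chromosomes, ~450 SNPs."""
    return SimConfig(
        n_sires=10,
        offspring_per_sire_range=(5, 15),
        n_dams=60,
        n_other_sires=5,
        n_extra_pedigree_generations=1,
        n_chromosomes=3,
        snps_per_chromosome=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_herd(small_config):
    return simulate_pedigree(small_config)


@pytest.fixture(scope="session")
def small_genotypes(small_herd, small_config):
    return simulate_genotypes(small_herd, small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_herd, small_genotypes, small_config):
    arch = sample_architecture(small_genotypes, small_config)
    return simulate_phenotypes(small_herd, small_genotypes, arch, small_config)


@pytest.fixture(scope="session")
def five_animal_pedigree():
    """Founders s, d; full sibs x, y; z is an offspring of the full-sib mating."""
    return Pedigree.from_records(
        [("s", "0", "0"), ("d", "0", "0"), ("x", "s", "d"), ("y", "s", "d"), ("z", "x", "y")]
    )


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random acyclic pedigree: each animal's parents drawn from its elders."""
    records = []
    for i in range(n):
        sire = dam = "0"
        if i >= 2 and rng.random() < 0.7:
            sire = f"A{rng.integers(i)}"
        if i >= 2 and rng.random() < 0.7:
            dam = f"A{rng.integers(i)}"
            if dam == sire:
                dam = "0"
        records.append((f"A{i}", sire, dam))
    return Pedigree.from_records(records)


def toy_genotypes(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Wrap a plain dosage array in a GenotypeMatrix with a simple map."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(p)],
            "chrom": chrom if chrom is not None else ["1"] * p,
            "pos": pos if pos is not None else [(j + 1) * 1000 for j in range(p)],
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(dosages, [f"a{i}" for i in range(n)], snps)
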