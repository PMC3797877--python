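import numpy as np
import pytest

from hierqst.design import PopulationInfo, StudyDesign, default_design
from hierqst.simulate import GenoSimParams, PhenoSimParams, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def design():
    """The standard 4-region / 21-population Alpine layout."""
    return default_design()


@pytest.fixture(scope="session")
def balanced_design():
    """Fully balanced 2-region / 2-pop / design for exact ANOVA checks."""
    pops = tuple(
        PopulationInfo(f"R{i}P{j}", f"R{i}", 1500.0 + 100 * j)
        for i in range(2)
        for j in range(2)
    )
    return StudyDesign(pops, families_per_population=2, plants_per_family=4)


@pytest.fixture(scope="session")
def pheno_table(design):
    return simulate_phenotypes(PhenoSimParams(design=design, seed=11))


@pytest.fixture(scope="session")
def geno_table(design):
    return simulate_genotypes(GenoSimParams(design=design, seed=12))


def random_toy_genotypes(rng: np.random.Generator, max_pops=4, max_ind=8, max_loci=3):
    """A small random genotype table spanning 2 regions, for oracle tests."""
    n_pops = rng.integers(3, max_pops + 1)
    pops = []
    for i in range(n_pops):
        region = "R1" if i < (n_pops + 1) // 2 else "R2"
        pops.append(PopulationInfo(f"P{i + 1}", region, 1000.0))
    design = StudyDesign(tuple(pops), 1, 1)
    n_loci = int(rng.integers(1, max_loci + 1))
    params = GenoSimParams(
        design=design,
        loci=n_loci,
        alleles_per_locus=int(rng.integers(2, 5)),
        theta_rt=float(rng.uniform(0, 0.5)),
        theta_sr=float(rng.uniform(0.05, 0.6)),
        individuals_per_population=int(rng.integers(3, max_ind + 1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return simulate_genotypes(params)
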