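"""Design-matched synthetic data with known ground truth.

The estimators in this package were built for a common-garden study whose
raw data are not redistributable, so every stage is exercised instead on
synthetic data that mirrors the sampling design: 4 phylogeographic regions,
21 populations, 6 open-pollinated seed families per population and 8 plants
per family, genotyped at 5 microsatellite loci.

Phenotypes follow the nested Gaussian random-effects model

    y = mu + region + population + family + slope * (x - mean(x))
        + clip_effect * 1[clipped] + residual

with each random effect drawn independently from a zero-mean normal with
its stated variance, resampled per level unit. Genotypes follow a
hierarchical balding-Nichols-style Dirichlet drift model: ancestral
allele frequencies per locus are drawn from a symmetric Dirichlet; region
frequencies from a Dirichlet centred on the ancestral vector with
concentration (1 - theta_RT) / theta_RT; population frequencies likewise
around their region with concentration (1 - theta_SR) / theta_SR; and
individuals are Hardy-Weinberg draws within populations. For a Dirichlet
with concentration c around its mean, E(F) = 1 / (1 + c), so the targets
theta_RT / theta_SR are the expected fixation indices at each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    LABEL_COLUMNS,
    DesignError,
    GenotypeTable,
    PhenotypeTable,
    StudyDesign,
    ValidationError,
    default_design,
)

__all__ = [
    "PhenoSimParams",
    "GenoSimParams",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_phenology",
    "PHENOLOGY_STAGES",
]

PHENOLOGY_STAGES = ("rosette", "bolting", "flowering", "ripening")


@dataclass
class PhenoSimParams:
    """Ground-truth generating values for one simulated trait.

    Variances are in squared trait units; ``slope`` is the effect of the
    initial rosette diameter (cm) on the trait; ``treatment_effect`` is
    added to every clipped plant.
    """

    design: StudyDesign = field(default_factory=default_design)
    sigma2_region: float = 2.0
    sigma2_population: float = 1.0
    sigma2_family: float = 1.0
    sigma2_residual: float = 4.0
    grand_mean: float = 0.0
    slope: float = 0.0
    covariate_mean: float = 5.0
    covariate_sd: float = 1.0
    treatment_effect: float = 0.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_region", "sigma2_population", "sigma2_family"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sigma2_residual <= 0:
            raise ValidationError("sigma2_residual must be > 0")
        if self.covariate_sd < 0:
            raise ValidationError("covariate_sd must be >= 0")


@dataclass
class GenoSimParams:
    """Drift-model parameters for simulated microsatellite genotypes."""

    design: StudyDesign = field(default_factory=default_design)
    loci: int = 5
    alleles_per_locus: int = 8
    theta_rt: float = 0.1
    theta_sr: float = 0.3
    ancestral_concentration: float = 1.0
    individuals_per_population: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_rt", "theta_sr"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if self.loci < 1 or self.alleles_per_locus < 2 or self.individuals_per_population < 1:
            raise ValidationError("loci >= 1, alleles_per_locus >= 2, individuals >= 1 required")
        if self.ancestral_concentration <= 0:
            raise ValidationError("ancestral_concentration must be > 0")


def simulate_phenotypes(params: PhenoSimParams) -> PhenotypeTable:
    """Draw one nested-Gaussian phenotype table under ``params``.

    Each family contributes ``plants_per_family`` plants split as evenly as
    possible between the control and clipped halves. Identical parameters
    and seed give identical tables.
    """
    rng = np.random.default_rng(params.seed)
    d = params.design
    rows: list[dict] = []
    region_eff = {r: rng.normal(0.0, np.sqrt(params.sigma2_region)) for r in d.regions}
    plant = 0
    for pop in d.populations:
        pop_eff = rng.normal(0.0, np.sqrt(params.sigma2_population))
        for fam in range(d.families_per_population):
            fam_eff = rng.normal(0.0, np.sqrt(params.sigma2_family))
            fam_id = f"{pop.population}-F{fam + 1}"
            n = d.plants_per_family
            treatments = ["control"] * ((n + 1) // 2) + ["clipped"] * (n // 2)
            for treat in treatments:
                # diameters are sizes: truncate the Gaussian draw at 0
                cov = max(rng.normal(params.covariate_mean, params.covariate_sd), 0.0)
                resid = rng.normal(0.0, np.sqrt(params.sigma2_residual))
                value = (
                    params.grand_mean
                    + region_eff[pop.region]
                    + pop_eff
                    + fam_eff
                    + params.slope * (cov - params.covariate_mean)
                    + params.treatment_effect * (treat == "clipped")
                    + resid
                )
                plant += 1
                rows.append(
                    {
                        "plant_id": f"P{plant:05d}",
                        "region": pop.region,
                        "population": pop.population,
                        "family": fam_id,
                        "treatment": treat,
                        "initial_diameter": cov,
                        params.trait_name: value,
                    }
                )
    df = pd.DataFrame(rows, columns=LABEL_COLUMNS + [params.trait_name])
    return PhenotypeTable(df, d, [params.trait_name])


def _dirichlet_around(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Dirichlet draw centred on ``mean`` with E(F) = theta; theta=0 copies."""
    if theta == 0.0:
        return mean.copy()
    c = (1.0 - theta) / theta
    alpha = np.maximum(c * mean, 1e-12)
    return rng.dirichlet(alpha)


def simulate_genotypes(params: GenoSimParams) -> GenotypeTable:
    """Draw codominant genotypes from the hierarchical Dirichlet drift model."""
    rng = np.random.default_rng(params.seed)
    d = params.design
    loci = [f"locus{i + 1}" for i in range(params.loci)]
    k = params.alleles_per_locus
    pop_freqs: dict[str, list[np.ndarray]] = {p.population: [] for p in d.populations}
    for _ in loci:
        ancestral = rng.dirichlet(np.full(k, params.ancestral_concentration))
        region_freqs = {r: _dirichlet_around(rng, ancestral, params.theta_rt) for r in d.regions}
        for pop in d.populations:
            pop_freqs[pop.population].append(
                _dirichlet_around(rng, region_freqs[pop.region], params.theta_sr)
            )
    n = params.individuals_per_population
    blocks: list[pd.DataFrame] = []
    ind = 0
    for pop in d.populations:
        block = {
            "individual_id": [f"I{ind + i + 1:05d}" for i in range(n)],
            "region": pop.region,
            "population": pop.population,
        }
        ind += n
        for li, locus in enumerate(loci):
            freqs = pop_freqs[pop.population][li]
            copies = rng.choice(k, size=2 * n, p=freqs) + 1  # HW: independent copies
            block[f"{locus}_1"] = copies[:n].astype(np.int64)
            block[f"{locus}_2"] = copies[n:].astype(np.int64)
        blocks.append(pd.DataFrame(block))
    df = pd.concat(blocks, ignore_index=True)
    return GenotypeTable(df, d, loci)


def simulate_phenology(
    design: StudyDesign,
    stage_probabilities: dict[str, np.ndarray],
    n_per_population: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial phenological-stage counts per population.

    ``stage_probabilities`` maps each region to a probability vector over
    :data:`PHENOLOGY_STAGES`; every population draws ``n_per_population``
    plants from its region's vector. Returns a populations x stages count
    table with ``region`` and ``population`` columns.
    """
    rng = np.random.default_rng(seed)
    for region in design.regions:
        if region not in stage_probabilities:
            raise ValidationError(f"no stage probabilities for region {region!r}")
        p = np.asarray(stage_probabilities[region], dtype=float)
        if p.shape != (len(PHENOLOGY_STAGES),) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValidationError(
                f"region {region!r}: stage probabilities must be a simplex over "
                f"{PHENOLOGY_STAGES}"
            )
    if n_per_population < 1:
        raise DesignError("n_per_population must be positive")
    rows = []
    for pop in design.populations:
        counts = rng.multinomial(n_per_population, np.asarray(stage_probabilities[pop.region]))
        rows.append(
            {"region": pop.region, "population": pop.population}
            | dict(zip(PHENOLOGY_STAGES, counts.tolist()))
        )
    return pd.DataFrame(rows)
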