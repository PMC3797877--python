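"""Study design and core data containers.

The analyses in this package operate on a nested sampling design:
phylogeographic regions contain populations, populations contain
open-pollinated seed families, and families contain individual plants
raised in a common garden. :class:`StudyDesign` records that hierarchy
together with per-population elevation and coordinates;
:class:`PhenotypeTable` and :class:`GenotypeTable` are thin validated
wrappers around :class:`pandas.DataFrame` carrying per-plant trait
measurements and per-individual codominant genotypes respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ValidationError",
    "PopulationInfo",
    "StudyDesign",
    "PhenotypeTable",
    "GenotypeTable",
    "default_design",
    "TREATMENTS",
    "LABEL_COLUMNS",
]

#: Allowed treatment labels for common-garden plants.
TREATMENTS = ("control", "clipped")

#: Label columns every phenotype table carries before trait columns.
LABEL_COLUMNS = ["plant_id", "region", "population", "family", "treatment", "initial_diameter"]


class DesignError(ValueError):
    """Raised when a study design is internally inconsistent."""


class ValidationError(ValueError):
    """Raised when a data table violates the design or format contract."""


@dataclass(frozen=True)
class PopulationInfo:
    """One sampled population: identifier, region membership and location."""

    population: str
    region: str
    elevation: float  # m a.s.l.
    longitude: float = float("nan")
    latitude: float = float("nan")


@dataclass(frozen=True)
class StudyDesign:
    """Nested region / population / family / plant sampling design.

    Parameters
    ----------
    populations
        One :class:`PopulationInfo` per sampled population. Every population
        belongs to exactly one region.
    families_per_population
        Number of open-pollinated seed families sampled per population.
    plants_per_family
        Number of seedlings raised per family (both treatment halves).
    """

    populations: tuple[PopulationInfo, ...]
    families_per_population: int = 6
    plants_per_family: int = 8

    def __post_init__(self) -> None:
        ids = [p.population for p in self.populations]
        if len(ids) != len(set(ids)):
            raise DesignError("duplicate population identifiers in design")
        if not self.populations:
            raise DesignError("design must contain at least one population")
        if self.families_per_population < 1 or self.plants_per_family < 1:
            raise DesignError("family and plant counts must be positive")
        for p in self.populations:
            if not np.isfinite(p.elevation) or p.elevation < 0:
                raise DesignError(f"population {p.population!r}: elevation must be finite and >= 0")

    @property
    def regions(self) -> list[str]:
        """Region identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p.region, None)
        return list(seen)

    @property
    def population_ids(self) -> list[str]:
        return [p.population for p in self.populations]

    def region_of(self, population: str) -> str:
        for p in self.populations:
            if p.population == population:
                return p.region
        raise DesignError(f"unknown population {population!r}")

    def populations_in(self, region: str) -> list[str]:
        return [p.population for p in self.populations if p.region == region]

    def elevations(self) -> pd.Series:
        """Per-population elevation (m a.s.l.), indexed by population id."""
        return pd.Series(
            {p.population: p.elevation for p in self.populations}, name="elevation"
        )

    def check_within_region_feasible(self) -> None:
        """Within-region indices need >= 2 populations in some region."""
        counts = pd.Series([p.region for p in self.populations]).value_counts()
        if (counts < 2).all():
            raise DesignError("no region has >= 2 populations; within-region indices undefined")

    def subset(self, populations: Sequence[str]) -> "StudyDesign":
        keep = [p for p in self.populations if p.population in set(populations)]
        return StudyDesign(tuple(keep), self.families_per_population, self.plants_per_family)


def _check_labels(df: pd.DataFrame, design: StudyDesign, context: str) -> None:
    known = set(design.population_ids)
    bad = sorted(set(df["population"].astype(str)) - known)
    if bad:
        raise ValidationError(f"{context}: unknown population(s) {bad!r} not in design")
    region_map = {p.population: p.region for p in design.populations}
    mismatch = df.loc[
        df["region"].astype(str) != df["population"].astype(str).map(region_map), "population"
    ]
    if len(mismatch):
        raise ValidationError(
            f"{context}: region label inconsistent with design for population(s) "
            f"{sorted(set(mismatch))!r}"
        )


@dataclass
class PhenotypeTable:
    """Per-plant trait measurements with nested origin labels.

    ``data`` holds one row per plant with the columns of
    :data:`LABEL_COLUMNS` followed by one numeric column per trait; missing
    trait values are ``NaN`` (written as ``NA`` on disk, never silently 0).
    """

    data: pd.DataFrame
    design: StudyDesign
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in LABEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table missing label column(s) {missing!r}")
        if not self.traits:
            self.traits = [c for c in self.data.columns if c not in LABEL_COLUMNS]
        if len(self.data):
            _check_labels(self.data, self.design, "phenotype table")
            bad = ~self.data["treatment"].isin(TREATMENTS)
            if bad.any():
                raise ValidationError(
                    f"invalid treatment label(s) {sorted(set(self.data.loc[bad, 'treatment']))!r}"
                )
        for t in self.traits:
            if not pd.api.types.is_numeric_dtype(self.data[t]):
                raise ValidationError(f"trait column {t!r} is not numeric")

    def __len__(self) -> int:
        return len(self.data)

    def subset_treatment(self, treatment: str) -> "PhenotypeTable":
        if treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {treatment!r}")
        return PhenotypeTable(
            self.data[self.data["treatment"] == treatment].reset_index(drop=True),
            self.design,
            list(self.traits),
        )

    def without_population(self, population: str) -> "PhenotypeTable":
        """Delete-one-population view used by the jackknife."""
        keep = self.data[self.data["population"] != population].reset_index(drop=True)
        remaining = [p for p in self.design.population_ids if p != population]
        return PhenotypeTable(keep, self.design.subset(remaining), list(self.traits))

    @property
    def populations(self) -> list[str]:
        return [p for p in self.design.population_ids if p in set(self.data["population"])]


@dataclass
class GenotypeTable:
    """Per-individual codominant genotypes at one or more loci.

    ``data`` has columns ``individual_id``, ``region``, ``population`` and,
    for each locus name ``L``, two integer allele columns ``L_1``/``L_2``.
    Allele codes are positive integers; 0 marks a missing copy, and a locus
    is missing for an individual iff both copies are 0.
    """

    data: pd.DataFrame
    design: StudyDesign
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in ("individual_id", "region", "population"):
            if c not in self.data.columns:
                raise ValidationError(f"genotype table missing column {c!r}")
        if not self.loci:
            allele_cols = [
                c for c in self.data.columns if c.endswith("_1") and f"{c[:-2]}_2" in self.data.columns
            ]
            self.loci = [c[:-2] for c in allele_cols]
        if not self.loci:
            raise ValidationError("genotype table declares no loci")
        for locus in self.loci:
            for slot in (1, 2):
                col = f"{locus}_{slot}"
                if col not in self.data.columns:
                    raise ValidationError(f"locus {locus!r} missing allele column {col!r}")
                vals = self.data[col]
                if not pd.api.types.is_integer_dtype(vals):
                    raise ValidationError(f"allele column {col!r} is not integer")
                if (vals < 0).any():
                    raise ValidationError(f"negative allele code in column {col!r}")
            a = self.data[f"{locus}_1"].to_numpy()
            b = self.data[f"{locus}_2"].to_numpy()
            half = (a == 0) != (b == 0)
            if half.any():
                raise ValidationError(
                    f"locus {locus!r}: individuals with exactly one missing allele copy; "
                    "a locus is missing iff both copies are 0"
                )
        if len(self.data):
            _check_labels(self.data, self.design, "genotype table")

    def __len__(self) -> int:
        return len(self.data)

    def without_population(self, population: str) -> "GenotypeTable":
        keep = self.data[self.data["population"] != population].reset_index(drop=True)
        remaining = [p for p in self.design.population_ids if p != population]
        return GenotypeTable(keep, self.design.subset(remaining), list(self.loci))

    @property
    def populations(self) -> list[str]:
        return [p for p in self.design.population_ids if p in set(self.data["population"])]

    def allele_counts(self, locus: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Per-population allele-copy counts at ``locus``.

        Returns ``(counts, alleles, populations)`` where ``counts[i, j]`` is
        the number of copies of allele ``alleles[j]`` scored in population
        ``populations[i]`` (missing copies excluded).
        """
        pops = self.populations
        a = self.data[f"{locus}_1"].to_numpy()
        b = self.data[f"{locus}_2"].to_numpy()
        copies = np.concatenate([a, b])
        pop_labels = np.concatenate([self.data["population"].to_numpy()] * 2)
        scored = copies > 0
        copies, pop_labels = copies[scored], pop_labels[scored]
        alleles = np.unique(copies)
        allele_idx = np.searchsorted(alleles, copies)
        pop_idx = pd.Categorical(pop_labels, categories=pops).codes.astype(np.int64)
        counts = np.bincount(
            pop_idx * len(alleles) + allele_idx, minlength=len(pops) * len(alleles)
        ).reshape(len(pops), len(alleles))
        return counts, alleles, pops


def default_design(seed: int | None = None) -> StudyDesign:
    """The 4-region / 21-population Alpine sampling layout used throughout.

    Four phylogeographic regions (Western Alps, Central Swiss Alps, Central
    Austrian Alps, South-eastern Alps) holding 6/5/4/6 populations, six seed
    families per population and eight plants per family. Elevations span the
    species' range (roughly 1000-2300 m a.s.l.), decreasing towards the
    south-east; coordinates are nominal west-to-east positions.
    """
    split = {"WA": 6, "CSA": 5, "CAA": 4, "SEA": 6}
    base_elev = {"WA": 2000.0, "CSA": 1900.0, "CAA": 1800.0, "SEA": 1200.0}
    rng = np.random.default_rng(seed if seed is not None else 20210923)
    pops: list[PopulationInfo] = []
    lon = 6.0
    for region, n in split.items():
        for k in range(n):
            elev = base_elev[region] + float(rng.integers(-300, 301))
            pops.append(
                PopulationInfo(
                    population=f"{region}{k + 1}",
                    region=region,
                    elevation=max(elev, 200.0),
                    longitude=round(lon, 2),
                    latitude=46.0 + float(rng.uniform(-0.8, 0.8)),
                )
            )
            lon += 0.45
    return StudyDesign(tuple(pops))
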