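"""Full analysis pipeline: variance components -> Q indices -> AMOVA ->
jackknife CIs -> selection calls, plus trait-elevation correlations and
phenology G tests. Produces the tables a differentiation study reports:
per-trait Q_RT/Q_SR with CIs, molecular F'_RT/F'_SR/F'_ST and G'_ST with
CIs, the per-trait selection regime at both hierarchical levels, and the
among- vs within-region comparison.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import varcomp as vc_mod
from .amova import amova_hierarchical, standardize
from .config import RunConfig
from .design import GenotypeTable, PhenotypeTable
from .qst import compute_q
from .resampling import IndexWithCI, classify_selection, compare_levels, jackknife
from .simulate import PHENOLOGY_STAGES
from .stats import correlate_elevation, g_test, holm_adjust, population_means

__all__ = ["q_with_ci", "molecular_with_ci", "run_pipeline", "correlation_table", "gtest_table"]

ARROW = {"diversifying": "up", "unifying": "down", "neutral": "ns"}
LEVEL_SYMBOL = {"greater": ">", "less": "<", "equal": "="}


def _q_estimator(trait: str, which: str, config: RunConfig):
    def est(table: PhenotypeTable) -> float:
        components = vc_mod.estimate(table, trait, config.variance_method, treatment="control")
        q = compute_q(components, config.family_structure, config.q_convention)
        return q.q_rt if which == "rt" else q.q_sr

    return est


def q_with_ci(
    table: PhenotypeTable, trait: str, config: RunConfig
) -> tuple[IndexWithCI, IndexWithCI]:
    """Jackknifed Q_RT and Q_SR for one trait."""
    q_rt = jackknife(
        _q_estimator(trait, "rt", config), table, name=f"Q_RT[{trait}]", z=config.z
    )
    q_sr = jackknife(
        _q_estimator(trait, "sr", config), table, name=f"Q_SR[{trait}]", z=config.z
    )
    return q_rt, q_sr


def molecular_with_ci(genotypes: GenotypeTable, config: RunConfig) -> dict[str, IndexWithCI]:
    """Jackknifed standardized molecular indices F'_RT, F'_SR, F'_ST, G'_ST."""

    def make(attr: str):
        def est(table: GenotypeTable) -> float:
            return float(getattr(standardize(table), attr))

        return est

    out = {}
    for name, attr in (
        ("F'_RT", "f_rt_std"),
        ("F'_SR", "f_sr_std"),
        ("F'_ST", "f_st_std"),
        ("G'_ST", "g_st_hedrick"),
    ):
        out[name] = jackknife(make(attr), genotypes, name=name, z=config.z)
    return out


def correlation_table(
    table: PhenotypeTable,
    traits: Sequence[str],
    subsets: dict[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Trait-elevation Pearson correlations, Holm-corrected per subset.

    Each population subset (column of the output) is its own family of
    tests across traits, mirroring how per-subset significance is starred.
    """
    design = table.design
    if subsets is None:
        subsets = {"all": design.population_ids}
    rows = []
    for label, pops in subsets.items():
        results = []
        for trait in traits:
            means = population_means(table, trait)
            results.append(correlate_elevation(means, design, subset=pops, label=label))
        adjusted = holm_adjust([r.p for r in results])
        for res, p_holm in zip(results, adjusted):
            rows.append(
                {
                    "trait": res.trait,
                    "subset": label,
                    "n_populations": res.n_populations,
                    "r": res.r,
                    "p": res.p,
                    "p_holm": p_holm,
                }
            )
    return pd.DataFrame(rows)


def gtest_table(phenology: pd.DataFrame) -> pd.DataFrame:
    """G tests of phenological-state composition.

    One among-regions test on the regions x stages table (populations
    pooled within region), then one populations x stages test per region.
    """
    stages = [s for s in PHENOLOGY_STAGES if s in phenology.columns]
    rows = []
    region_table = phenology.groupby("region", observed=True)[stages].sum()
    res = g_test(region_table.to_numpy())
    rows.append({"scope": "among_regions", "g": res.g, "df": res.df, "p": res.p})
    for region, block in phenology.groupby("region", observed=True):
        if len(block) < 2:
            continue
        try:
            res = g_test(block[stages].to_numpy())
        except Exception:
            continue  # a region with degenerate stage counts is skipped
        rows.append(
            {"scope": f"within_{region}", "g": res.g, "df": res.df, "p": res.p}
        )
    return pd.DataFrame(rows)


def run_pipeline(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeTable,
    config: RunConfig | None = None,
    traits: Sequence[str] | None = None,
    phenology: pd.DataFrame | None = None,
    subsets: dict[str, Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full differentiation analysis and return named result tables."""
    config = config or RunConfig()
    traits = list(traits or phenotypes.traits)

    vc_rows, q_rows, call_rows = [], [], []
    mol = molecular_with_ci(genotypes, config)
    for trait in traits:
        components = vc_mod.estimate(
            phenotypes, trait, config.variance_method, treatment="control"
        )
        vc_rows.append(
            {"trait": trait, "method": components.method, "n": components.n_plants}
            | {f"sigma2_{k}": v for k, v in components.as_dict().items()}
        )
        q_rt, q_sr = q_with_ci(phenotypes, trait, config)
        for iv in (q_rt, q_sr):
            q_rows.append(
                {
                    "index": iv.name,
                    "trait": trait,
                    "estimate": iv.estimate,
                    "lower": iv.lower,
                    "upper": iv.upper,
                    "se": iv.se,
                }
            )
        call_rt = classify_selection(q_rt, mol["F'_RT"], trait=trait, level="among_regions")
        call_sr = classify_selection(q_sr, mol["F'_SR"], trait=trait, level="within_regions")
        level_cmp = compare_levels(q_rt, q_sr)
        call_rows.append(
            {
                "trait": trait,
                "q_rt": q_rt.estimate,
                "q_rt_lower": q_rt.lower,
                "q_rt_upper": q_rt.upper,
                "among_regions": ARROW[call_rt.regime],
                "q_sr": q_sr.estimate,
                "q_sr_lower": q_sr.lower,
                "q_sr_upper": q_sr.upper,
                "within_regions": ARROW[call_sr.regime],
                "q_rt_vs_q_sr": LEVEL_SYMBOL[level_cmp],
            }
        )

    mol_rows = [
        {"index": name, "estimate": iv.estimate, "lower": iv.lower, "upper": iv.upper, "se": iv.se}
        for name, iv in mol.items()
    ]
    raw = amova_hierarchical(genotypes)
    mol_rows.extend(
        [
            {"index": "F_RT", "estimate": raw.f_rt, "lower": np.nan, "upper": np.nan, "se": np.nan},
            {"index": "F_SR", "estimate": raw.f_sr, "lower": np.nan, "upper": np.nan, "se": np.nan},
            {"index": "F_ST", "estimate": raw.f_st, "lower": np.nan, "upper": np.nan, "se": np.nan},
        ]
    )

    results: dict[str, pd.DataFrame] = {
        "variance_components": pd.DataFrame(vc_rows),
        "q_indices": pd.DataFrame(q_rows),
        "molecular_indices": pd.DataFrame(mol_rows),
        "selection_calls": pd.DataFrame(call_rows),
        "correlations": correlation_table(phenotypes, traits, subsets),
    }
    if phenology is not None:
        results["g_tests"] = gtest_table(phenology)
    return results
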