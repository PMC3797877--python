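"""Auxiliary statistics: family-mean aggregation, trait-elevation
correlations with sequential Holm-Bonferroni correction, G tests on
phenological-state tables, and the power transforms applied to skewed
traits before variance-component estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import PhenotypeTable, StudyDesign, ValidationError

__all__ = [
    "CorrelationResult",
    "GTestResult",
    "population_means",
    "correlate_elevation",
    "holm_adjust",
    "g_test",
    "power_transform",
]

log = logging.getLogger("hierqst")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of population trait means with elevation."""

    trait: str
    subset: str
    n_populations: int
    r: float
    p: float
    p_holm: float | None = None


@dataclass(frozen=True)
class GTestResult:
    """Log-likelihood-ratio goodness-of-fit / independence test."""

    g: float
    df: int
    p: float


def population_means(
    table: PhenotypeTable, trait: str, treatment: str | None = "control"
) -> pd.Series:
    """Two-stage population means: plants -> family means -> population mean.

    Families are weighted equally regardless of size, matching how the
    common-garden region and population summaries are built. Populations
    with no measured family are excluded with a warning.
    """
    work = table.subset_treatment(treatment) if treatment is not None else table
    df = work.data.dropna(subset=[trait])
    if df.empty:
        raise ValidationError(f"no usable rows for trait {trait!r}")
    fam_means = df.groupby(["population", "family"], observed=True)[trait].mean()
    pop_means = fam_means.groupby(level="population", observed=True).mean()
    missing = [p for p in work.design.population_ids if p not in pop_means.index]
    if missing:
        log.warning("population(s) %s have no data for trait %s; excluded", missing, trait)
    pop_means.name = trait
    return pop_means


def correlate_elevation(
    pop_means: pd.Series,
    design: StudyDesign,
    subset: Sequence[str] | None = None,
    label: str = "all",
) -> CorrelationResult:
    """Pearson r between population trait means and elevation of origin.

    ``subset`` restricts to a population set (e.g. one subspecies); the
    two-sided p-value comes from the t transformation with n - 2 df.
    """
    elev = design.elevations()
    pops = [p for p in (subset if subset is not None else list(pop_means.index)) if p in pop_means.index]
    if len(pops) < 3:
        raise ValidationError(f"correlation needs >= 3 populations with values, got {len(pops)}")
    x = elev.loc[pops].to_numpy(dtype=float)
    y = pop_means.loc[pops].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in trait means or elevation")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        trait=str(pop_means.name), subset=label, n_populations=len(pops),
        r=float(r), p=float(p),
    )


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Sequential Holm-Bonferroni step-down adjustment, original order."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return []
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adjusted]


def g_test(
    observed: np.ndarray | pd.DataFrame,
    expected: np.ndarray | None = None,
    *,
    ddof: int = 0,
    williams: bool = False,
) -> GTestResult:
    """G test: goodness of fit against ``expected``, or independence.

    With ``expected`` given, G = 2 sum O ln(O/E) over cells with O > 0 and
    df = cells - 1 - ddof. Without it, ``observed`` is a rows x columns
    contingency table tested for independence with df = (r-1)(c-1).
    Cells with expected 0 and observed 0 are dropped; expected 0 with
    observed > 0 is an error. ``williams`` applies Williams' continuity
    correction (off by default).
    """
    obs = np.asarray(observed, dtype=float)
    if (obs < 0).any():
        raise ValidationError("negative counts in contingency table")
    if expected is not None:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValidationError("observed and expected shapes differ")
        obs, exp = obs.ravel(), exp.ravel()
        keep = ~((exp == 0) & (obs == 0))
        obs, exp = obs[keep], exp[keep]
        if (exp == 0).any():
            raise ValidationError("expected count 0 with observed > 0")
        df = obs.size - 1 - ddof
    else:
        if obs.ndim != 2 or min(obs.shape) < 2:
            raise ValidationError("independence test needs a 2-D table with >= 2 rows and columns")
        # drop all-zero margins: those categories were never observed
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
        if obs.ndim != 2 or min(obs.shape) < 2:
            raise ValidationError("contingency table degenerate after dropping empty margins")
        total = obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        obs, exp = obs.ravel(), exp.ravel()
    if df < 1:
        raise ValidationError("G test has no degrees of freedom")
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    g = max(g, 0.0)
    if williams:
        n = obs.sum()
        q = 1.0 + (obs.size**2 - 1) / (6.0 * n * df) if n > 0 else 1.0
        g /= q
    p = float(sps.chi2.sf(g, df))
    return GTestResult(g=g, df=int(df), p=min(max(p, np.nextafter(0, 1)), 1.0))


def power_transform(values: np.ndarray | Sequence[float], exponent: float) -> np.ndarray:
    """Elementwise power transform used to normalise skewed count traits.

    The standard exponents in this pipeline are 0.656 (number of leaves),
    0.620 (number of flowers) and 0.331 (above-ground biomass). Values
    must be >= 0; missing values pass through unchanged.
    """
    arr = np.asarray(values, dtype=float)
    finite = ~np.isnan(arr)
    if (arr[finite] < 0).any():
        raise ValidationError("power transform requires nonnegative values")
    out = arr.copy()
    out[finite] = np.power(arr[finite], exponent)
    return out
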