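"""Jackknife-over-populations confidence intervals and selection calls.

Confidence intervals for every differentiation index come from the
delete-one-population jackknife: the estimator is recomputed with each
population removed in turn, pseudovalues theta_i* = n theta_hat -
(n-1) theta_(-i) are formed, and the CI is the pseudovalue mean plus or
minus z times their standard error. Indices defined on [0, 1] have their
intervals clamped to that range after construction.

Selection regimes follow from CI overlap. For a trait at a given level,
Q above the neutral molecular interval indicates diversifying selection
(trait differentiation beyond drift), Q below it indicates unifying
selection, and overlapping intervals are read as neutral — drift alone
suffices. The same interval logic compares Q_RT with Q_SR to ask whether
differentiation was stronger among regions (glacial survival) or among
populations within regions (postglacial recolonisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .design import ValidationError

__all__ = [
    "IndexWithCI",
    "SelectionCall",
    "jackknife",
    "classify_selection",
    "compare_levels",
]

log = logging.getLogger("hierqst")


class _PopulationData(Protocol):
    @property
    def populations(self) -> list[str]: ...

    def without_population(self, population: str) -> "_PopulationData": ...


@dataclass(frozen=True)
class IndexWithCI:
    """A differentiation index with its jackknife interval."""

    name: str
    estimate: float
    se: float
    lower: float
    upper: float
    n_deleted: int

    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


@dataclass(frozen=True)
class SelectionCall:
    """Per-trait, per-level selection regime from Q-vs-F' interval overlap."""

    trait: str
    level: str  # among_regions | within_regions
    regime: str  # diversifying | unifying | neutral
    q: IndexWithCI
    f: IndexWithCI

    @property
    def symbol(self) -> str:
        return {"diversifying": "up", "unifying": "down", "neutral": "ns"}[self.regime]


def jackknife(
    estimator: Callable[[object], float],
    data: _PopulationData,
    *,
    name: str = "index",
    z: float = 1.96,
    clamp: tuple[float, float] | None = (0.0, 1.0),
    max_failure_fraction: float = 0.2,
) -> IndexWithCI:
    """Delete-one-population jackknife CI for ``estimator(data)``.

    Subsets on which the estimator fails (for instance a region losing its
    last population) are skipped with a warning and n adjusted; more than
    ``max_failure_fraction`` failures is an error. Needs >= 3 populations.
    """
    pops = data.populations
    if len(pops) < 3:
        raise ValidationError(f"jackknife needs >= 3 populations, got {len(pops)}")
    theta_hat = float(estimator(data))
    leave_one_out = []
    failures = []
    for pop in pops:
        try:
            leave_one_out.append(float(estimator(data.without_population(pop))))
        except Exception as exc:  # estimator undefined on this subset
            failures.append(pop)
            log.warning("jackknife: estimator failed without population %s (%s)", pop, exc)
    if len(failures) > max_failure_fraction * len(pops):
        raise ValidationError(
            f"jackknife: estimator failed on {len(failures)}/{len(pops)} delete-one subsets"
        )
    n = len(leave_one_out)
    theta = np.asarray(leave_one_out)
    # theta_hat + (n-1)(theta_hat - theta_i): exact when the estimator is constant
    pseudo = theta_hat + (n - 1) * (theta_hat - theta)
    if np.all(pseudo == pseudo[0]):  # constant estimator: CI is the point
        centre, se = float(pseudo[0]), 0.0
    else:
        centre = float(pseudo.mean())
        se = float(pseudo.std(ddof=1) / np.sqrt(n))
    lower, upper = centre - z * se, centre + z * se
    if clamp is not None:
        lo, hi = clamp
        lower, upper = max(lower, lo), min(upper, hi)
    return IndexWithCI(name=name, estimate=theta_hat, se=se, lower=lower, upper=upper, n_deleted=n)


def classify_selection(q: IndexWithCI, f: IndexWithCI, *, trait: str = "", level: str = "") -> SelectionCall:
    """Classify the selection regime from the Q and F' intervals.

    diversifying iff the Q interval lies wholly above the F' interval;
    unifying iff wholly below; neutral otherwise.
    """
    for iv in (q, f):
        if not (np.isfinite(iv.lower) and np.isfinite(iv.upper)):
            raise ValidationError(f"non-finite interval for {iv.name!r}")
    if q.lower > f.upper:
        regime = "diversifying"
    elif q.upper < f.lower:
        regime = "unifying"
    else:
        regime = "neutral"
    return SelectionCall(trait=trait, level=level, regime=regime, q=q, f=f)


def compare_levels(q_rt: IndexWithCI, q_sr: IndexWithCI) -> str:
    """Compare among-region with within-region trait differentiation.

    Returns ``"greater"`` iff the Q_RT interval lies wholly above the Q_SR
    interval, ``"less"`` iff wholly below, else ``"equal"``.
    """
    for iv in (q_rt, q_sr):
        if not (np.isfinite(iv.lower) and np.isfinite(iv.upper)):
            raise ValidationError(f"non-finite interval for {iv.name!r}")
    if q_rt.lower > q_sr.upper:
        return "greater"
    if q_rt.upper < q_sr.lower:
        return "less"
    return "equal"
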