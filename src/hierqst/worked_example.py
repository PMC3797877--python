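"""Worked example: hierarchical differentiation estimates for seven
common-garden traits of an alpine bellflower, with jackknife 95% CIs.

These published point estimates and intervals for Q_RT (differentiation
among four phylogeographic regions) and Q_SR (among 21 populations within
regions), together with the standardized molecular indices F'_RT and
F'_SR from five microsatellite loci, drive the selection-classification
example in the README and the comparison subcommand's documentation. Each
entry is (estimate, lower, upper).
"""

from __future__ import annotations

from .resampling import IndexWithCI

__all__ = ["Q_INTERVALS", "F_INTERVALS", "intervals"]

Q_INTERVALS: dict[str, dict[str, tuple[float, float, float]]] = {
    "leaf_ratio_2008": {"rt": (0.093, 0.079, 0.107), "sr": (0.213, 0.097, 0.329)},
    "leaf_ratio_2009": {"rt": (0.000, 0.000, 0.000), "sr": (0.202, 0.101, 0.303)},
    "number_of_leaves": {"rt": (0.062, 0.052, 0.072), "sr": (0.092, 0.015, 0.170)},
    "number_of_inflorescences": {"rt": (0.106, 0.097, 0.116), "sr": (0.030, 0.022, 0.038)},
    "max_inflorescence_height": {"rt": (0.371, 0.355, 0.387), "sr": (0.230, 0.157, 0.304)},
    "number_of_flowers": {"rt": (0.097, 0.030, 0.164), "sr": (0.269, 0.013, 0.526)},
    "above_ground_biomass": {"rt": (0.750, 0.698, 0.802), "sr": (0.121, 0.000, 0.284)},
}

F_INTERVALS: dict[str, tuple[float, float, float]] = {
    "rt": (0.092, 0.080, 0.105),
    "sr": (0.499, 0.488, 0.510),
}

#: Published selection calls and level comparisons for the same traits.
EXPECTED_CALLS: dict[str, tuple[str, str, str]] = {
    "leaf_ratio_2008": ("neutral", "unifying", "equal"),
    "leaf_ratio_2009": ("unifying", "unifying", "less"),
    "number_of_leaves": ("unifying", "unifying", "equal"),
    "number_of_inflorescences": ("neutral", "unifying", "greater"),
    "max_inflorescence_height": ("diversifying", "unifying", "greater"),
    "number_of_flowers": ("neutral", "neutral", "equal"),
    "above_ground_biomass": ("diversifying", "unifying", "greater"),
}


def intervals(name: str, triple: tuple[float, float, float]) -> IndexWithCI:
    """Wrap a printed (estimate, lower, upper) triple as an IndexWithCI."""
    est, lo, hi = triple
    return IndexWithCI(name=name, estimate=est, se=float("nan"), lower=lo, upper=hi, n_deleted=0)
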