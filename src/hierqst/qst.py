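"""Hierarchical quantitative-trait differentiation indices Q_RT and Q_SR.

Q_ST-style indices compare among-group genetic variance with within-group
additive variance. In the two-region-level design used here, Q_RT measures
trait differentiation among phylogeographic regions and Q_SR among
populations within regions. The within-group additive variance V_A is
recovered from the seed-family variance via the family-structure
multiplier k: open-pollinated maternal families of an outcrossing,
self-incompatible species approximate half-sibs (k = 4); full-sib families
give k = 2; k = 1 uses the family variance as-is (broad sense).

Because hierarchical Q formulas differ in what "within" means at the
region level, both conventions are offered and reported side by side:

``total_within``  Q_RT = s2_R / (s2_R + 2 (s2_P + V_A))
``pooled``        Q_RT = s2_R / (s2_R + 2 V_A)

with Q_SR = s2_P / (s2_P + 2 V_A) under either convention. With a single
region, Q_SR reduces to the classical two-level Q_ST. The residual
variance never enters any index: in a common garden it is environmental
plus within-family segregation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import ValidationError
from .varcomp import VarianceComponents

__all__ = ["QIndices", "additive_within", "compute_q"]

_K = {"half_sib": 4.0, "full_sib": 2.0, "broad_sense": 1.0}


@dataclass(frozen=True)
class QIndices:
    """Hierarchical Q estimates for one trait."""

    trait: str
    q_rt: float
    q_sr: float
    k: float
    convention: str


def additive_within(vc: VarianceComponents, structure: str = "half_sib") -> float:
    """Within-population additive variance V_A = k * sigma2_family."""
    if structure not in _K:
        raise ValidationError(f"unknown family structure {structure!r}")
    return _K[structure] * vc.sigma2_family


def compute_q(
    vc: VarianceComponents,
    structure: str = "half_sib",
    convention: str = "total_within",
) -> QIndices:
    """Convert variance components into Q_RT and Q_SR.

    Raises when a denominator is 0 (constant trait at that level of the
    hierarchy), since the index is then undefined rather than 0 or 1.
    """
    if convention not in ("total_within", "pooled"):
        raise ValidationError(f"unknown hierarchical-Q convention {convention!r}")
    v_a = additive_within(vc, structure)
    s_r, s_p = vc.sigma2_region, vc.sigma2_population
    den_sr = s_p + 2.0 * v_a
    den_rt = s_r + 2.0 * (s_p + v_a) if convention == "total_within" else s_r + 2.0 * v_a
    if den_rt <= 0 or den_sr <= 0:
        raise ValidationError("index undefined for constant trait (zero denominator)")
    return QIndices(
        trait=vc.trait,
        q_rt=s_r / den_rt,
        q_sr=s_p / den_sr,
        k=_K[structure],
        convention=convention,
    )
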