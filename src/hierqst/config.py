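"""Run configuration: estimation options, CI multiplier, seed, conventions."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .design import ValidationError

__all__ = ["RunConfig"]

_FAMILY_STRUCTURES = ("half_sib", "full_sib", "broad_sense")
_VARIANCE_METHODS = ("anova", "reml")
_NEGATIVE_POLICIES = ("truncate",)
_Q_CONVENTIONS = ("total_within", "pooled")


@dataclass
class RunConfig:
    """Options controlling estimation and index conventions.

    Attributes
    ----------
    family_structure
        Relation between seed-family variance and additive variance:
        ``half_sib`` (open-pollinated maternal families of an outcrosser,
        V_A = 4 sigma2_family, the default), ``full_sib`` (V_A = 2 sigma2_family)
        or ``broad_sense`` (V_A = sigma2_family).
    variance_method
        ``anova`` (method of moments, exact expected-sums-of-squares
        coefficients) or ``reml`` (EM-REML; recommended for unbalanced data).
    z
        CI half-width multiplier on the jackknife SE; 1.96 gives nominal
        95% normal-approximation intervals.
    seed
        Seed for every stochastic step of a run.
    negative_policy
        How negative variance-component solutions are handled; only
        ``truncate`` (set to 0 and flag) is offered.
    q_convention
        Hierarchical Q denominator convention, ``total_within`` or ``pooled``.
    """

    family_structure: str = "half_sib"
    variance_method: str = "anova"
    z: float = 1.96
    seed: int = 0
    negative_policy: str = "truncate"
    q_convention: str = "total_within"

    def __post_init__(self) -> None:
        if self.family_structure not in _FAMILY_STRUCTURES:
            raise ValidationError(f"family_structure must be one of {_FAMILY_STRUCTURES}")
        if self.variance_method not in _VARIANCE_METHODS:
            raise ValidationError(f"variance_method must be one of {_VARIANCE_METHODS}")
        if self.negative_policy not in _NEGATIVE_POLICIES:
            raise ValidationError(f"negative_policy must be one of {_NEGATIVE_POLICIES}")
        if self.q_convention not in _Q_CONVENTIONS:
            raise ValidationError(f"q_convention must be one of {_Q_CONVENTIONS}")
        if not self.z > 0:
            raise ValidationError("z multiplier must be > 0")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path}: expected a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"config file {path}: unknown key(s) {sorted(unknown)!r}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
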