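"""Reserve-need estimation from a reference matrix.

The rule of thumb implemented here: regional reserve need is a fixed
fraction (default 20 %) of the area considered *management
incompatible* — forest that conventional even-aged, low-retention
forestry cannot reproduce.  Incompatible area is forest at or above the
final-felling age (110 years in the Swedish analysis) and, optionally,
younger forest maintained by gap or cohort dynamics, whose structural
complexity clear-cut rotations likewise cannot maintain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .age_distributions import rebin_shares
from .exceptions import InvalidParameterError
from .reference_models import DynamicsType, ReferenceMatrix

__all__ = ["CompatibilityRule", "ReserveEstimate", "incompatible_share", "reserve_need",
           "estimate_reserve"]


@dataclass(frozen=True)
class CompatibilityRule:
    """What counts as management-incompatible, and the reserve fraction.

    ``age_threshold`` is inclusive (age ≥ threshold is incompatible).
    With ``include_gap_cohort_younger`` set, gap- and cohort-dynamics
    area below the threshold is also counted.  ``reserve_fraction`` is
    the protected share of incompatible area (default 20 %, the level
    associated with minimally functional habitat networks).
    """

    age_threshold: float = 110.0
    include_gap_cohort_younger: bool = False
    reserve_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not self.age_threshold >= 0:
            raise InvalidParameterError("age threshold must be >= 0")
        if not 0.0 < self.reserve_fraction <= 1.0:
            raise InvalidParameterError("reserve fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ReserveEstimate:
    """A reserve-need record for one model × rule combination."""

    model: str
    rule: CompatibilityRule
    incompatible_share: float
    reserve_need: float

    @property
    def incompatible_percent(self) -> float:
        return round(100.0 * self.incompatible_share)

    @property
    def reserve_percent(self) -> float:
        """Reserve need rounded to the nearest percent (headline figure)."""
        return round(100.0 * self.reserve_need)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "age_threshold": self.rule.age_threshold,
            "include_gap_cohort_younger": self.rule.include_gap_cohort_younger,
            "reserve_fraction": self.rule.reserve_fraction,
            "incompatible_share": self.incompatible_share,
            "reserve_need": self.reserve_need,
            "reserve_percent": self.reserve_percent,
        }


def _column_share_at_or_above(matrix: ReferenceMatrix, dynamics: DynamicsType,
                              threshold: float) -> float:
    """Share of one dynamics column at or above the age threshold.

    Splits the column at the threshold with the uniform-within-bin rule;
    a threshold inside the unbounded bin raises RebinError.
    """
    bounds = list(matrix.scheme.boundaries)
    if threshold not in bounds:
        bounds = sorted(set(bounds) | {float(threshold)})
    new = rebin_shares(matrix.scheme.boundaries, matrix.column(dynamics), bounds)
    return float(sum(s for s, b in zip(new, bounds) if b >= threshold))


def incompatible_share(matrix: ReferenceMatrix, rule: CompatibilityRule | None = None) -> float:
    """Management-incompatible area share under ``rule``.

    Always counts all area with age ≥ threshold (all dynamics types);
    with the flag set, adds gap- and cohort-dynamics area below it.
    """
    rule = rule if rule is not None else CompatibilityRule()
    total = 0.0
    for d in DynamicsType:
        ge = _column_share_at_or_above(matrix, d, rule.age_threshold)
        total += ge
        if rule.include_gap_cohort_younger and d in (DynamicsType.GD, DynamicsType.CD):
            total += float(matrix.column(d).sum()) - ge
    return total


def reserve_need(share: float, rule: CompatibilityRule | None = None) -> float:
    """Reserve need as ``reserve_fraction × incompatible share``."""
    rule = rule if rule is not None else CompatibilityRule()
    if not 0.0 <= share <= 1.0:
        raise InvalidParameterError("incompatible share must lie in [0, 1]")
    return rule.reserve_fraction * share


def estimate_reserve(matrix: ReferenceMatrix, rule: CompatibilityRule | None = None,
                     model: str = "") -> ReserveEstimate:
    """Full-record convenience wrapper: classify, then apply the fraction."""
    rule = rule if rule is not None else CompatibilityRule()
    share = incompatible_share(matrix, rule)
    return ReserveEstimate(model=model, rule=rule, incompatible_share=share,
                           reserve_need=reserve_need(share, rule))
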