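"""Equilibrium age-class mathematics for time-since-disturbance models.

Under a stationary disturbance regime in which every stand is disturbed
independently with the same interval distribution, the landscape-level
distribution of time since last disturbance ("stand age") has a closed
form: the fraction of area older than ``t`` equals the survivor function
of the inter-disturbance interval distribution evaluated at ``t`` (for
the constant-hazard case) or, more generally, the normalised integral of
that survivor function.  This module implements the two classical model
families used for boreal fire regimes — the negative exponential
(constant hazard) and the Weibull (age-dependent hazard) — plus the
bookkeeping needed to express their predictions as discrete age-class
distributions and to convert between age-class schemes.

Conventions
-----------
* Ages are in years; bins are half-open ``[a, b)`` with the last bin
  unbounded (``a+``).
* A Weibull regime is parameterised by its *mean* return interval and a
  shape; the scale is derived so that the mean matches, which makes the
  two families directly comparable at equal fire cycles.
* Re-binning assumes ages are uniformly distributed within each source
  bin.  The unbounded bin carries no internal age information, so a new
  boundary strictly inside it is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

from .exceptions import InvalidParameterError, RebinError, SchemeMismatchError

__all__ = [
    "DisturbanceRegime",
    "AgeClassScheme",
    "AgeClassDistribution",
    "REFERENCE_SCHEME",
    "SWEDISH_NFI_SCHEME",
    "survivor_fraction",
    "interval_fraction_below_mean",
    "age_class_shares",
    "average_distributions",
    "rebin",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DisturbanceRegime:
    """A stationary stand-replacing disturbance regime.

    Parameters
    ----------
    family:
        ``"negative_exponential"`` (constant hazard) or ``"weibull"``
        (power-law hazard).
    mean_return_interval:
        Mean time between disturbances at a point, in years (the "fire
        cycle"); must be positive.
    shape:
        Weibull shape parameter ``c`` (> 0).  ``c = 1`` reduces exactly
        to the negative exponential; ``c > 1`` means hazard increasing
        with stand age.  Ignored for the negative exponential family.
        The default of 2.0 is a conventional mid-range choice for
        boreal fire-interval data and is deliberately configurable: the
        shape is a modelling assumption, not an estimated constant.
    """

    family: str
    mean_return_interval: float
    shape: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in ("negative_exponential", "weibull"):
            raise InvalidParameterError(f"unknown regime family {self.family!r}")
        if not self.mean_return_interval > 0:
            raise InvalidParameterError(
                f"mean_return_interval must be > 0, got {self.mean_return_interval}"
            )
        if not self.shape > 0:
            raise InvalidParameterError(f"shape must be > 0, got {self.shape}")

    @property
    def weibull_scale(self) -> float:
        """Scale ``b`` such that the Weibull mean equals the return interval.

        ``mean = b * Γ(1 + 1/c)``, hence ``b = λ / Γ(1 + 1/c)``.
        """
        return self.mean_return_interval / _gamma(1.0 + 1.0 / self.shape)

    def survivor_fraction(self, t):
        """Equilibrium fraction of area with stand age ≥ ``t`` years."""
        return survivor_fraction(self, t)


def survivor_fraction(regime: DisturbanceRegime, t):
    """P(stand age ≥ t) at equilibrium under ``regime``.

    Negative exponential: ``exp(−t/λ)``.  Weibull: ``exp(−(t/b)^c)`` with
    the scale ``b`` derived from the mean return interval.  Accepts scalar
    or array ``t``; ages must be non-negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("stand age t must be >= 0")
    if regime.family == "negative_exponential":
        out = np.exp(-t_arr / regime.mean_return_interval)
    else:
        out = np.exp(-((t_arr / regime.weibull_scale) ** regime.shape))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def interval_fraction_below_mean(regime: DisturbanceRegime) -> float:
    """Fraction of inter-disturbance intervals shorter than the mean interval.

    For the negative exponential this is the classical ``1 − e^{−1} =
    0.632``; for a Weibull with shape ``c`` it is
    ``1 − exp(−Γ(1+1/c)^c)``, which decreases with ``c`` toward
    ``1 − exp(−e^{−γ}) ≈ 0.430`` as the interval distribution
    concentrates at its mean.
    """
    if regime.family == "negative_exponential":
        return float(1.0 - np.exp(-1.0))
    c = regime.shape
    return float(1.0 - np.exp(-(_gamma(1.0 + 1.0 / c) ** c)))


def _default_labels(boundaries: Sequence[float]) -> tuple[str, ...]:
    labels = []
    bounds = list(boundaries)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if float(lo).is_integer() and float(hi).is_integer():
            labels.append(f"{int(lo)}-{int(hi) - 1}")
        else:
            labels.append(f"[{lo:g},{hi:g})")
    last = bounds[-1]
    labels.append(f"{int(last)}+" if float(last).is_integer() else f">={last:g}")
    return tuple(labels)


@dataclass(frozen=True)
class AgeClassScheme:
    """Ordered half-open age bins ``[b0,b1), [b1,b2), …, [bk, ∞)``.

    ``boundaries`` are the left edges; the first must be 0 and they must
    be strictly increasing.  ``labels`` default to ``"0-74"``-style
    strings.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.boundaries)
        object.__setattr__(self, "boundaries", bounds)
        if len(bounds) < 1:
            raise InvalidParameterError("scheme needs at least one boundary")
        if bounds[0] != 0.0:
            raise InvalidParameterError("first boundary must be 0")
        if any(b2 <= b1 for b1, b2 in zip(bounds[:-1], bounds[1:])):
            raise InvalidParameterError("boundaries must be strictly increasing")
        if self.labels is None:
            object.__setattr__(self, "labels", _default_labels(bounds))
        else:
            labels = tuple(self.labels)
            if len(labels) != len(bounds):
                raise InvalidParameterError("need exactly one label per bin")
            object.__setattr__(self, "labels", labels)

    @property
    def n_classes(self) -> int:
        return len(self.boundaries)

    @property
    def widths(self) -> np.ndarray:
        """Bin widths in years; the last (unbounded) bin is ``inf``."""
        edges = np.append(self.boundaries, np.inf)
        return np.diff(edges)

    def midpoint(self, i: int) -> float:
        """Midpoint age of finite bin ``i`` (undefined for the last bin)."""
        if i == self.n_classes - 1:
            raise InvalidParameterError("the unbounded bin has no midpoint")
        return 0.5 * (self.boundaries[i] + self.boundaries[i + 1])

    def index_of(self, age: float) -> int:
        """Index of the bin containing ``age``."""
        if age < 0:
            raise InvalidParameterError("age must be >= 0")
        return int(np.searchsorted(self.boundaries, age, side="right") - 1)

    def bin_counts(self, ages: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        """Total weight (default: count) of ``ages`` per bin."""
        edges = np.append(self.boundaries, np.inf)
        counts, _ = np.histogram(np.asarray(ages, dtype=float), bins=edges, weights=weights)
        return counts


#: The three-class reference scheme: young 0–74, mid-aged 75–149, old ≥150.
REFERENCE_SCHEME = AgeClassScheme((0.0, 75.0, 150.0))

#: The national-inventory classification used in the Swedish case study:
#: young 0–109 (below the 110-year final-felling age), mid 110–149, old ≥150.
SWEDISH_NFI_SCHEME = AgeClassScheme((0.0, 110.0, 150.0))


@dataclass(frozen=True)
class AgeClassDistribution:
    """Area shares per age class, summing to one."""

    scheme: AgeClassScheme
    shares: tuple[float, ...]

    def __post_init__(self) -> None:
        shares = tuple(float(s) for s in self.shares)
        object.__setattr__(self, "shares", shares)
        if len(shares) != self.scheme.n_classes:
            raise InvalidParameterError("need exactly one share per bin")
        arr = np.asarray(shares)
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise InvalidParameterError("shares must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise InvalidParameterError(f"shares must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.shares, dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_array(), index=list(self.scheme.labels), name="share")

    def share_at_or_above(self, age: float) -> float:
        """Share of area with age ≥ ``age`` (uniform splitting within bins)."""
        bounds = self.scheme.boundaries
        if age > bounds[-1]:
            raise RebinError(
                f"threshold {age} lies inside the unbounded bin (>= {bounds[-1]:g})"
            )
        total = 0.0
        edges = list(bounds) + [np.inf]
        for share, lo, hi in zip(self.shares, edges[:-1], edges[1:]):
            if age <= lo:
                total += share
            elif age < hi:  # finite bin split uniformly
                total += share * (hi - age) / (hi - lo)
        return total


def age_class_shares(regime: DisturbanceRegime, scheme: AgeClassScheme) -> AgeClassDistribution:
    """Equilibrium age-class distribution implied by ``regime`` on ``scheme``.

    The share of bin ``[a, b)`` is ``S(a) − S(b)`` and the last bin keeps
    the tail ``S(b_last)``, so shares always sum to one.
    """
    surv = np.array([survivor_fraction(regime, b) for b in scheme.boundaries])
    shares = np.empty(scheme.n_classes)
    shares[:-1] = surv[:-1] - surv[1:]
    shares[-1] = surv[-1]
    return AgeClassDistribution(scheme, tuple(shares))


def average_distributions(
    dists: Iterable[AgeClassDistribution],
    weights: Sequence[float] | None = None,
) -> AgeClassDistribution:
    """Area-weighted mixture of distributions sharing one scheme."""
    dists = list(dists)
    if not dists:
        raise InvalidParameterError("need at least one distribution")
    scheme = dists[0].scheme
    for d in dists[1:]:
        if d.scheme != scheme:
            raise SchemeMismatchError("all distributions must share one scheme")
    if weights is None:
        weights = np.full(len(dists), 1.0 / len(dists))
    w = np.asarray(weights, dtype=float)
    if len(w) != len(dists):
        raise InvalidParameterError("need one weight per distribution")
    if np.any(w < 0) or abs(w.sum() - 1.0) > _SUM_TOL:
        raise InvalidParameterError("weights must be non-negative and sum to 1")
    mixed = np.zeros(scheme.n_classes)
    for wi, d in zip(w, dists):
        mixed += wi * d.as_array()
    return AgeClassDistribution(scheme, tuple(mixed))


def rebin_shares(
    old_boundaries: Sequence[float],
    old_shares: Sequence[float],
    new_boundaries: Sequence[float],
) -> np.ndarray:
    """Redistribute (not necessarily normalised) bin masses onto new bins.

    Uniform-age-within-bin assumption; the unbounded source bin may not
    be split (any new boundary strictly above the last source boundary
    raises :class:`RebinError`).
    """
    old_b = [float(b) for b in old_boundaries]
    new_b = [float(b) for b in new_boundaries]
    last_src = old_b[-1]
    if any(b > last_src for b in new_b):
        raise RebinError(
            "new boundary inside the unbounded source bin: ages beyond "
            f"{last_src:g} carry no within-bin information"
        )
    out = np.zeros(len(new_b))
    old_edges = old_b + [np.inf]
    new_edges = new_b + [np.inf]
    for share, lo, hi in zip(old_shares, old_edges[:-1], old_edges[1:]):
        if not np.isfinite(hi):
            # whole unbounded mass lands in the new bin containing its start
            out[-1] += share  # guaranteed: no new boundary exceeds `lo`
            continue
        width = hi - lo
        for j, (nlo, nhi) in enumerate(zip(new_edges[:-1], new_edges[1:])):
            overlap = min(hi, nhi) - max(lo, nlo)
            if overlap > 0:
                out[j] += share * overlap / width
    return out


def rebin(dist: AgeClassDistribution, new_scheme: AgeClassScheme) -> AgeClassDistribution:
    """Convert a distribution to a new scheme, conserving total share."""
    shares = rebin_shares(dist.scheme.boundaries, dist.shares, new_scheme.boundaries)
    return AgeClassDistribution(new_scheme, tuple(shares))
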