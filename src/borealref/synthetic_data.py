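"""Synthetic stand tables emulating a regional forest inventory.

No stand-level inventory data ship with the package; instead this
module draws stand tables whose *marginal* structure matches the
northern-Sweden case study — site-type shares of 73/14/13 % (mesic,
moist-wet, dry-poor) and age-class shares of 78/13/9 % on the 0–109 /
110–149 / ≥150-year classification — so that every pipeline stage can
be exercised end to end.  Site type and age class are sampled
independently because only the marginals are reported; stand areas are
log-normal with a 10-ha median, a typical skew for managed boreal
holdings.  A second generator inverts a reference matrix (sampling
stands from the 9-cell joint distribution, tagged with their dynamics
type) for round-trip recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .age_distributions import AgeClassScheme, SWEDISH_NFI_SCHEME
from .exceptions import InvalidParameterError
from .landscape_simulator import Landscape
from .reference_models import DynamicsType, ReferenceMatrix

__all__ = [
    "CaseStudyProfile",
    "generate_landscape",
    "generate_natural_landscape",
    "estimate_matrix",
]

_SUM_TOL = 1e-9

#: Upper age assumed for sampling within the unbounded old class, in
#: years.  300 matches the reference renewal rotation implied by the
#: default 25/25/50 marginals.
DEFAULT_MAX_AGE = 300.0


@dataclass(frozen=True)
class CaseStudyProfile:
    """Marginal structure of the emulated regional stand table."""

    site_shares: Mapping[str, float] = field(
        default_factory=lambda: {"mesic": 0.73, "moist_wet": 0.14, "dry_poor": 0.13}
    )
    scheme: AgeClassScheme = SWEDISH_NFI_SCHEME
    age_shares: tuple[float, ...] = (0.78, 0.13, 0.09)
    area_median_ha: float = 10.0
    area_sigma: float = 0.8
    max_age: float = DEFAULT_MAX_AGE

    def __post_init__(self) -> None:
        if abs(sum(self.site_shares.values()) - 1.0) > _SUM_TOL:
            raise InvalidParameterError("site-type shares must sum to 1")
        if any(v < 0 for v in self.site_shares.values()):
            raise InvalidParameterError("site-type shares must be non-negative")
        if len(self.age_shares) != self.scheme.n_classes:
            raise InvalidParameterError("need one age share per scheme bin")
        if abs(sum(self.age_shares) - 1.0) > _SUM_TOL or any(
            s < 0 for s in self.age_shares
        ):
            raise InvalidParameterError("age shares must be non-negative and sum to 1")
        if self.max_age <= self.scheme.boundaries[-1]:
            raise InvalidParameterError("max_age must exceed the last class boundary")
        if self.area_median_ha <= 0 or self.area_sigma <= 0:
            raise InvalidParameterError("invalid stand-area distribution")


def _sample_ages(rng: np.random.Generator, scheme: AgeClassScheme,
                 class_idx: np.ndarray, max_age: float,
                 spacing: str = "random") -> np.ndarray:
    """Uniform ages within each sampled class (even spacing optional)."""
    edges = np.append(scheme.boundaries, max_age)
    lo = edges[class_idx]
    hi = edges[class_idx + 1]
    if spacing == "random":
        return lo + rng.random(class_idx.size) * (hi - lo)
    if spacing == "even":
        ages = np.empty(class_idx.size)
        for k in range(scheme.n_classes):
            members = np.flatnonzero(class_idx == k)
            m = members.size
            if m:
                ages[members] = edges[k] + (np.arange(m) + 0.5) / m * (edges[k + 1] - edges[k])
        return ages
    raise InvalidParameterError(f"unknown age spacing {spacing!r}")


def _sample_areas(rng: np.random.Generator, n: int, median: float, sigma: float) -> np.ndarray:
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=n)


def generate_landscape(
    profile: CaseStudyProfile | None = None,
    n_stands: int = 10_000,
    seed: int = 0,
) -> Landscape:
    """Draw a stand table from the case-study marginals.

    Per stand: site type and age class are independent categorical
    draws, age is uniform within its class (the old class is capped at
    ``profile.max_age``), area is log-normal.  Identical seeds give
    byte-identical tables.
    """
    profile = profile if profile is not None else CaseStudyProfile()
    if n_stands < 100:
        raise InvalidParameterError("need at least 100 stands for a stable table")
    rng = np.random.default_rng(seed)
    sites = list(profile.site_shares)
    site = rng.choice(sites, size=n_stands, p=[profile.site_shares[s] for s in sites])
    class_idx = rng.choice(profile.scheme.n_classes, size=n_stands, p=profile.age_shares)
    age = _sample_ages(rng, profile.scheme, class_idx, profile.max_age)
    area = _sample_areas(rng, n_stands, profile.area_median_ha, profile.area_sigma)
    return Landscape(age=age, area=area, site_type=site)


def generate_natural_landscape(
    matrix: ReferenceMatrix,
    n_stands: int,
    seed: int = 0,
    profile: CaseStudyProfile | None = None,
    quota: bool = False,
    equal_area: bool = False,
    age_spacing: str = "random",
    max_age: float = DEFAULT_MAX_AGE,
) -> Landscape:
    """Sample stands from the 9-cell joint distribution of a matrix.

    Each stand gets an (age class, dynamics type) cell — multinomial by
    default, or exact largest-remainder quotas with ``quota=True`` — an
    age uniform within its class, a site type from the case-study
    marginals and a log-normal (or unit, with ``equal_area=True``) area.
    Stands carry their dynamics type, so a matrix can be re-estimated
    from the output (see :func:`estimate_matrix`).
    """
    profile = profile if profile is not None else CaseStudyProfile()
    if n_stands < 1:
        raise InvalidParameterError("need at least one stand")
    rng = np.random.default_rng(seed)
    probs = matrix.cells.ravel()  # (age, dynamics) in row-major order
    if quota:
        raw = probs * n_stands
        counts = np.floor(raw).astype(int)
        remainder = n_stands - counts.sum()
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        counts[order[:remainder]] += 1
        cell_idx = np.repeat(np.arange(probs.size), counts)
    else:
        cell_idx = rng.choice(probs.size, size=n_stands, p=probs / probs.sum())
    class_idx = cell_idx // 3
    dyn_idx = cell_idx % 3
    dyn_names = np.array([d.name for d in (DynamicsType.GD, DynamicsType.ED, DynamicsType.CD)])
    age = _sample_ages(rng, matrix.scheme, class_idx, max_age, spacing=age_spacing)
    if equal_area:
        area = np.ones(n_stands)
    else:
        area = _sample_areas(rng, n_stands, profile.area_median_ha, profile.area_sigma)
    sites = list(profile.site_shares)
    site = rng.choice(sites, size=n_stands, p=[profile.site_shares[s] for s in sites])
    return Landscape(age=age, area=area, site_type=site,
                     dynamics=dyn_names[dyn_idx])


def estimate_matrix(landscape: Landscape, scheme: AgeClassScheme) -> ReferenceMatrix:
    """Re-estimate a reference matrix from a dynamics-tagged stand table.

    Cells are area-weighted (age class × dynamics type) shares; the
    round trip through :func:`generate_natural_landscape` recovers the
    input matrix up to sampling error.
    """
    if landscape.dynamics is None:
        raise InvalidParameterError("landscape stands carry no dynamics tags")
    cells = np.zeros((scheme.n_classes, 3))
    dyn_order = [d.name for d in (DynamicsType.GD, DynamicsType.ED, DynamicsType.CD)]
    class_idx = np.array([scheme.index_of(a) for a in landscape.age])
    for j, name in enumerate(dyn_order):
        mask = landscape.dynamics == name
        for i in range(scheme.n_classes):
            cells[i, j] = landscape.area[mask & (class_idx == i)].sum()
    return ReferenceMatrix(scheme, cells / landscape.area.sum())
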