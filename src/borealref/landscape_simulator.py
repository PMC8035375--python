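"""Stand-level stochastic disturbance simulator.

A non-spatial Monte-Carlo model: each stand is an independent point
process subject to up to three severity classes of disturbance per
year — stand-replacing (kills everything), partial (kills 25–75 % of
the canopy, creating a new cohort) and gap (kills under 25 %).  The
simulator's main role is as an independent oracle: with only
stand-replacing events at constant annual hazard ``1/λ``, the
stationary distribution of stand age must converge to the negative
exponential survivorship ``exp(−t/λ)``, which the closed-form module
predicts analytically.  Mixed regimes let one explore how partial and
gap disturbance shift the landscape toward old, structurally complex
forest without ever resetting the dominant cohort.

"Forest age" throughout is the age of the *dominant* cohort.  Partial
and gap events add a cohort and shrink the survivors proportionally;
dominance transfers to the new cohort only when it exceeds all
survivors combined — a killed fraction above one half — so
low-severity disturbance rejuvenates a stand only when it removes the
majority of the canopy.  This is the property that separates these
regimes from the classical stand-replacing picture: under the default
killed-fraction ranges (gap < 0.25, partial ≤ 0.5) non-replacing
events never move the dominant-cohort age at all, they only build
multi-cohort structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .age_distributions import AgeClassDistribution, AgeClassScheme, REFERENCE_SCHEME
from .exceptions import InvalidParameterError

__all__ = [
    "SeverityRegime",
    "SimConfig",
    "StandRecord",
    "Landscape",
    "SimulationResult",
    "simulate",
    "classify_dynamics",
    "equilibrium_check",
]

SEVERITIES = ("stand_replacing", "partial", "gap")

# cohorts below this surviving fraction are dropped (and the rest renormalised)
_PRUNE_FRACTION = 1e-4


@dataclass(frozen=True)
class SeverityRegime:
    """Annual per-stand hazards and killed-fraction ranges per severity class.

    Hazards are probabilities per stand per year (``1/return interval``).
    Killed fractions: stand-replacing is always 1.0; partial events draw
    uniformly from ``partial_killed_range`` ⊆ [0.25, 0.75); gap events
    from ``gap_killed_range`` ⊆ (0, 0.25).  The default partial range
    stops at 0.5 so that partial events never claim canopy majority and
    hence never reset the dominant-cohort age; widen it beyond 0.5 to
    study regimes where severe partial disturbance rejuvenates stands.
    """

    stand_replacing_hazard: float = 0.0
    partial_hazard: float = 0.0
    gap_hazard: float = 0.0
    partial_killed_range: tuple[float, float] = (0.25, 0.50)
    gap_killed_range: tuple[float, float] = (0.05, 0.25)

    def __post_init__(self) -> None:
        for name in ("stand_replacing_hazard", "partial_hazard", "gap_hazard"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.total_hazard > 1.0:
            raise InvalidParameterError("summed annual hazards exceed 1")
        lo, hi = self.partial_killed_range
        if not (0.25 <= lo <= hi < 0.75 + 1e-12):
            raise InvalidParameterError("partial killed fractions must lie in [0.25, 0.75)")
        lo, hi = self.gap_killed_range
        if not (0.0 < lo <= hi < 0.25 + 1e-12):
            raise InvalidParameterError("gap killed fractions must lie in (0, 0.25)")

    @property
    def total_hazard(self) -> float:
        return self.stand_replacing_hazard + self.partial_hazard + self.gap_hazard

    @property
    def longest_return_interval(self) -> float:
        """Longest mean return interval among active severity classes."""
        hazards = [h for h in (self.stand_replacing_hazard, self.partial_hazard,
                               self.gap_hazard) if h > 0]
        return max((1.0 / h for h in hazards), default=0.0)


@dataclass(frozen=True)
class SimConfig:
    """Run dimensions: stands, recorded years, burn-in, mandatory seed.

    ``burn_in=None`` defaults to ten times the longest mean return
    interval of the regime, enough for the age distribution to forget
    its bare-ground initial state.
    """

    n_stands: int
    years: int
    burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stands <= 0:
            raise InvalidParameterError("need at least one stand")
        if self.years < 0 or (self.burn_in is not None and self.burn_in < 0):
            raise InvalidParameterError("years and burn_in must be non-negative")

    def resolved_burn_in(self, regime: SeverityRegime) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return int(round(10.0 * regime.longest_return_interval))


@dataclass(frozen=True)
class StandRecord:
    """Snapshot of one stand: cohorts, dominant age and event history.

    ``cohorts`` are ``(age, surviving_fraction)`` pairs, oldest first,
    fractions summing to ~1.  ``events`` are ``(year, severity,
    killed_fraction)`` with years counted from the start of the recorded
    (post burn-in) period; ``history_years`` says how many trailing
    years the event record covers.
    """

    stand_id: str
    site_type: str
    area: float
    cohorts: tuple[tuple[float, float], ...]
    dominant_cohort_age: float
    events: tuple[tuple[int, str, float], ...] = ()
    history_years: int = 0


class Landscape:
    """A set of independent stands with ages, areas and optional history.

    The canonical exchange format is a stand-table CSV with columns
    ``stand_id, site_type, age_years, area_ha`` (plus ``dynamics_type``
    when stands are tagged).
    """

    def __init__(
        self,
        age: Sequence[float],
        area: Sequence[float] | None = None,
        site_type: Sequence[str] | None = None,
        stand_id: Sequence[str] | None = None,
        cohorts: list[list[tuple[float, float]]] | None = None,
        dynamics: Sequence[str] | None = None,
        events: list[list[tuple[int, str, float]]] | None = None,
        history_years: int = 0,
    ):
        self.age = np.asarray(age, dtype=float)
        n = self.age.size
        if n == 0:
            raise InvalidParameterError("a landscape needs at least one stand")
        if np.any(self.age < 0):
            raise InvalidParameterError("stand ages must be >= 0")
        self.area = (np.ones(n) if area is None else np.asarray(area, dtype=float))
        if self.area.size != n or np.any(self.area <= 0):
            raise InvalidParameterError("need one positive area per stand")
        self.site_type = (
            np.full(n, "mesic", dtype=object)
            if site_type is None
            else np.asarray(site_type, dtype=object)
        )
        self.stand_id = (
            np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)
            if stand_id is None
            else np.asarray(stand_id, dtype=object)
        )
        self.cohorts = cohorts  # None means single-cohort stands
        self.dynamics = None if dynamics is None else np.asarray(dynamics, dtype=object)
        self.events = events
        self.history_years = history_years

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.age.size

    @property
    def n_stands(self) -> int:
        return self.age.size

    @property
    def total_area(self) -> float:
        return float(self.area.sum())

    def stand(self, i: int) -> StandRecord:
        cohorts = (
            tuple(self.cohorts[i]) if self.cohorts is not None
            else ((float(self.age[i]), 1.0),)
        )
        events = tuple(self.events[i]) if self.events is not None else ()
        return StandRecord(
            stand_id=str(self.stand_id[i]),
            site_type=str(self.site_type[i]),
            area=float(self.area[i]),
            cohorts=cohorts,
            dominant_cohort_age=float(self.age[i]),
            events=events,
            history_years=self.history_years,
        )

    def __iter__(self) -> Iterator[StandRecord]:
        return (self.stand(i) for i in range(len(self)))

    # -- summaries ----------------------------------------------------------
    def age_class_distribution(self, scheme: AgeClassScheme = REFERENCE_SCHEME,
                               by_area: bool = True) -> AgeClassDistribution:
        """Empirical (area-weighted by default) age-class distribution."""
        weights = self.area if by_area else None
        counts = scheme.bin_counts(self.age, weights=weights)
        return AgeClassDistribution(scheme, tuple(counts / counts.sum()))

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "stand_id": self.stand_id,
                "site_type": self.site_type,
                "age_years": self.age,
                "area_ha": self.area,
            }
        )
        if self.dynamics is not None:
            df["dynamics_type"] = self.dynamics
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Landscape":
        return cls(
            age=df["age_years"].to_numpy(dtype=float),
            area=df["area_ha"].to_numpy(dtype=float),
            site_type=df["site_type"].to_numpy(dtype=object),
            stand_id=df["stand_id"].to_numpy(dtype=object),
            dynamics=(
                df["dynamics_type"].to_numpy(dtype=object)
                if "dynamics_type" in df.columns else None
            ),
        )

    @classmethod
    def from_csv(cls, path) -> "Landscape":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SimulationResult:
    """Trajectory of age-class shares plus the final landscape state."""

    trajectory: pd.DataFrame  # long format: year, bin, share
    landscape: Landscape
    scheme: AgeClassScheme

    def final_distribution(self) -> AgeClassDistribution:
        return self.landscape.age_class_distribution(self.scheme)


def simulate(
    config: SimConfig,
    regime: SeverityRegime,
    initial: Landscape | None = None,
    scheme: AgeClassScheme = REFERENCE_SCHEME,
    record_every: int = 10,
) -> SimulationResult:
    """Run the annual per-stand disturbance process.

    Each stand draws at most one event per year; severity is sampled by
    priority (stand-replacing, then partial, then gap) from the summed
    hazards, equivalent to competing risks at annual resolution.
    Stand-replacing events reset the stand to a single age-0 cohort;
    partial and gap events insert a new cohort with a killed fraction
    drawn from the regime's range and renormalise the survivors.  Event
    history is recorded after burn-in.  Identical configs (including the
    seed) give bit-identical trajectories.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stands
    burn_in = config.resolved_burn_in(regime)
    total_years = burn_in + config.years

    if initial is not None:
        if len(initial) != n:
            raise InvalidParameterError("initial landscape size must match n_stands")
        dom_est = -initial.age.copy()  # establishment year of dominant cohort
        area = initial.area.copy()
        site = initial.site_type.copy()
        stand_id = initial.stand_id.copy()
    else:
        dom_est = np.zeros(n)
        area = np.ones(n)
        site = np.full(n, "mesic", dtype=object)
        stand_id = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)

    track_cohorts = (regime.partial_hazard + regime.gap_hazard) > 0
    cohorts: list[list[list[float]]] | None = None
    if track_cohorts:
        # [est_year, fraction] per cohort, oldest first
        cohorts = [[[float(dom_est[i]), 1.0]] for i in range(n)]
    events: list[list[tuple[int, str, float]]] = [[] for _ in range(n)]

    h_sr = regime.stand_replacing_hazard
    h_pa = regime.partial_hazard
    h_ga = regime.gap_hazard

    records: list[tuple[int, np.ndarray]] = []
    edges = np.append(scheme.boundaries, np.inf)
    total_area = area.sum()

    def snapshot(year: int) -> np.ndarray:
        ages = year - dom_est
        counts, _ = np.histogram(ages, bins=edges, weights=area)
        return counts / total_area

    for year in range(1, total_years + 1):
        u = rng.random(n)
        sr_idx = np.flatnonzero(u < h_sr)
        pa_idx = np.flatnonzero((u >= h_sr) & (u < h_sr + h_pa))
        ga_idx = np.flatnonzero((u >= h_sr + h_pa) & (u < h_sr + h_pa + h_ga))

        if sr_idx.size:
            dom_est[sr_idx] = year
            if track_cohorts:
                for i in sr_idx:
                    cohorts[i] = [[float(year), 1.0]]
        for idx, sev, killed_range in (
            (pa_idx, "partial", regime.partial_killed_range),
            (ga_idx, "gap", regime.gap_killed_range),
        ):
            if idx.size == 0:
                continue
            killed = rng.uniform(killed_range[0], killed_range[1], idx.size)
            for i, f in zip(idx, killed):
                stand = cohorts[i]
                for coh in stand:
                    coh[1] *= 1.0 - f
                stand.append([float(year), float(f)])
                kept = [c for c in stand if c[1] >= _PRUNE_FRACTION]
                if kept:
                    norm = sum(c[1] for c in kept)
                    for c in kept:
                        c[1] /= norm
                    cohorts[i] = kept
                stand = cohorts[i]
                if f > 0.5:
                    # the new cohort holds the canopy majority: dominance transfers
                    dom_est[i] = year
                elif not any(c[0] == dom_est[i] for c in stand):
                    # dominant cohort eroded below the pruning floor;
                    # fall back to the largest fraction, ties to the oldest
                    best = max(range(len(stand)), key=lambda k: (stand[k][1], -stand[k][0]))
                    dom_est[i] = stand[best][0]
                if year > burn_in:
                    events[i].append((year - burn_in, sev, float(f)))
        if year > burn_in:
            for i in sr_idx:
                events[i].append((year - burn_in, "stand_replacing", 1.0))
            if (year - burn_in) % record_every == 0 or year == total_years:
                records.append((year - burn_in, snapshot(year)))
    if config.years == 0:
        records.append((0, snapshot(total_years)))

    final_cohorts = None
    if track_cohorts:
        final_cohorts = [
            [(float(total_years - est), frac) for est, frac in stand]
            for stand in cohorts
        ]
    landscape = Landscape(
        age=total_years - dom_est,
        area=area,
        site_type=site,
        stand_id=stand_id,
        cohorts=final_cohorts,
        events=events,
        history_years=config.years,
    )
    traj = pd.DataFrame(
        [
            {"year": yr, "bin": lab, "share": s}
            for yr, shares in records
            for lab, s in zip(scheme.labels, shares)
        ]
    )
    return SimulationResult(trajectory=traj, landscape=landscape, scheme=scheme)


def classify_dynamics(stand: StandRecord, window: float) -> "DynamicsType":
    """Classify a stand's dynamics type from its recent event history.

    Even-aged (ED) if any stand-replacing event fell inside the trailing
    ``window`` years; else cohort (CD) if at least one partial event;
    else gap (GD).  Raises if the recorded history is shorter than the
    window.
    """
    from .reference_models import DynamicsType  # local import avoids a cycle

    if stand.history_years < window:
        raise InvalidParameterError(
            f"event history covers {stand.history_years} years, need {window}"
        )
    cutoff = stand.history_years - window
    severities = {sev for year, sev, _ in stand.events if year > cutoff}
    if "stand_replacing" in severities:
        return DynamicsType.ED
    if "partial" in severities:
        return DynamicsType.CD
    return DynamicsType.GD


def equilibrium_check(
    simulated: AgeClassDistribution,
    analytic: AgeClassDistribution,
    n_stands: int,
) -> pd.DataFrame:
    """Per-bin z-scores of a simulated distribution against an analytic one.

    The standard error is binomial, ``sqrt(p(1−p)/n)`` with ``p`` the
    analytic share.  Degenerate bins (p exactly 0 or 1) get z = 0 when
    the simulation agrees exactly and ±inf otherwise.
    """
    if simulated.scheme != analytic.scheme:
        raise InvalidParameterError("distributions must share one scheme")
    sim = simulated.as_array()
    ana = analytic.as_array()
    se = np.sqrt(ana * (1.0 - ana) / n_stands)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            se > 0,
            (sim - ana) / np.where(se > 0, se, 1.0),
            np.where(sim == ana, 0.0, np.inf * np.sign(sim - ana + 1e-300)),
        )
    return pd.DataFrame(
        {
            "bin": list(simulated.scheme.labels),
            "simulated": sim,
            "analytic": ana,
            "z": z,
        }
    )
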