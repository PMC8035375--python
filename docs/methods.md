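# Methods

This note documents the models implemented in `borealref`, the
assumptions behind their defaults, and the design choices made where
the underlying science leaves the construction open.

## Equilibrium time-since-disturbance models

Under a stationary disturbance regime in which every stand is disturbed
independently at constant hazard `1/λ`, the landscape-level
distribution of time since the last stand-replacing disturbance is
negative exponential: the share of area older than `t` years is

    S(t) = exp(−t/λ),

with `λ` the mean return interval ("fire cycle", years).  The Weibull
generalisation `S(t) = exp(−(t/b)^c)` allows the hazard to rise
(`c > 1`) or fall (`c < 1`) with stand age.  `borealref` parameterises
the Weibull by its *mean* return interval; the scale is derived as
`b = λ / Γ(1 + 1/c)` so the two families are comparable at equal fire
cycles.  `c = 1` reduces exactly to the negative exponential (verified
as a property test).  The default shape `c = 2.0` is a conventional
mid-range value for boreal fire-interval data; it is an assumption, not
an estimate, and every consumer accepts an override.

The fraction of inter-disturbance intervals shorter than the mean is
`1 − e^{−1} ≈ 0.632` for the exponential and `1 − exp(−Γ(1+1/c)^c)` for
the Weibull.  Note the large-shape limit is `1 − exp(−e^{−γ}) ≈ 0.430`
(γ Euler's constant), not 0.5: the Weibull concentrates asymmetrically
around its mean.  The closed form is cross-checked against a seeded
sampling oracle in the tests.

### Age-class schemes and re-binning

Age classes are half-open bins `[a, b)` with an unbounded last bin.
Two schemes matter in practice: the reference classification (young
0–74, mid-aged 75–149, old ≥150) and the national-inventory
classification (young 0–109, mid 110–149, old ≥150, with 110 the
Swedish final-felling age).  Conversion between schemes assumes ages
are **uniformly distributed within each source bin**; a new boundary
strictly inside the unbounded bin is an error because the old-forest
tail carries no internal age information.  Under this rule re-binning
conserves total mass to 1e−9 and is exact whenever the new boundaries
are a superset of the old ones.  The uniform-within-bin assumption is
what yields the case-study splits 36.7 / 13.3 / 50 % (young / mid /
old at the 110-year boundary) from 25 / 25 / 50 %.

## The revised reference matrix

The revised reference model allocates landscape area over three age
classes × three dynamics types — gap (GD), even-aged (ED) and cohort
(CD) dynamics.  Construction rules, in order:

1. Fix the age marginals (default 25 / 25 / 50 %, i.e. at least half
   the landscape old) and the dynamics marginals (default equal
   thirds).
2. For each non-stand-replacing type (GD, CD), put a fraction
   (default 2/3) of its total in the old class.
3. Split the remainder between young and mid **in proportion to the
   age-class midpoints** (37.5 : 112.5 = 1 : 3 for the default 75-year
   boundary).  This operationalises "increases linearly with age": the
   within-class share is proportional to the class's mean age.  Other
   readings of linearity (e.g. equal increments) fail to reproduce the
   2.8 / 8.3 / 22.2 % column, which is why this one is hard-wired.
4. The even-aged column takes each age class's residual.  This is the
   only rule consistent with all nine published cells
   (19.4 / 8.3 / 5.6 %); it also guarantees the ED column total equals
   its marginal whenever the construction is feasible.  A negative
   residual (e.g. an old class too small to hold 2/3 of both GD and
   CD) raises an error naming the offending age class.

Internal arithmetic keeps full precision; percentages are rounded only
for display (one decimal for matrix cells, nearest integer for
headline shares).

## The bottom-up (site-type) estimate

The older ASIO-style logic assigns one prevailing dynamics type per
site-type group: even-aged on mesic/intermediate/rich sites (73 % of
the case-study region), gap dynamics on moist–wet (14 %) and cohort
dynamics on dry–poor (13 %) sites.  Only the 27 % total of the two
non-mesic groups is reported regionally; the 14/13 split is a package
default.  Even-aged area receives the average of the negative
exponential and Weibull equilibrium distributions at a 100-year cycle;
gap/cohort area receives an old-skewed age profile, default
30 / 10 / 60 % on the 0–109 / 110–149 / ≥150 classification.  That
profile is a declared assumption: the original analysis's full
parameterisation was never published.

Because of this, the package deliberately reports the bottom-up
≥110-year share as a **sensitivity scan** over the two unpublished
knobs (Weibull shape 1.5–3, profile ≥110-share 60–90 %) rather than a
point estimate.  The scan spans roughly 42–51 %, which brackets
neither the historically reported 36 % ≥110-year share nor, jointly,
the 28 % old share: under the 73/27 site weighting those two published
figures are mutually inconsistent with *any* gap/cohort age profile
(the implied profile would need a ≥110-year share below its own
≥150-year share).  The reported 64 % young share equals exactly the
averaged two-model split applied to the whole area, suggesting the
historical numbers were not produced by the per-site-type mixture
reconstructed here.  The implementation keeps the per-site-type
construction, reports full precision, and leaves the reconciliation as
a documented open point.

## Reserve-need estimation

Management-incompatible forest is (i) all area at or above the
final-felling age (110 years, inclusive) and, optionally, (ii) gap- and
cohort-dynamics area below it, since neither can be maintained by
conventional even-aged low-retention forestry.  Class-internal
splitting at the threshold uses the same uniform-within-bin rule as
re-binning.  Reserve need is a fixed fraction (default 20 %) of the
incompatible share, reported at full precision and rounded to the
nearest percent.  For the default revised matrix this gives
63.3 % → 12.7 % ≈ 13 % (threshold only) and 76.7 % → 15.3 % ≈ 15 %
(including younger gap/cohort forest).

## The stand-level simulator

A non-spatial Monte-Carlo process over independent stands with an
annual time step.  Each year each stand draws at most one event;
severity is sampled by priority (stand-replacing > partial > gap) from
the summed annual hazards, equivalent to competing risks at annual
resolution.  Killed fractions: stand-replacing ≡ 1; partial uniform in
a configurable range within [0.25, 0.75); gap within (0, 0.25).
Defaults are partial (0.25, 0.50) and gap (0.05, 0.25).

Stand age is the **dominant-cohort age**.  Partial and gap events add
a cohort with the killed fraction and scale survivors by its
complement; cohorts below 1e−4 of the stand are pruned and the rest
renormalised.  Dominance transfers to the new cohort only when it
exceeds all survivors combined, i.e. when the killed fraction is above
one half.  Consequently, under the default ranges non-replacing events
never move the dominant-cohort age — they only build multi-cohort
structure — which is the mechanism by which mixed-severity regimes
accumulate old forest.  (If repeated heavy partials erode the dominant
cohort below the pruning floor, dominance falls back to the largest
remaining cohort, oldest on ties; this matters only at implausibly
high partial frequencies and is unit-tested as such.)

The simulator's central role is as an independent oracle: with only
stand-replacing events at hazard `1/λ`, the stationary age
distribution must match `exp(−t/λ)`.  The equivalence test runs 10⁴
stands for a 1000-year burn-in (the default burn-in is ten times the
longest mean return interval) and requires every age-class share to
fall within three binomial standard errors of the closed form.
Dynamics-type classification from event history (stand-replacing in
the window → ED; else any partial → CD; else GD) is validated against
hazards solved analytically to give expected equal thirds.

Not emulated: fire spread and spatial contagion (stands are
independent — the oracle role needs only marginal hazards),
climate-driven non-stationarity, and within-stand structure beyond
cohort fractions.

## The management planner

Each matrix cell becomes a plan record pairing its area share with the
cutting method that emulates its dynamics (GD→gap/selection cutting,
ED→clear-cutting with retention, CD→partial cutting), a rotation and a
target mean age.  Young-class records use a 75-year rotation with a
40-year target mean age; gap/partial records carry cutting cycles
harvesting 25 % of their area every 25 years (mid-range of the 20–30 %
/ 20–30-year envelopes).  Mid- and old-class rotations (150 and 300
years) are package defaults standing in for "extended rotations".

Projection is scheduled at the **landscape level**: ages advance one
year per year, and an oldest-first renewal (clear-cut) flow runs at
the rate that sustains the reference young share —
`young_share / young_width` per year, an effective 300-year renewal
rotation for the default 25/25/50 marginals — plus a proportional
correction (gain 0.5) when the current young share is off target.
Per-record closed rotations were rejected because they cannot hold the
reference marginals fixed: any finite rotation recycles area through
age zero (a 150-year mid-class rotation puts half its steady state in
the young class), and gap/partial cutting never resets dominant age,
so mid and old cells must be sustained by through-flow, not by
rotating in place.  The landscape flow at equilibrium is uniform over
0–300 years, which reproduces 25/25/50 exactly and makes the
young-class mean age ≈ 37.5, consistent with the 75-year/40-year
pairing.  Gap and partial cutting cycles shape within-stand structure
and do not enter the age-class bookkeeping.

Realised natural disturbances can be credited against the plan: a
stand-replacing event reduces the young × clear-cut record, partial
events the partial-cutting records, gap events the gap-cutting
records (proportionally), moving the event area into a `natural_share`
ledger so total area accounting stays closed.

## The synthetic stand-table generator

Emulates a regional inventory with the case-study marginal structure:
site types 73/14/13 % (mesic, moist–wet, dry–poor), age classes
78/13/9 % on the 0–109 / 110–149 / ≥150 classification, ages uniform
within class (old capped at 300 years, matching the reference renewal
rotation), stand areas log-normal with a 10-ha median and σ = 0.8 (a
typical skew for managed boreal holdings).  Site type and age class
are drawn **independently** because only the marginals are reported;
real inventories show site-by-age association (old forest concentrates
on poorer sites), so tests passing on these tables validate the
pipeline arithmetic, not any site–age interaction.  A second generator
inverts a reference matrix (multinomial or exact largest-remainder
quotas over the nine cells, stands tagged with their dynamics type)
for round-trip recovery tests; with equal areas and even age spacing
it also constructs landscapes exactly at the reference for fixed-point
checks.

## Numerical conventions and problem sizes

* Share vectors must sum to 1 within 1e−9; matrix cells are clipped at
  −1e−12 for floating-point noise only.
* Cohort pruning floor 1e−4; annual time step; at most one event per
  stand-year.
* All randomness flows through `numpy.random.default_rng` with
  explicit seeds; identical seeds give byte-identical stand tables and
  bit-identical trajectories.
* Test problem sizes: 10⁴ stands × 1100 years for the simulator
  oracle; 10⁴ stands for generator marginals and round trips; 2000
  stands × 300 years for the management projection (checkpoints every
  75 years, one young rotation).  These sizes put binomial sampling
  error well inside the asserted tolerances.

## Known limitations

* Non-spatial throughout: no fire spread, no reserve connectivity.
* The gap/cohort age profile and the Weibull shape of the bottom-up
  estimate are assumptions; results depending on them are reported as
  scans.
* The equilibrium mathematics assumes stationary regimes; transient
  age structures under changing disturbance climates are out of scope.
* Mid- and old-class rotation defaults (150 / 300 years) are
  placeholders for unpublished table values and should be revisited
  against management practice before operational use.
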