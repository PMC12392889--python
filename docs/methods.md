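# Methods

## The dose model

`thyrodose` reconstructs the protracted absorbed dose to the thyroid for
every member of a closed cohort exposed to reactor fallout, accumulated
from the fallout onset (the epoch, 1986-04-28, t = 0) to each person's
individual end of follow-up. The total decomposes into four pathways:

    D_tot(t) = D_milk(t) + D_inh(t) + D_ext(t) + D_Cs-ing(t)

- **D_milk** — ingestion of I-131 via dairy milk. Modeled as a saturating
  exponential: the asymptotic dose is the product of the I-131 deposition,
  the time-integrated milk concentration per unit deposition, daily milk
  intake, the thyroid dose coefficient per Bq ingested, and a
  countermeasure factor in [0, 1]; the fraction delivered by time t follows
  the effective half-life of I-131 in milk (physical + ecological, so at
  most the physical 8.06 d).
- **D_inh** — inhalation of airborne I-131 during cloud passage. The
  time-integrated air concentration is inferred from ground deposition via
  an effective deposition velocity; the dose is delivered within
  `cloud_duration` days (linear ramp inside that window), after which it is
  constant.
- **D_ext** — external ground shine from Cs-134 and Cs-137. The open-field
  dose rate per nuclide is deposition x kerma coefficient, attenuated by a
  two-exponential weathering function (soil migration; normalized to 1 at
  t = 0), physical decay, an occupancy-weighted building shielding factor,
  and an annual-average snow correction
  `1 - snow_fraction_of_year * (1 - snow_factor)`. Short-lived
  ground-deposited nuclides (Te-132/I-132, Ba/La-140, Ru-103, ...) are folded
  into a single multiplier (>= 1) on the first 365.25 days of the integral
  rather than modeled nuclide by nuclide.
- **D_Cs-ing** — dietary radiocesium. An aggregate transfer factor maps
  deposition directly to whole-body concentration (Bq/kg per kBq/m2) as a
  two-component exponential decline (fast agricultural component,
  ~1 y ecological half-life; slow forest/game/lake-fish component, ~15 y)
  times physical decay, with a fixed male factor (males carry higher body
  concentrations than females). The dose is the time integral of body
  concentration times a thyroid dose-rate coefficient per nuclide.

All cumulative doses are evaluated in closed form through one shared
kernel, the integral of one or two decaying exponentials over an
interval (`physics.integrated_exponential`,
`physics.double_exponential_integral`). Decay chains are not solved
explicitly; emission-weighted coefficients absorb progeny (e.g. Ba-137m
inside the Cs-137 kerma coefficient).

### Units and conventions

- Time: days since the epoch; year = 365.25 d for all half-life
  conversions. The administrative end of follow-up, 2015-12-31, is
  10 839 days after the epoch (computed from the calendar, not hard-coded).
- Dose: mGy to the thyroid throughout; deposition: kBq/m2 (the kBq -> Bq
  factor 1000 appears once, in the inhalation pathway).
- Half-lives: I-131 8.06 d, Cs-134 2.06 y, Cs-137 30.2 y.
- Numerical guard: when `rate * interval < 1e-10` the exponential integral
  switches to its linear limit, avoiding catastrophic cancellation; this
  also makes a zero rate exact.

## Cohort assembly

A `PersonRecord` carries sex, birth date (on or before the epoch — the
cohort is closed, no later entrants), a contiguous residence history of
half-open intervals tiling [0, followup_day], the end of follow-up and
its reason (death, emigration, or administrative end). The protracted
pathways (external, dietary cesium) are integrated piecewise over the
residence history as `D(interval_end) - D(interval_start)` per location;
the acute iodine pathways use the deposition of the residence occupied
at the epoch, since both complete within weeks. A
`freeze_epoch_residence` flag evaluates the whole follow-up at the 1986
residence instead (both accounting modes are supported because register
studies differ on whether internal migration is tracked; the default is
full residence-history accounting). A person whose follow-up ends at the
epoch receives zero dose.

Summaries are sex-stratified per component: arithmetic mean, median, 5th
and 95th percentiles, min, max. Percentiles use linear interpolation
between order statistics (type 7, the numpy default), a choice that
matters only in the far tails of small groups. The reported summary
table is rounded to 3 decimals; per-person CSVs keep full double
precision.

## Synthetic data

The generator emulates the two inputs a real reconstruction would take
from an airborne survey and a population register:

- **Deposition field**: lognormal Cs-137 levels across discrete locations
  (default median 10 kBq/m2, geometric SD 2.5 — a right-skewed field of
  the magnitude seen in the most affected Nordic counties), with fixed
  activity ratios at the epoch (Cs-134/Cs-137 = 0.55, I-131/Cs-137 = 10).
- **Cohort**: ages at the epoch from a piecewise-uniform pyramid
  (0–90 y), a Gompertz mortality hazard (exponential in age, slope
  0.085/y) and a constant emigration hazard. The Gompertz scale and the
  emigration rate are calibrated by alternating 1-D bisections (they
  compete) so the expected 30-year exit fractions match the configured
  targets, by default 34.05% deaths and 3.61% emigrations — the
  register proportions of the study population this pipeline is designed
  for, scaled to any n. Death times are drawn by exact inverse-transform
  sampling of the conditional Gompertz residual lifetime; emigration
  times are exponential. Internal migration is a Poisson number of moves
  with uniform destinations, default rate 0.

What the generator does **not** emulate: real geography (locations are
exchangeable labels, not counties), correlation between deposition and
population density, real demography (the pyramid is a documented
stand-in), seasonality of deposition or diet, and age-dependent dose
coefficients (a per-person scalar multiplier exists but defaults to 1).
Passing tests therefore demonstrate the correctness and calibration of
the pipeline's machinery on structurally faithful inputs, not agreement
with any real register.

## Parameter defaults

No radioecological constant in `data/default_params.toml` is ground
truth; each is a package decision set to a literature-typical magnitude
for Chernobyl-type fallout at Nordic latitudes (provenance comments sit
next to every key). With these defaults and the default scenario, the
synthetic cohort's 30-y mean total lands near 2 mGy with external ground
shine the largest single component — the qualitative regime the model is
meant to represent when early milk countermeasures suppress the iodine
pathway. Tests never assert specific default values; they assert closed
forms, oracles, and structural invariants that hold for any valid
parameter set.

## Numerical choices and verification

- Closed forms are verified against independent midpoint Riemann
  integrations of the underlying dose rates, at 1-day resolution for the
  slowly varying external and dietary-cesium pathways (1e-4 relative
  over 30 y) and 0.1-day resolution for the milk pathway, whose rate
  time constant is a few days and cannot be resolved to 1e-4 by daily
  steps; the external oracle places a bin edge exactly at the first-year
  multiplier discontinuity.
- The exponential kernels are additionally checked against adaptive
  quadrature (1e-8–1e-9 relative) and for interval additivity, scale
  invariance and monotonicity by property tests.
- The two-component aggregate-transfer function is identifiable from a
  noiseless body-burden series: a least-squares refit recovers both
  ecological half-lives to better than 1%.
- Determinism: the entire pipeline is reproducible byte-for-byte from a
  single integer seed; all randomness flows through
  `numpy.random.default_rng` with seeds derived from it.
- Problem sizes: the verification suite uses cohorts of 50–50 000
  persons and 100 random parameter draws for the oracle sweep, sizes at
  which the binomial calibration checks have standard errors well below
  the tolerances tested.

## Known limitations

- Point estimates only: no uncertainty propagation, matching the
  deterministic design of the dose model.
- Thyroid only; no other organs, no ICRP biokinetic compartments.
- The snow correction is an annual average, not a seasonal square wave;
  30-y cumulative doses are insensitive to within-year phasing.
- Sex enters only through the cesium body-concentration factor and an
  optional per-sex shielding factor (default equal).
- Age dependence is a single optional scalar per person (default 1);
  infant/child dose coefficients are out of scope.
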