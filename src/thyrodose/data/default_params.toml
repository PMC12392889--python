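# Default radioecological parameter set for the thyroid dose model.
#
# None of these constants are ground truth for any specific fallout event:
# each is a package decision set to a literature-typical magnitude for
# Chernobyl-type fallout at Nordic latitudes. Override any of them in a copy
# of this file for a specific study.

[external]
# Two-exponential weathering (soil migration) of ground shine, normalized to
# 1 at t = 0: fast component ~1.5 y, slow component ~50 y half-time.
# decision, not ground truth
weathering_w1 = 0.5
weathering_T1 = 548.0
weathering_w2 = 0.5
weathering_T2 = 18263.0
# Occupancy-weighted building shielding for a mostly wooden housing stock.
# decision, not ground truth
shielding_factor = 0.4
# Snow attenuates ground shine by ~30% for ~30% of the year (annual average).
# decision, not ground truth
snow_factor = 0.7
snow_fraction_of_year = 0.3
# Short-lived ground-deposited nuclides (Te-132/I-132, Ba/La-140, Ru-103...)
# folded into a multiplier on the first-year external integral.
# decision, not ground truth
shortlived_multiplier = 1.5

# Open-field thyroid dose rate per unit ground deposition, (mGy/day)/(kBq/m2).
# Cs-137 value corresponds to ~1.9 nGy/h per kBq/m2 for a fresh plane source
# (incl. Ba-137m); Cs-134 emits ~2.6x the photon energy per decay.
# decision, not ground truth
[external.kerma_coeff]
Cs137 = 4.6e-5
Cs134 = 1.2e-4

[cs_ingestion]
# Aggregate transfer factor deposition -> whole-body concentration,
# (Bq/kg)/(kBq/m2): fast dietary component ~1 y, slow (forest/game/lake
# fish) component ~15 y ecological half-life.
# decision, not ground truth
tf_a1 = 3.0
tf_T1 = 365.25
tf_a2 = 0.5
tf_T2 = 5478.75
# Males carry higher radiocesium body concentrations than females.
# decision, not ground truth
male_factor = 1.6
# Thyroid absorbed dose rate per unit whole-body concentration,
# (mGy/day)/(Bq/kg), consistent with ICRP-type ingestion coefficients
# divided by the integrated body residence per Bq ingested.
# decision, not ground truth
[cs_ingestion.thyroid_doserate_coeff]
Cs137 = 5.7e-6
Cs134 = 9.6e-6

[milk]
# Time-integrated I-131 milk concentration per unit deposition,
# (Bq day/L)/(kBq/m2), pasture season, before countermeasures.
# decision, not ground truth
milk_transfer_integral = 130.0
# Effective half-life of I-131 in milk (physical 8.06 d + ecological).
# decision, not ground truth
milk_effective_half_life = 5.0
# Adult dairy-milk consumption, L/day. decision, not ground truth
milk_intake = 0.3
# Thyroid absorbed dose per Bq I-131 ingested, mGy/Bq (adult).
# decision, not ground truth
ingestion_dose_coeff = 4.3e-4
# Fraction of the milk pathway remaining after grazing restrictions and
# dairy-milk control. decision, not ground truth
countermeasure_factor = 0.1

[inhalation]
# Effective deposition velocity linking time-integrated air concentration
# to ground deposition, m/day (~2 cm/s, wet deposition dominated).
# decision, not ground truth
deposition_velocity = 1700.0
# Adult breathing rate, m3/day. decision, not ground truth
breathing_rate = 22.0
# Thyroid absorbed dose per Bq I-131 inhaled, mGy/Bq (adult).
# decision, not ground truth
inhalation_dose_coeff = 1.5e-4
# Cloud passage duration, days. decision, not ground truth
cloud_duration = 2.0

[scenario]
# Synthetic-study defaults: a right-skewed deposition field over discrete
# locations and a closed cohort fixed at the epoch.
n_locations = 50
# Lognormal Cs-137 deposition: median kBq/m2 and geometric SD.
# decision, not ground truth
dep_median = 10.0
dep_gsd = 2.5
# Activity ratios relative to Cs-137 at the reference date.
# decision, not ground truth
cs134_ratio = 0.55
i131_ratio = 10.0
n_persons = 1000
male_fraction = 0.5
# Piecewise-uniform age pyramid at the epoch (years).
# decision, not ground truth
age_breaks = [0.0, 20.0, 45.0, 65.0, 90.0]
age_weights = [0.25, 0.33, 0.24, 0.18]
# Gompertz mortality slope per year of age; the scale is calibrated so the
# expected 30-y death fraction matches target_death_fraction.
mortality_b = 0.085
# 30-y targets: 734211/2156084 deaths, 77865/2156084 emigrations.
target_death_fraction = 0.3405
target_emigration_fraction = 0.0361
# Internal-migration rate, moves per person-year (0 = stay put).
migration_rate = 0.0
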