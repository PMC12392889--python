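"""The four thyroid dose pathways as pure closed-form functions.

The total protracted thyroid dose accumulated ``t`` days after fallout
onset decomposes as

    D_tot(t) = D_milk(t) + D_inh(t) + D_ext(t) + D_Cs-ing(t)

with the two iodine pathways (dairy milk, inhalation of the passing
cloud) essentially complete within weeks, and the two radiocesium
pathways (ground shine, dietary intake via the aggregate transfer
factor) accumulating over decades.

Every function here is deterministic, cumulative from the epoch, and
linear in the ground deposition.  Doses are in mGy to the thyroid;
deposition in kBq/m2 of Cs-137 at the epoch, with fixed activity ratios
for Cs-134 and I-131.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from importlib import resources

from .physics import (
    DAYS_PER_YEAR,
    LN2,
    NUCLIDES,
    double_exponential_integral,
    integrated_exponential,
)

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "DepositionRecord",
    "ExternalParams",
    "CsIngestionParams",
    "MilkParams",
    "InhalationParams",
    "PathwayParameterSet",
    "load_params",
    "default_params",
    "weathering",
    "external_dose",
    "cs_body_concentration",
    "cs_ingestion_dose",
    "milk_iodine_dose",
    "inhalation_dose",
]

_CS_NUCLIDES = ("Cs134", "Cs137")


@dataclass(frozen=True)
class DepositionRecord:
    """Ground deposition at one location at the epoch.

    ``cs137_dep`` is the Cs-137 deposition density (kBq/m2); the Cs-134
    and I-131 depositions are derived from activity ratios relative to
    Cs-137, never stored separately.
    """

    location_id: str
    cs137_dep: float
    cs134_ratio: float
    i131_ratio: float

    def __post_init__(self) -> None:
        if self.cs137_dep < 0:
            raise ValueError(f"cs137_dep must be >= 0, got {self.cs137_dep!r}")
        if self.cs134_ratio < 0 or self.i131_ratio < 0:
            raise ValueError("activity ratios must be >= 0")

    @property
    def cs134_dep(self) -> float:
        return self.cs137_dep * self.cs134_ratio

    @property
    def i131_dep(self) -> float:
        return self.cs137_dep * self.i131_ratio

    def nuclide_dep(self, name: str) -> float:
        if name == "Cs137":
            return self.cs137_dep
        if name == "Cs134":
            return self.cs134_dep
        if name == "I131":
            return self.i131_dep
        raise KeyError(f"unknown nuclide {name!r}")


def _check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must be in [{lo}, {hi}], got {value!r}")


@dataclass(frozen=True)
class ExternalParams:
    """Ground-shine (external) pathway parameters.

    ``kerma_coeff`` maps deposition to unshielded open-field thyroid dose
    rate, (mGy/day) per (kBq/m2), per cesium nuclide.  Weathering is a
    two-exponential decline of the dose rate beyond physical decay,
    normalized to 1 at t = 0.  Shielding (indoor occupancy and building
    attenuation) and snow cover reduce the open-field rate; short-lived
    ground-deposited nuclides are represented by a multiplier on the
    first year of the integral.
    """

    kerma_coeff: dict[str, float]
    weathering_w1: float
    weathering_w2: float
    weathering_T1: float
    weathering_T2: float
    shielding_factor: float
    snow_factor: float
    snow_fraction_of_year: float
    shortlived_multiplier: float
    shielding_factor_male: float | None = None

    def __post_init__(self) -> None:
        if abs(self.weathering_w1 + self.weathering_w2 - 1.0) > 1e-9:
            raise ValueError("weathering weights must sum to 1")
        if self.weathering_w1 < 0 or self.weathering_w2 < 0:
            raise ValueError("weathering weights must be >= 0")
        if self.weathering_T1 <= 0 or self.weathering_T2 <= 0:
            raise ValueError("weathering half-times must be > 0")
        _check_fraction("shielding_factor", self.shielding_factor, 1e-12, 1.0)
        _check_fraction("snow_factor", self.snow_factor, 1e-12, 1.0)
        _check_fraction("snow_fraction_of_year", self.snow_fraction_of_year)
        if self.shortlived_multiplier < 1:
            raise ValueError("shortlived_multiplier must be >= 1")
        for nuc in self.kerma_coeff:
            if nuc not in _CS_NUCLIDES:
                raise ValueError(f"kerma_coeff for unknown nuclide {nuc!r}")

    def shielding(self, sex: str) -> float:
        if sex == "M" and self.shielding_factor_male is not None:
            return self.shielding_factor_male
        return self.shielding_factor


@dataclass(frozen=True)
class CsIngestionParams:
    """Aggregate-transfer (dietary radiocesium) pathway parameters.

    The aggregate transfer factor maps ground deposition directly to
    whole-body concentration as a two-component exponential decline with
    fast and slow ecological half-lives, multiplied by physical decay.
    Males carry a fixed factor on body concentration.
    """

    tf_a1: float
    tf_a2: float
    tf_T1: float
    tf_T2: float
    male_factor: float
    thyroid_doserate_coeff: dict[str, float]

    def __post_init__(self) -> None:
        if self.tf_a1 < 0 or self.tf_a2 < 0:
            raise ValueError("transfer amplitudes must be >= 0")
        if self.tf_T1 <= 0 or self.tf_T2 <= 0:
            raise ValueError("ecological half-lives must be > 0")
        if self.male_factor < 1:
            raise ValueError("male_factor must be >= 1")
        for nuc, c in self.thyroid_doserate_coeff.items():
            if nuc not in _CS_NUCLIDES:
                raise ValueError(f"doserate coeff for unknown nuclide {nuc!r}")
            if c < 0:
                raise ValueError("doserate coefficients must be >= 0")


@dataclass(frozen=True)
class MilkParams:
    """I-131 via dairy milk: a saturating first-weeks pathway.

    ``milk_transfer_integral`` is the time-integrated milk concentration
    per unit deposition before truncation, (Bq day/L) per (kBq/m2); the
    effective half-life combines physical decay and ecological decline in
    milk and therefore cannot exceed the physical 8.06 d.  The
    countermeasure factor scales the pathway down for grazing
    restrictions and milk control.
    """

    milk_transfer_integral: float
    milk_effective_half_life: float
    milk_intake: float
    ingestion_dose_coeff: float
    countermeasure_factor: float

    def __post_init__(self) -> None:
        for name in (
            "milk_transfer_integral",
            "milk_effective_half_life",
            "milk_intake",
            "ingestion_dose_coeff",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        _check_fraction("countermeasure_factor", self.countermeasure_factor)
        if self.milk_effective_half_life > NUCLIDES["I131"].half_life:
            raise ValueError(
                "milk_effective_half_life cannot exceed the physical "
                f"I-131 half-life {NUCLIDES['I131'].half_life} d"
            )


@dataclass(frozen=True)
class InhalationParams:
    """I-131 inhalation from the passing cloud.

    The time-integrated air concentration is inferred from ground
    deposition through an effective deposition velocity; the dose is
    delivered within ``cloud_duration`` days of the epoch.
    """

    deposition_velocity: float
    breathing_rate: float
    inhalation_dose_coeff: float
    cloud_duration: float

    def __post_init__(self) -> None:
        for name in (
            "deposition_velocity",
            "breathing_rate",
            "inhalation_dose_coeff",
            "cloud_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PathwayParameterSet:
    """All radioecological constants, grouped per pathway."""

    external: ExternalParams
    cs_ingestion: CsIngestionParams
    milk: MilkParams
    inhalation: InhalationParams
    age_factor: float = 1.0


def _params_from_mapping(cfg: dict) -> PathwayParameterSet:
    ext = dict(cfg["external"])
    kerma = {k: float(v) for k, v in ext.pop("kerma_coeff").items()}
    ing = dict(cfg["cs_ingestion"])
    coeff = {k: float(v) for k, v in ing.pop("thyroid_doserate_coeff").items()}
    return PathwayParameterSet(
        external=ExternalParams(kerma_coeff=kerma, **ext),
        cs_ingestion=CsIngestionParams(thyroid_doserate_coeff=coeff, **ing),
        milk=MilkParams(**cfg["milk"]),
        inhalation=InhalationParams(**cfg["inhalation"]),
        age_factor=float(cfg.get("age_factor", 1.0)),
    )


def load_params(path) -> PathwayParameterSet:
    """Read a :class:`PathwayParameterSet` from a TOML configuration file."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return _params_from_mapping(cfg)


def default_params() -> PathwayParameterSet:
    """The packaged default parameter set (see ``data/default_params.toml``)."""
    text = resources.files("thyrodose.data").joinpath("default_params.toml").read_bytes()
    return _params_from_mapping(tomllib.loads(text.decode("utf-8")))


# ---------------------------------------------------------------------------
# pathway functions


def weathering(t: float, p: ExternalParams) -> float:
    """Ground-shine attenuation beyond physical decay at time ``t`` (days).

    Two-exponential migration of deposited activity into soil; equals 1
    at t = 0 by the weight normalization.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    return p.weathering_w1 * math.exp(-LN2 * t / p.weathering_T1) + (
        p.weathering_w2 * math.exp(-LN2 * t / p.weathering_T2)
    )


def _external_integral(nuclide: str, t0: float, t1: float, p: ExternalParams) -> float:
    """Weathering x physical-decay integral for one cesium nuclide."""
    lam = NUCLIDES[nuclide].decay_constant
    return double_exponential_integral(
        p.weathering_w1,
        LN2 / p.weathering_T1,
        p.weathering_w2,
        LN2 / p.weathering_T2,
        lam,
        t0,
        t1,
    )


def external_dose(
    dep: DepositionRecord, sex: str, t_end: float, p: ExternalParams
) -> float:
    """Cumulative external (ground-shine) thyroid dose in mGy over [0, t_end].

    Sums Cs-134 and Cs-137 ground shine with weathering, physical decay,
    shielding and an annual-average snow correction; the first year of
    the integral carries the short-lived-nuclide multiplier.
    """
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end!r}")
    snow_correction = 1.0 - p.snow_fraction_of_year * (1.0 - p.snow_factor)
    shield = p.shielding(sex)
    first_year = DAYS_PER_YEAR
    total = 0.0
    for nuc in _CS_NUCLIDES:
        try:
            k = p.kerma_coeff[nuc]
        except KeyError:
            raise KeyError(f"no kerma coefficient configured for {nuc}") from None
        early = _external_integral(nuc, 0.0, min(t_end, first_year), p)
        late = _external_integral(nuc, first_year, t_end, p) if t_end > first_year else 0.0
        total += dep.nuclide_dep(nuc) * k * (p.shortlived_multiplier * early + late)
    return total * shield * snow_correction


def cs_body_concentration(
    dep: DepositionRecord,
    sex: str,
    t: float,
    p: CsIngestionParams,
    nuclide: str,
) -> float:
    """Whole-body concentration (Bq/kg) of one cesium nuclide at time ``t``.

    Aggregate transfer from deposition: two-component ecological decline
    times physical decay, with the male body-concentration factor.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    if nuclide not in _CS_NUCLIDES:
        raise ValueError(f"nuclide must be one of {_CS_NUCLIDES}, got {nuclide!r}")
    lam = NUCLIDES[nuclide].decay_constant
    tf = p.tf_a1 * math.exp(-LN2 * t / p.tf_T1) + p.tf_a2 * math.exp(-LN2 * t / p.tf_T2)
    sex_factor = p.male_factor if sex == "M" else 1.0
    return dep.nuclide_dep(nuclide) * tf * math.exp(-lam * t) * sex_factor


def cs_ingestion_dose(
    dep: DepositionRecord, sex: str, t_end: float, p: CsIngestionParams
) -> float:
    """Cumulative dietary-radiocesium thyroid dose in mGy over [0, t_end].

    Closed-form time integral of the body concentration times the
    thyroid dose-rate coefficient, summed over Cs-134 and Cs-137.
    """
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end!r}")
    sex_factor = p.male_factor if sex == "M" else 1.0
    total = 0.0
    for nuc in _CS_NUCLIDES:
        coeff = p.thyroid_doserate_coeff.get(nuc, 0.0)
        if coeff == 0.0:
            continue
        lam = NUCLIDES[nuc].decay_constant
        integral = double_exponential_integral(
            p.tf_a1, LN2 / p.tf_T1, p.tf_a2, LN2 / p.tf_T2, lam, 0.0, t_end
        )
        total += dep.nuclide_dep(nuc) * coeff * integral
    return total * sex_factor


def milk_iodine_dose(dep: DepositionRecord, t_end: float, p: MilkParams) -> float:
    """Cumulative I-131 dairy-milk thyroid dose in mGy over [0, t_end].

    Saturating closed form: the fraction delivered by ``t_end`` follows
    the effective half-life of I-131 in milk.
    """
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end!r}")
    if p.milk_effective_half_life == 0:
        frac = 1.0 if t_end > 0 else 0.0
    else:
        frac = 1.0 - math.exp(-LN2 * t_end / p.milk_effective_half_life)
    return (
        dep.i131_dep
        * p.milk_transfer_integral
        * frac
        * p.milk_intake
        * p.ingestion_dose_coeff
        * p.countermeasure_factor
    )


def inhalation_dose(
    dep: DepositionRecord, p: InhalationParams, t_end: float = math.inf
) -> float:
    """I-131 inhalation thyroid dose in mGy, complete by ``cloud_duration``.

    The time-integrated air concentration is deposition divided by the
    effective deposition velocity (kBq -> Bq factor 1000).  For
    ``t_end`` inside the cloud passage the dose ramps linearly;
    afterwards it is constant.
    """
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end!r}")
    full = (
        dep.i131_dep * 1000.0 / p.deposition_velocity
    ) * p.breathing_rate * p.inhalation_dose_coeff
    if t_end >= p.cloud_duration:
        return full
    return full * t_end / p.cloud_duration
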