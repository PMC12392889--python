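"""Synthetic fallout fields and closed cohorts.

Real inputs to a protracted dose reconstruction — an airborne-survey
deposition map and a national population register — are not
redistributable.  This module generates stand-ins with the statistical
structure the pipeline assumes: a right-skewed (lognormal) deposition
field over discrete locations, and a closed cohort fixed at the epoch
whose members leave follow-up by death (age-increasing Gompertz
hazard), emigration (constant hazard), or the administrative end of the
study, with 30-year exit fractions calibrated to configurable targets.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import datetime
import math
import sys
from dataclasses import dataclass, replace

import numpy as np

from .cohort import PersonRecord, Residence
from .pathways import DepositionRecord
from .physics import ADMINISTRATIVE_END, DAYS_PER_YEAR, EPOCH, FOLLOWUP_DAYS

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "calibrate_hazards",
    "generate_deposition",
    "generate_cohort",
    "generate_scenario",
]

_HORIZON_YEARS = FOLLOWUP_DAYS / DAYS_PER_YEAR


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Hazards are annual rates; ``mortality_h0`` is the Gompertz scale (the
    hazard at age 0, per year) and ``mortality_b`` the slope per year of
    age.  If ``mortality_h0`` or ``emigration_rate`` is None it is
    calibrated by bisection so the expected 30-year exit fractions match
    ``target_death_fraction`` / ``target_emigration_fraction``.
    """

    seed: int
    n_locations: int = 50
    dep_median: float = 10.0
    dep_gsd: float = 2.5
    cs134_ratio: float = 0.55
    i131_ratio: float = 10.0
    n_persons: int = 1000
    male_fraction: float = 0.5
    age_breaks: tuple[float, ...] = (0.0, 20.0, 45.0, 65.0, 90.0)
    age_weights: tuple[float, ...] = (0.25, 0.33, 0.24, 0.18)
    mortality_b: float = 0.085
    mortality_h0: float | None = None
    emigration_rate: float | None = None
    target_death_fraction: float = 0.3405
    target_emigration_fraction: float = 0.0361
    migration_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if self.dep_median <= 0 or self.dep_gsd < 1:
            raise ValueError("dep_median must be > 0 and dep_gsd >= 1")
        if self.cs134_ratio < 0 or self.i131_ratio < 0:
            raise ValueError("activity ratios must be >= 0")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if len(self.age_weights) != len(self.age_breaks) - 1:
            raise ValueError("age_weights must have one entry per age interval")
        if any(w < 0 for w in self.age_weights) or sum(self.age_weights) <= 0:
            raise ValueError("age_weights must be nonnegative with positive sum")
        if any(b <= a for a, b in zip(self.age_breaks, self.age_breaks[1:])):
            raise ValueError("age_breaks must be strictly increasing")
        for name in (
            "mortality_b",
            "migration_rate",
            "target_death_fraction",
            "target_emigration_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_scenario(path, seed: int) -> ScenarioConfig:
    """Read the ``[scenario]`` table of a TOML config file."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    sc = dict(cfg["scenario"])
    sc.pop("seed", None)
    for key in ("age_breaks", "age_weights"):
        if key in sc:
            sc[key] = tuple(float(x) for x in sc[key])
    return ScenarioConfig(seed=seed, **sc)


# ---------------------------------------------------------------------------
# hazard calibration


def _age_grid(cfg: ScenarioConfig, n: int = 181) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and weights over the age pyramid density."""
    breaks = np.asarray(cfg.age_breaks)
    weights = np.asarray(cfg.age_weights, dtype=float)
    weights = weights / weights.sum()
    ages = np.linspace(breaks[0], breaks[-1], n)
    density = np.zeros_like(ages)
    for lo, hi, w in zip(breaks[:-1], breaks[1:], weights):
        inside = (ages >= lo) & (ages < hi)
        density[inside] = w / (hi - lo)
    density[-1] = density[-2]
    density = density / np.trapezoid(density, ages)
    return ages, density


def _exit_fractions(cfg: ScenarioConfig, h0: float, mu: float) -> tuple[float, float]:
    """Expected 30-y death and emigration fractions under competing hazards."""
    b = cfg.mortality_b
    ages, density = _age_grid(cfg)
    s = np.linspace(0.0, _HORIZON_YEARS, 400)
    a = ages[:, None]
    if b > 0:
        cum_death = (h0 / b) * (np.exp(b * (a + s[None, :])) - np.exp(b * a))
        hazard_death = h0 * np.exp(b * (a + s[None, :]))
    else:
        cum_death = h0 * s[None, :]
        hazard_death = np.full((len(ages), len(s)), h0)
    surv = np.exp(-cum_death - mu * s[None, :])
    p_death_by_age = np.trapezoid(hazard_death * surv, s, axis=1)
    p_emig_by_age = mu * np.trapezoid(surv, s, axis=1)
    p_death = float(np.trapezoid(p_death_by_age * density, ages))
    p_emig = float(np.trapezoid(p_emig_by_age * density, ages))
    return p_death, p_emig


def _bisect(f, lo: float, hi: float, tol: float = 1e-10, maxit: int = 200) -> float:
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("bisection bracket does not contain a root")
    for _ in range(maxit):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol:
            return mid
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def calibrate_hazards(cfg: ScenarioConfig, rounds: int = 6) -> ScenarioConfig:
    """Fill in ``mortality_h0`` / ``emigration_rate`` to hit the target fractions.

    Death and emigration compete, so the two 1-D bisections are
    alternated; a handful of rounds suffices because emigration is rare.
    Targets of zero map to zero hazards.
    """
    h0 = cfg.mortality_h0
    mu = cfg.emigration_rate
    fit_h0 = h0 is None
    fit_mu = mu is None
    if not (fit_h0 or fit_mu):
        return cfg
    h0 = 1e-4 if fit_h0 else h0
    mu = 1e-3 if fit_mu else mu
    for _ in range(rounds):
        if fit_h0:
            if cfg.target_death_fraction == 0:
                h0 = 0.0
            else:
                h0 = _bisect(
                    lambda x: _exit_fractions(cfg, x, mu)[0]
                    - cfg.target_death_fraction,
                    1e-9,
                    1.0,
                )
        if fit_mu:
            if cfg.target_emigration_fraction == 0:
                mu = 0.0
            else:
                mu = _bisect(
                    lambda x: _exit_fractions(cfg, h0, x)[1]
                    - cfg.target_emigration_fraction,
                    1e-9,
                    1.0,
                )
    return replace(cfg, mortality_h0=h0, emigration_rate=mu)


# ---------------------------------------------------------------------------
# generators


def generate_deposition(cfg: ScenarioConfig) -> list[DepositionRecord]:
    """Lognormal Cs-137 deposition field with fixed nuclide ratios."""
    rng = np.random.default_rng(cfg.seed)
    sigma = math.log(cfg.dep_gsd)
    levels = cfg.dep_median * np.exp(sigma * rng.standard_normal(cfg.n_locations))
    width = len(str(cfg.n_locations))
    return [
        DepositionRecord(
            location_id=f"L{i + 1:0{width}d}",
            cs137_dep=float(lv),
            cs134_ratio=cfg.cs134_ratio,
            i131_ratio=cfg.i131_ratio,
        )
        for i, lv in enumerate(levels)
    ]


def _sample_death_years(
    rng: np.random.Generator, ages: np.ndarray, h0: float, b: float
) -> np.ndarray:
    """Inverse-transform Gompertz residual lifetimes (years from epoch)."""
    if h0 == 0:
        return np.full(len(ages), np.inf)
    u = rng.random(len(ages))
    if b == 0:
        return -np.log(u) / h0
    arg = np.exp(b * ages) - (b / h0) * np.log(u)
    return np.log(arg) / b - ages


def generate_cohort(
    cfg: ScenarioConfig, locations: list[DepositionRecord]
) -> list[PersonRecord]:
    """Closed cohort with calibrated exit hazards and contiguous residences."""
    if not locations:
        raise ValueError("locations must be nonempty")
    cfg = calibrate_hazards(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.n_persons

    sexes = np.where(rng.random(n) < cfg.male_fraction, "M", "F")

    weights = np.asarray(cfg.age_weights, dtype=float)
    weights = weights / weights.sum()
    bins = rng.choice(len(weights), size=n, p=weights)
    lo = np.asarray(cfg.age_breaks)[bins]
    hi = np.asarray(cfg.age_breaks)[bins + 1]
    ages = lo + rng.random(n) * (hi - lo)

    death_y = _sample_death_years(rng, ages, cfg.mortality_h0, cfg.mortality_b)
    mu = cfg.emigration_rate
    emig_y = rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)

    loc_ids = [d.location_id for d in locations]
    home_idx = rng.integers(0, len(loc_ids), n)

    width = len(str(n))
    persons: list[PersonRecord] = []
    for i in range(n):
        t_death = death_y[i] * DAYS_PER_YEAR
        t_emig = emig_y[i] * DAYS_PER_YEAR
        end_day = min(t_death, t_emig, float(FOLLOWUP_DAYS))
        if end_day == t_death and t_death <= t_emig and end_day < FOLLOWUP_DAYS:
            reason = "death"
        elif end_day == t_emig and end_day < FOLLOWUP_DAYS:
            reason = "emigration"
        else:
            reason = "administrative"
        end_day = int(round(end_day))
        end_day = min(end_day, FOLLOWUP_DAYS)

        birth = EPOCH - datetime.timedelta(days=int(round(ages[i] * DAYS_PER_YEAR)))

        move_days: list[int] = []
        if cfg.migration_rate > 0 and end_day > 1:
            n_moves = rng.poisson(cfg.migration_rate * end_day / DAYS_PER_YEAR)
            if n_moves:
                draws = rng.integers(1, end_day, n_moves)
                move_days = sorted(set(int(d) for d in draws))
        boundaries = [0, *move_days, end_day]
        res_locs = [int(home_idx[i])]
        for _ in move_days:
            res_locs.append(int(rng.integers(0, len(loc_ids))))
        residences = tuple(
            Residence(loc_ids[res_locs[j]], boundaries[j], boundaries[j + 1])
            for j in range(len(boundaries) - 1)
        )

        persons.append(
            PersonRecord(
                person_id=f"P{i + 1:0{width}d}",
                sex=str(sexes[i]),
                birth_date=birth,
                residences=residences,
                followup_end=EPOCH + datetime.timedelta(days=end_day),
                end_reason=reason,
            )
        )
    return persons


def generate_scenario(
    cfg: ScenarioConfig,
) -> tuple[list[DepositionRecord], list[PersonRecord]]:
    """Deposition field plus cohort for one scenario, from one seed."""
    deposition = generate_deposition(cfg)
    cohort = generate_cohort(cfg, deposition)
    return deposition, cohort
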