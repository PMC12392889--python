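"""Per-person dose assembly over residence histories, and cohort summaries.

A person contributes to the dose reconstruction from the epoch
(1986-04-28) until their individual end of follow-up (death, emigration,
or the administrative end 2015-12-31).  The protracted pathways
(external ground shine, dietary radiocesium) are integrated piecewise
over the residence history; the acute iodine pathways (milk,
inhalation) use the deposition at the residence occupied at the epoch,
since both complete within weeks of fallout.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pathways import (
    DepositionRecord,
    PathwayParameterSet,
    cs_ingestion_dose,
    external_dose,
    inhalation_dose,
    milk_iodine_dose,
)
from .physics import EPOCH, FOLLOWUP_DAYS

__all__ = [
    "Residence",
    "PersonRecord",
    "DoseResult",
    "COMPONENTS",
    "person_dose",
    "cohort_doses",
    "summarize",
    "cumulative_curves",
]

END_REASONS = ("death", "emigration", "administrative")

#: Dose table column names, in reporting order.
COMPONENTS = ("d_milk", "d_inh", "d_ext", "d_cs_ing", "d_total")


@dataclass(frozen=True)
class Residence:
    """A half-open residence interval [start_day, end_day) in days since epoch."""

    location_id: str
    start_day: int
    end_day: int


@dataclass(frozen=True)
class PersonRecord:
    """One cohort member: attributes, residence history, follow-up window.

    The cohort is closed at the epoch, so ``birth_date`` may not fall
    after it; residence intervals must tile [0, followup_day] without
    gaps or overlaps.
    """

    person_id: str
    sex: str
    birth_date: datetime.date
    residences: tuple[Residence, ...]
    followup_end: datetime.date
    end_reason: str
    age_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.birth_date > EPOCH:
            raise ValueError(
                f"person {self.person_id}: birth_date {self.birth_date} is after "
                f"the epoch {EPOCH} (closed cohort)"
            )
        if self.end_reason not in END_REASONS:
            raise ValueError(
                f"person {self.person_id}: end_reason must be one of {END_REASONS}"
            )
        if self.followup_end < EPOCH or self.followup_day > FOLLOWUP_DAYS:
            raise ValueError(
                f"person {self.person_id}: followup_end {self.followup_end} outside "
                f"[{EPOCH}, +{FOLLOWUP_DAYS} d]"
            )
        if not self.residences:
            raise ValueError(f"person {self.person_id}: no residence history")
        object.__setattr__(self, "residences", tuple(self.residences))
        if self.residences[0].start_day != 0:
            raise ValueError(
                f"person {self.person_id}: residence history must start at the epoch"
            )
        prev_end = 0
        for res in self.residences:
            if res.start_day != prev_end:
                raise ValueError(
                    f"person {self.person_id}: residence intervals not contiguous "
                    f"at day {res.start_day}"
                )
            if res.end_day < res.start_day:
                raise ValueError(
                    f"person {self.person_id}: residence interval ends before it starts"
                )
            prev_end = res.end_day
        if prev_end != self.followup_day:
            raise ValueError(
                f"person {self.person_id}: residence history ends at day {prev_end}, "
                f"follow-up at day {self.followup_day}"
            )
        if self.age_factor < 0:
            raise ValueError("age_factor must be >= 0")

    @property
    def followup_day(self) -> int:
        """End of follow-up in days since the epoch."""
        return (self.followup_end - EPOCH).days


@dataclass(frozen=True)
class DoseResult:
    """The four pathway components plus total, in mGy, for one person."""

    person_id: str
    sex: str
    d_milk: float
    d_inh: float
    d_ext: float
    d_cs_ing: float

    def __post_init__(self) -> None:
        for name in ("d_milk", "d_inh", "d_ext", "d_cs_ing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def d_total(self) -> float:
        return self.d_milk + self.d_inh + self.d_ext + self.d_cs_ing


def _resolve(depmap: dict[str, DepositionRecord], person_id: str, loc: str) -> DepositionRecord:
    try:
        return depmap[loc]
    except KeyError:
        raise KeyError(
            f"person {person_id}: residence location {loc!r} not found in the "
            "deposition table"
        ) from None


def person_dose(
    person: PersonRecord,
    depmap: dict[str, DepositionRecord],
    params: PathwayParameterSet,
    t_end: float | None = None,
    freeze_epoch_residence: bool = False,
) -> DoseResult:
    """Cumulative four-component thyroid dose for one person.

    Parameters
    ----------
    t_end
        Optional horizon in days since the epoch; the effective horizon is
        ``min(t_end, person.followup_day)``.  Default: the person's full
        follow-up.
    freeze_epoch_residence
        If True, evaluate the protracted pathways with the deposition of
        the residence occupied at the epoch for the whole follow-up,
        ignoring later moves.
    """
    horizon = float(person.followup_day)
    if t_end is not None:
        if t_end < 0:
            raise ValueError(f"t_end must be >= 0, got {t_end!r}")
        horizon = min(horizon, float(t_end))

    dep0 = _resolve(depmap, person.person_id, person.residences[0].location_id)
    intake_scale = person.age_factor * params.age_factor

    d_milk = milk_iodine_dose(dep0, horizon, params.milk) * intake_scale
    d_inh = inhalation_dose(dep0, params.inhalation, t_end=horizon) * intake_scale

    d_ext = 0.0
    d_cs = 0.0
    if freeze_epoch_residence:
        segments = [(dep0, 0.0, horizon)]
    else:
        segments = []
        for res in person.residences:
            start = float(res.start_day)
            if start >= horizon:
                break
            end = min(float(res.end_day), horizon)
            dep = _resolve(depmap, person.person_id, res.location_id)
            segments.append((dep, start, end))
    for dep, start, end in segments:
        d_ext += external_dose(dep, person.sex, end, params.external) - external_dose(
            dep, person.sex, start, params.external
        )
        d_cs += cs_ingestion_dose(
            dep, person.sex, end, params.cs_ingestion
        ) - cs_ingestion_dose(dep, person.sex, start, params.cs_ingestion)
    d_cs *= intake_scale

    return DoseResult(
        person_id=person.person_id,
        sex=person.sex,
        d_milk=d_milk,
        d_inh=d_inh,
        d_ext=max(d_ext, 0.0),
        d_cs_ing=max(d_cs, 0.0),
    )


def cohort_doses(
    cohort: list[PersonRecord],
    depmap: dict[str, DepositionRecord],
    params: PathwayParameterSet,
    freeze_epoch_residence: bool = False,
) -> pd.DataFrame:
    """Dose table for a cohort: one row per person, sorted by person_id."""
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rows = []
    for person in cohort:
        r = person_dose(
            person, depmap, params, freeze_epoch_residence=freeze_epoch_residence
        )
        rows.append(
            {
                "person_id": r.person_id,
                "sex": r.sex,
                "d_milk": r.d_milk,
                "d_inh": r.d_inh,
                "d_ext": r.d_ext,
                "d_cs_ing": r.d_cs_ing,
                "d_total": r.d_total,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("person_id", kind="mergesort").reset_index(drop=True)


def summarize(dose_table: pd.DataFrame) -> pd.DataFrame:
    """Sex-stratified summary per dose component.

    Returns one row per (sex, component) with n, arithmetic mean, median,
    5th and 95th percentiles (linear interpolation between order
    statistics), min and max, in mGy.
    """
    if dose_table.empty:
        raise ValueError("dose table must be nonempty")
    rows = []
    for sex in ("F", "M"):
        group = dose_table[dose_table["sex"] == sex]
        if group.empty:
            warnings.warn(f"no persons with sex {sex!r}; group omitted", stacklevel=2)
            continue
        for comp in COMPONENTS:
            values = group[comp].to_numpy(dtype=float)
            rows.append(
                {
                    "sex": sex,
                    "component": comp,
                    "n": len(values),
                    "mean": float(np.mean(values)),
                    "median": float(np.median(values)),
                    "p5": float(np.percentile(values, 5)),
                    "p95": float(np.percentile(values, 95)),
                    "min": float(np.min(values)),
                    "max": float(np.max(values)),
                }
            )
    return pd.DataFrame(rows)


def cumulative_curves(
    cohort: list[PersonRecord],
    depmap: dict[str, DepositionRecord],
    params: PathwayParameterSet,
    time_grid: list[float],
    freeze_epoch_residence: bool = False,
) -> pd.DataFrame:
    """Per-sex mean cumulative dose per component over a time grid.

    Long-format output: day, sex, component, mean_mGy.  Each person is
    truncated at their own follow-up end, so the final point of a grid
    ending at the full horizon reproduces the 30-y summary means.
    """
    grid = list(time_grid)
    if not grid:
        raise ValueError("time_grid must be nonempty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("time_grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > FOLLOWUP_DAYS:
        raise ValueError(f"time_grid must lie within [0, {FOLLOWUP_DAYS}]")

    sums: dict[tuple[str, str], np.ndarray] = {
        (sex, comp): np.zeros(len(grid)) for sex in ("F", "M") for comp in COMPONENTS
    }
    counts = {"F": 0, "M": 0}
    for person in cohort:
        counts[person.sex] += 1
        for i, t in enumerate(grid):
            r = person_dose(
                person,
                depmap,
                params,
                t_end=t,
                freeze_epoch_residence=freeze_epoch_residence,
            )
            for comp in COMPONENTS:
                sums[(person.sex, comp)][i] += getattr(r, comp)

    rows = []
    for sex in ("F", "M"):
        if counts[sex] == 0:
            continue
        for comp in COMPONENTS:
            means = sums[(sex, comp)] / counts[sex]
            for t, m in zip(grid, means):
                rows.append(
                    {"day": t, "sex": sex, "component": comp, "mean_mGy": float(m)}
                )
    return pd.DataFrame(rows)
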