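"""CSV readers/writers and the run manifest.

Fixed dialect: UTF-8, comma separator, period decimal, ISO-8601 dates.
Readers validate and reject malformed input rather than coercing it;
doses are serialized at full double precision, rounding happens only in
the human-readable summary table.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import COMPONENTS, PersonRecord, Residence
from .pathways import DepositionRecord
from .physics import EPOCH

__all__ = [
    "read_deposition",
    "write_deposition",
    "read_cohort",
    "write_cohort",
    "write_doses",
    "read_doses",
    "write_summary",
    "write_curves",
    "write_manifest",
]

DEPOSITION_COLUMNS = ["location_id", "cs137_kBq_m2", "cs134_ratio", "i131_ratio"]
COHORT_COLUMNS = [
    "person_id",
    "sex",
    "birth_date",
    "followup_end",
    "end_reason",
    "location_id",
    "res_start",
    "res_end",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file, line and field."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_date(value: str, path, line: int, column: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError:
        raise ParseError(
            f"{path}, line {line}: invalid ISO date {value!r} in column {column}"
        ) from None


def read_deposition(path) -> list[DepositionRecord]:
    """Read a deposition table; duplicates and negative values are rejected."""
    df = pd.read_csv(path, dtype={"location_id": str}, float_precision="round_trip")
    _require_columns(df, DEPOSITION_COLUMNS, path)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: deposition table is empty", stacklevel=2)
        return []
    records = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        loc = str(row["location_id"])
        if loc in seen:
            raise ParseError(f"{path}, line {line}: duplicate location_id {loc!r}")
        seen.add(loc)
        try:
            rec = DepositionRecord(
                location_id=loc,
                cs137_dep=float(row["cs137_kBq_m2"]),
                cs134_ratio=float(row["cs134_ratio"]),
                i131_ratio=float(row["i131_ratio"]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {line}: {exc}") from None
        records.append(rec)
    return records


def write_deposition(records: list[DepositionRecord], path) -> None:
    df = pd.DataFrame(
        {
            "location_id": [r.location_id for r in records],
            "cs137_kBq_m2": [repr(r.cs137_dep) for r in records],
            "cs134_ratio": [repr(r.cs134_ratio) for r in records],
            "i131_ratio": [repr(r.i131_ratio) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_cohort(path) -> list[PersonRecord]:
    """Read a cohort table (one row per residence interval).

    Rows sharing a person_id must agree on the person-level attributes;
    residence intervals are validated for contiguity from the epoch to
    the end of follow-up (PersonRecord enforces this on construction).
    """
    df = pd.read_csv(path, dtype={"person_id": str, "location_id": str, "sex": str})
    _require_columns(df, COHORT_COLUMNS, path)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: cohort table is empty", stacklevel=2)
        return []
    persons: list[PersonRecord] = []
    for pid, group in df.groupby("person_id", sort=True):
        first = group.iloc[0]
        line0 = int(group.index[0]) + 2
        for col in ("sex", "birth_date", "followup_end", "end_reason"):
            if group[col].nunique() != 1:
                raise ParseError(
                    f"{path}: person {pid}: inconsistent {col} across residence rows"
                )
        birth = _parse_date(first["birth_date"], path, line0, "birth_date")
        fend = _parse_date(first["followup_end"], path, line0, "followup_end")
        residences = []
        for idx, row in group.iterrows():
            line = int(idx) + 2
            start = _parse_date(row["res_start"], path, line, "res_start")
            end = _parse_date(row["res_end"], path, line, "res_end")
            residences.append(
                Residence(
                    location_id=str(row["location_id"]),
                    start_day=(start - EPOCH).days,
                    end_day=(end - EPOCH).days,
                )
            )
        residences.sort(key=lambda r: r.start_day)
        try:
            persons.append(
                PersonRecord(
                    person_id=str(pid),
                    sex=str(first["sex"]),
                    birth_date=birth,
                    residences=tuple(residences),
                    followup_end=fend,
                    end_reason=str(first["end_reason"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return persons


def write_cohort(persons: list[PersonRecord], path) -> None:
    rows = []
    for p in persons:
        for res in p.residences:
            rows.append(
                {
                    "person_id": p.person_id,
                    "sex": p.sex,
                    "birth_date": p.birth_date.isoformat(),
                    "followup_end": p.followup_end.isoformat(),
                    "end_reason": p.end_reason,
                    "location_id": res.location_id,
                    "res_start": (EPOCH + datetime.timedelta(days=res.start_day)).isoformat(),
                    "res_end": (EPOCH + datetime.timedelta(days=res.end_day)).isoformat(),
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def write_doses(dose_table: pd.DataFrame, path) -> None:
    """Per-person dose table at full double precision."""
    df = dose_table.copy()
    for comp in COMPONENTS:
        df[comp] = df[comp].map(repr)
    df.to_csv(path, index=False)


def read_doses(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"person_id": str, "sex": str}, float_precision="round_trip"
    )
    _require_columns(df, ["person_id", "sex", *COMPONENTS], path)
    return df


def write_summary(summary: pd.DataFrame, path) -> None:
    """Human-readable summary, rounded to 3 decimals (mGy)."""
    df = summary.copy()
    for col in ("mean", "median", "p5", "p95", "min", "max"):
        df[col] = df[col].round(3)
    df.to_csv(path, index=False)


def write_curves(curves: pd.DataFrame, path) -> None:
    df = curves.copy()
    df["mean_mGy"] = df["mean_mGy"].map(repr)
    df.to_csv(path, index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config_path=None,
    input_paths: list | None = None,
    seed: int | None = None,
) -> Path:
    """Record the provenance of one run: config hash, input checksums, seed."""
    manifest = {
        "tool": "thyrodose",
        "version": __version__,
        "command": command,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": None,
        "inputs": [],
    }
    if config_path is not None:
        manifest["config"] = {"path": str(config_path), "sha256": _sha256(config_path)}
    for p in input_paths or []:
        manifest["inputs"].append({"path": str(p), "sha256": _sha256(p)})
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return out
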