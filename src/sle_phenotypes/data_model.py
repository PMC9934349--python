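"""Simplified OMOP-flavoured flat-file database: containers and readers/writers.

Tables are plain comma-separated text with a header row, using the OMOP
column names this package needs and nothing more:

* ``person.csv`` — person_id, sex, birth_year
* ``observation_period.csv`` — person_id, observation_period_start_date,
  observation_period_end_date
* ``condition_occurrence.csv`` — person_id, condition_start_date,
  vocabulary, code, visit_context
* ``drug_exposure.csv`` — person_id, drug_exposure_start_date,
  vocabulary, code, visit_context
* ``ground_truth.csv`` (optional) — person_id, has_sle, onset_date

In memory, conditions and drugs are merged into a single *events* frame with
columns ``person_id, event_date, domain, vocabulary, code, visit_context``.
Dates are ISO-8601 calendar dates; all window arithmetic elsewhere in the
package is in whole days.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PERSON_COLUMNS = ["person_id", "sex", "birth_year"]
OBSERVATION_COLUMNS = [
    "person_id",
    "observation_period_start_date",
    "observation_period_end_date",
]
EVENT_COLUMNS = ["person_id", "event_date", "domain", "vocabulary", "code",
                 "visit_context"]
GROUND_TRUTH_COLUMNS = ["person_id", "has_sle", "onset_date"]

_TABLE_FILES = {
    "person": "person.csv",
    "observation_period": "observation_period.csv",
    "condition_occurrence": "condition_occurrence.csv",
    "drug_exposure": "drug_exposure.csv",
}


class DatabaseError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class Database:
    """One observational database: persons, observation periods, events.

    ``ground_truth`` is present only for simulated databases and carries the
    latent SLE status (``has_sle``) and true onset date of every person.
    """

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    events: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def __eq__(self, other) -> bool:  # value equality, for round-trip checks
        if not isinstance(other, Database):
            return NotImplemented
        if (self.ground_truth is None) != (other.ground_truth is None):
            return False
        pairs = [
            (self.persons, other.persons),
            (self.observation_periods, other.observation_periods),
            (self.events, other.events),
        ]
        if self.ground_truth is not None:
            pairs.append((self.ground_truth, other.ground_truth))
        return all(a.reset_index(drop=True).equals(b.reset_index(drop=True))
                   for a, b in pairs)


def canonical_events(events: pd.DataFrame) -> pd.DataFrame:
    """Stable canonical ordering so equal databases compare equal."""
    return (
        events.sort_values(EVENT_COLUMNS, kind="mergesort")
        .reset_index(drop=True)[EVENT_COLUMNS]
    )


def _parse_dates(frame: pd.DataFrame, column: str, table: str) -> pd.Series:
    raw = frame[column]
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise DatabaseError(
            f"{table}: unparseable date {raw[bad].iloc[0]!r} in column "
            f"{column!r} at line {row}"
        )
    return parsed


def _read_table(directory: Path, table: str, columns: list[str]) -> pd.DataFrame:
    path = directory / _TABLE_FILES.get(table, f"{table}.csv")
    if not path.exists():
        raise DatabaseError(f"missing required table file: {path.name}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise DatabaseError(f"{path.name}: missing columns {missing}")
    return frame[columns]


def load_database(directory: str | Path) -> Database:
    """Load a database directory into typed frames.

    Checks referential integrity: every event (and ground-truth row) must
    reference an existing person.  A missing table, an orphan ``person_id``
    or an unparseable date is fatal.
    """
    directory = Path(directory)

    persons = _read_table(directory, "person", PERSON_COLUMNS)
    persons["person_id"] = persons["person_id"].astype(np.int64)
    persons["birth_year"] = persons["birth_year"].astype(np.int64)
    persons = persons.sort_values("person_id", kind="mergesort").reset_index(drop=True)

    obs = _read_table(directory, "observation_period", OBSERVATION_COLUMNS)
    obs["person_id"] = obs["person_id"].astype(np.int64)
    obs["observation_period_start_date"] = _parse_dates(
        obs, "observation_period_start_date", "observation_period.csv")
    obs["observation_period_end_date"] = _parse_dates(
        obs, "observation_period_end_date", "observation_period.csv")
    if (obs["observation_period_start_date"] > obs["observation_period_end_date"]).any():
        raise DatabaseError("observation_period.csv: start_date after end_date")
    obs = obs.sort_values(["person_id", "observation_period_start_date"],
                          kind="mergesort").reset_index(drop=True)

    frames = []
    for table, date_col, domain in [
        ("condition_occurrence", "condition_start_date", "condition"),
        ("drug_exposure", "drug_exposure_start_date", "drug"),
    ]:
        cols = ["person_id", date_col, "vocabulary", "code", "visit_context"]
        frame = _read_table(directory, table, cols)
        frame["person_id"] = frame["person_id"].astype(np.int64)
        frame[date_col] = _parse_dates(frame, date_col, f"{table}.csv")
        frame = frame.rename(columns={date_col: "event_date"})
        frame["domain"] = domain
        frames.append(frame[EVENT_COLUMNS])
    events = canonical_events(pd.concat(frames, ignore_index=True))

    known = set(persons["person_id"])
    orphans = sorted(set(events["person_id"]) - known)
    if orphans:
        raise DatabaseError(
            f"events reference unknown person_id(s): {orphans[:10]}")
    orphans = sorted(set(obs["person_id"]) - known)
    if orphans:
        raise DatabaseError(
            f"observation periods reference unknown person_id(s): {orphans[:10]}")

    truth_path = directory / "ground_truth.csv"
    ground_truth = None
    if truth_path.exists():
        gt = pd.read_csv(truth_path, dtype=str, keep_default_na=False)
        gt = gt[GROUND_TRUTH_COLUMNS]
        gt["person_id"] = gt["person_id"].astype(np.int64)
        gt["has_sle"] = gt["has_sle"].map({"True": True, "False": False})
        if gt["has_sle"].isna().any():
            raise DatabaseError("ground_truth.csv: has_sle must be True/False")
        gt["has_sle"] = gt["has_sle"].astype(bool)
        gt["onset_date"] = pd.to_datetime(
            gt["onset_date"].replace("", pd.NA), format="%Y-%m-%d", errors="raise")
        if (gt["has_sle"] != gt["onset_date"].notna()).any():
            raise DatabaseError(
                "ground_truth.csv: onset_date must be present iff has_sle")
        orphans = sorted(set(gt["person_id"]) - known)
        if orphans:
            raise DatabaseError(
                f"ground truth references unknown person_id(s): {orphans[:10]}")
        ground_truth = gt.sort_values("person_id", kind="mergesort").reset_index(drop=True)

    return Database(persons, obs, events, ground_truth)


def write_database(db: Database, directory: str | Path) -> list[Path]:
    """Write a database to a directory; round-trips through :func:`load_database`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = directory / name
        frame.to_csv(path, index=False, date_format="%Y-%m-%d")
        written.append(path)

    _write(db.persons[PERSON_COLUMNS], "person.csv")
    _write(db.observation_periods[OBSERVATION_COLUMNS], "observation_period.csv")

    ev = canonical_events(db.events)
    cond = ev[ev["domain"] == "condition"].rename(
        columns={"event_date": "condition_start_date"})
    _write(cond[["person_id", "condition_start_date", "vocabulary", "code",
                 "visit_context"]], "condition_occurrence.csv")
    drug = ev[ev["domain"] == "drug"].rename(
        columns={"event_date": "drug_exposure_start_date"})
    _write(drug[["person_id", "drug_exposure_start_date", "vocabulary", "code",
                 "visit_context"]], "drug_exposure.csv")

    if db.ground_truth is not None:
        _write(db.ground_truth[GROUND_TRUTH_COLUMNS], "ground_truth.csv")
    return written
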