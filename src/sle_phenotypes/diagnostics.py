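"""Population-level cohort characterisation and matched-comparator construction.

Counts, person-level overlap, incidence rates per 100,000 person-years,
index-event breakdown, temporal covariate prevalence around the index date,
binary standardized differences, and 1:k matching of non-cases on sex, age
band, and calendar month of diagnosis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concepts import ConceptRegistry
from .data_model import Database
from .simulate import age_band

logger = logging.getLogger(__name__)

#: Day windows relative to the index date used for temporal characterisation.
DEFAULT_WINDOWS = ((-365, -31), (-30, -1), (0, 0), (1, 30), (31, 365))


def cohort_counts(cohorts: pd.DataFrame) -> pd.Series:
    """Distinct persons per algorithm from a long-format cohort frame."""
    if cohorts.empty:
        return pd.Series(dtype=np.int64, name="n_persons")
    return (cohorts.groupby("algorithm_id")["person_id"].nunique()
            .rename("n_persons"))


def overlap(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame) -> tuple[int, int, int]:
    """Person-level (only-A, both, only-B) between two cohorts."""
    a = set(cohort_a["person_id"])
    b = set(cohort_b["person_id"])
    return len(a - b), len(a & b), len(b - a)


def smd_binary(p1: float, p2: float, pooled: bool = False) -> float | None:
    """Standardized difference between two binary-covariate proportions.

    Default is ``(p1 − p2) / sqrt(p1·q1 + p2·q2)``, the variant under which
    published comparisons are reported here; ``pooled=True`` divides the
    variance sum by 2 (the textbook form).  Returns None (with a warning)
    when both proportions sit at the same degenerate endpoint.
    """
    var = p1 * (1 - p1) + p2 * (1 - p2)
    if pooled:
        var /= 2.0
    if var == 0:
        logger.warning("smd_binary undefined for p1=%s, p2=%s", p1, p2)
        return None
    return (p1 - p2) / math.sqrt(var)


@dataclass
class SmdResult:
    covariate: str
    p1: float
    p2: float
    smd: float | None


def rate_per_100k(events: float, person_years: float) -> float:
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1e5 * events / person_years


def incidence_rate(cohort: pd.DataFrame, persons: pd.DataFrame,
                   observation_periods: pd.DataFrame,
                   strata: tuple[str, ...] = ()) -> pd.DataFrame:
    """Incidence per 100,000 person-years with optional stratification.

    At-risk time per person runs from 365 days after observation start to
    the earlier of their cohort index date and observation end, mirroring
    the incident algorithms' washout; persons observed under 365 days
    contribute nothing.  ``strata`` may contain ``"sex"``, ``"age_band"``
    (10-year band at the midpoint of the at-risk interval) and ``"year"``
    (calendar year, with person-time split across years).  Strata with zero
    person-years are omitted with a warning.
    """
    valid = {"sex", "age_band", "year"}
    if not set(strata) <= valid:
        raise ValueError(f"strata must be a subset of {sorted(valid)}")

    obs = observation_periods.rename(columns={
        "observation_period_start_date": "obs_start",
        "observation_period_end_date": "obs_end"})
    frame = obs.merge(persons[["person_id", "sex", "birth_year"]], on="person_id")
    index = cohort.set_index("person_id")["index_date"] if len(cohort) else \
        pd.Series(dtype="datetime64[ns]")
    frame["index_date"] = frame["person_id"].map(index)

    frame["risk_start"] = frame["obs_start"] + pd.Timedelta(days=365)
    frame["risk_end"] = frame[["obs_end", "index_date"]].min(axis=1)
    frame = frame[frame["risk_end"] >= frame["risk_start"]].copy()
    if frame.empty:
        return pd.DataFrame(columns=["age_band", "sex", "year", "events",
                                     "person_years", "rate_per_100k"])

    mid = frame["risk_start"] + (frame["risk_end"] - frame["risk_start"]) / 2
    frame["age_band"] = [
        age_band(y - by) for y, by in zip(mid.dt.year, frame["birth_year"])
    ] if "age_band" in strata else "all"
    if "sex" not in strata:
        frame["sex"] = "all"
    frame["event"] = (frame["index_date"].notna()
                      & (frame["index_date"] >= frame["risk_start"])
                      & (frame["index_date"] <= frame["risk_end"])).astype(int)

    rows = []
    if "year" in strata:
        for row in frame.itertuples():
            for year in range(row.risk_start.year, row.risk_end.year + 1):
                seg_start = max(row.risk_start, pd.Timestamp(year=year, month=1, day=1))
                seg_end = min(row.risk_end, pd.Timestamp(year=year, month=12, day=31))
                days = (seg_end - seg_start).days + 1
                if days <= 0:
                    continue
                event = int(row.event and row.index_date.year == year)
                rows.append((row.age_band, row.sex, str(year), event, days))
        long = pd.DataFrame(rows, columns=["age_band", "sex", "year", "event",
                                           "days"])
    else:
        long = frame[["age_band", "sex", "event"]].copy()
        long["year"] = "all"
        long["days"] = (frame["risk_end"] - frame["risk_start"]).dt.days + 1

    grouped = (long.groupby(["age_band", "sex", "year"], as_index=False)
               .agg(events=("event", "sum"), days=("days", "sum")))
    grouped["person_years"] = grouped["days"] / 365.25
    zero = grouped["person_years"] <= 0
    if zero.any():
        logger.warning("omitting %d strata with zero person-years", int(zero.sum()))
        grouped = grouped[~zero]
    grouped["rate_per_100k"] = 1e5 * grouped["events"] / grouped["person_years"]
    return grouped.drop(columns="days").reset_index(drop=True)


def temporal_characterization(cohort: pd.DataFrame, events: pd.DataFrame,
                              registry: ConceptRegistry,
                              windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Fraction of cohort persons with ≥1 event per concept set per window.

    Windows are inclusive day ranges relative to each person's index date.
    """
    n = cohort["person_id"].nunique()
    rows = []
    if n == 0:
        return pd.DataFrame(columns=["window_start", "window_end", "concept_set",
                                     "proportion"])
    joined = events.merge(cohort[["person_id", "index_date"]], on="person_id")
    joined["delta"] = (joined["event_date"] - joined["index_date"]).dt.days
    for lo, hi in windows:
        in_window = joined[(joined["delta"] >= lo) & (joined["delta"] <= hi)]
        for name, cs in sorted(registry.sets.items()):
            pairs = cs.pairs()
            mask = in_window[["vocabulary", "code"]].apply(tuple, axis=1).isin(pairs) \
                if len(in_window) else pd.Series(dtype=bool)
            hit = in_window.loc[mask, "person_id"].nunique() if len(in_window) else 0
            rows.append((lo, hi, name, hit / n))
    return pd.DataFrame(rows, columns=["window_start", "window_end",
                                       "concept_set", "proportion"])


def index_event_breakdown(cohort: pd.DataFrame) -> pd.Series:
    """Fraction of cohort entries per entry-event role (sums to 1)."""
    if cohort.empty:
        return pd.Series(dtype=float, name="fraction")
    return (cohort["entry_event_role"].value_counts(normalize=True)
            .rename("fraction"))


def match_controls(cohort: pd.DataFrame, db: Database, ratio: int = 10,
                   seed: int = 0, exclude_person_ids=None,
                   age_band_width: int = 5) -> pd.DataFrame:
    """Match non-cohort persons to each cohort entry on sex, age band, and month.

    For each case, up to ``ratio`` controls are sampled without replacement
    (globally — a control serves one case only) from persons outside the
    cohort who share the case's sex and ``age_band_width``-year age band and
    have at least one clinical event in the calendar month of the case's
    index date; that event's date becomes the control's matched index.
    Controls must have ≥365 days of observation before their matched index,
    mirroring the incident washout.  Deterministic under a fixed seed;
    shortfalls are logged.
    """
    if exclude_person_ids is None:
        exclude_person_ids = set(cohort["person_id"])
    else:
        exclude_person_ids = set(exclude_person_ids) | set(cohort["person_id"])

    pool_persons = db.persons[~db.persons["person_id"].isin(exclude_person_ids)]
    if pool_persons.empty:
        raise ValueError("empty candidate pool: no persons outside the cohort")

    obs = db.observation_periods.rename(columns={
        "observation_period_start_date": "obs_start",
        "observation_period_end_date": "obs_end"})
    cand = (db.events[db.events["person_id"].isin(pool_persons["person_id"])]
            [["person_id", "event_date"]]
            .merge(pool_persons[["person_id", "sex", "birth_year"]], on="person_id")
            .merge(obs[["person_id", "obs_start", "obs_end"]], on="person_id"))
    cand = cand[(cand["event_date"] >= cand["obs_start"])
                & (cand["event_date"] <= cand["obs_end"])
                & ((cand["event_date"] - cand["obs_start"]).dt.days >= 365)]
    # earliest qualifying event per person per month is that person's
    # candidate index for the month
    cand = cand.assign(
        ym=cand["event_date"].dt.strftime("%Y-%m"),
        band=[age_band(y - by, age_band_width)
              for y, by in zip(cand["event_date"].dt.year, cand["birth_year"])],
    )
    cand = (cand.sort_values(["person_id", "ym", "event_date"], kind="mergesort")
            .groupby(["person_id", "ym", "band", "sex"], as_index=False)
            ["event_date"].first())

    cases = cohort.merge(db.persons[["person_id", "sex", "birth_year"]],
                         on="person_id")
    cases = cases.assign(
        ym=cases["index_date"].dt.strftime("%Y-%m"),
        band=[age_band(y - by, age_band_width)
              for y, by in zip(cases["index_date"].dt.year, cases["birth_year"])],
    ).sort_values("person_id", kind="mergesort")

    rng = np.random.default_rng(seed)
    grouped = {key: sub for key, sub in cand.groupby(["sex", "band", "ym"])}
    used: set[int] = set()
    rows = []
    for case in cases.itertuples():
        sub = grouped.get((case.sex, case.band, case.ym))
        if sub is None:
            logger.warning("no candidates at all for case %s", case.person_id)
            continue
        avail = sub[~sub["person_id"].isin(used)]
        take = min(ratio, len(avail))
        if take < ratio:
            logger.warning("case %s matched %d/%d controls",
                           case.person_id, take, ratio)
        if take == 0:
            continue
        pick = avail.iloc[rng.choice(len(avail), size=take, replace=False)]
        for ctrl in pick.itertuples():
            used.add(ctrl.person_id)
            rows.append((case.person_id, ctrl.person_id, ctrl.event_date,
                         case.sex, case.band))
    return pd.DataFrame(rows, columns=["case_person_id", "control_person_id",
                                       "matched_index_date", "sex", "age_band"])
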