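"""Phenotype algorithms for SLE cohort construction.

Four algorithms cross two axes:

* **incident vs prevalent** — incident requires at least 365 days of
  observation before the (corrected) index date; prevalent does not.
* **1X vs 2X** — 1X admits anyone with at least one SLE diagnosis code; 2X
  additionally requires a second SLE code 31–365 days (inclusive) after the
  first code.

Every algorithm corrects possible index-date misclassification: if a sign,
symptom, or SLE treatment drug occurs 1–90 days before the first diagnosis
code, the earliest such event becomes the index date.  Early disease is
frequently coded only as malaise, joint pain, fatigue, or a steroid
prescription, so anchoring on the first diagnosis code alone would date
cohort entry too late.

Two published comparator algorithms are also provided: three or more SLE
codes on distinct days plus ever-use of an antimalarial, with and without
exclusion of dermatomyositis / systemic sclerosis.

All operations are deterministic and order-independent: shuffling the input
event rows never changes the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .concepts import ConceptRegistry, PRECURSOR_ROLES
from .data_model import Database

COHORT_COLUMNS = [
    "algorithm_id",
    "person_id",
    "index_date",
    "first_dx_date",
    "entry_event_role",
    "vocabulary",
    "code",
]

ALGORITHM_IDS = (
    "incident_1x",
    "incident_2x",
    "prevalent_1x",
    "prevalent_2x",
    "barnado_3x_am",
    "barnado_3x_am_excl",
)


@dataclass(frozen=True)
class AlgorithmSpec:
    """Declarative description of one phenotype algorithm.

    ``washout_days`` is the minimum prior observation required at the
    corrected index date (365 for incident algorithms, 0 for prevalent);
    ``second_code_window`` is the inclusive (min, max) day window after the
    first diagnosis code within which a confirmatory code must fall, or
    ``None`` for the 1X algorithms.
    """

    algorithm_id: str
    washout_days: int = 0
    correction_window_days: int = 90
    second_code_window: Optional[tuple[int, int]] = None
    min_code_count: int = 1
    require_ever_antimalarial: bool = False
    exclusion_set_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.washout_days < 0 or self.correction_window_days < 0:
            raise ValueError("windows must be non-negative")
        if self.second_code_window is not None:
            lo, hi = self.second_code_window
            if lo > hi:
                raise ValueError("second_code_window min must be <= max")
        if self.min_code_count < 1:
            raise ValueError("min_code_count must be >= 1")


PAPER_ALGORITHMS: dict[str, AlgorithmSpec] = {
    "incident_1x": AlgorithmSpec("incident_1x", washout_days=365),
    "incident_2x": AlgorithmSpec(
        "incident_2x", washout_days=365, second_code_window=(31, 365),
        min_code_count=2),
    "prevalent_1x": AlgorithmSpec("prevalent_1x"),
    "prevalent_2x": AlgorithmSpec(
        "prevalent_2x", second_code_window=(31, 365), min_code_count=2),
}

BARNADO_ALGORITHMS: dict[str, AlgorithmSpec] = {
    "barnado_3x_am": AlgorithmSpec(
        "barnado_3x_am", correction_window_days=0, min_code_count=3,
        require_ever_antimalarial=True),
    "barnado_3x_am_excl": AlgorithmSpec(
        "barnado_3x_am_excl", correction_window_days=0, min_code_count=3,
        require_ever_antimalarial=True, exclusion_set_name="barnado_exclusions"),
}


def get_algorithm(algorithm_id: str) -> AlgorithmSpec:
    spec = PAPER_ALGORITHMS.get(algorithm_id) or BARNADO_ALGORITHMS.get(algorithm_id)
    if spec is None:
        raise ValueError(f"unknown algorithm_id {algorithm_id!r}; "
                         f"expected one of {ALGORITHM_IDS}")
    return spec


def tag_roles(events: pd.DataFrame, registry: ConceptRegistry) -> pd.DataFrame:
    """Attach a ``role`` column; events with several roles appear once per role."""
    roles = registry.role_frame()
    return events.merge(roles, on=["vocabulary", "code"], how="inner")


# ---------------------------------------------------------------------------
# scalar operations (per-person event histories)
# ---------------------------------------------------------------------------

def first_sle_code_date(events: pd.DataFrame, registry: ConceptRegistry):
    """Earliest SLE diagnosis code date in one person's history, or None."""
    tagged = tag_roles(events, registry)
    dx = tagged[tagged["role"] == "sle_diagnosis"]
    if dx.empty:
        return None
    return dx["event_date"].min()


def correct_index_date(events: pd.DataFrame, first_dx_date, registry: ConceptRegistry,
                       window_days: int = 90):
    """Re-anchor the index date on a qualifying precursor event.

    Among sign/symptom and treatment-drug events falling 1..``window_days``
    days before ``first_dx_date``, the earliest becomes the index date; with
    no qualifying precursor, the index stays at the first diagnosis code.
    There is no chaining: only events within the window of the first code
    qualify.  Returns ``(index_date, entry_event_role, (vocabulary, code))``.
    """
    tagged = tag_roles(events, registry)
    pre = tagged[tagged["role"].isin(PRECURSOR_ROLES)].copy()
    if not pre.empty:
        gap = (first_dx_date - pre["event_date"]).dt.days
        pre = pre[(gap >= 1) & (gap <= window_days)]
    if pre.empty:
        dx = tagged[(tagged["role"] == "sle_diagnosis")
                    & (tagged["event_date"] == first_dx_date)]
        dx = dx.sort_values(["vocabulary", "code"], kind="mergesort")
        return first_dx_date, "sle_diagnosis", (dx["vocabulary"].iloc[0],
                                                dx["code"].iloc[0])
    pre["role_rank"] = pre["role"].map({r: i for i, r in enumerate(PRECURSOR_ROLES)})
    pre = pre.sort_values(["event_date", "role_rank", "vocabulary", "code"],
                          kind="mergesort")
    top = pre.iloc[0]
    return top["event_date"], top["role"], (top["vocabulary"], top["code"])


def second_code_present(events: pd.DataFrame, first_dx_date,
                        registry: ConceptRegistry,
                        window: tuple[int, int] = (31, 365)) -> bool:
    """True iff a confirmatory SLE code falls in the inclusive day window."""
    tagged = tag_roles(events, registry)
    dx = tagged[tagged["role"] == "sle_diagnosis"]
    delta = (dx["event_date"] - first_dx_date).dt.days
    return bool(((delta >= window[0]) & (delta <= window[1])).any())


def lookback_satisfied(index_date, observation_period, washout_days: int = 365) -> bool:
    """True iff at least ``washout_days`` of observation precede the index."""
    start = observation_period["observation_period_start_date"] \
        if isinstance(observation_period, (dict, pd.Series)) else observation_period
    return (index_date - start).days >= washout_days


# ---------------------------------------------------------------------------
# vectorised cohort construction
# ---------------------------------------------------------------------------

def _precursor_correction(tagged: pd.DataFrame, first_dx: pd.DataFrame,
                          window_days: int) -> pd.DataFrame:
    """Per person: corrected index and entry event, vectorised.

    ``first_dx`` has columns person_id, first_dx_date.  Ties on the earliest
    qualifying precursor break on (role: sign/symptom first, vocabulary,
    code) for determinism.
    """
    pre = tagged[tagged["role"].isin(PRECURSOR_ROLES)].merge(first_dx, on="person_id")
    gap = (pre["first_dx_date"] - pre["event_date"]).dt.days
    pre = pre[(gap >= 1) & (gap <= window_days)].copy()
    pre["role_rank"] = pre["role"].map({r: i for i, r in enumerate(PRECURSOR_ROLES)})
    pre = pre.sort_values(
        ["person_id", "event_date", "role_rank", "vocabulary", "code"],
        kind="mergesort")
    best = pre.groupby("person_id", as_index=False).first()

    # entry event for uncorrected persons: the first diagnosis code itself
    dx = tagged[tagged["role"] == "sle_diagnosis"].merge(first_dx, on="person_id")
    dx = dx[dx["event_date"] == dx["first_dx_date"]]
    dx = dx.sort_values(["person_id", "vocabulary", "code"], kind="mergesort")
    dx_best = dx.groupby("person_id", as_index=False).first()

    out = first_dx.merge(
        best[["person_id", "event_date", "role", "vocabulary", "code"]],
        on="person_id", how="left")
    out = out.merge(
        dx_best[["person_id", "vocabulary", "code"]].rename(
            columns={"vocabulary": "dx_vocabulary", "code": "dx_code"}),
        on="person_id", how="left")
    corrected = out["event_date"].notna()
    out["index_date"] = out["event_date"].where(corrected, out["first_dx_date"])
    out["entry_event_role"] = out["role"].where(corrected, "sle_diagnosis")
    out["vocabulary"] = out["vocabulary"].where(corrected, out["dx_vocabulary"])
    out["code"] = out["code"].where(corrected, out["dx_code"])
    return out[["person_id", "first_dx_date", "index_date", "entry_event_role",
                "vocabulary", "code"]]


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame({
        "algorithm_id": pd.Series(dtype=str),
        "person_id": pd.Series(dtype=np.int64),
        "index_date": pd.Series(dtype="datetime64[ns]"),
        "first_dx_date": pd.Series(dtype="datetime64[ns]"),
        "entry_event_role": pd.Series(dtype=str),
        "vocabulary": pd.Series(dtype=str),
        "code": pd.Series(dtype=str),
    })


def build_cohort(spec: AlgorithmSpec | str, db: Database,
                 registry: ConceptRegistry) -> pd.DataFrame:
    """Run one of the four index-date–corrected algorithms over a database.

    Returns one row per admitted person with columns ``algorithm_id,
    person_id, index_date, first_dx_date, entry_event_role, vocabulary,
    code``.  The second-code window is anchored on the first diagnosis code
    (not the corrected index); the incident look-back is evaluated at the
    corrected index date.
    """
    if isinstance(spec, str):
        spec = get_algorithm(spec)
    if spec.algorithm_id in BARNADO_ALGORITHMS:
        return build_barnado_cohort(spec, db, registry)
    if spec.algorithm_id not in PAPER_ALGORITHMS:
        raise ValueError(f"unknown algorithm_id {spec.algorithm_id!r}")

    tagged = tag_roles(db.events, registry)
    dx = tagged[tagged["role"] == "sle_diagnosis"]
    if dx.empty:
        return _empty_cohort()

    first_dx = (dx.groupby("person_id", as_index=False)["event_date"].min()
                .rename(columns={"event_date": "first_dx_date"}))

    if spec.second_code_window is not None:
        lo, hi = spec.second_code_window
        joined = dx.merge(first_dx, on="person_id")
        delta = (joined["event_date"] - joined["first_dx_date"]).dt.days
        confirmed = joined.loc[(delta >= lo) & (delta <= hi), "person_id"].unique()
        first_dx = first_dx[first_dx["person_id"].isin(confirmed)]
        if first_dx.empty:
            return _empty_cohort()

    entries = _precursor_correction(tagged, first_dx, spec.correction_window_days)

    if spec.washout_days > 0:
        obs = db.observation_periods.rename(columns={
            "observation_period_start_date": "obs_start",
            "observation_period_end_date": "obs_end"})
        joined = entries.merge(obs, on="person_id", how="left")
        inside = (joined["index_date"] >= joined["obs_start"]) & (
            joined["index_date"] <= joined["obs_end"])
        lookback = (joined["index_date"] - joined["obs_start"]).dt.days >= spec.washout_days
        ok = joined.loc[inside & lookback, "person_id"].unique()
        entries = entries[entries["person_id"].isin(ok)]

    entries = entries.copy()
    entries["algorithm_id"] = spec.algorithm_id
    return (entries[COHORT_COLUMNS]
            .sort_values("person_id", kind="mergesort")
            .reset_index(drop=True))


def build_barnado_cohort(variant: AlgorithmSpec | str, db: Database,
                         registry: ConceptRegistry) -> pd.DataFrame:
    """Comparator algorithms: ≥3 SLE codes on distinct days + ever antimalarial.

    ``barnado_3x_am_excl`` additionally excludes anyone with a
    dermatomyositis or systemic sclerosis code at any time.  The index date
    is the later of the third distinct-day SLE code and the first
    antimalarial exposure.  Unlike the four correction algorithms, the index
    date here follows (never precedes) the first diagnosis code.
    """
    if isinstance(variant, str):
        variant = get_algorithm(variant)
    if variant.algorithm_id not in BARNADO_ALGORITHMS:
        raise ValueError(f"not a comparator algorithm: {variant.algorithm_id!r}")

    tagged = tag_roles(db.events, registry)
    dx = tagged[tagged["role"] == "sle_diagnosis"]
    am = tagged[tagged["role"] == "antimalarial"]
    if dx.empty or am.empty:
        return _empty_cohort()

    distinct = (dx[["person_id", "event_date"]].drop_duplicates()
                .sort_values(["person_id", "event_date"], kind="mergesort"))
    distinct["rank"] = distinct.groupby("person_id").cumcount() + 1
    third = distinct[distinct["rank"] == variant.min_code_count].rename(
        columns={"event_date": "third_dx_date"})[["person_id", "third_dx_date"]]

    first_am = (am.groupby("person_id", as_index=False)["event_date"].min()
                .rename(columns={"event_date": "first_am_date"}))
    qualified = third.merge(first_am, on="person_id")
    if variant.exclusion_set_name is not None:
        excluded = tagged.loc[tagged["role"] == "exclusion_dx", "person_id"].unique()
        qualified = qualified[~qualified["person_id"].isin(excluded)]
    if qualified.empty:
        return _empty_cohort()

    qualified["index_date"] = qualified[["third_dx_date", "first_am_date"]].max(axis=1)

    first_dx = (dx.groupby("person_id", as_index=False)["event_date"].min()
                .rename(columns={"event_date": "first_dx_date"}))
    entry = dx.merge(qualified[["person_id", "third_dx_date"]], on="person_id")
    entry = entry[entry["event_date"] == entry["third_dx_date"]]
    entry = (entry.sort_values(["person_id", "vocabulary", "code"], kind="mergesort")
             .groupby("person_id", as_index=False).first())

    out = qualified.merge(first_dx, on="person_id").merge(
        entry[["person_id", "vocabulary", "code"]], on="person_id")
    out["entry_event_role"] = "sle_diagnosis"
    out["algorithm_id"] = variant.algorithm_id
    return (out[COHORT_COLUMNS]
            .sort_values("person_id", kind="mergesort")
            .reset_index(drop=True))


def build_all_cohorts(db: Database, registry: ConceptRegistry,
                      algorithm_ids=ALGORITHM_IDS) -> pd.DataFrame:
    """Concatenated cohorts for several algorithms (one frame, long format)."""
    frames = [build_cohort(a, db, registry) for a in algorithm_ids]
    return pd.concat(frames, ignore_index=True)
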