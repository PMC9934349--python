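"""Synthetic longitudinal-claims simulator with known ground truth.

Real claims and EHR databases are proprietary; this module generates
databases with the same *structure* — persons with demographics, one bounded
observation period each, dated diagnosis and drug events — plus the latent
truth (SLE yes/no and true onset date) that real data never reveal.  The
generative model is a stand-in chosen for plausibility, not a fit to any
real database; see docs/methods.md for what it does and does not emulate.

Mechanisms the phenotype algorithms exploit are modelled explicitly:

* **diagnosis delay** — the first SLE code trails true onset by a geometric
  number of days (mean ``dx_delay_days_mean``);
* **prodrome** — with probability ``prodrome_prob`` a case has 1–3
  sign/symptom or treatment-drug events in the 90 days before its first
  code (what index-date correction recovers);
* **repeat coding** — further SLE codes arrive as a per-month Bernoulli
  process (what the 2X confirmation requires);
* **prevalent disease** — a fraction of cases have onset before observation
  start and are seen only through ongoing repeat coding (what the incident
  look-back excludes);
* **rule-out codes** — a small fraction of non-cases get exactly one
  spurious SLE code, never repeated and never accompanied by an
  antimalarial (the false positives the 2X and comparator rules remove).

Determinism: all draws come from one ``numpy`` generator seeded from
``config.seed``, in a fixed documented order (person-level vectors first,
then the per-case event loop in person order, then non-case and background
events).  The same config always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .concepts import ConceptRegistry, default_registry
from .data_model import Database, canonical_events

_EPOCH = np.datetime64("1970-01-01", "D")

#: Relative hazard by 10-year age band, peaking at the configured band.
_AGE_SHAPE = (0.3, 0.7, 1.0, 1.3, 1.6, 1.2, 0.8, 0.5)
_AGE_BANDS = ("10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79",
              "80-89")

_VISIT_TYPES = np.array(["outpatient", "inpatient", "emergency", "none"])
_VISIT_PROBS = np.array([0.75, 0.05, 0.10, 0.10])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population; defaults are the study conditions.

    Incidence defaults to 16 per 100,000 person-years with a female:male
    case hazard ratio giving roughly 88% female cases and an age peak in the
    50–59 band; 45% of cases carry a prodrome in the 90 days before their
    first diagnosis code; 38% of cases ever receive hydroxychloroquine.
    """

    n_persons: int = 10_000
    seed: int = 0
    calendar_window: tuple[str, str] = ("2010-01-01", "2020-12-31")
    followup_years_median: float = 1.5
    female_fraction_population: float = 0.5
    sle_incidence_per_100k_py: float = 16.0
    female_case_multiplier: float = 7.3
    age_peak_band: str = "50-59"
    prevalent_case_fraction: float = 0.3
    dx_delay_days_mean: float = 45.0
    prodrome_prob: float = 0.45
    prodrome_lead_days_max: int = 90
    repeat_code_prob_per_month: float = 0.25
    ruleout_code_prob: float = 0.002
    hcq_prob_cases: float = 0.38
    hcq_prob_noncases: float = 0.002
    background_symptom_rate_per_py: float = 0.3
    comorbidity_enrichment: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "rheumatoid_arthritis": (0.15, 0.01),
            "renal_impairment": (0.10, 0.01),
        })

    def __post_init__(self) -> None:
        if self.n_persons < 0:
            raise ValueError("invalid config field n_persons: must be >= 0")
        for name in ("female_fraction_population", "prevalent_case_fraction",
                     "prodrome_prob", "repeat_code_prob_per_month",
                     "ruleout_code_prob", "hcq_prob_cases", "hcq_prob_noncases"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid config field {name}: {v} not in [0, 1]")
        for name in ("followup_years_median", "sle_incidence_per_100k_py",
                     "female_case_multiplier", "dx_delay_days_mean",
                     "background_symptom_rate_per_py"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name}: must be >= 0")
        if self.prodrome_lead_days_max < 1:
            raise ValueError("invalid config field prodrome_lead_days_max: must be >= 1")
        if self.age_peak_band not in _AGE_BANDS:
            raise ValueError(
                f"invalid config field age_peak_band: {self.age_peak_band!r} "
                f"not one of {_AGE_BANDS}")
        start, end = (np.datetime64(d, "D") for d in self.calendar_window)
        if end - start < np.timedelta64(60, "D"):
            raise ValueError("invalid config field calendar_window: too short")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        if "comorbidity_enrichment" in kwargs and kwargs["comorbidity_enrichment"]:
            kwargs["comorbidity_enrichment"] = {
                k: tuple(v) for k, v in kwargs["comorbidity_enrichment"].items()}
        return replace(self, **kwargs)


def _age_multipliers(peak_band: str) -> dict[str, float]:
    shift = _AGE_BANDS.index(peak_band) - _AGE_SHAPE.index(max(_AGE_SHAPE))
    rolled = np.roll(_AGE_SHAPE, shift)
    return dict(zip(_AGE_BANDS, rolled))


def age_band(age: int, width: int = 10) -> str:
    lo = width * (int(age) // width)
    return f"{lo}-{lo + width - 1}"


def _uniform_dates(rng, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Uniform integer day in [start, end], elementwise."""
    u = rng.random(len(start))
    return start + np.floor(u * (end - start + 1)).astype(np.int64)


def simulate_population(config: SimulationConfig,
                        registry: ConceptRegistry | None = None) -> Database:
    """Generate a synthetic database plus ground truth.

    Codes are drawn from the registry's concept sets (defaults shipped with
    the package), so the generated events are classifiable by the same
    registry the algorithms use.
    """
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    cal_start = (np.datetime64(config.calendar_window[0], "D") - _EPOCH).astype(int)
    cal_end = (np.datetime64(config.calendar_window[1], "D") - _EPOCH).astype(int)
    span = cal_end - cal_start

    dx_codes = registry.codes_for_role("sle_diagnosis")
    sign_codes = registry.codes_for_role("sle_sign_symptom")
    drug_codes = registry.codes_for_role("sle_treatment_drug")
    hcq = ("RxNorm", "5521")

    # --- person-level draws (fixed order) -------------------------------
    person_id = np.arange(1, n + 1, dtype=np.int64)
    female = rng.random(n) < config.female_fraction_population
    age = np.clip(np.round(rng.normal(38.0, 16.0, n)), 18, 85).astype(np.int64)
    offset = rng.integers(0, max(span - 30, 1), n) if n else np.zeros(0, np.int64)
    obs_start = cal_start + offset
    scale = config.followup_years_median * 365.25 / np.log(2.0)
    duration = np.maximum(rng.exponential(scale, n).astype(np.int64), 30)
    duration = np.minimum(duration, cal_end - obs_start)
    obs_end = obs_start + duration
    py = duration / 365.25

    w_sex = np.where(female, config.female_case_multiplier, 1.0)
    age_mult_map = _age_multipliers(config.age_peak_band)
    bands = np.array([age_band(a) for a in age]) if n else np.zeros(0, dtype=object)
    w_age = np.array([age_mult_map[b] for b in bands]) if n else np.zeros(0)
    mult = w_sex * w_age
    if n and mult.mean() > 0:
        mult = mult / mult.mean()
    p_incident = config.sle_incidence_per_100k_py / 1e5 * py * mult
    denom = max(1.0 - config.prevalent_case_fraction, 1e-12)
    p_case = np.clip(p_incident / denom, 0.0, 1.0)

    u_case = rng.random(n)
    u_prev = rng.random(n)
    prev_lead = rng.integers(1, 3651, n) if n else np.zeros(0, np.int64)
    u_onset = rng.random(n)
    delay = rng.geometric(1.0 / max(config.dx_delay_days_mean, 1.0), n) if n \
        else np.zeros(0, np.int64)
    has_prodrome = rng.random(n) < config.prodrome_prob
    prodrome_k = rng.integers(1, 4, n) if n else np.zeros(0, np.int64)
    u_hcq_case = rng.random(n)
    u_ruleout = rng.random(n)
    u_hcq_noncase = rng.random(n)

    case = u_case < p_case
    prevalent = case & (u_prev < config.prevalent_case_fraction)
    onset = np.where(
        prevalent,
        obs_start - prev_lead,
        obs_start + np.floor(u_onset * (duration + 1)).astype(np.int64))
    onset = np.where(case, onset, 0)

    cols: dict[str, list] = {k: [] for k in
                             ("person_id", "event_date", "domain", "vocabulary",
                              "code", "visit_context")}

    def emit(pids, dates, domain, vocab, code, visits):
        cols["person_id"].extend(np.asarray(pids, dtype=np.int64))
        cols["event_date"].extend(np.asarray(dates, dtype=np.int64))
        k = len(dates)
        for key, val in (("domain", domain), ("vocabulary", vocab),
                         ("code", code), ("visit_context", visits)):
            if isinstance(val, str):
                cols[key].extend([val] * k)
            else:
                cols[key].extend(val)

    # --- per-case event loop (person order) -----------------------------
    truth_detected = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(case):
        first_code = onset[i] + delay[i]
        if first_code > obs_end[i]:
            continue
        n_months = max(int(np.ceil((obs_end[i] - first_code) / 30.0)), 0)
        hits = rng.random(n_months) < config.repeat_code_prob_per_month
        seq = np.concatenate([[first_code],
                              first_code + 30 * (np.flatnonzero(hits) + 1)])
        observed = seq[(seq >= obs_start[i]) & (seq <= obs_end[i])]
        if observed.size == 0:
            continue
        truth_detected[i] = True
        f = int(observed[0])
        idx = rng.integers(0, len(dx_codes), observed.size)
        visits = rng.choice(_VISIT_TYPES, observed.size, p=_VISIT_PROBS)
        emit(np.full(observed.size, person_id[i]), observed, "condition",
             [dx_codes[j][0] for j in idx], [dx_codes[j][1] for j in idx], visits)

        if has_prodrome[i]:
            lo = max(int(obs_start[i]), f - config.prodrome_lead_days_max)
            if lo <= f - 1:
                dates = rng.integers(lo, f, prodrome_k[i])
                kinds = rng.random(prodrome_k[i]) < 0.7
                for d, is_sign in zip(dates, kinds):
                    pool = sign_codes if is_sign else drug_codes
                    v, c = pool[rng.integers(0, len(pool))]
                    emit([person_id[i]], [d],
                         "condition" if is_sign else "drug", v, c,
                         "outpatient" if is_sign else "none")
        if u_hcq_case[i] < config.hcq_prob_cases:
            d = int(rng.integers(f, obs_end[i] + 1))
            emit([person_id[i]], [d], "drug", hcq[0], hcq[1], "none")

    # --- non-case rule-out codes and stray hydroxychloroquine -----------
    noncase = ~case
    ruleout = noncase & (u_ruleout < config.ruleout_code_prob)
    ro_idx = np.flatnonzero(ruleout)
    if ro_idx.size:
        dates = _uniform_dates(rng, obs_start[ro_idx], obs_end[ro_idx])
        idx = rng.integers(0, len(dx_codes), ro_idx.size)
        visits = rng.choice(_VISIT_TYPES, ro_idx.size, p=_VISIT_PROBS)
        emit(person_id[ro_idx], dates, "condition",
             [dx_codes[j][0] for j in idx], [dx_codes[j][1] for j in idx], visits)

    # rule-out persons never receive antimalarials (the comparator rules
    # and 2X confirmation rely on exactly that separation)
    stray = noncase & ~ruleout & (u_hcq_noncase < config.hcq_prob_noncases)
    st_idx = np.flatnonzero(stray)
    if st_idx.size:
        dates = _uniform_dates(rng, obs_start[st_idx], obs_end[st_idx])
        emit(person_id[st_idx], dates, "drug", hcq[0], hcq[1], "none")

    # --- background sign/symptom noise (everyone) -----------------------
    if config.background_symptom_rate_per_py > 0 and n:
        counts = rng.poisson(config.background_symptom_rate_per_py * py)
        rep = np.repeat(np.arange(n), counts)
        if rep.size:
            dates = _uniform_dates(rng, obs_start[rep], obs_end[rep])
            idx = rng.integers(0, len(sign_codes), rep.size)
            emit(person_id[rep], dates, "condition",
                 [sign_codes[j][0] for j in idx],
                 [sign_codes[j][1] for j in idx], "outpatient")

    # --- comorbidity enrichment -----------------------------------------
    for name in sorted(config.comorbidity_enrichment):
        case_rate, noncase_rate = config.comorbidity_enrichment[name]
        cs = registry.sets.get(name)
        if cs is None or not cs.codes:
            raise ValueError(f"comorbidity_enrichment names unknown concept set "
                             f"{name!r}")
        p = np.where(case, case_rate, noncase_rate)
        flag = np.flatnonzero(rng.random(n) < p)
        if flag.size:
            dates = _uniform_dates(rng, obs_start[flag], obs_end[flag])
            idx = rng.integers(0, len(cs.codes), flag.size)
            emit(person_id[flag], dates, "condition",
                 [cs.codes[j][0] for j in idx], [cs.codes[j][1] for j in idx],
                 "outpatient")

    # --- assemble frames -------------------------------------------------
    def _days_to_ts(arr) -> pd.Series:
        return pd.Series(pd.to_datetime(np.asarray(arr, dtype=np.int64),
                                        unit="D"))

    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": pd.Series(np.where(female, "female", "male"), dtype=str),
        "birth_year": np.asarray(
            pd.to_datetime(obs_start, unit="D").year - age
            if n else [], dtype=np.int64),
    })
    obs = pd.DataFrame({
        "person_id": person_id,
        "observation_period_start_date": _days_to_ts(obs_start),
        "observation_period_end_date": _days_to_ts(obs_end),
    })
    events = pd.DataFrame({
        "person_id": np.asarray(cols["person_id"], dtype=np.int64),
        "event_date": _days_to_ts(cols["event_date"]),
        "domain": pd.Series(cols["domain"], dtype=str),
        "vocabulary": pd.Series(cols["vocabulary"], dtype=str),
        "code": pd.Series(cols["code"], dtype=str),
        "visit_context": pd.Series(cols["visit_context"], dtype=str),
    })
    events = canonical_events(events)

    onset_ts = _days_to_ts(onset)
    truth = pd.DataFrame({
        "person_id": person_id,
        "has_sle": case,
        "onset_date": onset_ts.where(pd.Series(case), pd.NaT),
    })
    return Database(persons, obs, events, truth)
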