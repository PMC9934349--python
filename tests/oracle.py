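"""Brute-force reference implementation of the phenotype algorithms.

Deliberately naive: plain Python loops over per-person event lists, checking
every rule literally, with no shared code with the package's vectorised
engine.  Used to cross-check `build_cohort` on small databases.
"""

PRECURSOR = ("sle_sign_symptom", "sle_treatment_drug")


def _person_events(db, registry):
    by_person = {}
    for row in db.events.itertuples():
        roles = registry.classify(row.vocabulary, row.code)
        by_person.setdefault(row.person_id, []).append(
            (row.event_date, roles, row.vocabulary, row.code))
    return by_person


def oracle_cohort(algorithm_id, db, registry):
    """person_id -> (index_date, first_dx_date) under a literal rule reading."""
    events = _person_events(db, registry)
    periods = {row.person_id: (row.observation_period_start_date,
                               row.observation_period_end_date)
               for row in db.observation_periods.itertuples()}
    out = {}
    for pid, evs in events.items():
        dx_dates = sorted(d for d, roles, _, _ in evs if "sle_diagnosis" in roles)
        if algorithm_id in ("barnado_3x_am", "barnado_3x_am_excl"):
            distinct = sorted(set(dx_dates))
            am = sorted(d for d, roles, _, _ in evs if "antimalarial" in roles)
            if len(distinct) < 3 or not am:
                continue
            if algorithm_id == "barnado_3x_am_excl" and any(
                    "exclusion_dx" in roles for _, roles, _, _ in evs):
                continue
            out[pid] = (max(distinct[2], am[0]), distinct[0])
            continue

        if not dx_dates:
            continue
        first = dx_dates[0]
        if algorithm_id.endswith("_2x"):
            if not any(31 <= (d - first).days <= 365 for d in dx_dates):
                continue
        precursors = [d for d, roles, _, _ in evs
                      if roles & set(PRECURSOR) and 1 <= (first - d).days <= 90]
        index = min(precursors) if precursors else first
        if algorithm_id.startswith("incident"):
            if pid not in periods:
                continue
            start, end = periods[pid]
            if not (start <= index <= end and (index - start).days >= 365):
                continue
        out[pid] = (index, first)
    return out
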