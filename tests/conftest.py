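import pandas as pd
import pytest

from sle_phenotypes import Database, default_registry

BASE = pd.Timestamp("2015-01-01")


def day(d: int) -> pd.Timestamp:
    """Calendar date d days after the toy-database origin."""
    return BASE + pd.Timedelta(days=int(d))


def make_db(persons, periods, events, truth=None) -> Database:
    """Compact toy-database builder.

    persons: (person_id, sex, birth_year) triples
    periods: (person_id, start_day, end_day) with day offsets from BASE
    events:  (person_id, day, domain, vocabulary, code) tuples
    truth:   (person_id, has_sle, onset_day or None) tuples
    """
    persons_df = pd.DataFrame(persons, columns=["person_id", "sex", "birth_year"])
    periods_df = pd.DataFrame(
        [(p, day(s), day(e)) for p, s, e in periods],
        columns=["person_id", "observation_period_start_date",
                 "observation_period_end_date"])
    events_df = pd.DataFrame(
        [(p, day(d), dom, v, c, "outpatient") for p, d, dom, v, c in events],
        columns=["person_id", "event_date", "domain", "vocabulary", "code",
                 "visit_context"])
    if not len(events_df):
        events_df = events_df.astype({"person_id": "int64"})
        events_df["event_date"] = pd.to_datetime(events_df["event_date"])
    truth_df = None
    if truth is not None:
        truth_df = pd.DataFrame(
            [(p, h, day(o) if o is not None else pd.NaT) for p, h, o in truth],
            columns=["person_id", "has_sle", "onset_date"])
    return Database(persons_df, periods_df, events_df, truth_df)


@pytest.fixture(scope="session")
def registry():
    return default_registry()
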