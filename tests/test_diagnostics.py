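import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sle_phenotypes import (SimulationConfig, build_all_cohorts, build_cohort,
                            cohort_counts, incidence_rate,
                            index_event_breakdown, match_controls, overlap,
                            simulate_population, smd_binary,
                            temporal_characterization)
from sle_phenotypes.diagnostics import rate_per_100k
from conftest import day, make_db

DX = ("condition", "ICD9", "710.0")
MALAISE = ("condition", "ICD10", "R53.81")


@pytest.fixture(scope="module")
def sim(registry):
    db = simulate_population(SimulationConfig(
        n_persons=30_000, seed=31, sle_incidence_per_100k_py=800))
    cohorts = build_all_cohorts(db, registry)
    return db, cohorts


class TestSmd:
    def test_published_proportion_pairs(self):
        # hydroxychloroquine 27% vs 15%; SLE codes 83% vs 49%
        assert round(smd_binary(0.27, 0.15), 2) == 0.21
        assert round(smd_binary(0.83, 0.49), 2) == 0.54

    def test_equal_proportions_give_zero(self):
        assert smd_binary(0.4, 0.4) == 0.0

    def test_degenerate_endpoints_absent(self):
        assert smd_binary(1.0, 1.0) is None

    def test_pooled_variant_is_sqrt2_larger(self):
        assert smd_binary(0.3, 0.2, pooled=True) == pytest.approx(
            np.sqrt(2) * smd_binary(0.3, 0.2))

    @given(p1=st.floats(0.01, 0.99), p2=st.floats(0.01, 0.99))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry(self, p1, p2):
        assert smd_binary(p1, p2) == pytest.approx(-smd_binary(p2, p1))


class TestCountsAndOverlap:
    def test_counts_match_hand_tally_and_subset_property(self, registry):
        db = make_db(
            persons=[(1, "female", 1980), (2, "male", 1970), (3, "female", 1990)],
            periods=[(1, 0, 900), (2, 0, 900), (3, 0, 900)],
            events=[(1, 400, *DX), (1, 500, *DX), (2, 450, *DX),
                    (3, 100, *MALAISE)])
        cohorts = build_all_cohorts(db, registry)
        counts = cohort_counts(cohorts)
        assert counts["prevalent_1x"] == 2
        assert counts["prevalent_2x"] == 1
        assert counts["incident_1x"] == 2
        assert counts["incident_2x"] == 1
        assert "barnado_3x_am" not in counts.index  # nobody qualifies

    def test_overlap_identities(self, sim):
        db, cohorts = sim
        one = cohorts[cohorts["algorithm_id"] == "incident_1x"]
        two = cohorts[cohorts["algorithm_id"] == "incident_2x"]
        assert overlap(one, one) == (0, one["person_id"].nunique(), 0)
        only2, _, _ = overlap(two, one)
        assert only2 == 0  # 2X is a proper subset of 1X

    def test_empty_cohorts_all_zero(self):
        counts = cohort_counts(pd.DataFrame(columns=["algorithm_id", "person_id"]))
        assert counts.empty


class TestIncidence:
    def test_rate_arithmetic(self):
        assert rate_per_100k(2, 12_500) == pytest.approx(16.0)
        assert rate_per_100k(0, 100) == 0.0

    def test_stratified_counts_sum_to_total(self, sim, registry):
        db, cohorts = sim
        cohort = cohorts[cohorts["algorithm_id"] == "incident_1x"]
        total = incidence_rate(cohort, db.persons, db.observation_periods)
        strat = incidence_rate(cohort, db.persons, db.observation_periods,
                               strata=("sex", "age_band", "year"))
        assert strat["events"].sum() == total["events"].sum()
        assert strat["person_years"].sum() == pytest.approx(
            total["person_years"].sum(), rel=1e-6)
        assert total["rate_per_100k"].tolist() == pytest.approx(
            (1e5 * total["events"] / total["person_years"]).tolist())

    def test_short_observation_contributes_nothing(self, registry):
        db = make_db(persons=[(1, "female", 1980)], periods=[(1, 0, 200)],
                     events=[])
        empty = pd.DataFrame(columns=["person_id", "index_date"])
        assert incidence_rate(empty, db.persons, db.observation_periods).empty


class TestTemporalAndBreakdown:
    def test_toy_proportions_match_hand_tally(self, registry):
        db = make_db(
            persons=[(1, "female", 1980), (2, "male", 1970)],
            periods=[(1, 0, 900), (2, 0, 900)],
            events=[(1, 400, *DX), (1, 380, *MALAISE), (2, 450, *DX),
                    (1, 500, *DX)])
        cohort = build_cohort("prevalent_1x", db, registry)
        table = temporal_characterization(cohort, db.events, registry)
        def prop(window, name):
            row = table[(table["window_start"] == window[0])
                        & (table["window_end"] == window[1])
                        & (table["concept_set"] == name)]
            return row["proportion"].iloc[0]
        # person 1 indexes at the malaise (day 380): SLE codes at +20, +120
        assert prop((0, 0), "sle_diagnosis") == 0.5   # person 2 only
        assert prop((1, 30), "sle_diagnosis") == 0.5  # person 1 only
        assert prop((31, 365), "sle_diagnosis") == 0.5
        assert prop((0, 0), "sle_signs_symptoms") == 0.5

    def test_proportions_monotone_under_window_union(self, sim, registry):
        db, cohorts = sim
        cohort = cohorts[cohorts["algorithm_id"] == "prevalent_1x"]
        table = temporal_characterization(
            cohort, db.events, registry,
            windows=((1, 30), (1, 365), (-365, 365)))
        for name, sub in table.groupby("concept_set"):
            sub = sub.set_index(["window_start", "window_end"])["proportion"]
            assert sub[(1, 30)] <= sub[(1, 365)] <= sub[(-365, 365)]
            assert ((sub >= 0) & (sub <= 1)).all()

    def test_breakdown_sums_to_one_and_zero_window_is_all_dx(self, registry):
        from sle_phenotypes.engine import AlgorithmSpec
        db = simulate_population(SimulationConfig(
            n_persons=10_000, seed=37, sle_incidence_per_100k_py=1000))
        cohort = build_cohort("prevalent_1x", db, registry)
        breakdown = index_event_breakdown(cohort)
        assert breakdown.sum() == pytest.approx(1.0)
        no_corr = build_cohort(AlgorithmSpec("prevalent_1x",
                                             correction_window_days=0),
                               db, registry)
        breakdown = index_event_breakdown(no_corr)
        assert breakdown.to_dict() == {"sle_diagnosis": 1.0}


class TestMatching:
    def test_ample_pool_gives_full_ratio_and_exact_balance(self, registry):
        db = simulate_population(SimulationConfig(
            n_persons=30_000, seed=41, sle_incidence_per_100k_py=300,
            background_symptom_rate_per_py=6.0))
        cohort = build_cohort("incident_2x", db, registry)
        assert len(cohort) > 0
        matched = match_controls(cohort, db, ratio=10, seed=8)
        per_case = matched.groupby("case_person_id")["control_person_id"].nunique()
        assert (per_case == 10).mean() > 0.8  # ample pool: mostly full 1:10
        # matched variables balance exactly by construction
        cases = cohort.merge(db.persons, on="person_id")
        case_female = (cases["sex"] == "female").mean()
        full = per_case[per_case == 10].index
        ctrl = matched[matched["case_person_id"].isin(full)]
        exp = (cases[cases["person_id"].isin(full)]["sex"] == "female").mean()
        got = (ctrl["sex"] == "female").mean()
        assert got == pytest.approx(exp)

    def test_controls_reused_never_and_lookback_enforced(self, registry):
        db = simulate_population(SimulationConfig(
            n_persons=20_000, seed=43, sle_incidence_per_100k_py=300,
            background_symptom_rate_per_py=6.0))
        cohort = build_cohort("incident_2x", db, registry)
        matched = match_controls(cohort, db, ratio=10, seed=8)
        assert matched["control_person_id"].is_unique
        obs = db.observation_periods.set_index("person_id")
        starts = matched["control_person_id"].map(
            obs["observation_period_start_date"])
        lookback = (matched["matched_index_date"] - starts).dt.days
        assert (lookback >= 365).all()

    def test_empty_pool_is_fatal(self, registry):
        db = make_db(persons=[(1, "female", 1980)], periods=[(1, 0, 900)],
                     events=[(1, 400, *DX)])
        cohort = build_cohort("prevalent_1x", db, registry)
        with pytest.raises(ValueError, match="empty candidate pool"):
            match_controls(cohort, db, ratio=10, seed=0)

    def test_deterministic_under_fixed_seed(self, registry):
        db = simulate_population(SimulationConfig(
            n_persons=10_000, seed=47, sle_incidence_per_100k_py=300))
        cohort = build_cohort("prevalent_1x", db, registry)
        a = match_controls(cohort, db, ratio=5, seed=3)
        b = match_controls(cohort, db, ratio=5, seed=3)
        pd.testing.assert_frame_equal(a, b)
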