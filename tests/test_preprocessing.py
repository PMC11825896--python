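"""Cohort filters, outcome windows, imputation, standardisation and
design encoding."""

import numpy as np
import pandas as pd
import pytest

from edlatent import preprocessing as P


def _visit(**kw):
    base = dict(visit_id="v0", presentation="falls",
                visit_date="2016-06-01", age=80.0, female=1,
                insurance="medicare", diabetes=0, chf=0, hypertension=1,
                hcc=1.5, acuity=3, temperature=98.0, blood_pressure=75.0,
                respiration_rate=18.0, heart_rate=80.0, troponin=np.nan,
                pulse_oximetry=96.0, systolic_bp=130.0, stroke_flag=0,
                mi_flag=0, femur_fracture_flag=0, decision="discharge",
                disposition_destination="home", treatment_time=1.0,
                revisit_days=np.nan, readmission_days=np.nan,
                death_days=np.nan)
    base.update(kw)
    return base


@pytest.fixture(scope="module")
def hand_fixture():
    """Eight hand-written visits: six violating exactly one rule each,
    two clean (one of them sitting exactly on every boundary)."""
    visits = [
        _visit(visit_id="clean1", decision="admit",
               disposition_destination="hospital"),
        # all thresholds exactly on the boundary: retained (cutoffs strict)
        _visit(visit_id="boundary", acuity=3, heart_rate=120.0,
               systolic_bp=80.0, pulse_oximetry=88.0, respiration_rate=30.0,
               troponin=0.10, presentation="cellulitis", temperature=100.3),
        _visit(visit_id="x_dispo", decision="other",
               disposition_destination="other"),
        _visit(visit_id="x_acuity", acuity=4),
        _visit(visit_id="x_tail", visit_date="2018-09-01"),
        _visit(visit_id="x_troponin", troponin=0.11),
        _visit(visit_id="x_vitals", heart_rate=121.0),
        _visit(visit_id="x_cellulitis", presentation="cellulitis",
               temperature=100.4),
    ]
    return pd.DataFrame(visits)


class TestCohortFilters:
    def test_hand_fixture_counts_match_manual_application(self, hand_fixture):
        kept, rep = P.apply_cohort_filters(hand_fixture, "2018-09-27")
        assert rep.n_input == 8
        assert rep.n_retained == 2
        assert sorted(rep.retained_ids) == ["boundary", "clean1"]
        assert rep.exclusions == {"disposition": 1, "acuity": 1,
                                  "tail_45d": 1, "troponin": 1, "vitals": 1,
                                  "diagnosis_flags": 0,
                                  "cellulitis_fever": 1}

    @pytest.mark.parametrize("field,value", [
        ("heart_rate", 121.0), ("systolic_bp", 79.9),
        ("pulse_oximetry", 87.9), ("respiration_rate", 30.1)])
    def test_vital_rules_are_strict(self, field, value):
        t = pd.DataFrame([_visit(), _visit(visit_id="v1", **{field: value})])
        kept, rep = P.apply_cohort_filters(t, "2018-09-27")
        assert list(kept["visit_id"]) == ["v0"]
        assert rep.exclusions["vitals"] == 1

    def test_boundary_values_retained(self):
        t = pd.DataFrame([_visit(heart_rate=120.0, systolic_bp=80.0,
                                 pulse_oximetry=88.0, respiration_rate=30.0,
                                 troponin=0.10)])
        kept, _ = P.apply_cohort_filters(t, "2018-09-27")
        assert len(kept) == 1

    def test_missing_screening_vitals_do_not_exclude(self):
        t = pd.DataFrame([_visit(pulse_oximetry=np.nan, systolic_bp=np.nan,
                                 troponin=np.nan)])
        kept, _ = P.apply_cohort_filters(t, "2018-09-27")
        assert len(kept) == 1

    def test_diagnosis_flags_exclude(self):
        t = pd.DataFrame([_visit(mi_flag=1)])
        _, rep = P.apply_cohort_filters(t, "2018-09-27")
        assert rep.exclusions["diagnosis_flags"] == 1

    def test_first_failing_rule_gets_the_count(self):
        # fails both acuity and vitals: attributed to acuity (earlier rule)
        t = pd.DataFrame([_visit(acuity=5, heart_rate=150.0)])
        _, rep = P.apply_cohort_filters(t, "2018-09-27")
        assert rep.exclusions["acuity"] == 1
        assert rep.exclusions["vitals"] == 0

    def test_snf_irf_mapped_to_discharge(self):
        t = pd.DataFrame([_visit(disposition_destination="snf",
                                 decision="discharge")])
        kept, _ = P.apply_cohort_filters(t, "2018-09-27")
        assert kept["decision"].iloc[0] == "discharge"

    def test_filter_idempotence(self, hand_fixture):
        kept1, _ = P.apply_cohort_filters(hand_fixture, "2018-09-27")
        kept2, rep2 = P.apply_cohort_filters(kept1, "2018-09-27")
        assert list(kept1["visit_id"]) == list(kept2["visit_id"])
        assert rep2.n_retained == rep2.n_input

    def test_missing_visit_date_is_an_error(self, hand_fixture):
        broken = hand_fixture.copy()
        broken.loc[0, "visit_date"] = np.nan
        with pytest.raises(ValueError, match="visit_date"):
            P.apply_cohort_filters(broken, "2018-09-27")

    def test_report_counts_are_a_partition(self, hand_fixture):
        _, rep = P.apply_cohort_filters(hand_fixture, "2018-09-27")
        assert rep.n_retained + sum(rep.exclusions.values()) == rep.n_input


class TestOutcomeMatrix:
    def test_windows_inclusive_and_nested(self):
        t = pd.DataFrame([
            _visit(death_days=2.0),
            _visit(revisit_days=9.0),
            _visit(revisit_days=31.0),
        ])
        om = P.derive_outcome_matrix(t)
        assert om.iloc[0][["mortality_3d", "mortality_9d",
                           "mortality_30d"]].tolist() == [1, 1, 1]
        assert om.iloc[1][["revisit_3d", "revisit_9d",
                           "revisit_30d"]].tolist() == [0, 1, 1]
        assert om.iloc[2][["revisit_3d", "revisit_9d",
                           "revisit_30d"]].tolist() == [0, 0, 0]

    def test_absent_event_is_all_zero(self):
        om = P.derive_outcome_matrix(pd.DataFrame([_visit()]))
        assert om.iloc[0].sum() == 0

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            P.derive_outcome_matrix(pd.DataFrame([_visit(death_days=-1.0)]))


class TestImputation:
    def test_median_and_mode_fills(self):
        t = pd.DataFrame({"age": [1.0, 2.0, 4.0, np.nan],
                          "insurance": ["medicare", "medicare",
                                        "commercial", None]})
        out, log = P.impute_missing(t, continuous=("age",),
                                    categorical=("insurance",))
        assert out["age"].iloc[3] == 2.0
        assert out["insurance"].iloc[3] == "medicare"
        assert log["age"] == {"fill": 2.0, "n_filled": 1}

    def test_bimodal_tie_breaks_lexicographically(self):
        t = pd.DataFrame({"insurance": ["b", "b", "a", "a", None]})
        out, _ = P.impute_missing(t, continuous=(),
                                  categorical=("insurance",))
        assert out["insurance"].iloc[4] == "a"

    def test_observed_values_never_change(self):
        t = pd.DataFrame({"age": [1.0, np.nan, 3.0]})
        out, _ = P.impute_missing(t, continuous=("age",), categorical=())
        assert out["age"].iloc[0] == 1.0 and out["age"].iloc[2] == 3.0
        assert not out["age"].isna().any()

    def test_fully_missing_column_is_an_error(self):
        t = pd.DataFrame({"age": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="age"):
            P.impute_missing(t, continuous=("age",), categorical=())


class TestStandardization:
    def test_two_point_zscore(self):
        t = pd.DataFrame({"age": [2.0, 4.0]})
        out, _ = P.standardize_continuous(t, columns=("age",))
        assert out["age"].tolist() == pytest.approx(
            [-0.7071067812, 0.7071067812], abs=1e-9)

    def test_standardised_moments(self, small_cohort):
        _, table, _ = small_cohort
        out, _ = P.standardize_continuous(table, columns=("heart_rate",))
        assert abs(out["heart_rate"].mean()) < 1e-12
        assert out["heart_rate"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_is_identity(self, small_cohort):
        _, table, _ = small_cohort
        cols = ("age", "heart_rate")
        out, scaler = P.standardize_continuous(table, columns=cols)
        back = scaler.inverse_transform(out)
        for c in cols:
            assert np.allclose(back[c], table[c], atol=1e-10)

    def test_zero_variance_is_an_error(self):
        t = pd.DataFrame({"age": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="age"):
            P.standardize_continuous(t, columns=("age",))


class TestEncodeDesign:
    def test_acuity_two_indicator(self):
        t = pd.DataFrame([_visit(acuity=2), _visit(acuity=3)])
        enc = P.encode_design(t)
        assert enc["acuity2"].tolist() == [1.0, 0.0]

    def test_medicare_is_reference_level(self):
        enc = P.encode_design(pd.DataFrame([_visit(insurance="medicare")]))
        assert enc[["ins_medicaid", "ins_commercial",
                    "ins_self_pay"]].iloc[0].sum() == 0.0

    def test_full_row_matches_hand_encoding(self):
        v = _visit(age=0.5, female=1, insurance="commercial", diabetes=1,
                   chf=0, hypertension=1, hcc=-0.25, acuity=2,
                   temperature=0.1, blood_pressure=-0.2,
                   respiration_rate=0.3, heart_rate=-0.4)
        enc = P.encode_design(pd.DataFrame([v]))
        expected = [0.5, 1, 0, 1, 0, 1, 0, 1, -0.25, 1, 0.1, -0.2, 0.3, -0.4]
        assert enc.iloc[0].tolist() == pytest.approx(expected)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="insurance"):
            P.encode_design(pd.DataFrame([_visit(insurance="tricare")]))
        with pytest.raises(ValueError, match="acuity"):
            P.encode_design(pd.DataFrame([_visit(acuity=7)]))
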