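import pandas as pd
import pytest

from claimlines import (
    ClaimsDataset,
    baseline_characteristics,
    make_fixture,
    select_cohort,
)
from claimlines.cohort_selection import SELECTION_STEPS
from claimlines.synthetic_claims import DATA_END, FIXTURE_DATA_END


def _fails_by_patient(attrition):
    out = {}
    for name, _, _, excluded in attrition.steps:
        for pid in excluded:
            out[pid] = name
    return out


class TestAttrition:
    def test_monotone_and_partitions_population(self, pipeline_small, small_cohort):
        _, dataset, _ = small_cohort
        attrition = pipeline_small[3]["attrition"]
        assert [s for s, *_ in attrition.steps] == list(SELECTION_STEPS)
        n0 = dataset.n_patients
        total_excluded = 0
        for name, n_before, n_after, excluded in attrition.steps:
            assert n_after <= n_before
            assert n_before - n_after == len(excluded)
            total_excluded += len(excluded)
        cohort = pipeline_small[3]["cohort"]
        assert total_excluded + len(cohort) == n0


class TestTruthRecovery:
    def test_selected_set_equals_ground_truth(self, pipeline_small):
        _, _, truth, res = pipeline_small
        assert set(res["cohort"].patient_id) == truth.eligible_ids()

    def test_exclusion_steps_match_ground_truth(self, pipeline_small):
        _, _, truth, res = pipeline_small
        fails = _fails_by_patient(res["attrition"])
        for row in truth.patients.itertuples():
            want = row.excluded_at_step if pd.notna(row.excluded_at_step) else None
            assert fails.get(row.patient_id) == want, row.patient_id

    def test_index_and_window_dates_match_ground_truth(self, pipeline_small):
        _, _, truth, res = pipeline_small
        cohort = res["cohort"].set_index("patient_id")
        eligible = truth.patients[truth.patients.eligible].set_index("patient_id")
        for pid in eligible.index:
            assert cohort.loc[pid, "first_lc_dx_date"] == eligible.loc[pid, "first_lc_dx"]
            assert cohort.loc[pid, "first_line_start_date"] == eligible.loc[pid, "first_line_start"]
            assert cohort.loc[pid, "index_date"] == eligible.loc[pid, "index_date"]
            assert cohort.loc[pid, "observation_end"] == eligible.loc[pid, "observation_end"]
            base_len = (cohort.loc[pid, "baseline_end"]
                        - cohort.loc[pid, "baseline_start"]).days + 1
            assert base_len == 365


class TestOrderInvariance:
    def test_shuffled_claim_rows_give_same_cohort(self, small_cohort, codes):
        _, dataset, _ = small_cohort
        shuffled = ClaimsDataset(
            patients=dataset.patients.sample(frac=1, random_state=1),
            enrollment=dataset.enrollment.sample(frac=1, random_state=2),
            medical=dataset.medical.sample(frac=1, random_state=3),
            pharmacy=dataset.pharmacy.sample(frac=1, random_state=4),
        )
        a, _ = select_cohort(dataset, codes, DATA_END)
        b, _ = select_cohort(shuffled, codes, DATA_END)
        assert set(a.patient_id) == set(b.patient_id)
        a = a.sort_values("patient_id").reset_index(drop=True)
        b = b.sort_values("patient_id").reset_index(drop=True)
        for col in ("first_lc_dx_date", "first_line_start_date", "index_date",
                    "observation_end", "advanced_qualifier"):
            assert (a[col] == b[col]).all()


class TestMetastaticWindowBoundary:
    """Surgery before index excludes only patients without the 30-day
    metastatic qualifier; day 30 is inside the window, day 31 outside."""

    @pytest.mark.parametrize("fixture,included", [
        ("met_day30", True),
        ("met_day31", False),
        ("surgery_exclusion", False),
    ])
    def test_selection(self, fixture, included, codes):
        dataset, truth = make_fixture(fixture)
        cohort, attrition = select_cohort(dataset, codes, FIXTURE_DATA_END)
        assert (len(cohort) == 1) is included
        assert set(cohort.patient_id) == truth.eligible_ids()
        if not included:
            assert _fails_by_patient(attrition) == {
                truth.patients.patient_id.iloc[0]: "lc_surgery_pre_index"}
        else:
            assert cohort.advanced_qualifier.iloc[0] == "metastatic_dx_within_30d"


class TestBaselineCharacteristics:
    def _tiny_dataset(self, radio_offset_days):
        t1l = pd.Timestamp("2019-06-01")
        dx0 = pd.Timestamp("2019-05-01")
        med = pd.DataFrame([
            {"patient_id": "P1", "service_date": dx0, "end_date": dx0,
             "setting": "outpatient", "diagnosis_codes": "C3490",
             "procedure_codes": "99213", "provider_type": "oncologist",
             "paid_amount": 100.0, "service_year": 2019},
            {"patient_id": "P1",
             "service_date": t1l - pd.Timedelta(days=radio_offset_days),
             "end_date": t1l - pd.Timedelta(days=radio_offset_days),
             "setting": "outpatient", "diagnosis_codes": "C3490",
             "procedure_codes": "77412", "provider_type": "radiologist",
             "paid_amount": 900.0, "service_year": 2019},
        ])
        pha = pd.DataFrame([{"patient_id": "P1",
                             "fill_date": t1l - pd.Timedelta(days=10),
                             "drug_code": "dexamethasone", "days_supply": 10,
                             "paid_amount": 12.0, "service_year": 2019}])
        ds = ClaimsDataset(
            patients=pd.DataFrame([{"patient_id": "P1", "birth_year": 1960,
                                    "sex": "F"}]),
            enrollment=pd.DataFrame([{"patient_id": "P1",
                                      "start_date": pd.Timestamp("2018-01-01"),
                                      "end_date": pd.Timestamp("2020-12-31"),
                                      "plan_type": "commercial"}]),
            medical=med, pharmacy=pha)
        record = {"patient_id": "P1", "first_lc_dx_date": dx0,
                  "first_line_start_date": t1l,
                  "index_date": t1l,
                  "eligibility_start": pd.Timestamp("2018-01-01")}
        return ds, record

    def test_radiotherapy_29_days_before_1l_sets_both_flags(self, codes):
        ds, record = self._tiny_dataset(29)
        out = baseline_characteristics(record, ds, codes)
        assert out["radiotherapy_pre1l"] and out["radiotherapy_30d_pre1l"]
        assert out["corticosteroids_pre1l"]
        assert not out["surgery_pre1l"]
        assert out["months_dx_to_1l"] == pytest.approx(31 / 30.4375)

    def test_radiotherapy_outside_30_days_is_ever_only(self, codes):
        ds, record = self._tiny_dataset(31)
        out = baseline_characteristics(record, ds, codes)
        assert out["radiotherapy_pre1l"] and not out["radiotherapy_30d_pre1l"]
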