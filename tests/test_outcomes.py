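import numpy as np
import pandas as pd
import pytest

from claimlines import ClaimsDataset
from claimlines.outcomes import (
    CPITable,
    QuanCCIMap,
    collect_dx_codes,
    cpi_adjust,
    pppm,
    quan_cci,
    summarize_line,
    summarize_window,
    supportive_care_flags,
)
from oracles import quan_oracle

T0 = pd.Timestamp("2020-01-01")


class TestPPPM:
    def test_arithmetic_identity(self):
        # a 61-day closed interval divided by the 30.4375-day month
        got = pppm(2000.0, T0, T0 + pd.Timedelta(days=60))
        assert got == pytest.approx(2000.0 / (61 / 30.4375))
        # ~2 months of exposure gives ~1000/month
        assert round(got, 0) == 998.0

    def test_zero_events(self):
        assert pppm(0, T0, T0 + pd.Timedelta(days=100)) == 0.0

    def test_twelve_months(self):
        # a 365-day line is ~12 months; 3 admissions -> 0.25 per month
        assert round(pppm(3, T0, T0 + pd.Timedelta(days=364)), 2) == 0.25


class TestCPI:
    def test_identity_year(self):
        t = CPITable({2022: 1.0, 2019: 1.10})
        assert cpi_adjust(100.0, 2022, t) == 100.0

    def test_deflation(self):
        t = CPITable({2022: 1.0, 2019: 1.10})
        assert cpi_adjust(100.0, 2019, t) == pytest.approx(110.0)

    def test_round_trip(self):
        t = CPITable.default()
        for year, d in t.deflators.items():
            assert cpi_adjust(250.0, year, t) / d == pytest.approx(250.0)

    def test_packaged_table_anchored_at_2022(self):
        t = CPITable.default()
        assert t.deflators[2022] == 1.0
        assert all(v > 0 for v in t.deflators.values())

    def test_missing_year_names_it(self):
        with pytest.raises(ValueError, match="1999"):
            cpi_adjust(1.0, 1999, CPITable({2022: 1.0}))


def _med(rows):
    return pd.DataFrame(rows, columns=["patient_id", "service_date", "end_date",
                                       "setting", "diagnosis_codes",
                                       "procedure_codes", "provider_type",
                                       "paid_amount", "service_year"])


def _pha(rows):
    return pd.DataFrame(rows, columns=["patient_id", "fill_date", "drug_code",
                                       "days_supply", "paid_amount",
                                       "service_year"])


class TestSummarizeWindow:
    def test_no_claims_all_zero(self, codes, cpi_identity):
        out = summarize_window(_med([]), _pha([]), T0, T0 + pd.Timedelta(days=99),
                               codes, cpi_identity)
        assert out["cost_total_pppm"] == 0.0
        assert not out["any_outpatient"] and not out["any_inpatient"] and not out["any_ed"]
        assert out["outpatient_service_days_pppm"] == 0.0

    def test_same_day_rows_count_one_service_day(self, codes, cpi_identity):
        med = _med([("P1", T0, T0, "outpatient", "C3490", "99213", "x", 100.0, 2020),
                    ("P1", T0, T0, "outpatient", "C3490", "99213", "x", 50.0, 2020)])
        out = summarize_window(med, _pha([]), T0, T0 + pd.Timedelta(days=29),
                               codes, cpi_identity)
        months = 30 / 30.4375
        assert out["outpatient_service_days_pppm"] == pytest.approx(1 / months)
        assert out["cost_outpatient_total_pppm"] == pytest.approx(150.0 / months)

    def test_ed_claim_inside_admission_counts_as_inpatient(self, codes, cpi_identity):
        d2 = T0 + pd.Timedelta(days=2)
        med = _med([
            ("P1", T0, T0 + pd.Timedelta(days=4), "inpatient", "C3490", "99222",
             "x", 5000.0, 2020),
            ("P1", d2, d2, "emergency", "C3490", "99284", "x", 800.0, 2020),
        ])
        out = summarize_window(med, _pha([]), T0, T0 + pd.Timedelta(days=29),
                               codes, cpi_identity)
        months = 30 / 30.4375
        assert out["ed_visit_days_pppm"] == 0.0
        assert out["cost_ed_plus_other_pppm"] == 0.0
        assert out["cost_inpatient_pppm"] == pytest.approx(5800.0 / months)
        assert out["inpatient_days_pppm"] == pytest.approx(5 / months)
        assert out["any_inpatient"] and not out["any_ed"]

    def test_antineoplastic_outpatient_split(self, codes, cpi_identity):
        med = _med([
            ("P1", T0, T0, "outpatient", "C3490", "carboplatin;chemo_admin",
             "x", 4000.0, 2020),
            ("P1", T0 + pd.Timedelta(days=3), T0 + pd.Timedelta(days=3),
             "outpatient", "C3490", "99213", "x", 120.0, 2020),
        ])
        out = summarize_window(med, _pha([]), T0, T0 + pd.Timedelta(days=29),
                               codes, cpi_identity)
        months = 30 / 30.4375
        assert out["cost_outpatient_antineoplastic_plus_admin_pppm"] == \
            pytest.approx(4000.0 / months)
        assert out["cost_outpatient_other_pppm"] == pytest.approx(120.0 / months)


class TestAdditivityAndLinearity:
    def test_components_add_up_on_generated_lines(self, pipeline_small):
        s = pipeline_small[3]["summaries"]
        assert len(s) > 100
        np.testing.assert_allclose(
            s.cost_total_pppm, s.cost_medical_pppm + s.cost_pharmacy_pppm,
            rtol=1e-6)
        np.testing.assert_allclose(
            s.cost_medical_pppm,
            s.cost_inpatient_pppm + s.cost_outpatient_total_pppm
            + s.cost_ed_plus_other_pppm, rtol=1e-6)
        np.testing.assert_allclose(
            s.cost_outpatient_total_pppm,
            s.cost_outpatient_antineoplastic_plus_admin_pppm
            + s.cost_outpatient_other_pppm, rtol=1e-6)
        assert (s[[c for c in s.columns if c.startswith("cost_")]] >= 0).all().all()

    def test_scaling_paid_amounts_scales_every_component(self, small_cohort,
                                                         codes, cpi_identity,
                                                         pipeline_small):
        _, dataset, _ = small_cohort
        line = pipeline_small[3]["lines"].iloc[0].to_dict()
        pid = line["patient_id"]
        med = dataset.medical[dataset.medical.patient_id == pid]
        pha = dataset.pharmacy[dataset.pharmacy.patient_id == pid]
        base = summarize_line(line, med, pha, codes, cpi_identity)
        med3 = med.assign(paid_amount=med.paid_amount * 3)
        pha3 = pha.assign(paid_amount=pha.paid_amount * 3)
        scaled = summarize_line(line, med3, pha3, codes, cpi_identity)
        for k in base:
            if isinstance(base[k], float) and k.startswith("cost_"):
                assert scaled[k] == pytest.approx(3 * base[k])
            elif k.endswith("_pppm"):
                assert scaled[k] == base[k]


class TestQuanCCI:
    def test_no_matching_codes(self):
        assert quan_cci(["Z000", "XYZ"]) == 0

    def test_metastatic_supersedes_malignancy(self):
        cci = QuanCCIMap.default()
        assert quan_cci(["C3490"], cci) == 2
        assert quan_cci(["C7800"], cci) == 6
        assert quan_cci(["C3490", "C7800"], cci) == 6

    def test_diabetes_and_liver_hierarchies(self):
        cci = QuanCCIMap.default()
        assert quan_cci(["E119", "E112"], cci) == 2  # complicated wins
        assert quan_cci(["K700", "K721"], cci) == 3  # severe liver wins

    def test_monotone_in_added_codes(self):
        cci = QuanCCIMap.default()
        rng = np.random.default_rng(11)
        pool = ["C3490", "C7800", "E119", "E112", "J449", "I10", "K700",
                "K721", "I21", "B20", "N18", "G81"]
        for _ in range(50):
            k = int(rng.integers(0, 6))
            bag = list(rng.choice(pool, size=k, replace=False))
            extra = str(rng.choice(pool))
            assert quan_cci(bag + [extra], cci) >= quan_cci(bag, cci)

    def test_random_bags_match_enumeration_oracle(self):
        from importlib import resources
        path = resources.files("claimlines.data").joinpath("quan_cci.csv")
        cci = QuanCCIMap.default()
        rng = np.random.default_rng(23)
        pool = ["C3490", "C7800", "E119", "E112", "J449", "I10", "K700",
                "K721", "I21", "I50", "B20", "N18", "G81", "F01", "M05",
                "K25", "I70", "I63", "Z000"]
        for _ in range(50):
            k = int(rng.integers(0, 8))
            bag = list(rng.choice(pool, size=k, replace=True))
            assert quan_cci(bag, cci) == quan_oracle(bag, str(path))


class TestSupportiveFlags:
    def test_no_claims_all_false(self, codes):
        flags = supportive_care_flags(_pha([]), T0, T0 + pd.Timedelta(days=30), codes)
        assert not any(flags.values())

    def test_gcsf_on_line_end_date_is_inclusive(self, codes):
        end = T0 + pd.Timedelta(days=30)
        pha = _pha([("P1", end, "filgrastim", 7, 500.0, 2020)])
        flags = supportive_care_flags(pha, T0, end, codes)
        assert flags["gcsf_gmcsf"]
        flags_before = supportive_care_flags(pha, T0, end - pd.Timedelta(days=1), codes)
        assert not flags_before["gcsf_gmcsf"]

    def test_pain_claim_in_second_line_only(self, codes):
        l2_start = T0 + pd.Timedelta(days=100)
        pha = _pha([("P1", l2_start + pd.Timedelta(days=5), "oxycodone", 14,
                     20.0, 2020)])
        l1 = supportive_care_flags(pha, T0, l2_start - pd.Timedelta(days=1), codes)
        l2 = supportive_care_flags(pha, l2_start, l2_start + pd.Timedelta(days=90),
                                   codes)
        assert not l1["pain_management"] and l2["pain_management"]


def test_collect_dx_codes_window():
    med = _med([("P1", T0, T0, "outpatient", "C3490;E119", "99213", "x", 1.0, 2020),
                ("P1", T0 + pd.Timedelta(days=40), T0 + pd.Timedelta(days=40),
                 "outpatient", "J449", "99213", "x", 1.0, 2020)])
    codes = collect_dx_codes(med, T0, T0 + pd.Timedelta(days=30))
    assert codes == ["C3490", "E119"]
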