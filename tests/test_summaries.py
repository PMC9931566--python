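"""Procedure categories, new-medication rollup, code-uptake series."""

import pandas as pd
import pytest

from lcnet.cohort import included
from lcnet.summaries import (atc_rollup, categorize_procedures,
                             filter_informative_procedures, new_medications,
                             uptake_series)
from lcnet.vocab import atc_level3


def proc_events(rows):
    return pd.DataFrame(rows, columns=["person_id", "code", "date"]).assign(
        vocabulary="CPT4", event_class="procedure", inpatient=0)


def drug_events(rows):
    return pd.DataFrame(rows, columns=["person_id", "code", "date"]).assign(
        vocabulary="RxNorm", event_class="drug", inpatient=0)


class TestProcedureFilter:
    def test_encounter_only_codes_removed(self):
        ev = proc_events([("P1", "99212", "2022-01-02"),
                          ("P1", "93306", "2022-01-02")])
        out = filter_informative_procedures(ev)
        assert list(out["code"]) == ["93306"]

    def test_empty_exclusion_list_is_identity(self):
        ev = proc_events([("P1", "99212", "2022-01-02")])
        assert len(filter_informative_procedures(ev, exclusion_list=set())) == 1


class TestProcedureCategories:
    def _cohort(self, n, age_group="21–45"):
        birth = {"<21": "2012-01-01", "21–45": "1990-01-01",
                 "46–65": "1965-01-01", "66+": "1950-01-01"}[age_group]
        persons = pd.DataFrame({
            "person_id": [f"P{i}" for i in range(n)],
            "birth_date": birth, "sex": "Female", "race": "White",
            "ethnicity": "Not Hispanic/Latino", "zip": "10001", "deceased": 0,
            "site_id": "S00", "hospitalized_acute": 0, "severe_acute": 0})
        from lcnet.cohort import apply_exclusions
        idx = pd.Series(pd.Timestamp("2022-01-15"),
                        index=persons["person_id"], name="index_date")
        return apply_exclusions(persons, pd.DataFrame(
            columns=["person_id", "start_date", "end_date", "inpatient"]), idx)

    def test_repeat_events_count_patient_once_per_category(self):
        cohort = self._cohort(100)
        ev = proc_events([("P0", "71045", "2022-01-20"),
                          ("P0", "71046", "2022-01-25")])  # both radiography
        table = categorize_procedures(ev, cohort, min_count=1,
                                      min_percent=0.0)
        f = table.frame.set_index("category")
        assert f.loc["radiography", "n_patients"] == 1

    def test_small_count_suppressed(self):
        cohort = self._cohort(2000)
        ev = proc_events([(f"P{i}", "93000", "2022-01-20")
                          for i in range(19)])
        table = categorize_procedures(ev, cohort)
        assert table.frame["suppressed"].all()
        assert table.shown().empty

    def test_low_percent_suppressed_even_with_enough_patients(self):
        cohort = self._cohort(3000)
        ev = proc_events([(f"P{i}", "93000", "2022-01-20")
                          for i in range(25)])  # 25/3000 = 0.8%
        table = categorize_procedures(ev, cohort)
        assert table.frame["suppressed"].all()

    def test_released_cell_satisfies_both_thresholds(self):
        cohort = self._cohort(1000)
        ev = proc_events([(f"P{i}", "93000", "2022-01-20")
                          for i in range(30)])  # 3.0%
        table = categorize_procedures(ev, cohort)
        shown = table.shown()
        assert len(shown) == 1
        assert shown.loc[0, "n_patients"] == 30
        assert shown.loc[0, "percent"] == 3.0

    def test_unmapped_code_warns_and_buckets(self):
        cohort = self._cohort(50)
        ev = proc_events([("P0", "00000", "2022-01-20")])
        with pytest.warns(UserWarning, match="unmapped"):
            table = categorize_procedures(ev, cohort, min_count=1,
                                          min_percent=0.0)
        assert "uncategorized" in set(table.frame["category"])

    def test_counts_never_exceed_stratum_size(self, small_extract,
                                              small_cohort, small_windowed):
        procs = filter_informative_procedures(small_windowed)
        table = categorize_procedures(procs, small_cohort)
        for _, row in table.frame.iterrows():
            assert row["n_patients"] <= table.stratum_sizes[
                str(row["age_group"])]


class TestNewMedications:
    IDX = pd.Series(pd.Timestamp("2022-01-01"), index=["P1"],
                    name="index_date")

    def test_prior_record_excludes_drug(self):
        ev = drug_events([("P1", "prednisone", "2021-12-22"),
                          ("P1", "prednisone", "2022-01-06")])
        assert new_medications(ev, self.IDX).empty

    def test_clean_new_start_included(self):
        ev = drug_events([("P1", "prednisone", "2022-01-31")])
        assert len(new_medications(ev, self.IDX)) == 1

    def test_record_outside_window_excluded(self):
        ev = drug_events([("P1", "prednisone", "2022-03-03")])  # index + 61
        assert new_medications(ev, self.IDX).empty
        ev = drug_events([("P1", "prednisone", "2022-03-02")])  # index + 60
        assert len(new_medications(ev, self.IDX)) == 1

    def test_prior_record_of_other_drug_irrelevant(self):
        ev = drug_events([("P1", "albuterol", "2021-11-01"),
                          ("P1", "prednisone", "2022-01-10")])
        out = new_medications(ev, self.IDX)
        assert list(out["code"]) == ["prednisone"]

    def test_antimonotone_in_lookback(self):
        """Extending lookback (moving records earlier into view) never adds
        drugs: any drug excluded under a short history stays excluded."""
        ev = drug_events([("P1", "prednisone", "2021-06-01"),
                          ("P1", "prednisone", "2022-01-10"),
                          ("P1", "albuterol", "2022-01-12")])
        full = set(new_medications(ev, self.IDX)["code"])
        truncated = ev[ev["date"] >= "2021-12-01"]
        short = set(new_medications(truncated, self.IDX)["code"])
        assert full <= short


class TestAtcRollup:
    def test_level3_is_four_character_prefix(self):
        assert atc_level3("J01CA04") == "J01C"
        assert atc_level3("R03AC02") == "R03A"

    def test_same_class_ingredients_count_patient_once(self):
        from lcnet.cohort import apply_exclusions
        persons = pd.DataFrame({
            "person_id": ["P1"], "birth_date": "1990-01-01", "sex": "Female",
            "race": "White", "ethnicity": "Not Hispanic/Latino",
            "zip": "10001", "deceased": 0, "site_id": "S00",
            "hospitalized_acute": 0, "severe_acute": 0})
        idx = pd.Series(pd.Timestamp("2022-01-01"), index=["P1"],
                        name="index_date")
        cohort = apply_exclusions(persons, pd.DataFrame(
            columns=["person_id", "start_date", "end_date", "inpatient"]), idx)
        # amoxicillin J01CA04 and doxycycline J01AA02 differ at level 3;
        # prednisone H02AB07 / dexamethasone H02AB02 share H02A
        ev = drug_events([("P1", "prednisone", "2022-01-10"),
                          ("P1", "dexamethasone", "2022-01-12")])
        out = atc_rollup(ev, cohort).set_index("atc_level3")
        assert out.loc["H02A", "n_patients"] == 1

    def test_empty_input_gives_empty_table(self, small_cohort):
        out = atc_rollup(drug_events([]).iloc[:0], small_cohort)
        assert out.empty

    def test_unmapped_ingredient_warns_and_buckets(self, small_cohort):
        base = included(small_cohort)["person_id"].iloc[0]
        ev = drug_events([(base, "unobtainium", "2022-01-10")])
        with pytest.warns(UserWarning, match="unmapped"):
            out = atc_rollup(ev, small_cohort)
        assert "unmapped" in set(out["atc_level3"])


class TestUptake:
    def test_repeat_use_in_month_counts_once(self):
        ev = pd.DataFrame({"person_id": ["P1", "P1"],
                           "code": ["U09.9", "U09.9"],
                           "date": ["2021-11-03", "2021-11-20"],
                           "event_class": "condition"})
        series = uptake_series(ev, date_range=("2021-11-01", "2021-11-30"))
        assert series.pivot().loc["2021-11", "U09.9"] == 1

    def test_planted_coding_switch_visible(self, small_extract):
        series = uptake_series(small_extract.coded_events,
                               date_range=("2020-04-01", "2022-05-31"))
        piv = series.pivot()
        before = piv.loc["2021-07":"2021-09"]
        after = piv.loc["2021-12":"2022-02"]
        assert (before["B94.8"] > before["U09.9"]).all()
        assert (after["U09.9"] > after["B94.8"]).all()

    def test_totals_match_brute_force_triples(self, small_extract):
        ev = small_extract.coded_events
        series = uptake_series(ev, date_range=("2018-01-01", "2022-07-31"))
        tracked = ev[ev["code"].isin(["U09.9", "B94.8"])].copy()
        tracked["month"] = pd.to_datetime(tracked["date"]).dt.to_period("M")
        brute = len({(p, c, m) for p, c, m in zip(tracked["person_id"],
                                                  tracked["code"],
                                                  tracked["month"])})
        assert series.frame["n_patients"].sum() == brute

    def test_months_contiguous_and_zero_filled(self):
        ev = pd.DataFrame({"person_id": ["P1"], "code": ["U09.9"],
                           "date": ["2021-11-03"], "event_class": "condition"})
        series = uptake_series(ev, date_range=("2021-09-01", "2022-01-31"))
        piv = series.pivot()
        assert list(piv.index) == ["2021-09", "2021-10", "2021-11",
                                   "2021-12", "2022-01"]
        assert piv["U09.9"].sum() == 1

    def test_absent_codes_give_all_zero_series(self):
        ev = pd.DataFrame({"person_id": ["P1"], "code": ["R53.83"],
                           "date": ["2021-11-03"], "event_class": "condition"})
        series = uptake_series(ev, date_range=("2021-10-01", "2021-12-31"))
        assert (series.frame["n_patients"] == 0).all()

    def test_empty_date_range_rejected(self):
        with pytest.raises(ValueError, match="date range"):
            uptake_series(pd.DataFrame(columns=["person_id", "code", "date"]),
                          date_range=("2022-01-01", "2021-01-01"))
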