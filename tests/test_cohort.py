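"""Deduplication, occupation/role filtering and drug-name resolution."""

import pandas as pd
import pytest

from pvsignal.cohort import (CleanDataset, DrugDictionary, EmptyDatasetError,
                             assign_age_group, deduplicate, filter_reports,
                             match_drug)
from tests.conftest import make_bundle


class TestDeduplicate:
    def _demo(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])

    def test_keeps_most_recent_fda_dt(self):
        demo = self._demo([("91", "9", "20200101"), ("92", "9", "20210101")])
        assert list(deduplicate(demo)) == ["92"]

    def test_date_tie_keeps_largest_primaryid(self):
        demo = self._demo([("92", "9", "20200101"), ("91", "9", "20200101")])
        assert list(deduplicate(demo)) == ["92"]

    def test_single_version_case_is_kept(self):
        demo = self._demo([("7", "3", "20190615")])
        assert list(deduplicate(demo)) == ["7"]

    def test_idempotent(self):
        demo = self._demo([("91", "9", "20200101"), ("92", "9", "20210101"),
                           ("5", "2", "20180101")])
        once = deduplicate(demo)
        twice = deduplicate(demo[demo["primaryid"].isin(once)])
        assert set(once) == set(twice)

    def test_stable_under_input_order(self, rng):
        demo = self._demo([(str(100 + i), str(i % 10), str(20200101 + i))
                           for i in range(50)])
        shuffled = demo.sample(frac=1, random_state=4)
        assert set(deduplicate(demo)) == set(deduplicate(shuffled))


class TestMatchDrug:
    def test_salt_suffix_stripped_from_prod_ai(self, dhp_dictionary):
        assert match_drug("", "AMLODIPINE BESYLATE", dhp_dictionary) == \
            {"amlodipine"}

    def test_brand_name_matches(self, dhp_dictionary):
        assert match_drug("NORVASC", "", dhp_dictionary) == {"amlodipine"}

    def test_non_member_is_empty(self, dhp_dictionary):
        assert match_drug("ASPIRIN", "", dhp_dictionary) == set()

    def test_combination_product_components_match(self, dhp_dictionary):
        hits = match_drug("", r"AMLODIPINE BESYLATE\BENAZEPRIL HYDROCHLORIDE",
                          dhp_dictionary)
        assert hits == {"amlodipine"}

    def test_case_insensitive(self, dhp_dictionary):
        assert match_drug("norvasc", "", dhp_dictionary) == {"amlodipine"}


class TestFilterReports:
    def test_consumer_reports_are_excluded(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": 1, "caseid": 1, "fda_dt": 20200101,
             "occp_cod": "CN", "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
            {"primaryid": 2, "caseid": 2, "fda_dt": 20200101,
             "occp_cod": "MD", "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
        ])
        ds = filter_reports(bundle, dictionary=dhp_dictionary)
        assert list(ds.reports["primaryid"]) == ["2"]

    def test_concomitant_mention_dropped_but_report_kept(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": 1, "caseid": 1, "fda_dt": 20200101,
             "drugs": [("AMLODIPINE", "C"), ("LISINOPRIL", "PS")],
             "pts": ["X"]},
        ])
        ds = filter_reports(bundle, dictionary=dhp_dictionary)
        assert ds.n_reports == 1
        assert "amlodipine" not in set(ds.drug_roles["ingredient"])
        # ...but the mention is still visible to the co-medication filter
        assert "amlodipine" in set(ds.all_mentions["ingredient"])

    def test_all_qualifying_is_a_no_op(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": i, "caseid": i, "fda_dt": 20200101,
             "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]}
            for i in range(1, 6)])
        ds = filter_reports(bundle, dictionary=dhp_dictionary)
        assert ds.n_reports == 5

    def test_missing_key_fields_drop_records(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": 1, "caseid": 1, "fda_dt": 20200101,
             "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
            {"primaryid": 2, "caseid": 2, "fda_dt": "",
             "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
            {"primaryid": 3, "caseid": "", "fda_dt": 20200101,
             "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
        ])
        ds = filter_reports(bundle, dictionary=dhp_dictionary)
        assert list(ds.reports["primaryid"]) == ["1"]

    def test_missing_sex_and_age_do_not_drop(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": 1, "caseid": 1, "fda_dt": 20200101, "sex": "",
             "age": "", "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]}])
        ds = filter_reports(bundle, dictionary=dhp_dictionary)
        assert ds.n_reports == 1
        assert ds.reports.loc[0, "sex"] == "unknown"
        assert ds.reports.loc[0, "age_group"] == "unknown"

    def test_empty_result_is_explicit(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": 1, "caseid": 1, "fda_dt": 20200101,
             "occp_cod": "CN", "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]}])
        with pytest.raises(EmptyDatasetError):
            filter_reports(bundle, dictionary=dhp_dictionary)

    def test_caseid_is_a_key_after_cleaning(self, dhp_dictionary):
        bundle = make_bundle([
            {"primaryid": 1, "caseid": 9, "fda_dt": 20200101,
             "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
            {"primaryid": 2, "caseid": 9, "fda_dt": 20210101,
             "drugs": [("AMLODIPINE", "PS")], "pts": ["Y"]},
        ])
        ds = filter_reports(bundle, dictionary=dhp_dictionary)
        assert ds.reports["caseid"].is_unique
        assert list(ds.reports["primaryid"]) == ["2"]


@pytest.mark.parametrize("age, group", [
    (0, "<18"), (17.9, "<18"), (18, "18-44"), (44, "18-44"),
    (44.5, "45-64"), (64, "45-64"), (64.5, "65-75"), (75, "65-75"),
    (75.5, ">75"), (float("nan"), "unknown"),
])
def test_age_group_bin_edges(age, group):
    got = assign_age_group(pd.Series([age]))
    assert got.iloc[0] == group


def test_dictionary_rejects_ambiguous_synonyms():
    with pytest.raises(ValueError, match="maps to both"):
        DrugDictionary.from_mapping([
            {"name": "a", "tag": "target", "synonyms": ["ZZZ"]},
            {"name": "b", "tag": "target", "synonyms": ["ZZZ"]}])
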