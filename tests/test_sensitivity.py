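"""Exclusion filters: examples, algebraic laws, persistence comparison."""

import itertools

import pandas as pd
import pytest

from pvsignal.cohort import filter_reports
from pvsignal.report import signal_screen
from pvsignal.sensitivity import (ExclusionRule, compare_runs, default_lists,
                                  exclude_comedication,
                                  exclude_pregnancy_indications,
                                  stratify_physician)
from pvsignal.synthetic_faers import generate
from tests.conftest import lean_config, make_bundle


@pytest.fixture
def mixed_dataset(dhp_dictionary):
    return filter_reports(make_bundle([
        {"primaryid": 1, "caseid": 1, "fda_dt": 20200101, "occp_cod": "MD",
         "drugs": [("AMLODIPINE", "PS"), ("SERTRALINE", "C")],
         "pts": ["Completed suicide"]},
        {"primaryid": 2, "caseid": 2, "fda_dt": 20200101, "occp_cod": "PH",
         "drugs": [("AMLODIPINE", "PS")], "pts": ["Nausea"],
         "indications": ["Hypertension"]},
        {"primaryid": 3, "caseid": 3, "fda_dt": 20200101, "occp_cod": "MD",
         "drugs": [("NIFEDIPINE", "SS"), ("LISINOPRIL", "PS")],
         "pts": ["Premature delivery"]},
        {"primaryid": 4, "caseid": 4, "fda_dt": 20200101, "occp_cod": "HP",
         "drugs": [("NIFEDIPINE", "PS")], "pts": ["Premature delivery"],
         "indications": ["Pre-eclampsia"]},
        {"primaryid": 5, "caseid": 5, "fda_dt": 20200101, "occp_cod": "MD",
         "drugs": [("LISINOPRIL", "PS")], "pts": ["Headache"]},
    ]), dictionary=dhp_dictionary)


class TestExcludeComedication:
    def test_co_mentioned_listed_drug_removed(self, mixed_dataset):
        out = exclude_comedication(mixed_dataset, ["sertraline"])
        assert "1" not in set(out.reports["primaryid"])
        assert out.n_reports == 4

    def test_any_role_matches(self, mixed_dataset):
        # sertraline had role C, which never qualifies for counting
        assert "sertraline" not in set(mixed_dataset.drug_roles["ingredient"])
        out = exclude_comedication(mixed_dataset, ["sertraline"])
        assert out.n_reports == mixed_dataset.n_reports - 1

    def test_empty_list_rejected(self, mixed_dataset):
        with pytest.raises(ValueError):
            exclude_comedication(mixed_dataset, [])


class TestExcludePregnancyIndications:
    def test_non_ps_target_removed(self, mixed_dataset):
        out = exclude_pregnancy_indications(mixed_dataset, ["Pre-eclampsia"])
        assert "3" not in set(out.reports["primaryid"])   # nifedipine SS

    def test_pregnancy_indication_removed(self, mixed_dataset):
        out = exclude_pregnancy_indications(mixed_dataset, ["Pre-eclampsia"])
        assert "4" not in set(out.reports["primaryid"])

    def test_ps_with_benign_indication_retained(self, mixed_dataset):
        out = exclude_pregnancy_indications(mixed_dataset, ["Pre-eclampsia"])
        assert "2" in set(out.reports["primaryid"])

    def test_background_reports_untouched(self, mixed_dataset):
        out = exclude_pregnancy_indications(mixed_dataset, ["Pre-eclampsia"])
        assert "5" in set(out.reports["primaryid"])


class TestStratifyPhysician:
    def test_non_physicians_removed(self, mixed_dataset):
        out = stratify_physician(mixed_dataset)
        assert set(out.reports["occupation"]) == {"MD"}
        assert out.n_reports == 3

    def test_all_md_dataset_unchanged(self, mixed_dataset):
        once = stratify_physician(mixed_dataset)
        assert stratify_physician(once).n_reports == once.n_reports


class TestFilterAlgebra:
    RULES = {
        "comed": lambda ds: exclude_comedication(ds, ["sertraline",
                                                      "quetiapine"]),
        "preg": lambda ds: exclude_pregnancy_indications(
            ds, ["Pre-eclampsia", "Premature labour"]),
        "md": stratify_physician,
    }

    @pytest.mark.parametrize("name", list(RULES))
    def test_idempotent_and_monotone_on_random_fixtures(self, name):
        rule = self.RULES[name]
        for seed in range(12):
            bundle, _ = generate(lean_config(250, seed=seed,
                                             indication_probs={
                                                 "Pre-eclampsia": 0.05,
                                                 "Hypertension": 0.3}))
            ds = filter_reports(bundle)
            once = rule(ds)
            assert set(once.reports["primaryid"]) <= \
                set(ds.reports["primaryid"])
            twice = rule(once)
            assert set(twice.reports["primaryid"]) == \
                set(once.reports["primaryid"])

    def test_rules_commute_pairwise(self):
        for seed in range(8):
            bundle, _ = generate(lean_config(250, seed=100 + seed,
                                             indication_probs={
                                                 "Pre-eclampsia": 0.05,
                                                 "Hypertension": 0.3}))
            ds = filter_reports(bundle)
            for r1, r2 in itertools.permutations(self.RULES.values(), 2):
                assert set(r2(r1(ds)).reports["primaryid"]) == \
                    set(r1(r2(ds)).reports["primaryid"])


class TestCompareRuns:
    def test_identical_runs_all_persist(self):
        bundle, _ = generate(lean_config(
            4000, seed=3,
            planted={("amlodipine", "Completed suicide"): 8.0}))
        ds = filter_reports(bundle)
        res = signal_screen(ds, k=5, backgrounds=("full",))
        rep = compare_runs(res, res)
        assert rep["persisted"].equals(rep["consensus_before"])
        assert (rep.filter(like="delta_").fillna(0) == 0).all().all()

    def test_key_mismatch_rejected(self):
        bundle, _ = generate(lean_config(2000, seed=3))
        ds = filter_reports(bundle)
        res = signal_screen(ds, k=4, backgrounds=("full",))
        with pytest.raises(ValueError, match="different"):
            compare_runs(res, res[res["pt"] != res["pt"].iloc[0]])

    def test_signal_lost_below_min_count_reports_reason(self):
        before = pd.DataFrame([{
            "drug": "d", "pt": "p", "background": "full", "a": 10,
            "ror": 5.0, "prr": 4.0, "chi2": 30.0, "ic025": 1.0,
            "ror_signal": True, "prr_signal": True, "mhra_signal": True,
            "ic_signal": True, "consensus": True}])
        after = before.assign(a=2, ror_signal=False, prr_signal=False,
                              mhra_signal=False, ic_signal=False,
                              consensus=False)
        rep = compare_runs(before, after)
        assert not rep.loc[0, "persisted"]
        assert rep.loc[0, "reason_lost"] == "min_count"


def test_exclusion_rule_guards():
    with pytest.raises(ValueError):
        ExclusionRule("co_medication", frozenset())
    with pytest.raises(ValueError):
        ExclusionRule("nonsense")
    lists = default_lists()
    assert "sertraline" in lists["antidepressants"]
    assert any("eclampsia" in p.lower()
               for p in lists["pregnancy_indications"])
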