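"""Shared fixtures: tiny hand-built bundles and lean synthetic configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvsignal.cohort import DrugDictionary, filter_reports
from pvsignal.faers_io import RawReportBundle
from pvsignal.synthetic_faers import DrugSpec, SyntheticConfig


@pytest.fixture(scope="session")
def dhp_dictionary() -> DrugDictionary:
    return DrugDictionary.default()


def make_bundle(reports: list[dict]) -> RawReportBundle:
    """Build a RawReportBundle from a compact per-report description.

    Each dict: primaryid, caseid, fda_dt, drugs=[(name, role)], pts=[...],
    plus optional sex/age/age_cod/occp_cod/country/outcomes/indications.
    """
    demo, drug, reac, outc, indi = [], [], [], [], []
    for r in reports:
        demo.append({
            "primaryid": str(r["primaryid"]), "caseid": str(r["caseid"]),
            "fda_dt": str(r["fda_dt"]), "sex": r.get("sex", "F"),
            "age": str(r.get("age", "50")), "age_cod": r.get("age_cod", "YR"),
            "occp_cod": r.get("occp_cod", "MD"),
            "reporter_country": r.get("country", "US")})
        for seq, (name, role) in enumerate(r.get("drugs", []), start=1):
            drug.append({"primaryid": str(r["primaryid"]),
                         "drug_seq": str(seq), "role_cod": role,
                         "drugname": name, "prod_ai": name})
        for pt in r.get("pts", []):
            reac.append({"primaryid": str(r["primaryid"]), "pt": pt})
        for code in r.get("outcomes", []):
            outc.append({"primaryid": str(r["primaryid"]), "outc_cod": code})
        for ind in r.get("indications", []):
            indi.append({"primaryid": str(r["primaryid"]), "indi_pt": ind})
    return RawReportBundle(
        demo=pd.DataFrame(demo),
        drug=pd.DataFrame(drug, columns=["primaryid", "drug_seq", "role_cod",
                                         "drugname", "prod_ai"]),
        reac=pd.DataFrame(reac, columns=["primaryid", "pt"]),
        outc=pd.DataFrame(outc, columns=["primaryid", "outc_cod"]),
        indi=pd.DataFrame(indi, columns=["primaryid", "indi_pt"]))


@pytest.fixture
def toy_pairs_dataset(dhp_dictionary):
    """Three reports: {R1: drug D=amlodipine, PTs X,Y}, {R2: D, X},
    {R3: E=lisinopril, PTs X,Z} — five distinct (report, PT) pairs."""
    bundle = make_bundle([
        {"primaryid": 1, "caseid": 1, "fda_dt": 20200101,
         "drugs": [("AMLODIPINE", "PS")], "pts": ["X", "Y"]},
        {"primaryid": 2, "caseid": 2, "fda_dt": 20200102,
         "drugs": [("AMLODIPINE", "PS")], "pts": ["X"]},
        {"primaryid": 3, "caseid": 3, "fda_dt": 20200103,
         "drugs": [("LISINOPRIL", "PS")], "pts": ["X", "Z"]},
    ])
    return filter_reports(bundle, dictionary=dhp_dictionary)


def lean_config(n_cases: int, seed: int, planted=None, *,
                target_exposure: float = 0.05,
                baseline_pt: float = 0.002, **overrides) -> SyntheticConfig:
    """Two-drug, six-PT world for fast simulation experiments: one target
    at 5% exposure, one broad comparator, and one rare PT of interest at
    baseline probability 0.002."""
    catalog = [
        DrugSpec("amlodipine", ("NORVASC",), "target"),
        DrugSpec("nicardipine", (), "target"),
        DrugSpec("lisinopril", (), "other"),
    ]
    pts = {"Completed suicide": baseline_pt, "Nausea": 0.35,
           "Headache": 0.25, "Dizziness": 0.2, "Rash": 0.1,
           "Fatigue": 1.0 - baseline_pt - 0.9}
    params = dict(
        n_cases=n_cases, drug_catalog=catalog, pt_catalog=pts,
        exposure_probs={"amlodipine": target_exposure, "nicardipine": 0.01,
                        "lisinopril": 0.6},
        planted_rr=planted or {}, pts_per_report_mean=2.0, dup_prob=0.1,
        seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250929)
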