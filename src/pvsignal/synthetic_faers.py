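"""Synthetic FAERS-dialect report generator with known ground truth.

Emulates the structure of spontaneous adverse-event reporting data — multi-PT
reports, multi-drug reports with suspect/concomitant role codes, follow-up
duplicates sharing a caseid, reporter occupations, demographics, outcomes and
indications — while planting known (drug, PT) reporting-rate multipliers so
that every downstream stage (dedup, filtering, 2x2 construction, signal
detection) can be validated against an analytic expectation.

Generative model, per case:

1. Drug exposure: each catalog drug is mentioned independently with its
   configured probability; a case that would mention no drug is assigned one
   drug sampled proportionally to the exposure probabilities (FAERS reports
   always name at least one drug).  One mention per case is the Primary
   Suspect; the others draw their role code from a categorical.
2. PT count ``m = min(1 + Poisson(pts_per_report_mean - 1), n_pts)`` — at
   least one event term per report, as FAERS requires.
3. PT identities: ``m`` i.i.d. draws from the baseline PT multinomial whose
   probabilities are multiplied by every planted multiplier of an exposed
   drug and renormalized.  Duplicate draws within a report are legitimate
   (they collapse to one distinct (report, PT) pair downstream).
4. Demographics (sex, age group -> age with unit code, country, occupation),
   outcomes (independent per code, so a report can carry several) and an
   optional indication PT.
5. With probability ``dup_prob`` the case emits one follow-up version: a new,
   larger primaryid, a strictly later fda_dt, identical child rows, and one
   demographic field re-drawn at random — exercising the "keep the most
   recent version" deduplication semantics.

:func:`expected_cells` computes the exact expected 2x2 cells of the cleaned
dataset under this model (enumerating exposure classes over the planted
drugs), and is the oracle against which the sampled output is tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .faers_io import RawReportBundle

QUALIFYING_OCCUPATIONS = ("MD", "PH", "HP")

STUDY_WINDOW = (20140701, 20241231)  # yyyymmdd bounds for original reports


class ConfigurationError(ValueError):
    """A SyntheticConfig field violates its invariant; names the field."""


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: canonical ingredient, brand synonyms, class tag."""

    name: str
    brands: tuple[str, ...] = ()
    tag: str = "other"  # target | class_background | other

    def __post_init__(self):
        if self.tag not in {"target", "class_background", "other"}:
            raise ConfigurationError(f"drug {self.name!r}: bad class tag {self.tag!r}")


def _check_categorical(name: str, probs: dict[str, float]) -> None:
    for key, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name}[{key!r}] = {p} outside [0, 1]")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")


@dataclass
class SyntheticConfig:
    """Full generative specification for one synthetic report bundle."""

    n_cases: int
    drug_catalog: list[DrugSpec]
    pt_catalog: dict[str, float]                 # PT label -> baseline prob
    exposure_probs: dict[str, float]             # drug -> mention prob
    planted_rr: dict[tuple[str, str], float] = field(default_factory=dict)
    pts_per_report_mean: float = 2.5
    dup_prob: float = 0.25
    occupation_probs: dict[str, float] = field(default_factory=lambda: {
        "MD": 0.45, "HP": 0.20, "PH": 0.10, "CN": 0.20, "LW": 0.01,
        "unknown": 0.04})
    sex_probs: dict[str, float] = field(default_factory=lambda: {
        "F": 0.53, "M": 0.43, "unknown": 0.04})
    age_group_probs: dict[str, float] = field(default_factory=lambda: {
        "<18": 0.05, "18-44": 0.20, "45-64": 0.30, "65-75": 0.20,
        ">75": 0.15, "unknown": 0.10})
    country_probs: dict[str, float] = field(default_factory=lambda: {
        "US": 0.50, "GB": 0.10, "CA": 0.08, "FR": 0.08, "JP": 0.06,
        "DE": 0.05, "OTHER": 0.13})
    outcome_probs: dict[str, float] = field(default_factory=lambda: {
        "OT": 0.39, "HO": 0.33, "DE": 0.10, "LT": 0.07, "DS": 0.02,
        "CA": 0.005, "RI": 0.002})
    indication_probs: dict[str, float] = field(default_factory=dict)
    missingness_probs: dict[str, float] = field(default_factory=lambda: {
        "reporter_country": 0.02})
    role_probs: dict[str, float] = field(default_factory=lambda: {
        "SS": 0.35, "C": 0.45, "I": 0.05, "SC": 0.15})
    brand_name_prob: float = 0.3     # drugname uses a brand synonym
    salt_suffix_prob: float = 0.3    # prod_ai carries a salt suffix
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ConfigurationError(f"n_cases = {self.n_cases} must be >= 1")
        if not self.drug_catalog:
            raise ConfigurationError("drug_catalog is empty")
        if not self.pt_catalog:
            raise ConfigurationError("pt_catalog is empty")
        names = [d.name for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ConfigurationError("drug_catalog names are not unique")
        _check_categorical("pt_catalog", self.pt_catalog)
        for cat in ("occupation_probs", "sex_probs", "age_group_probs",
                    "country_probs", "role_probs"):
            _check_categorical(cat, getattr(self, cat))
        for drug, p in self.exposure_probs.items():
            if drug not in names:
                raise ConfigurationError(f"exposure_probs names unknown drug {drug!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"exposure_probs[{drug!r}] = {p} outside [0, 1]")
        for d in names:
            self.exposure_probs.setdefault(d, 0.0)
        if sum(self.exposure_probs.values()) <= 0:
            raise ConfigurationError("exposure_probs: all zero")
        for (drug, pt), rr in self.planted_rr.items():
            if drug not in names:
                raise ConfigurationError(f"planted_rr names unknown drug {drug!r}")
            if pt not in self.pt_catalog:
                raise ConfigurationError(f"planted_rr names unknown PT {pt!r}")
            if rr < 0:
                raise ConfigurationError(f"planted_rr[{(drug, pt)}] = {rr} < 0")
        for f in ("dup_prob", "brand_name_prob", "salt_suffix_prob"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{f} = {v} outside [0, 1]")
        for key, p in {**self.outcome_probs, **self.indication_probs,
                       **self.missingness_probs}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability for {key!r} = {p} outside [0, 1]")
        if sum(self.indication_probs.values()) > 1.0 + 1e-9:
            raise ConfigurationError("indication_probs sum exceeds 1")
        if self.pts_per_report_mean < 1.0:
            raise ConfigurationError(
                f"pts_per_report_mean = {self.pts_per_report_mean} must be >= 1")

    # -- derived views -----------------------------------------------------
    @property
    def drug_names(self) -> list[str]:
        return [d.name for d in self.drug_catalog]

    @property
    def targets(self) -> list[str]:
        return [d.name for d in self.drug_catalog if d.tag == "target"]

    @property
    def class_members(self) -> list[str]:
        return [d.name for d in self.drug_catalog
                if d.tag in ("target", "class_background")]

    def rate_multiplier(self, drug: str, pt: str) -> float:
        return self.planted_rr.get((drug, pt), 1.0)


@dataclass
class GroundTruth:
    """Echo of the planted multipliers plus analytic expected 2x2 cells.

    ``expected_cells`` maps (drug, pt, background) to expected real-valued
    (a, b, c, d) in the cleaned (deduplicated, occupation-filtered) dataset,
    where the analysis unit is a distinct (report, PT) pair and exposure is
    a drug mention of any role.
    """

    planted_rr: dict[tuple[str, str], float]
    expected_cells: dict[tuple[str, str, str], tuple[float, float, float, float]]

    def expected_ror(self, drug: str, pt: str, background: str = "full") -> float:
        a, b, c, d = self.expected_cells[(drug, pt, background)]
        return (a * d) / (b * c)

    def expected_prr(self, drug: str, pt: str, background: str = "full") -> float:
        a, b, c, d = self.expected_cells[(drug, pt, background)]
        return (a / (a + b)) / (c / (c + d))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_rr": [
                {"drug": d, "pt": p, "rr": rr}
                for (d, p), rr in sorted(self.planted_rr.items())],
            "expected_cells": [
                {"drug": d, "pt": p, "background": bg,
                 "a": a, "b": b, "c": c, "d": dd}
                for (d, p, bg), (a, b, c, dd) in sorted(self.expected_cells.items())],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# analytic expectations


def _distinct_pt_factor(q: np.ndarray, lam: float, k: int) -> np.ndarray:
    """E[1 - (1 - q)^m] with m = min(1 + Poisson(lam), k), elementwise in q.

    This is the probability that a report whose PT law is ``q`` mentions a
    given PT at least once, i.e. contributes one distinct (report, PT) pair.
    """
    if k == 1:
        return q.copy()
    t = np.arange(0, k - 1)
    pmf = sps.poisson.pmf(t, lam)
    tail = sps.poisson.sf(k - 2, lam)
    one_minus = 1.0 - q[:, None]
    expect = (pmf[None, :] * one_minus ** (1 + t)[None, :]).sum(axis=1)
    expect += tail * (1.0 - q) ** k
    return 1.0 - expect


def expected_cells(config: SyntheticConfig,
                   pairs: list[tuple[str, str]] | None = None,
                   backgrounds: tuple[str, ...] = ("full", "class"),
                   ) -> GroundTruth:
    """Closed-form expected 2x2 cells of the cleaned dataset.

    Enumerates exposure classes over the planted drugs (the only drugs that
    alter the PT law) together with the target drug; every other drug is
    marginalized analytically, including the no-drug fallback and the
    class-background membership of non-enumerated class drugs.
    """
    if pairs is None:
        pairs = sorted(set(config.planted_rr))
    pts = list(config.pt_catalog)
    base = np.array([config.pt_catalog[p] for p in pts])
    lam = config.pts_per_report_mean - 1.0
    k = len(pts)
    q_occ = sum(config.occupation_probs.get(o, 0.0) for o in QUALIFYING_OCCUPATIONS)
    n_eff = config.n_cases * q_occ
    exp_p = config.exposure_probs
    total_p = sum(exp_p.values())
    planted_drugs = sorted({d for d, _ in config.planted_rr})
    cm = set(config.class_members)

    def pt_law(active: frozenset[str]) -> np.ndarray:
        mult = np.ones(k)
        for d in active:
            for i, p in enumerate(pts):
                mult[i] *= config.rate_multiplier(d, p)
        q = base * mult
        return q / q.sum()

    cells: dict[tuple[str, str, str], tuple[float, float, float, float]] = {}
    for drug, pt in pairs:
        enum = sorted(set(planted_drugs) | {drug})
        pt_idx = pts.index(pt)
        # classes: (probability, drug exposed?, active planted set, in-class prob)
        classes: list[tuple[float, bool, frozenset, float]] = []
        p_other_cm = 1.0 - math.prod(1.0 - exp_p.get(j, 0.0)
                                     for j in cm if j not in enum)
        for mask in range(1 << len(enum)):
            exposed = frozenset(e for i, e in enumerate(enum) if mask >> i & 1)
            prob = math.prod(exp_p.get(e, 0.0) if e in exposed
                             else 1.0 - exp_p.get(e, 0.0) for e in enum)
            if prob == 0.0:
                continue
            active = frozenset(exposed & set(planted_drugs))
            if exposed:
                in_class = 1.0 if exposed & cm else p_other_cm
                classes.append((prob, drug in exposed, active, in_class))
            else:
                # Bernoulli draw empty over enumerated drugs: split on the
                # non-enumerated drugs being all absent (-> fallback) or not.
                p_rest_empty = math.prod(1.0 - exp_p.get(j, 0.0)
                                         for j in config.drug_names
                                         if j not in enum)
                if p_rest_empty < 1.0:
                    # class membership must be conditioned on the rest of the
                    # catalog being nonempty (cm drugs are part of that rest)
                    classes.append((prob * (1.0 - p_rest_empty), False,
                                    frozenset(),
                                    p_other_cm / (1.0 - p_rest_empty)))
                p_empty = prob * p_rest_empty
                for j in config.drug_names:  # fallback drug j
                    pj = p_empty * exp_p.get(j, 0.0) / total_p
                    if pj == 0.0:
                        continue
                    classes.append((pj, j == drug,
                                    frozenset({j} & set(planted_drugs)),
                                    1.0 if j in cm else 0.0))
        law_cache: dict[frozenset, tuple[float, float]] = {}
        for bg in backgrounds:
            a = ab = ac = n_pairs = 0.0
            for prob, has_drug, active, in_class in classes:
                weight = prob * (in_class if bg == "class" else 1.0)
                if weight == 0.0:
                    continue
                if active not in law_cache:
                    g = _distinct_pt_factor(pt_law(active), lam, k)
                    law_cache[active] = (float(g[pt_idx]), float(g.sum()))
                g_pt, g_all = law_cache[active]
                n_pairs += weight * g_all
                ac += weight * g_pt
                if has_drug:
                    a += weight * g_pt
                    ab += weight * g_all
            a, ab, ac, n_pairs = (n_eff * x for x in (a, ab, ac, n_pairs))
            cells[(drug, pt, bg)] = (a, ab - a, ac - a, n_pairs - ab - ac + a)
    return GroundTruth(planted_rr=dict(config.planted_rr), expected_cells=cells)


# ---------------------------------------------------------------------------
# sampling

SALT_SUFFIXES = ("BESYLATE", "MALEATE", "HYDROCHLORIDE", "MESYLATE", "TARTRATE")

_MUTABLE_FIELDS = ("sex", "age", "reporter_country", "occp_cod")


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float],
                      n: int) -> np.ndarray:
    keys = np.array(list(probs), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return keys[rng.choice(len(keys), size=n, p=p / p.sum())]


_AGE_RANGES = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64),
               "65-75": (65, 75), ">75": (76, 95)}


def _draw_ages(rng: np.random.Generator, groups: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    ages = np.full(len(groups), "", dtype=object)
    codes = np.full(len(groups), "", dtype=object)
    for grp, (lo, hi) in _AGE_RANGES.items():
        idx = np.flatnonzero(groups == grp)
        if idx.size == 0:
            continue
        vals = rng.integers(lo, hi + 1, size=idx.size)
        ages[idx] = vals.astype(str)
        codes[idx] = "YR"
        # occasional month-coded infant ages inside the <18 bin
        if grp == "<18":
            mon = idx[rng.random(idx.size) < 0.2]
            ages[mon] = rng.integers(1, 12, size=mon.size).astype(str)
            codes[mon] = "MON"
    return ages, codes


def _yyyymmdd(dates: pd.DatetimeIndex) -> np.ndarray:
    nums = dates.year * 10000 + dates.month * 100 + dates.day
    return nums.astype(str).astype(object).to_numpy()


def _draw_dates(rng: np.random.Generator, n: int) -> np.ndarray:
    start = pd.Timestamp("2014-07-01")
    end = pd.Timestamp("2024-12-31")
    offsets = rng.integers(0, (end - start).days + 1, size=n)
    return _yyyymmdd(start + pd.to_timedelta(offsets, unit="D"))


def generate(config: SyntheticConfig) -> tuple[RawReportBundle, GroundTruth]:
    """Sample one report bundle and return it with its analytic ground truth.

    Identical configs (including ``seed``) produce byte-identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drug_names
    pts = list(config.pt_catalog)
    k = len(pts)
    base = np.array([config.pt_catalog[p] for p in pts])

    # --- exposure -------------------------------------------------------
    p_vec = np.array([config.exposure_probs[d] for d in drugs])
    exposed = rng.random((n, len(drugs))) < p_vec[None, :]
    empty = ~exposed.any(axis=1)
    if empty.any():
        fallback = rng.choice(len(drugs), size=int(empty.sum()),
                              p=p_vec / p_vec.sum())
        exposed[np.flatnonzero(empty), fallback] = True

    # --- PT draws, grouped by planted-exposure signature ----------------
    planted_drugs = sorted({d for d, _ in config.planted_rr})
    planted_idx = [drugs.index(d) for d in planted_drugs]
    lam = max(config.pts_per_report_mean - 1.0, 0.0)
    m = np.minimum(1 + rng.poisson(lam, size=n), k)
    pt_indices = np.empty(m.sum(), dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(m)])
    if planted_idx:
        signature = exposed[:, planted_idx]
        sig_codes = signature.dot(1 << np.arange(len(planted_idx)))
    else:
        sig_codes = np.zeros(n, dtype=np.int64)
    for code in np.unique(sig_codes):
        rows = np.flatnonzero(sig_codes == code)
        mult = np.ones(k)
        for bit, d in enumerate(planted_drugs):
            if code >> bit & 1:
                for i, p in enumerate(pts):
                    mult[i] *= config.rate_multiplier(d, p)
        q = base * mult
        q = q / q.sum()
        total = int(m[rows].sum())
        draws = rng.choice(k, size=total, p=q)
        lengths = m[rows]
        offsets = np.repeat(starts[rows], lengths)
        within = np.arange(total) - np.repeat(np.cumsum(lengths) - lengths, lengths)
        pt_indices[offsets + within] = draws

    # --- demographics ----------------------------------------------------
    caseid = np.arange(1, n + 1).astype(str).astype(object)
    primaryid = (10_000_000 + np.cumsum(rng.integers(1, 10, size=n))).astype(str).astype(object)
    fda_dt = _draw_dates(rng, n)
    sex = _draw_categorical(rng, config.sex_probs, n)
    sex[sex == "unknown"] = ""
    groups = _draw_categorical(rng, config.age_group_probs, n)
    age, age_cod = _draw_ages(rng, groups)
    occp = _draw_categorical(rng, config.occupation_probs, n)
    occp[occp == "unknown"] = ""
    country = _draw_categorical(rng, config.country_probs, n)
    for fld, p_miss in config.missingness_probs.items():
        col = {"sex": sex, "age": age, "age_cod": age_cod,
               "reporter_country": country, "occp_cod": occp}.get(fld)
        if col is not None and p_miss > 0:
            col[rng.random(n) < p_miss] = ""

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
        "sex": sex, "age": age, "age_cod": age_cod, "occp_cod": occp,
        "reporter_country": country})

    # --- drug rows --------------------------------------------------------
    rep_idx, drug_idx = np.nonzero(exposed)
    n_mentions = len(rep_idx)
    roles = _draw_categorical(rng, config.role_probs, n_mentions)
    # one PS per case: the first mention of each report (mentions are emitted
    # in catalog order; which drug comes first is arbitrary w.r.t. the model)
    first_of_case = np.concatenate([[True], np.diff(rep_idx) > 0])
    roles[first_of_case] = "PS"
    upper_names = np.array([d.name.upper() for d in config.drug_catalog],
                           dtype=object)
    use_brand = rng.random(n_mentions) < config.brand_name_prob
    use_salt = rng.random(n_mentions) < config.salt_suffix_prob
    salt_pick = rng.integers(0, len(SALT_SUFFIXES), size=n_mentions)
    brand_pick = rng.random(n_mentions)
    drugname = upper_names[drug_idx].copy()
    for j, spec in enumerate(config.drug_catalog):  # few catalog entries
        if not spec.brands:
            continue
        sel = use_brand & (drug_idx == j)
        if sel.any():
            picks = (brand_pick[sel] * len(spec.brands)).astype(int)
            drugname[sel] = np.array(spec.brands, dtype=object)[picks]
    prod_ai = upper_names[drug_idx].copy()
    salts = np.array(SALT_SUFFIXES, dtype=object)[salt_pick[use_salt]]
    prod_ai[use_salt] = np.char.add(
        np.char.add(prod_ai[use_salt].astype(str), " "),
        salts.astype(str)).astype(object)
    counts = np.bincount(rep_idx, minlength=n)
    drug_seq = (np.arange(n_mentions)
                - np.repeat(np.cumsum(counts) - counts, counts) + 1).astype(str)
    drug_df = pd.DataFrame({
        "primaryid": primaryid[rep_idx], "drug_seq": drug_seq,
        "role_cod": roles, "drugname": drugname, "prod_ai": prod_ai})

    # --- reac rows --------------------------------------------------------
    reac_rep = np.repeat(np.arange(n), m)
    reac_df = pd.DataFrame({
        "primaryid": primaryid[reac_rep],
        "pt": np.array(pts, dtype=object)[pt_indices]})

    # --- outcomes & indications ------------------------------------------
    outc_frames = []
    for code, p in config.outcome_probs.items():
        hit = np.flatnonzero(rng.random(n) < p)
        if hit.size:
            outc_frames.append(pd.DataFrame({
                "primaryid": primaryid[hit], "outc_cod": code}))
    outc_df = (pd.concat(outc_frames, ignore_index=True) if outc_frames
               else pd.DataFrame(columns=["primaryid", "outc_cod"]))

    indi_df = pd.DataFrame(columns=["primaryid", "indi_pt"])
    if config.indication_probs:
        labels = list(config.indication_probs)
        p = np.array([config.indication_probs[x] for x in labels])
        p_none = max(0.0, 1.0 - p.sum())
        choice = rng.choice(len(labels) + 1, size=n,
                            p=np.append(p, p_none))
        has = choice < len(labels)
        if has.any():
            indi_df = pd.DataFrame({
                "primaryid": primaryid[has],
                "indi_pt": np.array(labels, dtype=object)[choice[has]]})

    # --- follow-up duplicates --------------------------------------------
    dup = np.flatnonzero(rng.random(n) < config.dup_prob)
    if dup.size:
        max_id = int(primaryid[-1])
        dup_primaryid = (max_id + np.cumsum(rng.integers(1, 10, size=dup.size))
                         ).astype(str).astype(object)
        dup_demo = demo.iloc[dup].copy()
        dup_demo["primaryid"] = dup_primaryid
        later = (pd.DatetimeIndex(pd.to_datetime(demo["fda_dt"].iloc[dup],
                                                 format="%Y%m%d"))
                 + pd.to_timedelta(rng.integers(1, 301, size=dup.size), unit="D"))
        dup_demo["fda_dt"] = _yyyymmdd(later)
        # mutate one demographic field per follow-up
        which = rng.integers(0, len(_MUTABLE_FIELDS), size=dup.size)
        new_sex = _draw_categorical(rng, config.sex_probs, dup.size)
        new_sex[new_sex == "unknown"] = ""
        new_grp = _draw_categorical(rng, config.age_group_probs, dup.size)
        new_age, new_cod = _draw_ages(rng, new_grp)
        new_country = _draw_categorical(rng, config.country_probs, dup.size)
        new_occp = _draw_categorical(rng, config.occupation_probs, dup.size)
        new_occp[new_occp == "unknown"] = ""
        cols = dup_demo.columns.get_indexer
        for j, (field_name, values) in enumerate(zip(
                _MUTABLE_FIELDS,
                (new_sex, (new_age, new_cod), new_country, new_occp))):
            sel = which == j
            if not sel.any():
                continue
            if field_name == "age":
                dup_demo.iloc[sel, cols(["age"])[0]] = values[0][sel]
                dup_demo.iloc[sel, cols(["age_cod"])[0]] = values[1][sel]
            else:
                dup_demo.iloc[sel, cols([field_name])[0]] = values[sel]
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        id_map = dict(zip(primaryid[dup], dup_primaryid))

        def _with_copies(df: pd.DataFrame) -> pd.DataFrame:
            mask = df["primaryid"].isin(id_map)
            if not mask.any():
                return df
            extra = df[mask].copy()
            extra["primaryid"] = extra["primaryid"].map(id_map)
            return pd.concat([df, extra], ignore_index=True)

        drug_df = _with_copies(drug_df)
        reac_df = _with_copies(reac_df)
        outc_df = _with_copies(outc_df)
        indi_df = _with_copies(indi_df)

    bundle = RawReportBundle(demo=demo, drug=drug_df, reac=reac_df,
                             outc=outc_df, indi=indi_df)
    truth = expected_cells(config)
    return bundle, truth


# ---------------------------------------------------------------------------
# study-condition defaults


def default_config(n_cases: int = 200_000, seed: int = 0,
                   **overrides) -> SyntheticConfig:
    """The default synthetic world: four DHP-CCB targets against a broad
    co-medication background, with planted multipliers that mirror the kinds
    of signals a real disproportionality screen surfaces (a psychiatric event
    on the most-reported target, an otologic event on a low-volume target,
    and obstetric events on the two targets used in pregnancy).
    """
    catalog = [
        DrugSpec("amlodipine", ("NORVASC", "KATERZIA"), "target"),
        DrugSpec("felodipine", ("PLENDIL",), "target"),
        DrugSpec("nicardipine", ("CARDENE",), "target"),
        DrugSpec("nifedipine", ("ADALAT", "PROCARDIA"), "target"),
        DrugSpec("nimodipine", ("NYMALIZE",), "class_background"),
        DrugSpec("lercanidipine", ("ZANIDIP",), "class_background"),
        DrugSpec("isradipine", (), "class_background"),
        DrugSpec("lisinopril", ("ZESTRIL",), "other"),
        DrugSpec("atorvastatin", ("LIPITOR",), "other"),
        DrugSpec("metformin", ("GLUCOPHAGE",), "other"),
        DrugSpec("omeprazole", ("PRILOSEC",), "other"),
        DrugSpec("aspirin", (), "other"),
        DrugSpec("paracetamol", ("TYLENOL",), "other"),
        DrugSpec("sertraline", ("ZOLOFT",), "other"),
        DrugSpec("quetiapine", ("SEROQUEL",), "other"),
        DrugSpec("furosemide", ("LASIX",), "other"),
    ]
    exposure = {
        "amlodipine": 0.05, "felodipine": 0.008, "nicardipine": 0.006,
        "nifedipine": 0.015, "nimodipine": 0.004, "lercanidipine": 0.004,
        "isradipine": 0.002, "lisinopril": 0.12, "atorvastatin": 0.15,
        "metformin": 0.12, "omeprazole": 0.12, "aspirin": 0.20,
        "paracetamol": 0.15, "sertraline": 0.05, "quetiapine": 0.03,
        "furosemide": 0.08,
    }
    pt_catalog = {
        "Completed suicide": 0.002, "Suicide attempt": 0.004,
        "Tinnitus": 0.003, "Palpitations": 0.010, "Hypotension": 0.015,
        "Dizziness": 0.060, "Nausea": 0.100, "Headache": 0.080,
        "Fatigue": 0.070, "Dyspnoea": 0.050, "Fall": 0.030,
        "Acute kidney injury": 0.012, "Hyperkalaemia": 0.004,
        "Premature delivery": 0.001, "Exposure during pregnancy": 0.003,
        "Cerebral vasoconstriction": 0.0002, "Angioedema": 0.005,
        "Rash": 0.060, "Vomiting": 0.070, "Diarrhoea": 0.080,
        "Oedema peripheral": 0.020, "Malaise": 0.060, "Asthenia": 0.050,
        "Bradycardia": 0.006, "Drug interaction": 0.040,
        "Off label use": 0.050, "Product use in unapproved indication": 0.015,
    }
    # the catch-all term absorbs the remaining probability mass exactly
    pt_catalog["Drug ineffective"] = 1.0 - math.fsum(pt_catalog.values())
    planted = {
        ("amlodipine", "Completed suicide"): 8.0,
        ("amlodipine", "Suicide attempt"): 4.0,
        ("felodipine", "Tinnitus"): 20.0,
        ("nicardipine", "Hyperkalaemia"): 15.0,
        ("nicardipine", "Cerebral vasoconstriction"): 100.0,
        ("nifedipine", "Premature delivery"): 30.0,
        ("nifedipine", "Exposure during pregnancy"): 8.0,
    }
    indications = {"Hypertension": 0.30, "Diabetes mellitus": 0.08,
                   "Pre-eclampsia": 0.01, "Premature labour": 0.005,
                   "Depression": 0.04}
    params = dict(n_cases=n_cases, drug_catalog=catalog, pt_catalog=pt_catalog,
                  exposure_probs=exposure, planted_rr=planted,
                  indication_probs=indications, seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)
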