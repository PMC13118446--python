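"""Case-level cleaning: deduplication, filtering and drug-name resolution.

Turns a :class:`~pvsignal.faers_io.RawReportBundle` into a
:class:`CleanDataset`, the unit on which all counting downstream is defined:

1. drop DEMO rows missing any of the key fields (caseid, primaryid, fda_dt);
2. deduplicate follow-up versions — per caseid keep the row with the most
   recent fda_dt, ties broken by the largest primaryid;
3. keep only reports from physicians, pharmacists and other health
   professionals (occp_cod MD / PH / HP);
4. keep only drug mentions whose role is Primary Suspect, Secondary Suspect
   or Interacting (PS / SS / I); a report left with no drug mention at all
   is dropped;
5. resolve drug names against an ingredient dictionary (generic + brand
   synonyms, salt/ester suffixes stripped) to per-report ingredient flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .faers_io import RawReportBundle, ages_in_years, parse_fda_dt

logger = logging.getLogger(__name__)

DEFAULT_OCCUPATIONS = frozenset({"MD", "PH", "HP"})
DEFAULT_ROLES = frozenset({"PS", "SS", "I"})

#: Trailing salt/ester words removed from active-ingredient tokens before
#: dictionary lookup ("AMLODIPINE BESYLATE" -> "AMLODIPINE").
SALT_SUFFIXES = frozenset({
    "BESYLATE", "BESILATE", "MALEATE", "MESYLATE", "MESILATE",
    "HYDROCHLORIDE", "HCL", "TARTRATE", "SUCCINATE", "CITRATE", "FUMARATE",
    "ACETATE", "PHOSPHATE", "SULFATE", "SULPHATE", "SODIUM", "CALCIUM",
    "POTASSIUM", "BITARTRATE", "OXALATE", "ERBUMINE",
})

#: Preference order when one (report, ingredient) pair carries several roles.
ROLE_RANK = {"PS": 0, "SS": 1, "I": 2, "SC": 3, "C": 4}

AGE_GROUP_LABELS = ["<18", "18-44", "45-64", "65-75", ">75", "unknown"]


class EmptyDatasetError(ValueError):
    """Cleaning removed every report; downstream counting would be vacuous."""


def _normalize(name: str) -> str:
    return " ".join(str(name).upper().split())


def _norm_series(s: pd.Series, upper: bool = False) -> pd.Series:
    """strip (and optionally uppercase) via the unique values only."""
    codes, uniques = pd.factorize(s.fillna("").astype(str))
    vals = [u.strip().upper() if upper else u.strip() for u in uniques]
    arr = np.array(vals + [""], dtype=object)   # -1 codes (NaN) -> ""
    return pd.Series(arr[codes], index=s.index)


def _strip_salt(token: str, suffixes: frozenset[str] = SALT_SUFFIXES) -> str:
    words = _normalize(token).split()
    while len(words) > 1 and words[-1] in suffixes:
        words.pop()
    return " ".join(words)


@dataclass(frozen=True)
class DrugDictionary:
    """Canonical ingredient -> synonym sets, with target/class annotations."""

    entries: dict[str, frozenset[str]]       # canonical -> uppercase synonyms
    class_members: frozenset[str]            # DHP-CCB class (ATC C08CA)
    targets: tuple[str, ...]                 # study drugs, ordered

    def __post_init__(self):
        if not set(self.targets) <= self.class_members:
            raise ValueError("targets must be a subset of class_members")
        seen: dict[str, str] = {}
        for canon, syns in self.entries.items():
            for s in syns:
                if s in seen and seen[s] != canon:
                    raise ValueError(
                        f"synonym {s!r} maps to both {seen[s]!r} and {canon!r}")
                seen[s] = canon

    @property
    def synonym_map(self) -> dict[str, str]:
        out = {}
        for canon, syns in self.entries.items():
            for s in syns:
                out[s] = canon
        return out

    @classmethod
    def from_mapping(cls, drugs: list[dict]) -> "DrugDictionary":
        entries, members, targets = {}, set(), []
        for item in drugs:
            canon = str(item["name"]).lower()
            syns = {_normalize(canon)} | {_normalize(s)
                                          for s in item.get("synonyms", [])}
            entries[canon] = frozenset(syns)
            tag = item.get("tag", "other")
            if tag in ("target", "class_background"):
                members.add(canon)
            if tag == "target":
                targets.append(canon)
        return cls(entries=entries, class_members=frozenset(members),
                   targets=tuple(targets))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugDictionary":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_mapping(payload["drugs"])

    @classmethod
    def default(cls) -> "DrugDictionary":
        """The shipped dihydropyridine-CCB dictionary (four targets + class)."""
        ref = resources.files("pvsignal.data") / "drug_dictionary.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text())["drugs"])


def match_drug(drugname: str, prod_ai: str,
               dictionary: DrugDictionary) -> set[str]:
    """Resolve one drug mention to canonical ingredients (possibly empty).

    The active-ingredient string is split on the combination separators
    ``'\\'`` and ``'+'``; each component is matched after salt-suffix
    stripping.  The verbatim drugname is matched as a whole (brand names) and
    component-wise.  Matching is deterministic and case-insensitive.
    """
    syn = dictionary.synonym_map
    hits: set[str] = set()
    for raw in (prod_ai, drugname):
        if not raw or not str(raw).strip():
            continue
        text = _normalize(raw)
        if text in syn:
            hits.add(syn[text])
            continue
        for part in text.replace("+", "\\").split("\\"):
            part = _strip_salt(part)
            if part in syn:
                hits.add(syn[part])
    return hits


def deduplicate(demo: pd.DataFrame) -> pd.Index:
    """Select one primaryid per caseid: latest fda_dt, then largest primaryid.

    Rows with a missing caseid, primaryid or unparseable fda_dt are ignored
    (they are dropped by the upstream key-field rule).  The selection is
    stable with respect to input order.
    """
    df = demo[["primaryid", "caseid", "fda_dt"]].copy()
    df["fda_dt"] = parse_fda_dt(df["fda_dt"].astype(str))
    df["pid_num"] = pd.to_numeric(df["primaryid"], errors="coerce")
    df = df[(df["caseid"].astype(str).str.strip() != "")
            & df["pid_num"].notna() & df["fda_dt"].notna()]
    order = df.sort_values(["caseid", "fda_dt", "pid_num"], kind="mergesort")
    kept = order.groupby("caseid", sort=False).tail(1)
    return pd.Index(kept["primaryid"])


@dataclass
class CleanDataset:
    """Deduplicated, filtered report-level records with joined mentions.

    ``reports`` has one row per retained case (caseid is a key), with parsed
    demographics. ``drug_roles`` holds the qualifying-role mentions resolved
    to canonical ingredients (best role per pair, PS > SS > I > SC > C);
    ``all_mentions`` additionally keeps non-qualifying roles, which the
    co-medication sensitivity filter needs. ``pts`` / ``indications`` /
    ``outcomes`` are distinct per (report, label) pairs.
    """

    reports: pd.DataFrame
    drug_roles: pd.DataFrame       # primaryid, ingredient, role
    all_mentions: pd.DataFrame     # primaryid, ingredient, role (any role)
    pts: pd.DataFrame              # primaryid, pt
    indications: pd.DataFrame      # primaryid, indi_pt
    outcomes: pd.DataFrame         # primaryid, outc_cod
    dictionary: DrugDictionary = field(default_factory=DrugDictionary.default)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def report_ids(self) -> pd.Index:
        return pd.Index(self.reports["primaryid"])

    def ids_with_drug(self, ingredient: str) -> pd.Index:
        sel = self.drug_roles["ingredient"] == ingredient
        return pd.Index(self.drug_roles.loc[sel, "primaryid"].unique())

    def ids_in_class(self) -> pd.Index:
        sel = self.drug_roles["ingredient"].isin(self.dictionary.class_members)
        return pd.Index(self.drug_roles.loc[sel, "primaryid"].unique())

    def subset(self, primaryids: pd.Index | set) -> "CleanDataset":
        """Restrict every table to the given report ids (filter monotone)."""
        ids = pd.Index(primaryids)
        keep = {
            "reports": self.reports[self.reports["primaryid"].isin(ids)],
            "drug_roles": self.drug_roles[self.drug_roles["primaryid"].isin(ids)],
            "all_mentions": self.all_mentions[self.all_mentions["primaryid"].isin(ids)],
            "pts": self.pts[self.pts["primaryid"].isin(ids)],
            "indications": self.indications[self.indications["primaryid"].isin(ids)],
            "outcomes": self.outcomes[self.outcomes["primaryid"].isin(ids)],
        }
        return replace(self, **{k: v.reset_index(drop=True)
                                for k, v in keep.items()})


def assign_age_group(age_years: pd.Series) -> pd.Series:
    """Five-bin grouping: [0,18), [18,44], (44,64], (64,75], (75,inf)."""
    a = age_years
    out = pd.Series(
        np.select(
            [a < 18, a <= 44, a <= 64, a <= 75, a > 75],
            AGE_GROUP_LABELS[:5], default="unknown"),
        index=a.index)
    out[a.isna()] = "unknown"
    return out


def filter_reports(bundle: RawReportBundle,
                   dictionary: DrugDictionary | None = None,
                   occupations: frozenset[str] | None = DEFAULT_OCCUPATIONS,
                   roles: frozenset[str] | None = DEFAULT_ROLES,
                   ) -> CleanDataset:
    """Apply the full cleaning cascade and return the CleanDataset.

    ``occupations=None`` / ``roles=None`` disable the respective filter
    (useful for validating the generator against its pre-filter expectation).

    Raises
    ------
    EmptyDatasetError
        If no report survives cleaning.
    """
    dictionary = dictionary or DrugDictionary.default()
    demo = bundle.demo.copy()
    demo["primaryid"] = _norm_series(demo["primaryid"])
    demo["caseid"] = _norm_series(demo["caseid"])
    demo["fda_dt_parsed"] = parse_fda_dt(demo["fda_dt"].astype(str))
    n0 = len(demo)
    demo = demo[(demo["primaryid"] != "") & (demo["caseid"] != "")
                & demo["fda_dt_parsed"].notna()]
    logger.info("key-field filter: %d -> %d DEMO rows", n0, len(demo))

    # dedup: latest fda_dt per caseid, ties to the largest primaryid
    # (same selection as deduplicate(), reusing the already-parsed dates)
    demo = demo.assign(_pid=pd.to_numeric(demo["primaryid"], errors="coerce"))
    demo = demo[demo["_pid"].notna()]
    demo = demo.sort_values(["caseid", "fda_dt_parsed", "_pid"],
                            kind="mergesort").groupby("caseid", sort=False) \
               .tail(1).drop(columns="_pid")
    logger.info("deduplication: %d unique cases", len(demo))

    if occupations is not None:
        occ = _norm_series(demo["occp_cod"], upper=True)
        demo = demo[occ.isin(occupations)]
        logger.info("occupation filter (%s): %d reports",
                    ",".join(sorted(occupations)), len(demo))

    ids = pd.Index(demo["primaryid"])
    drug = bundle.drug.copy()
    drug["primaryid"] = _norm_series(drug["primaryid"])
    drug = drug[drug["primaryid"].isin(ids)]
    drug["role_cod"] = _norm_series(drug["role_cod"], upper=True)

    # resolve unique name pairs once, then map back to mentions; a mention
    # outside the dictionary keeps its normalized ingredient string so the
    # co-medication sensitivity filter can still match it
    def _resolve(dn: str, ai: str) -> set[str]:
        hits = match_drug(dn, ai, dictionary)
        if hits:
            return hits
        fallback = _strip_salt(ai if str(ai).strip() else dn).lower()
        return {fallback} if fallback else set()

    pairs = drug[["drugname", "prod_ai"]].fillna("").drop_duplicates()
    resolved = {(dn, ai): _resolve(dn, ai)
                for dn, ai in pairs.itertuples(index=False)}
    keys = list(zip(drug["drugname"].fillna(""), drug["prod_ai"].fillna("")))
    drug = drug.assign(_match=[resolved[key] for key in keys])
    mentions = drug.loc[drug["_match"].map(len) > 0,
                        ["primaryid", "role_cod", "_match"]].explode("_match")
    mentions = mentions.rename(columns={"_match": "ingredient",
                                        "role_cod": "role"})
    mentions["rank"] = mentions["role"].map(ROLE_RANK).fillna(len(ROLE_RANK))
    best = (mentions.sort_values("rank", kind="mergesort")
            .drop_duplicates(["primaryid", "ingredient"], keep="first")
            .drop(columns="rank").reset_index(drop=True))

    if roles is not None:
        qualifying_rows = drug[drug["role_cod"].isin(roles)]
        q_best = best[best["role"].isin(roles)].reset_index(drop=True)
    else:
        qualifying_rows = drug
        q_best = best
    # a report with no remaining drug mention (matched or not) is dropped
    with_drug = pd.Index(qualifying_rows["primaryid"].unique())
    demo = demo[demo["primaryid"].isin(with_drug)]
    ids = pd.Index(demo["primaryid"])

    reac = bundle.reac.copy()
    reac["primaryid"] = _norm_series(reac["primaryid"])
    reac["pt"] = _norm_series(reac["pt"])
    reac = reac[reac["primaryid"].isin(ids) & (reac["pt"] != "")]
    pts = reac.drop_duplicates(["primaryid", "pt"])[["primaryid", "pt"]] \
              .reset_index(drop=True)
    has_pt = pd.Index(pts["primaryid"].unique())
    demo = demo[demo["primaryid"].isin(has_pt)]
    ids = pd.Index(demo["primaryid"])
    logger.info("after drug/PT requirements: %d reports", len(demo))
    if demo.empty:
        raise EmptyDatasetError("no report survived cleaning")

    age_years = ages_in_years(demo.get("age", pd.Series("", index=demo.index)),
                              demo.get("age_cod", pd.Series("", index=demo.index)))
    sex = _norm_series(demo.get("sex", pd.Series("", index=demo.index)), upper=True)
    sex = sex.where(sex.isin(["M", "F"]), "unknown")
    reports = pd.DataFrame({
        "primaryid": demo["primaryid"].to_numpy(),
        "caseid": demo["caseid"].to_numpy(),
        "fda_dt": demo["fda_dt_parsed"].to_numpy(),
        "sex": sex.to_numpy(),
        "age_years": age_years.to_numpy(),
        "age_group": assign_age_group(age_years).to_numpy(),
        "occupation": _norm_series(demo["occp_cod"], upper=True).to_numpy(),
        "country": demo.get("reporter_country",
                            pd.Series("", index=demo.index)).to_numpy(),
    })

    def _clean_child(df: pd.DataFrame, col: str) -> pd.DataFrame:
        if df is None or df.empty:
            return pd.DataFrame(columns=["primaryid", col])
        out = df.copy()
        out["primaryid"] = _norm_series(out["primaryid"])
        out = out[out["primaryid"].isin(ids)]
        out[col] = _norm_series(out[col])
        out = out[out[col] != ""]
        return out.drop_duplicates(["primaryid", col])[["primaryid", col]] \
                  .reset_index(drop=True)

    return CleanDataset(
        reports=reports.reset_index(drop=True),
        drug_roles=q_best[q_best["primaryid"].isin(ids)].reset_index(drop=True),
        all_mentions=best[best["primaryid"].isin(ids)].reset_index(drop=True),
        pts=pts[pts["primaryid"].isin(ids)].reset_index(drop=True),
        indications=_clean_child(bundle.indi, "indi_pt"),
        outcomes=_clean_child(bundle.outc, "outc_cod"),
        dictionary=dictionary,
    )
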