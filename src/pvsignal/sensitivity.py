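"""Robustness re-analyses: composable report filters + signal persistence.

Three re-analyses probe the stability of detected signals:

* :func:`exclude_comedication` — remove reports co-mentioning (any role) a
  listed ingredient, e.g. antidepressants/antipsychotics when probing
  suicide-related signals for confounding by co-medication;
* :func:`exclude_pregnancy_indications` — retain reports only where the
  target drug is the Primary Suspect and drop reports whose indications are
  pregnancy-related, probing indication bias behind obstetric signals;
* :func:`stratify_physician` — physician-submitted reports only.

Each filter maps a CleanDataset to a smaller CleanDataset (monotone and
idempotent; filters commute).  Signal detection is then re-run on the
filtered dataset — with its own, recomputed margins — and
:func:`compare_runs` reports which consensus signals persisted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import CleanDataset

KEY = ["drug", "pt", "background"]


def default_lists() -> dict[str, list[str]]:
    """The shipped antidepressant / antipsychotic / pregnancy-PT lists."""
    ref = resources.files("pvsignal.data") / "sensitivity_lists.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class ExclusionRule:
    """One named report-level filter in a scenario chain."""

    kind: str                       # co_medication | indication | reporter
    match_list: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.kind not in {"co_medication", "indication", "reporter"}:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind in {"co_medication", "indication"} and not self.match_list:
            raise ValueError(f"{self.kind} rule requires a nonempty match list")

    def apply(self, dataset: CleanDataset) -> CleanDataset:
        if self.kind == "co_medication":
            return exclude_comedication(dataset, self.match_list)
        if self.kind == "indication":
            return exclude_pregnancy_indications(dataset, self.match_list)
        return stratify_physician(dataset)


def exclude_comedication(dataset: CleanDataset,
                         drug_class_list) -> CleanDataset:
    """Drop reports with any drug mention (any role) on *drug_class_list*."""
    listed = {str(d).lower() for d in drug_class_list}
    if not listed:
        raise ValueError("co-medication list must be nonempty")
    hit = dataset.all_mentions.loc[
        dataset.all_mentions["ingredient"].str.lower().isin(listed),
        "primaryid"].unique()
    keep = dataset.report_ids().difference(pd.Index(hit))
    return dataset.subset(keep)


def exclude_pregnancy_indications(dataset: CleanDataset,
                                  pregnancy_pt_list,
                                  target_drugs: tuple[str, ...] | None = None,
                                  ) -> CleanDataset:
    """PS-only retention for target drugs + drop pregnancy-indicated reports.

    A report carrying a target drug is retained only if that drug's best
    role is Primary Suspect; reports without any target mention are
    untouched (they form the comparator background).  Independently, any
    report whose indication set intersects *pregnancy_pt_list* is dropped.
    """
    listed = {str(p).lower() for p in pregnancy_pt_list}
    if not listed:
        raise ValueError("pregnancy indication list must be nonempty")
    targets = set(target_drugs or dataset.dictionary.targets)
    troles = dataset.drug_roles[dataset.drug_roles["ingredient"].isin(targets)]
    non_ps = troles.loc[troles["role"] != "PS", "primaryid"].unique()
    pregnant = dataset.indications.loc[
        dataset.indications["indi_pt"].str.lower().isin(listed),
        "primaryid"].unique()
    drop = pd.Index(non_ps).union(pd.Index(pregnant))
    return dataset.subset(dataset.report_ids().difference(drop))


def stratify_physician(dataset: CleanDataset) -> CleanDataset:
    """Keep physician-submitted reports only (occp_cod MD)."""
    keep = dataset.reports.loc[dataset.reports["occupation"] == "MD",
                               "primaryid"]
    return dataset.subset(pd.Index(keep))


def compare_runs(primary_results: pd.DataFrame,
                 sensitivity_results: pd.DataFrame) -> pd.DataFrame:
    """Signal-persistence report between a primary and a sensitivity screen.

    Both inputs are long-format screen tables keyed by (drug, pt,
    background); the key sets must match.  Output adds, per key, the
    before/after consensus flags, per-statistic deltas, a persistence
    boolean and — for lost signals — the first failed criterion.
    """
    left = primary_results.set_index(KEY)
    right = sensitivity_results.set_index(KEY)
    if set(left.index) != set(right.index):
        raise ValueError("primary and sensitivity runs cover different "
                         "(drug, pt, background) keys")
    right = right.reindex(left.index)
    out = pd.DataFrame(index=left.index)
    out["consensus_before"] = left["consensus"]
    out["consensus_after"] = right["consensus"]
    out["persisted"] = out["consensus_before"] & out["consensus_after"]
    for col in ("a", "ror", "prr", "chi2", "ic025"):
        out[f"delta_{col}"] = right[col] - left[col]
    reasons = np.full(len(out), "", dtype=object)
    lost = out["consensus_before"] & ~out["consensus_after"]
    for i, key in enumerate(out.index):
        if not lost.iloc[i]:
            continue
        row = right.loc[key]
        if row["a"] < 3:
            reasons[i] = "min_count"
        elif not row["ror_signal"]:
            reasons[i] = "ror"
        elif not row["prr_signal"]:
            reasons[i] = "prr"
        elif not row["mhra_signal"]:
            reasons[i] = "mhra"
        else:
            reasons[i] = "ic"
    out["reason_lost"] = reasons
    return out.reset_index()
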