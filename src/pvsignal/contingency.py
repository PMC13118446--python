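"""2x2 contingency tables for (drug, PT) pairs under two backgrounds.

The analysis unit is one *distinct (report, PT) pair*; duplicate PT mentions
within one report collapse to a single pair, and drug exposure is defined at
report level.  Under the ``full`` background the universe is every pair in
the cleaned dataset; under the ``class`` background it is restricted to
pairs from reports carrying at least one drug of the comparison class, with
"without the target drug" meaning class reports not carrying the target —
the two exposure groups always partition the universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import CleanDataset

logger = logging.getLogger(__name__)

BACKGROUNDS = ("full", "class")


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one (drug, PT, background) triple.

    a: pairs with target drug and the PT; b: target drug, other PTs;
    c: the PT without the target drug; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def _pair_universe(dataset: CleanDataset, background: str) -> pd.DataFrame:
    if background == "full":
        return dataset.pts
    if background == "class":
        ids = dataset.ids_in_class()
        return dataset.pts[dataset.pts["primaryid"].isin(ids)]
    raise ValueError(f"unknown background {background!r}")


def build_table(dataset: CleanDataset, drug: str, pt: str,
                background: str = "full") -> ContingencyTable:
    """Count the 2x2 cells for one (drug, PT) pair.

    A PT absent from the dataset yields a valid table with a = c = 0 (logged)
    rather than an error.
    """
    if dataset.n_reports == 0:
        raise ValueError("empty dataset")
    universe = _pair_universe(dataset, background)
    exposed_ids = dataset.ids_with_drug(drug)
    exposed = universe["primaryid"].isin(exposed_ids)
    is_pt = universe["pt"] == pt
    a = int((exposed & is_pt).sum())
    b = int((exposed & ~is_pt).sum())
    c = int((~exposed & is_pt).sum())
    d = int((~exposed & ~is_pt).sum())
    if a + c == 0:
        logger.warning("PT %r never reported under %s background", pt, background)
    return ContingencyTable(a, b, c, d)


def tables_for_drug(dataset: CleanDataset, drug: str, pts: list[str],
                    background: str = "full") -> dict[str, ContingencyTable]:
    """All 2x2 tables of one drug at once (one pass over the pair universe)."""
    universe = _pair_universe(dataset, background)
    exposed_ids = dataset.ids_with_drug(drug)
    exposed = universe["primaryid"].isin(exposed_ids)
    n_pairs = len(universe)
    margin_drug = int(exposed.sum())
    counts_exposed = universe.loc[exposed, "pt"].value_counts()
    counts_all = universe["pt"].value_counts()
    out = {}
    for pt in pts:
        a = int(counts_exposed.get(pt, 0))
        ac = int(counts_all.get(pt, 0))
        out[pt] = ContingencyTable(a, margin_drug - a, ac - a,
                                   n_pairs - margin_drug - ac + a)
    return out


#: PTs that describe how a drug was used rather than a reaction to it; they
#: are removed from the top-k screen before ranking.
DEFAULT_EXCLUSIONS = frozenset({
    "drug interaction",
    "off label use",
    "product use in unapproved indication",
    "intentional product misuse",
})


def top_k_pts(dataset: CleanDataset, drug: str, k: int = 20,
              exclusion_list: frozenset[str] | set[str] = DEFAULT_EXCLUSIONS,
              background: str = "full") -> list[str]:
    """The drug's k most frequent PTs by distinct (report, PT) pair count.

    PTs on the exclusion list are removed (case-insensitively) before the
    top k is taken; ties in count break alphabetically.  If fewer than k PTs
    remain, all are returned and the shortfall is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    universe = _pair_universe(dataset, background)
    exposed_ids = dataset.ids_with_drug(drug)
    counts = universe.loc[universe["primaryid"].isin(exposed_ids), "pt"] \
                     .value_counts()
    excluded = {e.lower() for e in exclusion_list}
    counts = counts[~counts.index.str.lower().isin(excluded)]
    ranked = counts.sort_index(kind="mergesort") \
                   .sort_values(ascending=False, kind="mergesort")
    if len(ranked) < k:
        logger.info("only %d PTs available for %s (requested %d)",
                    len(ranked), drug, k)
    return list(ranked.index[:k])


def export_long(tables: dict[tuple[str, str, str], ContingencyTable]
                ) -> pd.DataFrame:
    """Long-format (drug, pt, background, a, b, c, d, N) table for CSV export."""
    rows = [
        {"drug": drug, "pt": pt, "background": bg,
         "a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.n}
        for (drug, pt, bg), t in sorted(tables.items())]
    return pd.DataFrame(rows)
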