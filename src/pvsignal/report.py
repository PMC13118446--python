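"""Presentation artifacts: screen driver, demographics summary, ROR heatmap.

:func:`signal_screen` is the study driver: for each target drug it ranks the
top-k PTs, builds every 2x2 table under the requested backgrounds and
evaluates the four disproportionality methods, returning one long-format
row per (drug, PT, background).  :func:`summarize_demographics` tabulates
report-level clinical features per drug, and :func:`build_heatmap` renders
the signal-strength matrix (cells shown only where the ROR 95% lower limit
exceeds 1, shading on log10 ROR).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CleanDataset
from .contingency import (DEFAULT_EXCLUSIONS, BACKGROUNDS, tables_for_drug,
                          top_k_pts)
from .dispro import SignalThresholds, evaluate_signal

logger = logging.getLogger(__name__)


def signal_screen(dataset: CleanDataset,
                  drugs: tuple[str, ...] | None = None,
                  backgrounds: tuple[str, ...] = BACKGROUNDS,
                  k: int = 20,
                  exclusion_list=DEFAULT_EXCLUSIONS,
                  thresholds: SignalThresholds | None = None,
                  pts_by_drug: dict[str, list[str]] | None = None,
                  ) -> pd.DataFrame:
    """Run the full disproportionality screen.

    PTs are selected per drug under the *full* background (the screening
    step) unless ``pts_by_drug`` pins them explicitly — a sensitivity re-run
    passes the primary run's PT sets so both runs cover the same keys.
    """
    drugs = drugs or dataset.dictionary.targets
    rows = []
    for drug in drugs:
        if pts_by_drug is not None:
            pts = pts_by_drug[drug]
        else:
            pts = top_k_pts(dataset, drug, k=k, exclusion_list=exclusion_list)
        for bg in backgrounds:
            tables = tables_for_drug(dataset, drug, pts, background=bg)
            for pt in pts:
                t = tables[pt]
                res = evaluate_signal(t, thresholds)
                row = {"drug": drug, "pt": pt, "background": bg,
                       "b": t.b, "c": t.c, "d": t.d, "N": t.n}
                row.update(asdict(res))
                row["consensus"] = res.consensus
                rows.append(row)
    cols = ["drug", "pt", "background", "a", "b", "c", "d", "N",
            "ror", "ror_low", "ror_high", "prr", "prr_low", "prr_high",
            "chi2", "ic", "ic025", "e_count",
            "ror_signal", "prr_signal", "mhra_signal", "ic_signal",
            "consensus"]
    return pd.DataFrame(rows, columns=cols)


def summarize_demographics(dataset: CleanDataset,
                           drugs: tuple[str, ...] | None = None,
                           top_countries: int = 5) -> pd.DataFrame:
    """Report-level clinical features per drug: sex, age group, top
    countries, reporter occupation and outcome codes, with a total column.

    Outcome rows count (report, outcome) entries and may exceed the report
    count, since one report can carry several outcomes.
    """
    drugs = drugs or dataset.dictionary.targets
    reports = dataset.reports.set_index("primaryid")
    groups: dict[str, pd.Index] = {
        d: dataset.ids_with_drug(d) for d in drugs}

    all_ids = pd.Index(np.concatenate([g.to_numpy() for g in groups.values()])
                       ).unique() if groups else pd.Index([])
    country_rank = reports.loc[reports.index.isin(all_ids), "country"] \
        .replace("", "unknown").value_counts().index[:top_countries]

    rows = []

    def _tab(section: str, level: str, values_by_drug: dict[str, int]):
        row = {"section": section, "level": level}
        row.update(values_by_drug)
        row["total"] = sum(values_by_drug.values())
        rows.append(row)

    def _counts(series_by_drug, levels, section):
        for level in levels:
            _tab(section, level,
                 {d: int((series_by_drug[d] == level).sum()) for d in drugs})

    sex_by = {d: reports.loc[reports.index.isin(g), "sex"]
              for d, g in groups.items()}
    _counts(sex_by, ["M", "F", "unknown"], "sex")
    age_by = {d: reports.loc[reports.index.isin(g), "age_group"]
              for d, g in groups.items()}
    _counts(age_by, ["<18", "18-44", "45-64", "65-75", ">75", "unknown"], "age_group")
    country_by = {d: reports.loc[reports.index.isin(g), "country"]
                  .replace("", "unknown") for d, g in groups.items()}
    _counts(country_by, list(country_rank), "country")
    occ_by = {d: reports.loc[reports.index.isin(g), "occupation"]
              for d, g in groups.items()}
    _counts(occ_by, ["MD", "HP", "PH"], "occupation")

    outc = dataset.outcomes
    for code in ["OT", "HO", "DE", "LT", "DS", "CA", "RI"]:
        _tab("outcome", code,
             {d: int(((outc["outc_cod"] == code)
                      & outc["primaryid"].isin(g)).sum())
              for d, g in groups.items()})
    _tab("reports", "n", {d: int(len(g)) for d, g in groups.items()})
    return pd.DataFrame(rows)


def build_heatmap(results: pd.DataFrame, background: str = "full",
                  out_tsv: str | Path | None = None,
                  out_figure: str | Path | None = None) -> pd.DataFrame:
    """ROR heatmap matrix: rows = PTs, columns = drugs.

    A cell holds the ROR point only where the ROR 95% lower limit exceeds 1;
    otherwise it is empty (NaN).  Labels are sorted for determinism.  The
    TSV is the testable artifact; the rendered figure (shading on log10 ROR
    clipped to [0, 3.5]) is presentational.
    """
    sel = results[results["background"] == background].copy()
    sel["cell"] = np.where(sel["ror_low"] > 1.0, sel["ror"], np.nan)
    matrix = sel.pivot_table(index="pt", columns="drug", values="cell",
                             aggfunc="first", dropna=False)
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    if out_tsv is not None:
        matrix.to_csv(out_tsv, sep="\t", float_format="%.4f")
    if out_figure is not None:
        _render_heatmap(matrix, Path(out_figure))
    return matrix


def _render_heatmap(matrix: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shade = np.log10(matrix.to_numpy(dtype=float))
    shade = np.clip(shade, 0.0, 3.5)
    fig, ax = plt.subplots(
        figsize=(2 + 0.8 * matrix.shape[1], 1 + 0.3 * matrix.shape[0]))
    im = ax.imshow(np.ma.masked_invalid(shade), aspect="auto",
                   cmap="Reds", vmin=0.0, vmax=3.5)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log10 ROR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
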