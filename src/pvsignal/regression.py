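"""Case-noncase logistic regression for adjusted reporting odds ratios.

Within a spontaneous-report database, "cases" are reports that contain the
outcome PT and "noncases" are all other reports.  A multivariate logistic
model of case status on drug, sex, age group and reporter occupation yields
adjusted odds ratios (aOR) that control for the listed confounders — the
validation step applied to suicide-related signals in the screening stage.

Reference levels follow the screening design: amlodipine, male, 18-44 years,
physician.  Reports carrying two or more target drugs are excluded (their
exposure is ambiguous and within-case correlation would otherwise leak in),
as are reports with unknown sex or age; both counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CleanDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionSpec:
    """Outcome PT, predictors and their reference levels."""

    outcome_pt: str
    drug_levels: tuple[str, ...] = ("amlodipine", "felodipine",
                                    "nicardipine", "nifedipine")
    reference_drug: str = "amlodipine"
    reference_sex: str = "M"
    age_levels: tuple[str, ...] = ("18-44", "<18", "45-64", "65-75", ">75")
    reference_age: str = "18-44"
    occupation_levels: tuple[str, ...] = ("MD", "PH", "HP")
    reference_occupation: str = "MD"


@dataclass
class RegressionResult:
    """Per-level estimates plus fit diagnostics."""

    table: pd.DataFrame          # term, coef, se, aor, ci_low, ci_high, p
    log_likelihood: float
    n_obs: int
    n_events: int
    converged: bool
    iterations: int
    excluded_multi_drug: int = 0
    excluded_unknown: int = 0
    dropped_levels: list[str] = field(default_factory=list)

    def aor(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "aor"])


class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


class RankDeficiencyError(ValueError):
    """The design matrix is not full rank; lists the collinear columns."""


def build_design(dataset: CleanDataset, spec: RegressionSpec
                 ) -> tuple[pd.DataFrame, pd.Series, dict[str, int]]:
    """Dummy-coded design matrix and outcome vector, one row per report.

    Rows: cleaned reports carrying exactly one target drug with a qualifying
    role and known sex and age group.  Outcome: 1 iff the report's PT set
    contains ``spec.outcome_pt``.  Columns: an intercept plus one dummy per
    non-reference level; a level with zero rows is dropped with a warning.
    """
    targets = set(spec.drug_levels)
    tmentions = dataset.drug_roles[
        dataset.drug_roles["ingredient"].isin(targets)]
    per_report = tmentions.groupby("primaryid")["ingredient"].nunique()
    single = set(per_report[per_report == 1].index)
    n_multi = int((per_report > 1).sum())
    if n_multi:
        logger.info("excluded %d reports carrying >=2 target drugs", n_multi)

    rows = dataset.reports[dataset.reports["primaryid"].isin(single)].copy()
    drug_of = tmentions.drop_duplicates("primaryid") \
                       .set_index("primaryid")["ingredient"]
    rows["drug"] = rows["primaryid"].map(drug_of)
    known = (rows["sex"].isin(["M", "F"])
             & (rows["age_group"] != "unknown")
             & rows["occupation"].isin(spec.occupation_levels))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("excluded %d reports with unknown sex/age/occupation",
                    n_unknown)
    rows = rows[known]

    case_ids = set(dataset.pts.loc[dataset.pts["pt"] == spec.outcome_pt,
                                   "primaryid"])
    y = rows["primaryid"].isin(case_ids).astype(int)
    y.name = "outcome"

    pieces, dropped = [], []
    for name, values, levels, ref in (
            ("drug", rows["drug"], spec.drug_levels, spec.reference_drug),
            ("sex", rows["sex"], ("M", "F"), spec.reference_sex),
            ("age", rows["age_group"], spec.age_levels, spec.reference_age),
            ("occ", rows["occupation"], spec.occupation_levels,
             spec.reference_occupation)):
        for level in levels:
            if level == ref:
                continue
            col = (values == level).astype(float)
            col.name = f"{name}[{level}]"
            if col.sum() == 0:
                logger.warning("level %s has zero rows; dropped", col.name)
                dropped.append(col.name)
                continue
            pieces.append(col)
    x = pd.concat([pd.Series(1.0, index=rows.index, name="const"), *pieces],
                  axis=1)
    meta = {"excluded_multi_drug": n_multi, "excluded_unknown": n_unknown,
            "dropped_levels": dropped}
    return x, y, meta


def fit_logistic(design: pd.DataFrame, outcome: pd.Series,
                 meta: dict | None = None, z: float = 1.96,
                 maxiter: int = 100) -> RegressionResult:
    """Maximum-likelihood logistic fit with Wald intervals exp(coef +/- z*SE).

    Raises
    ------
    ValueError
        Fewer than one event or one non-event.
    RankDeficiencyError
        Collinear design columns (named in the message).
    SeparationError
        Complete separation: the optimizer diverges or a fitted probability
        pins to 0/1 on an entire level.
    """
    y = np.asarray(outcome, dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one event and one non-event")
    x = design.astype(float)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the columns involved: those whose removal restores full rank
        collinear = [c for c in x.columns if c != "const" and
                     np.linalg.matrix_rank(x.drop(columns=c).to_numpy()) == rank]
        raise RankDeficiencyError(f"design not full rank; collinear columns: "
                                  f"{collinear}")
    model = sm.Logit(y, x)
    try:
        fit = model.fit(disp=0, maxiter=maxiter, method="newton", tol=1e-10)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False) or \
            np.abs(fit.params).max() > 30:
        worst = x.columns[int(np.abs(fit.params).argmax())]
        raise SeparationError(f"non-convergence, likely separation on {worst!r}")

    coefs = pd.Series(fit.params, index=x.columns)
    ses = pd.Series(fit.bse, index=x.columns)
    table = pd.DataFrame({
        "term": x.columns,
        "coef": coefs.to_numpy(),
        "se": ses.to_numpy(),
        "aor": np.exp(coefs.to_numpy()),
        "ci_low": np.exp(coefs.to_numpy() - z * ses.to_numpy()),
        "ci_high": np.exp(coefs.to_numpy() + z * ses.to_numpy()),
        "p": pd.Series(fit.pvalues, index=x.columns).to_numpy(),
    })
    meta = meta or {}
    return RegressionResult(
        table=table.reset_index(drop=True),
        log_likelihood=float(fit.llf),
        n_obs=int(len(y)),
        n_events=int(y.sum()),
        converged=bool(fit.mle_retvals.get("converged", False)),
        iterations=int(fit.mle_retvals.get("iterations", 0)),
        excluded_multi_drug=meta.get("excluded_multi_drug", 0),
        excluded_unknown=meta.get("excluded_unknown", 0),
        dropped_levels=meta.get("dropped_levels", []),
    )


def run_regression(dataset: CleanDataset, outcome_pt: str,
                   spec: RegressionSpec | None = None) -> RegressionResult:
    """Convenience wrapper: build the design for *outcome_pt* and fit."""
    spec = spec or RegressionSpec(outcome_pt=outcome_pt)
    if spec.outcome_pt != outcome_pt:
        spec = RegressionSpec(outcome_pt=outcome_pt,
                              drug_levels=spec.drug_levels,
                              reference_drug=spec.reference_drug)
    x, y, meta = build_design(dataset, spec)
    return fit_logistic(x, y, meta)
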