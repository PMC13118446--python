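# Methods

This note documents the models, assumptions and numerical choices behind
`pvsignal`, in the order the pipeline runs.

## Cleaning model

A FAERS *case* (caseid) can have several *versions* (primaryid) from
follow-up submissions. Deduplication keeps, per caseid, the version with
the most recent FDA receipt date (`fda_dt`), breaking date ties by the
largest primaryid. Records missing any of caseid, primaryid or a parseable
`fda_dt` are dropped — these three are the key fields the dedup rule needs;
missing sex or age never drops a record (they become an explicit `unknown`
category, which the demographics tables report). Reports are then
restricted to health-care reporters (`occp_cod` MD/PH/HP) and drug mentions
to suspect roles (PS/SS/I); a report left with no drug mention at all is
dropped, but concomitant-only mentions of a *particular* drug merely remove
that drug from the report's exposure flags. Non-qualifying mentions are
retained in a side table because the co-medication sensitivity filter must
see them.

Drug-name resolution is exact-match after normalization: uppercase,
whitespace collapse, splitting combination products on `\` or `+`, and
stripping trailing salt/ester words (BESYLATE, MALEATE, HYDROCHLORIDE, ...;
the list is configurable). Fuzzy matching is deliberately out of scope;
misspelled names simply fail to resolve. Mentions that match no dictionary
entry keep their normalized ingredient string so that list-based filters
(e.g. antidepressant exclusion) still work. Ages are converted to years
(DEC ×10, YR ×1, MON ÷12, WK ÷52.1775, DY ÷365.25, HR ÷8766); an age with
a missing unit code is treated as years — the common convention — and
logged, since source data do not say how such rows were coded. Age groups
use half-open bins [0,18), [18,44], (44,64], (64,75], (75,∞).

## Counting model

The analysis unit is a **distinct (report, PT) pair** with drug exposure
defined at report level; duplicate PT mentions within one report collapse.
Pair-level counting is what makes a drug's per-PT counts and the universe
size N mutually consistent in published screens of this design (report-level
counting cannot produce several hundred counts of one PT from a few hundred
reports). Consequences tested as invariants: for a fixed drug and
background, `a+b` is constant across PTs and `Σa` over PTs equals the
drug's total pair count.

Two backgrounds are supported. Under the *class* background the universe is
restricted to reports carrying at least one DHP-CCB class member, and
reports carrying the target **and** another class drug stay on the target
side — the two exposure groups always partition the universe. The top-k PT
screen ranks by descending `a` with alphabetical tie-break, removing
usage-pattern PTs (drug interaction, off-label use, unapproved indication,
intentional misuse — configurable) *before* truncating to k.

## Signal statistics

Formulas and thresholds are in the README. Numerical choices:

- **Zero cells.** If any cell is 0, all four cells get +0.5
  (Haldane–Anscombe) before ROR/PRR/chi-square; signal flags still require
  the *raw* `a ≥ 3`. The IC needs no correction (its +0.5 shrinkage is part
  of the definition).
- **Chi-square** uses the Yates continuity correction with truncation at
  zero when `|ad−bc| ≤ N/2`. The inversion oracle confirms this variant:
  recomputing a published chi-square of 5544.18 from its reconstructed
  table agrees within 0.02%, whereas the uncorrected statistic misses by
  ~0.5%.
- **IC025** uses the closed-form credibility approximation
  `IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)` rather than a Monte-Carlo
  posterior; it reproduces published IC025 values within ±0.01.
- `z = 1.96` exactly (not 1.959964), matching printed intervals within
  rounding; configurable via `SignalThresholds`.
- Published tables in this design print the PRR *lower limit* in the PRR
  column and the PRR *point* inside the MHRA tuple; output columns name
  both explicitly (`prr`, `prr_low`) to avoid the ambiguity.

**Inversion oracle.** `invert_stats` solves the forward interval formulas
in closed form (README). It is infeasible exactly when the printed inputs
are mutually inconsistent (`R ≤ P`, `R ≤ 1`, `P ≤ L`, or a nonpositive
intermediate), which it reports rather than silently repairing. Round-trip
identity (forward → invert → forward) holds to 1e-6 relative error on exact
inputs; two-decimal rounding of printed inputs dominates the residual error
in practice, hence the 0.5%-relative / ±0.03-absolute validation bands.

## Synthetic-report generator

The generator emulates, per case: independent Bernoulli drug exposure (a
case that would mention no drug gets one drug proportionally to exposure
probabilities — every report names at least one drug, with one Primary
Suspect); a PT count `m = min(1 + Poisson(mean−1), catalog size)` so every
report has at least one event; `m` i.i.d. PT draws from the baseline
multinomial, with every exposed drug's planted multiplier applied to its
PT and the vector renormalized; demographics, outcomes (independent per
code, so one report may carry several) and an optional indication; and with
probability `dup_prob` a follow-up version with a larger primaryid, a
strictly later date, copied child rows, and one demographic field redrawn —
exercising the dedup semantics. Identical configs reproduce byte-identical
bundles.

`expected_cells` computes the *exact* expected 2×2 cells of the cleaned
dataset under this model by enumerating exposure classes over the planted
drugs (the only drugs that change the PT law) and marginalizing everything
else analytically, including the no-drug fallback and class-background
membership through non-enumerated class drugs. The per-PT "distinct pair"
probability is `E[1−(1−q)^m]`, evaluated from the truncated-Poisson mass
function. Two deliberate approximations of scope, not of math: expectations
are computed for exposure defined as *any-role* mention (role thinning is
uniform and PT-independent, so it leaves the rate ratios unbiased and only
scales counts — validated by passing `roles=None` when testing the oracle);
and the planted multiplier acts multiplicatively before renormalization, so
the realized rate ratio sits slightly *below* the planted value for
non-negligible baseline probabilities (≈3% attenuation at baseline 0.002
with 2–3 PTs per report; vanishing in the rare-PT limit).

Default study conditions (`default_config`): four target drugs at
exposures 0.05/0.008/0.006/0.015, three further class members, nine common
co-medications; a 29-term PT catalog whose baseline probabilities sum to 1;
seven planted multipliers (8 on a 0.002-baseline psychiatric PT for the
most-reported target, 20 on an otologic PT for a low-volume target, 15 and
100 on metabolic/neurovascular PTs, 30 and 8 on obstetric PTs); 2.5 PTs
per report on average; 25% follow-up probability; occupation mix 45% MD /
20% HP / 10% PH / 25% non-qualifying; dates uniform over 2014-07-01 to
2024-12-31 (follow-ups may spill past the window end). These mirror the
magnitudes a real spontaneous-report screen of this drug class encounters.
What the generator does **not** emulate: correlated drug co-mention (except
when a test constructs it explicitly), reporting-rate drift over time,
country-specific reporting cultures, free-text name misspellings, and
MedDRA hierarchy — PTs are opaque labels throughout. Passing tests
therefore demonstrate correctness of the counting and inference machinery
under a known model, not robustness to real-world coding noise.

## Regression

Case–noncase multivariate logistic regression: outcome = presence of the
outcome PT in the report's PT set; predictors drug (reference amlodipine),
sex (reference male), age group (reference 18–44), reporter occupation
(reference physician), dummy-coded. Reports carrying two or more target
drugs are excluded (ambiguous exposure; avoids within-case correlation), as
are reports with unknown sex/age/occupation; both counts are logged, not
imputed. Fitting is maximum likelihood (Newton), at most 100 iterations,
tolerance 1e-10; Wald intervals `exp(coef ± 1.96·SE)` and Wald p-values,
matching the aOR / 95% CI / p reporting convention. Rank deficiency raises
an error naming the collinear columns; separation raises an error naming
the worst level (detected via non-convergence or a coefficient magnitude
above 30). With a single binary predictor the fit equals the 2×2 odds ratio
to 1e-8 — tested against the independently computed ROR point.

## Sensitivity analyses

Three composable report-level filters: exclusion of reports co-mentioning
(any role) a listed ingredient; pregnancy-indication exclusion, which keeps
reports whose *target-drug* role is PS (reports without a target mention
stay — they form the background; reference-level ambiguity of whose role
"PS" refers to is resolved to the target drug and documented here) and
drops reports whose indication set intersects the pregnancy list; and the
physician-only stratum. All are monotone, idempotent and pairwise commuting
(tested on random fixtures). Re-runs recompute every margin on the filtered
dataset — never reusing the primary run's N — and the persistence report
names the first failed criterion for each lost signal (`min_count` when the
count drops below 3). Default antidepressant (ATC N06A), antipsychotic
(N05A) and pregnancy-indication lists ship as an editable YAML.

## Problem sizes used in the test suite

Simulation-based checks use: planted-multiplier recovery at 200,000 cases ×
100 seeds (a lean 3-drug / 6-PT catalog holding the stated conditions —
5% target exposure, 0.002 baseline, multiplier 8); the null-model
false-positive control at 30,000 cases × 20 seeds over the full default
catalog; regression CI coverage at 50,000 rows × 100 seeds; exhaustive
formula sweeps over all 2×2 tables with cells ≤ 25. These sizes keep each
suite in the minutes range on one CPU while leaving planted-effect standard
errors far smaller than the tested tolerances.

## Known limitations

- Exact-match drug resolution only; no RxNorm/fuzzy matching.
- The `'$'` dialect is unquoted; an embedded `'$'` in a field cannot be
  represented (a write raises rather than corrupting the table).
- PT strings are opaque: no SOC-level aggregation, no MedDRA hierarchy.
- No multiplicity correction across the screened pairs — the four-method
  consensus is the (conservative) false-positive control, as in the study
  design this pipeline implements.
- The BCPNN implementation is the closed-form approximation; a full
  Monte-Carlo posterior is not provided.
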