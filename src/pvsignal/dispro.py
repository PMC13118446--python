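"""Disproportionality statistics for 2x2 spontaneous-report tables.

Four classical signal-detection methods on the contingency table

    =============  ==========  ==========
    .              event PT    other PTs
    =============  ==========  ==========
    target drug    a           b
    other drugs    c           d
    =============  ==========  ==========

* **ROR** — reporting odds ratio ``ad/bc`` with Woolf (log-scale) 95% limits.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with
  log-scale 95% limits.
* **MHRA** — rule requiring count >= 3, PRR >= 2 and Yates-corrected
  chi-square >= 4.
* **BCPNN IC** — information component ``log2 O/E`` with a +0.5 shrinkage
  and the Noren closed-form approximation to the lower 95% credibility bound.

A pair is a *consensus* (effective) signal only when all four methods flag it
simultaneously; the conjunction is the pipeline's false-positive control.

The module also provides :func:`invert_stats`, a closed-form inversion that
reconstructs the real-valued cells ``(b, c, d)`` of a table from a published
``(a, ROR point, PRR point, PRR 95% lower limit)`` quadruple.  Re-running the
forward formulas on the reconstructed table recovers every other published
statistic of the row, which turns printed signal tables into numerical
regression fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

Z95 = 1.96  # two-sided 95% normal quantile as used in published intervals


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for this table (e.g. zero margin)."""


class InversionInfeasibleError(ValueError):
    """Printed inputs are mutually inconsistent; no positive table exists."""


@dataclass(frozen=True)
class SignalThresholds:
    """Per-method signal criteria (defaults are the conventional ones)."""

    min_count: int = 3      # minimum raw event count a
    ci_floor: float = 1.0   # ROR/PRR 95% lower limit must exceed this
    mhra_prr: float = 2.0
    mhra_chi2: float = 4.0
    ic025_floor: float = 0.0
    z: float = Z95


@dataclass
class DisproResult:
    """All four statistics, their intervals and flags for one (drug, PT) pair."""

    a: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    ic025: float
    e_count: float
    ror_signal: bool
    prr_signal: bool
    mhra_signal: bool
    ic_signal: bool

    @property
    def consensus(self) -> bool:
        return (self.ror_signal and self.prr_signal
                and self.mhra_signal and self.ic_signal)


def _corrected(table) -> tuple[float, float, float, float]:
    """Apply the Haldane-Anscombe rule: +0.5 to every cell if any cell is 0."""
    a, b, c, d = (float(x) for x in _cells(table))
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a == b == c == d == 0:
        raise UndefinedResultError("all-zero table")
    if a * b * c * d == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def _cells(table) -> tuple[float, float, float, float]:
    if hasattr(table, "a"):
        return table.a, table.b, table.c, table.d
    a, b, c, d = table
    return a, b, c, d


def compute_ror(table, z: float = Z95) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% confidence limits.

    ROR = ad/bc; limits = exp(ln ROR -/+ z*sqrt(1/a + 1/b + 1/c + 1/d)).
    Zero cells are handled by the Haldane-Anscombe +0.5 correction.
    """
    a, b, c, d = _corrected(table)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def compute_prr(table, z: float = Z95) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-scale 95% limits.

    PRR = [a/(a+b)] / [c/(c+d)];
    limits = exp(ln PRR -/+ z*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
    """
    a, b, c, d = _corrected(table)
    if c + d == 0 or a + b == 0:
        raise UndefinedResultError("zero margin")
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, prr * math.exp(-z * se), prr * math.exp(z * se)


def compute_chi2(table) -> float:
    """Yates continuity-corrected chi-square, truncated at zero.

    chi2 = N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)]; when the
    discrepancy |ad - bc| does not exceed N/2 the corrected statistic is 0.
    """
    a, b, c, d = _corrected(table)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise UndefinedResultError("zero margin in chi-square")
    disc = abs(a * d - b * c)
    if disc <= n / 2:
        return 0.0
    return n * (disc - n / 2) ** 2 / denom


def compute_ic(table) -> tuple[float, float, float]:
    """Information component with shrinkage and its lower 95% credibility bound.

    E = (a+b)(a+c)/N; IC = log2[(a + 0.5)/(E + 0.5)];
    IC025 = IC - 3.3 (a + 0.5)^{-1/2} - 2 (a + 0.5)^{-3/2}
    (Noren's closed-form approximation to the BCPNN posterior quantile).

    Returns ``(ic, ic025, e_count)``.
    """
    a, b, c, d = (float(x) for x in _cells(table))
    n = a + b + c + d
    if n == 0:
        raise UndefinedResultError("empty table")
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025, e


def evaluate_signal(table, thresholds: SignalThresholds | None = None
                    ) -> DisproResult:
    """Compute all four methods on *table* and apply the signal criteria.

    Flags (each also requires raw count ``a >= min_count``):

    * ROR:  95% lower limit > 1
    * PRR:  95% lower limit > 1
    * MHRA: PRR >= 2 and Yates chi-square >= 4
    * IC:   IC025 > 0

    An undefined statistic (degenerate table) yields a non-signal for the
    affected method rather than an exception.
    """
    th = thresholds or SignalThresholds()
    raw_a = int(_cells(table)[0])
    try:
        ror, ror_lo, ror_hi = compute_ror(table, th.z)
        prr, prr_lo, prr_hi = compute_prr(table, th.z)
    except UndefinedResultError:
        ror = ror_lo = ror_hi = prr = prr_lo = prr_hi = float("nan")
    try:
        chi2 = compute_chi2(table)
    except UndefinedResultError:
        chi2 = float("nan")
    try:
        ic, ic025, e = compute_ic(table)
    except UndefinedResultError:
        ic = ic025 = e = float("nan")

    enough = raw_a >= th.min_count
    return DisproResult(
        a=raw_a,
        ror=ror, ror_low=ror_lo, ror_high=ror_hi,
        prr=prr, prr_low=prr_lo, prr_high=prr_hi,
        chi2=chi2, ic=ic, ic025=ic025, e_count=e,
        ror_signal=bool(enough and ror_lo > th.ci_floor),
        prr_signal=bool(enough and prr_lo > th.ci_floor),
        mhra_signal=bool(enough and prr >= th.mhra_prr and chi2 >= th.mhra_chi2),
        ic_signal=bool(enough and ic025 > th.ic025_floor),
    )


@dataclass(frozen=True)
class InversionSolution:
    """Real-valued table cells reconstructed from printed statistics."""

    a: float
    b: float
    c: float
    d: float
    w: float  # background event rate c/(c+d)
    u: float  # drug margin a+b
    v: float  # squared standardized log-PRR half-width

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def invert_stats(a: float, ror_point: float, prr_point: float,
                 prr_low: float, z: float = Z95) -> InversionSolution:
    """Reconstruct (b, c, d) from a published (a, ROR, PRR, PRR lower limit).

    The forward formulas admit a closed-form inverse.  Writing R for the ROR
    point, P for the PRR point, L for the PRR 95% lower limit and
    w = c/(c+d) for the background event rate:

        w = (R - P) / (P (R - 1))          (from R/P = (1 - w d/(c+d))...)
        u = a + b = a / (P w)
        V = (ln(P / L) / z)^2              (squared standardized half-width)
        c = (1 - w) / (V - 1/a + 1/u)
        d = c (1 - w) / w

    Re-running the forward statistics on the solution reproduces the inputs
    exactly (up to the rounding of the printed values).

    Raises
    ------
    InversionInfeasibleError
        If R <= P, R <= 1, P <= L or an intermediate quantity is nonpositive,
        i.e. the printed numbers are not jointly realisable by any table.
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    r, p, low = float(ror_point), float(prr_point), float(prr_low)
    if not (r > p > low > 0) or r <= 1:
        raise InversionInfeasibleError(
            f"need ROR > PRR > lower limit > 0 and ROR > 1; "
            f"got R={r}, P={p}, L={low}")
    w = (r - p) / (p * (r - 1))
    if not 0 < w < 1:
        raise InversionInfeasibleError(f"background rate w={w} outside (0,1)")
    u = a / (p * w)
    if u <= a:
        raise InversionInfeasibleError("implied drug margin a+b <= a")
    v = (math.log(p / low) / z) ** 2
    denom = v - 1 / a + 1 / u
    if denom <= 0:
        raise InversionInfeasibleError("interval width inconsistent with a")
    c = (1 - w) / denom
    d = c * (1 - w) / w
    b = u - a
    if min(b, c, d) <= 0:
        raise InversionInfeasibleError("reconstructed cell nonpositive")
    return InversionSolution(a=float(a), b=b, c=c, d=d, w=w, u=u, v=v)
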