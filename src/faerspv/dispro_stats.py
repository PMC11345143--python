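"""Disproportionality estimators and the combined signal criterion.

Four estimators are computed on each 2x2 table:

* **ROR** — reporting odds ratio ``ad/bc`` with a lognormal 95% interval.
* **PRR** — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with its
  lognormal interval and the Pearson chi-square statistic (no continuity
  correction).
* **BCPNN IC** — information component ``log2(a*N/((a+b)(a+c)))``; its
  lower credibility bound IC025 is the Bate posterior expectation minus
  two posterior standard deviations under the standard BCPNN priors.
* **EBGM** — here the observed/expected reporting ratio
  ``a*N/((a+b)(a+c))`` with a lognormal lower 95% bound EBGM05. No
  gamma-mixture (MGPS) shrinkage is applied; see docs/methods.md.

A (drug, term) pair is a **signal** when all six conditions hold:
a >= 3, ROR lower bound > 1, PRR >= 2, chi-square >= 4, IC025 > 0, and
EBGM05 > 2. Any table with a zero cell leaves the affected statistics
undefined (NaN) and the pair is never flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from faerspv.contingency import ContingencyTable

__all__ = [
    "BcpnnPrior",
    "SignalCriteria",
    "SignalStats",
    "ror_stats",
    "prr_stats",
    "bcpnn_stats",
    "ebgm_stats",
    "compute_signal_stats",
    "evaluate_criteria",
    "rank_signals",
]

Z95 = 1.96
_LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class BcpnnPrior:
    """BCPNN prior constants (Bate et al. parameterization).

    ``gamma`` is not free: it is recomputed per table so that the prior
    expectation of the joint cell matches independence,
    gamma = gamma11*(N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)).
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def gamma(self, t: ContingencyTable) -> float:
        return (
            self.gamma11
            * (t.n + self.alpha)
            * (t.n + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the six-part combined signal criterion."""

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class SignalStats:
    """All four estimators with bounds for one (drug, term) pair."""

    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float


def _log_interval(point: float, se: float) -> tuple[float, float]:
    return (
        math.exp(math.log(point) - Z95 * se),
        math.exp(math.log(point) + Z95 * se),
    )


def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with lognormal 95% bounds.

    Any zero cell makes the estimate undefined (NaN, NaN, NaN); no
    continuity correction is applied since the combined criterion requires
    a >= 3 anyway.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo, hi = _log_interval(ror, se)
    return (ror, lo, hi)


def prr_stats(t: ContingencyTable) -> tuple[float, float, float, float]:
    """PRR with lognormal 95% bounds and the Pearson chi-square.

    chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), without Yates correction.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan, math.nan, math.nan)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    lo, hi = _log_interval(prr, se)
    chi2 = (
        t.n
        * (t.a * t.d - t.b * t.c) ** 2
        / ((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d))
    )
    return (prr, lo, hi, chi2)


def bcpnn_stats(
    t: ContingencyTable, prior: BcpnnPrior | None = None
) -> tuple[float, float]:
    """Information component and its lower credibility bound IC025.

    The IC point estimate is the unshrunk log2 observed/expected ratio;
    IC025 is the BCPNN posterior expectation minus two posterior standard
    deviations (Bate's closed-form moments) under ``prior``.
    """
    if t.a == 0 or (t.a + t.b) == 0 or (t.a + t.c) == 0:
        return (math.nan, math.nan)
    prior = prior or BcpnnPrior()
    n, a = t.n, t.a
    row, col = t.a + t.b, t.a + t.c
    ic = math.log2(a * n / (row * col))

    g = prior.gamma(t)
    e_ic = math.log2(
        (a + prior.gamma11)
        * (n + prior.alpha)
        * (n + prior.beta)
        / ((n + g) * (row + prior.alpha1) * (col + prior.beta1))
    )
    v_ic = (
        (n - a + g - prior.gamma11) / ((a + prior.gamma11) * (1 + n + g))
        + (n - row + prior.alpha - prior.alpha1)
        / ((row + prior.alpha1) * (1 + n + prior.alpha))
        + (n - col + prior.beta - prior.beta1)
        / ((col + prior.beta1) * (1 + n + prior.beta))
    ) / _LN2_SQ
    return (ic, e_ic - 2.0 * math.sqrt(v_ic))


def ebgm_stats(t: ContingencyTable) -> tuple[float, float]:
    """Observed/expected reporting ratio with its lognormal lower bound."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return (math.nan, math.nan)
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ebgm, math.exp(math.log(ebgm) - Z95 * se))


def compute_signal_stats(
    t: ContingencyTable, prior: BcpnnPrior | None = None
) -> SignalStats:
    """All four estimators on one table, full precision."""
    ror, ror_lo, ror_hi = ror_stats(t)
    prr, prr_lo, prr_hi, chi2 = prr_stats(t)
    ic, ic025 = bcpnn_stats(t, prior)
    ebgm, ebgm05 = ebgm_stats(t)
    return SignalStats(
        n=t.a,
        ror=ror,
        ror_lo=ror_lo,
        ror_hi=ror_hi,
        prr=prr,
        prr_lo=prr_lo,
        prr_hi=prr_hi,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
    )


def evaluate_criteria(
    stats: SignalStats, criteria: SignalCriteria | None = None
) -> dict[str, bool]:
    """Per-criterion flags plus the combined conjunction.

    An undefined (NaN) statistic fails its criterion: NaN comparisons are
    false, so a zero-cell table can never be a signal.
    """
    c = criteria or SignalCriteria()
    flags = {
        "flag_n": stats.n >= c.min_a,
        "flag_ror": stats.ror_lo > c.ror_lo_gt,
        "flag_prr": stats.prr >= c.prr_ge,
        "flag_chi2": stats.chi2 >= c.chi2_ge,
        "flag_ic": stats.ic025 > c.ic025_gt,
        "flag_ebgm": stats.ebgm05 > c.ebgm05_gt,
    }
    flags["signal"] = all(flags.values())
    return flags


_STAT_COLUMNS = [
    "n",
    "ror",
    "ror_lo",
    "ror_hi",
    "prr",
    "prr_lo",
    "prr_hi",
    "chi2",
    "ic",
    "ic025",
    "ebgm",
    "ebgm05",
]


def rank_signals(
    stats_by_term: dict[str, SignalStats],
    criteria: SignalCriteria | None = None,
    top_k: int | None = None,
    signals_only: bool = True,
) -> pd.DataFrame:
    """Rank (term -> stats) rows by ROR descending.

    Ties break by n descending, then term name; by default only rows
    passing the combined criterion are kept.
    """
    rows = []
    for term, stats in stats_by_term.items():
        row = {"term": term}
        row.update({col: getattr(stats, col) for col in _STAT_COLUMNS})
        row.update(evaluate_criteria(stats, criteria))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["term", *_STAT_COLUMNS, "flag_n", "flag_ror",
                                     "flag_prr", "flag_chi2", "flag_ic",
                                     "flag_ebgm", "signal"])
    if df.empty:
        return df
    if signals_only:
        df = df[df["signal"]]
    df = df.sort_values(
        by=["ror", "n", "term"], ascending=[False, False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
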