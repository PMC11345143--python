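"""Descriptive summaries of a report cohort.

Covers the standard characteristics blocks of a spontaneous-report study:
sex, age bands, reporter occupation, top countries, top administration
routes, outcome codes, annual report counts, onset-time quartiles, and
top-K term frequency tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from faerspv.contingency import EventCounts
from faerspv.ingest import ReportCase

logger = logging.getLogger("faerspv.descriptives")

__all__ = [
    "CharacteristicsSummary",
    "summarize_characteristics",
    "onset_days",
    "onset_quartiles",
    "annual_counts",
    "top_terms",
]

# Age bands closed on the left: [0,18), [18,45), [45,65), [65, inf).
AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "UNK")


@dataclass
class CharacteristicsSummary:
    n_cases: int
    sex: dict[str, int] = field(default_factory=dict)
    age_bands: dict[str, int] = field(default_factory=dict)
    reporter: dict[str, int] = field(default_factory=dict)
    countries: dict[str, int] = field(default_factory=dict)
    routes: dict[str, int] = field(default_factory=dict)
    outcomes: dict[str, int] = field(default_factory=dict)
    onset_median: float | None = None
    onset_q1: float | None = None
    onset_q3: float | None = None

    def percentages(self, block: str) -> dict[str, float]:
        """Counts of one block as percentages of the cohort size."""
        counts: dict[str, int] = getattr(self, block)
        if self.n_cases == 0:
            return {k: 0.0 for k in counts}
        return {k: 100.0 * v / self.n_cases for k, v in counts.items()}


def _age_band(age: float | None) -> str:
    if age is None:
        return "UNK"
    if age < 18:
        return "<18"
    if age < 45:
        return "18-44"
    if age < 65:
        return "45-64"
    return ">=65"


def _parse_dt(raw: str | None) -> date | None:
    if raw is None or len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


def onset_days(case: ReportCase, target_ingredients) -> int | None:
    """Days from the earliest PS target-drug start date to the event date.

    Requires full 8-digit dates on both sides; a negative difference
    (event before therapy start) is treated as missing. Zero is a legal
    value — same-day onset is common for administration-site events.
    """
    event = _parse_dt(case.event_dt)
    if event is None:
        return None
    targets = frozenset(target_ingredients)
    starts = [
        _parse_dt(d.start_dt)
        for d in case.drugs
        if d.role == "PS" and d.ingredient in targets
    ]
    starts = [s for s in starts if s is not None]
    if not starts:
        return None
    days = (event - min(starts)).days
    if days < 0:
        logger.debug("primaryid=%s: event precedes therapy start", case.primaryid)
        return None
    return days


def onset_quartiles(values) -> tuple[float, float, float] | None:
    """(median, Q1, Q3) by linear interpolation over the sorted values."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return None
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return (float(med), float(q1), float(q3))


def summarize_characteristics(
    cases: list[ReportCase], target_ingredients=()
) -> CharacteristicsSummary:
    """Tabulate cohort characteristics; percentages use the cohort size."""
    summary = CharacteristicsSummary(n_cases=len(cases))
    if not cases:
        logger.warning("summarize_characteristics: empty cohort")
        return summary
    for case in cases:
        summary.sex[case.sex] = summary.sex.get(case.sex, 0) + 1
        band = _age_band(case.age_years)
        summary.age_bands[band] = summary.age_bands.get(band, 0) + 1
        summary.reporter[case.reporter] = summary.reporter.get(case.reporter, 0) + 1
        summary.countries[case.country] = summary.countries.get(case.country, 0) + 1
        for route in {d.route for d in case.drugs} or {"UNK"}:
            summary.routes[route] = summary.routes.get(route, 0) + 1
        for code in case.outcomes:
            summary.outcomes[code] = summary.outcomes.get(code, 0) + 1
    if target_ingredients:
        onsets = [onset_days(c, target_ingredients) for c in cases]
        quartiles = onset_quartiles(onsets)
        if quartiles is not None:
            summary.onset_median, summary.onset_q1, summary.onset_q3 = quartiles
    return summary


def annual_counts(cases: list[ReportCase]) -> dict[str, int]:
    """Report counts per receipt year; unparseable years pool under UNK."""
    counts: dict[str, int] = {}
    for case in cases:
        year = case.fda_dt[:4] if case.fda_dt[:4].isdigit() else "UNK"
        counts[year] = counts.get(year, 0) + 1
    return counts


def top_terms(
    counts: EventCounts,
    k: int,
    level: str = "PT",
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Top-k target-drug terms by event count with whole-level percentages.

    Percentages are taken over the target drug's total events at that
    level, so they are invariant to k. Ties break by term name.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if level == "PT":
        a_counts: dict = counts.pt_a
        label = (lambda pt: names.get(pt, str(pt))) if names else str
        rows = [{"term": label(pt), "a": n} for pt, n in a_counts.items()]
    elif level == "SOC":
        rows = [{"term": soc, "a": n} for soc, n in counts.soc_a.items()]
    else:
        raise ValueError(f"unknown level {level!r}")
    df = pd.DataFrame(rows, columns=["term", "a"])
    total = df["a"].sum()
    df["pct"] = 100.0 * df["a"] / total if total else 0.0
    df = df.sort_values(by=["a", "term"], ascending=[False, True])
    return df.head(k).reset_index(drop=True)
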