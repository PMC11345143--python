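"""Event-level 2x2 contingency tables for (drug, term) pairs.

The counting unit is the distinct (report, PT) pair: a report listing k
distinct reaction PTs contributes k events to the grand total N. For a
target drug class and a term t within a stratum the table is::

                    term t      other terms
    target drug       a             b
    other drugs       c             d

with N = a + b + c + d. The comparator is always "all other drugs in the
same stratum", so pregnancy-subgroup signals are measured against the
pregnancy background rather than the whole database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from faerspv.ingest import ReportCase

__all__ = [
    "ContingencyTable",
    "EventCounts",
    "tabulate_events",
    "make_table",
    "reconstruct_table",
]

UNMAPPED_SOC = "unmapped"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts (a, b, c, d) with the grand event total N."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def term_total(self) -> int:
        return self.a + self.c


@dataclass
class EventCounts:
    """Event tallies for one stratum: per-term target counts and margins."""

    pt_a: dict[int, int] = field(default_factory=dict)
    pt_total: dict[int, int] = field(default_factory=dict)
    soc_a: dict[str, int] = field(default_factory=dict)
    soc_total: dict[str, int] = field(default_factory=dict)
    drug_total: int = 0
    n: int = 0
    n_unmapped: int = 0

    def pt_table(self, pt_code: int) -> ContingencyTable:
        return make_table(
            self.pt_a.get(pt_code, 0), self.drug_total, self.pt_total[pt_code], self.n
        )

    def soc_table(self, soc: str) -> ContingencyTable:
        return make_table(
            self.soc_a.get(soc, 0), self.drug_total, self.soc_total[soc], self.n
        )


def tabulate_events(
    cases: list[ReportCase],
    target_ingredients,
    pt2soc: dict[int, str] | None = None,
) -> EventCounts:
    """Tally distinct (report, PT) events for a stratum of cases.

    Target events are those of reports naming a target ingredient as the
    primary-suspect drug. SOC counts sum the events of their member PTs; a
    PT with no SOC mapping is still counted at PT level and pooled under
    the ``unmapped`` SOC label.
    """
    targets = frozenset(target_ingredients)
    pt2soc = pt2soc or {}
    counts = EventCounts()
    for case in cases:
        is_target = any(
            d.role == "PS" and d.ingredient in targets for d in case.drugs
        )
        for pt in case.reactions:
            counts.n += 1
            counts.pt_total[pt] = counts.pt_total.get(pt, 0) + 1
            soc = pt2soc.get(pt)
            if soc is None:
                soc = UNMAPPED_SOC
                counts.n_unmapped += 1
            counts.soc_total[soc] = counts.soc_total.get(soc, 0) + 1
            if is_target:
                counts.drug_total += 1
                counts.pt_a[pt] = counts.pt_a.get(pt, 0) + 1
                counts.soc_a[soc] = counts.soc_a.get(soc, 0) + 1
    return counts


def make_table(a: int, drug_total: int, term_total: int, n: int) -> ContingencyTable:
    """Build a 2x2 table from the target-cell count and its margins."""
    if a > min(drug_total, term_total) or drug_total + term_total - a > n:
        raise ValueError(
            f"inconsistent margins: a={a}, drug_total={drug_total}, "
            f"term_total={term_total}, N={n}"
        )
    b = drug_total - a
    c = term_total - a
    d = n - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def reconstruct_table(
    a: int, drug_total: int, n: int, anchor_ror: float
) -> ContingencyTable:
    """Invert a published ROR to recover the comparator cell count c.

    Validation utility: given the target cell ``a``, the drug and grand
    event margins, and a ROR printed at 2 decimal places, solve
    ROR = a*d/(b*c) with d = N - drug_total - c for the unique integer c,
    then verify the recomputed ROR rounds back to the anchor.
    """
    if anchor_ror <= 0:
        raise ValueError("anchor ROR must be positive")
    if a < 1:
        raise ValueError("a must be >= 1 to invert a ratio")
    b = drug_total - a
    c = round((n - drug_total) / (1.0 + anchor_ror * b / a))
    if c < 1:
        raise ValueError(
            f"irreconcilable row: inversion gives c={c} for anchor {anchor_ror}"
        )
    table = make_table(a, drug_total, a + c, n)
    ror = (table.a * table.d) / (table.b * table.c)
    if round(ror, 2) != round(anchor_ror, 2):
        raise ValueError(
            f"irreconcilable row: c={c} gives ROR {ror:.4f}, anchor {anchor_ror}"
        )
    return table
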