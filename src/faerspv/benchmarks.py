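"""Frozen benchmark rows for regression-testing the estimators.

Each row is a published disproportionality result for the LMWH drug class:
the target cell count ``a``, the stratum margins (target-drug event total
and grand event total), the published ROR anchor used to invert the
comparator cell ``c``, and every published statistic. Rebuilding the 2x2
table via :func:`faerspv.contingency.reconstruct_table` and recomputing
all statistics must reproduce the published values at their printed
precision (2 decimal places; interval bounds to 3 significant digits,
where published rounding occasionally disagrees in the 4th digit).

Stratum margins: overall population — 61,949 target events of 52,373,206
total; pregnancy stratum — 7,840 target events of 1,279,728 total.
"""

from __future__ import annotations

from dataclasses import dataclass

from faerspv.contingency import ContingencyTable, reconstruct_table
from faerspv.dispro_stats import SignalStats, compute_signal_stats

__all__ = ["BenchmarkRow", "BENCHMARK_ROWS", "OVERALL_MARGINS", "PREGNANCY_MARGINS",
           "reconstructed_table", "recompute", "validate_all"]

OVERALL_MARGINS = (61_949, 52_373_206)  # (target events, total events)
PREGNANCY_MARGINS = (7_840, 1_279_728)


@dataclass(frozen=True)
class BenchmarkRow:
    term: str
    stratum: str  # "overall" | "pregnancy"
    a: int
    anchor_ror: float
    expected: dict  # published statistics at printed precision
    c: int | None = None  # explicit comparator cell where the ROR anchor
    # alone is ambiguous (large a, small ROR); refined by a full-statistic
    # brute-force scan over integer c


def _row(term, stratum, a, ror, ror_lo, ror_hi, prr, prr_lo, prr_hi,
         chi2, ic, ic025, ebgm, ebgm05, c=None) -> BenchmarkRow:
    return BenchmarkRow(
        term=term,
        stratum=stratum,
        a=a,
        anchor_ror=ror,
        c=c,
        expected=dict(
            ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
            prr=prr, prr_lo=prr_lo, prr_hi=prr_hi,
            chi2=chi2, ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
        ),
    )


BENCHMARK_ROWS: tuple[BenchmarkRow, ...] = (
    _row("anti factor X antibody positive", "overall", 6,
         506.70, 184.15, 1394.23, 506.65, 184.14, 1394.01,
         1892.46, 8.31, 1.48, 317.03, 115.22),
    _row("heparin-induced thrombocytopenia test positive", "overall", 19,
         263.10, 157.20, 440.33, 263.02, 157.17, 440.14,
         3781.55, 7.65, 3.47, 200.79, 119.97),
    _row("anti factor X activity increased", "overall", 10,
         255.93, 126.13, 519.28, 255.89, 126.12, 519.15,
         1948.46, 7.62, 2.41, 196.61, 96.90),
    _row("heparin-induced thrombocytopenia test", "overall", 14,
         231.85, 128.34, 418.86, 231.80, 128.32, 418.72,
         2524.35, 7.51, 2.97, 182.09, 100.79),
    _row("spontaneous heparin-induced thrombocytopenia syndrome", "overall", 3,
         230.31, 64.25, 825.57, 230.30, 64.25, 825.49,
         538.14, 7.50, 0.35, 181.16, 50.54),
    _row("heparin-induced thrombocytopenia", "overall", 510,
         112.78, 102.79, 123.73, 111.86, 102.02, 122.64,
         49482.42, 6.63, 6.24, 98.89, 90.14),
    _row("extradural haematoma", "overall", 62,
         45.61, 35.32, 58.90, 45.57, 35.29, 58.83,
         2564.10, 5.44, 4.32, 43.28, 33.52),
    _row("abdominal wall haematoma", "overall", 255,
         145.99, 127.79, 166.78, 145.39, 127.33, 166.02,
         31196.88, 6.96, 6.20, 124.18, 108.71),
    _row("sternal fracture", "pregnancy", 3,
         243.44, 40.67, 1457.14, 243.35, 40.67, 1456.18,
         289.62, 6.61, 0.09, 97.94, 16.36),
    _row("syringe issue", "pregnancy", 12,
         97.49, 47.64, 199.49, 97.34, 47.60, 199.05,
         715.13, 5.94, 2.49, 61.21, 29.91),
    _row("bleeding time prolonged", "pregnancy", 3,
         97.38, 23.27, 407.53, 97.34, 23.27, 407.24,
         178.78, 5.94, 0.19, 61.21, 14.63),
    _row("spinal compression fracture", "pregnancy", 10,
         90.24, 41.64, 195.56, 90.13, 41.62, 195.18,
         566.62, 5.87, 2.20, 58.30, 26.90),
    _row("injection site haematoma", "pregnancy", 19,
         79.23, 45.76, 137.15, 79.04, 45.70, 136.70,
         984.40, 5.74, 3.13, 53.47, 30.89),
    _row("abortion", "pregnancy", 144,
         11.36, 9.58, 13.47, 11.17, 9.45, 13.20,
         1249.27, 3.39, 3.05, 10.51, 8.87, c=2092),
    _row("osteoporosis", "pregnancy", 23,
         14.28, 9.32, 21.88, 14.24, 9.30, 21.80,
         260.38, 3.72, 2.51, 13.17, 8.60),
)

# Fields compared at 2 decimal places; interval bounds at 3 significant digits.
POINT_FIELDS = ("ror", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05")
INTERVAL_FIELDS = ("ror_lo", "ror_hi", "prr_lo", "prr_hi")


def margins(stratum: str) -> tuple[int, int]:
    if stratum == "overall":
        return OVERALL_MARGINS
    if stratum == "pregnancy":
        return PREGNANCY_MARGINS
    raise ValueError(f"unknown stratum {stratum!r}")


def reconstructed_table(row: BenchmarkRow) -> ContingencyTable:
    drug_total, n = margins(row.stratum)
    if row.c is not None:
        from faerspv.contingency import make_table

        return make_table(row.a, drug_total, row.a + row.c, n)
    return reconstruct_table(row.a, drug_total, n, row.anchor_ror)


def recompute(row: BenchmarkRow) -> SignalStats:
    return compute_signal_stats(reconstructed_table(row))


def _sig3(x: float) -> float:
    from math import floor, log10

    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + 2)


def validate_all() -> list[dict]:
    """Recompute every benchmark row; return per-field pass/fail records."""
    results = []
    for row in BENCHMARK_ROWS:
        stats = recompute(row)
        rec = {"term": row.term, "stratum": row.stratum, "ok": True, "fields": {}}
        for f in POINT_FIELDS:
            got, want = round(getattr(stats, f), 2), row.expected[f]
            ok = got == round(want, 2)
            rec["fields"][f] = {"computed": got, "published": want, "ok": ok}
            rec["ok"] &= ok
        for f in INTERVAL_FIELDS:
            got, want = _sig3(getattr(stats, f)), _sig3(row.expected[f])
            ok = got == want
            rec["fields"][f] = {"computed": got, "published": row.expected[f], "ok": ok}
            rec["ok"] &= ok
        results.append(rec)
    return results
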