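import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.benchmarks import BENCHMARK_ROWS, recompute
from faerspv.contingency import ContingencyTable, make_table
from faerspv.dispro_stats import (
    SignalCriteria,
    SignalStats,
    bcpnn_stats,
    compute_signal_stats,
    ebgm_stats,
    evaluate_criteria,
    prr_stats,
    rank_signals,
    ror_stats,
)

INDEPENDENCE = ContingencyTable(20, 80, 200, 800)

cells = st.integers(min_value=1, max_value=1_000_000)


@st.composite
def tables(draw):
    return ContingencyTable(draw(cells), draw(cells), draw(cells), draw(cells))


class TestPointEstimates:
    def test_published_rows_reproduced(self):
        # spot checks on the strongest overall and pregnancy signals;
        # the full row-by-row regression lives in the acceptance suite
        by_term = {r.term: r for r in BENCHMARK_ROWS}
        s = recompute(by_term["anti factor X antibody positive"])
        assert round(s.ror, 2) == 506.70
        assert round(s.ic, 2) == 8.31
        assert round(s.ebgm, 2) == 317.03
        s = recompute(by_term["sternal fracture"])
        assert round(s.ror, 2) == 243.44
        assert round(s.chi2, 2) == 289.62

    def test_independence_table_is_null(self):
        ror, lo, hi = ror_stats(INDEPENDENCE)
        prr, _, _, chi2 = prr_stats(INDEPENDENCE)
        ic, _ = bcpnn_stats(INDEPENDENCE)
        ebgm, _ = ebgm_stats(INDEPENDENCE)
        assert ror == pytest.approx(1.0)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert ic == pytest.approx(0.0)
        assert ebgm == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_marks_stats_undefined(self):
        t = ContingencyTable(0, 10, 5, 100)
        assert all(math.isnan(v) for v in ror_stats(t))
        assert all(math.isnan(v) for v in prr_stats(t))
        assert all(math.isnan(v) for v in bcpnn_stats(t))
        flags = evaluate_criteria(compute_signal_stats(t))
        assert not flags["signal"]


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tables())
    def test_ic_equals_log2_ebgm(self, t):
        ic, _ = bcpnn_stats(t)
        ebgm, _ = ebgm_stats(t)
        assert math.isclose(ic, math.log2(ebgm), rel_tol=1e-12, abs_tol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tables())
    def test_bounds_bracket_estimates(self, t):
        ror, lo, hi = ror_stats(t)
        assert lo <= ror <= hi
        ebgm, ebgm05 = ebgm_stats(t)
        assert ebgm05 <= ebgm

    def test_chi2_matches_observed_expected_oracle(self):
        # independent oracle: Sum (O-E)^2 / E over the four cells
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 100_000, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            _, _, _, chi2 = prr_stats(t)
            n = t.n
            rows = (t.a + t.b, t.c + t.d)
            cols = (t.a + t.c, t.b + t.d)
            oracle = 0.0
            for obs, r, col in ((t.a, 0, 0), (t.b, 0, 1), (t.c, 1, 0), (t.d, 1, 1)):
                e = rows[r] * cols[col] / n
                oracle += (obs - e) ** 2 / e
            assert math.isclose(chi2, oracle, rel_tol=1e-9)

    def test_monotone_in_a_at_fixed_margins(self):
        # shifting one event from the off-diagonal into cell a (margins
        # fixed) must strictly increase all four estimators
        t0 = make_table(10, 500, 300, 100_000)
        t1 = make_table(11, 500, 300, 100_000)
        assert ror_stats(t1)[0] > ror_stats(t0)[0]
        assert prr_stats(t1)[0] > prr_stats(t0)[0]
        assert bcpnn_stats(t1)[0] > bcpnn_stats(t0)[0]
        assert ebgm_stats(t1)[0] > ebgm_stats(t0)[0]


class TestCriteria:
    def test_reconstructed_strong_signal_passes_all_six(self):
        row = next(r for r in BENCHMARK_ROWS
                   if r.term == "anti factor X antibody positive")
        flags = evaluate_criteria(recompute(row))
        assert flags["signal"] and all(
            flags[k] for k in ("flag_n", "flag_ror", "flag_prr",
                               "flag_chi2", "flag_ic", "flag_ebgm")
        )

    def test_min_case_count_gate(self):
        t = make_table(2, 100, 4, 100_000)
        flags = evaluate_criteria(compute_signal_stats(t))
        assert not flags["flag_n"] and not flags["signal"]

    def test_independence_fails_ror_bound(self):
        flags = evaluate_criteria(compute_signal_stats(INDEPENDENCE))
        assert not flags["flag_ror"] and not flags["signal"]

    def test_thresholds_configurable(self):
        t = make_table(2, 100, 4, 100_000)
        relaxed = SignalCriteria(min_a=1, prr_ge=1.0, chi2_ge=0.0,
                                 ebgm05_gt=0.0, ic025_gt=-10.0)
        assert evaluate_criteria(compute_signal_stats(t), relaxed)["signal"]


class TestRankSignals:
    def _stats(self, **kw):
        base = dict(n=5, ror=2.0, ror_lo=1.5, ror_hi=3.0, prr=2.0, prr_lo=1.5,
                    prr_hi=3.0, chi2=10.0, ic=1.0, ic025=0.5, ebgm=2.5,
                    ebgm05=2.1)
        base.update(kw)
        return SignalStats(**base)

    def test_descending_ror_order(self):
        stats = {
            "x": self._stats(ror=506.70),
            "y": self._stats(ror=263.10),
            "z": self._stats(ror=255.93),
        }
        df = rank_signals(stats)
        assert list(df["term"]) == ["x", "y", "z"]

    def test_tie_broken_by_n_descending(self):
        stats = {"low": self._stats(n=3), "high": self._stats(n=5)}
        df = rank_signals(stats)
        assert list(df["term"]) == ["high", "low"]

    def test_empty_input(self):
        assert rank_signals({}).empty

    def test_non_signals_filtered_by_default(self):
        stats = {"sig": self._stats(), "null": self._stats(ror_lo=0.9)}
        assert list(rank_signals(stats)["term"]) == ["sig"]
        assert len(rank_signals(stats, signals_only=False)) == 2
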