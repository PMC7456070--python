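"""DE classification, the self-implemented Fisher test and the control panel."""
import numpy as np
import pytest
from scipy import stats

from prfscan import (
    ContingencyTable,
    DERecord,
    build_contingency,
    classify_de_status,
    enrichment_test,
    hypergeom_tail,
    summarize_de,
)

from _oracles import enum_fisher


def de(tid, status):
    values = {"down": (-2.0, 0.01), "up": (2.0, 0.01), "unchanged": (0.0, 0.5)}
    l2fc, padj = values[status]
    return DERecord(tid, l2fc, padj, status)


class TestClassifyDeStatus:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (-1.5, 0.01, "down"),
            (-1.0, 0.01, "unchanged"),  # strict boundary
            (1.2, 0.049, "up"),
            (2.0, 0.20, "unchanged"),
            (1.2, 0.05, "unchanged"),  # padj boundary is strict too
        ],
    )
    def test_thresholds(self, log2fc, padj, expected):
        assert classify_de_status(log2fc, padj) == expected

    def test_padj_out_of_range(self):
        with pytest.raises(ValueError):
            classify_de_status(0.0, -0.1)

    def test_summary_percent_down(self):
        records = [de(f"d{i}", "down") for i in range(3)] + [de("u0", "up")]
        s = summarize_de(records)
        assert s["changed"] == 4
        assert s["percent_down_of_changed"] == 75.0


class TestHypergeomTail:
    def test_single_most_extreme_table_closed_form(self):
        assert hypergeom_tail(10, 0, 0, 10, "one_greater") == pytest.approx(
            1 / 184756, rel=1e-12
        )

    def test_balanced_table(self):
        t = ContingencyTable(5, 5, 5, 5)
        assert t.odds_ratio == 1.0
        assert hypergeom_tail(5, 5, 5, 5, "one_greater") == pytest.approx(
            enum_fisher(5, 5, 5, 5, "one_greater"), rel=1e-12
        )

    def test_depleted_table_near_one(self):
        p = hypergeom_tail(0, 10, 5, 5, "one_greater")
        assert p == pytest.approx(enum_fisher(0, 10, 5, 5, "one_greater"), rel=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 21, size=4))
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            for sided in ("one_greater", "two"):
                got = hypergeom_tail(a, b, c, d, sided)
                want = enum_fisher(a, b, c, d, sided)
                assert got == pytest.approx(want, rel=1e-10), (a, b, c, d, sided)

    def test_matches_independent_library_routine(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 25, size=4))
            assert hypergeom_tail(a, b, c, d, "one_greater") == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]], "greater")[1], rel=1e-9
            )
            assert hypergeom_tail(a, b, c, d, "two") == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]], "two-sided")[1], rel=1e-7
            )

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        rng = np.random.default_rng(37)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 30, size=4))
            for sided in ("one_greater", "two"):
                assert hypergeom_tail(a, b, c, d, sided) == pytest.approx(
                    hypergeom_tail(d, c, b, a, sided), rel=1e-10
                )

    def test_one_greater_monotone_in_a_at_fixed_margins(self):
        r1, r2, c1 = 15, 20, 12
        lo, hi = max(0, c1 - r2), min(r1, c1)
        ps = [
            hypergeom_tail(a, r1 - a, c1 - a, r2 - (c1 - a), "one_greater")
            for a in range(lo, hi + 1)
        ]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert hypergeom_tail(0, 0, 5, 5, "one_greater") == 1.0


class TestBuildContingency:
    def test_direct_count(self):
        records = (
            [de(f"d{i}", "down") for i in range(4)]
            + [de(f"u{i}", "up") for i in range(6)]
        )
        table = build_contingency(records, {"d0", "d1", "u0"}, "up_regulated")
        assert (table.a, table.b, table.c, table.d) == (2, 2, 1, 5)

    def test_background_comparator_uses_non_down(self):
        records = [de("d0", "down"), de("u0", "up"), de("n0", "unchanged")]
        table = build_contingency(records, {"d0", "n0"}, "prfdb_background")
        assert (table.a, table.b, table.c, table.d) == (1, 0, 1, 1)

    def test_unknown_signal_ids_error(self):
        records = [de("d0", "down"), de("u0", "up")]
        with pytest.raises(ValueError, match="absent from DE table"):
            build_contingency(records, {"zz"}, "up_regulated")

    def test_duplicate_de_ids_error(self):
        records = [de("d0", "down"), de("d0", "down"), de("u0", "up")]
        with pytest.raises(ValueError, match="duplicate"):
            build_contingency(records, set(), "up_regulated")

    def test_empty_classes_error(self):
        with pytest.raises(ValueError, match="empty down"):
            build_contingency([de("u0", "up")], set(), "up_regulated")
        with pytest.raises(ValueError, match="empty comparator"):
            build_contingency([de("d0", "down")], set(), "up_regulated")

    def test_all_positive_degenerate_margin_warns(self):
        records = [de("d0", "down"), de("u0", "up")]
        with pytest.warns(UserWarning, match="degenerate"):
            r = enrichment_test(records, {"d0", "u0"}, "phe_uuuu_c")
        assert r.p == 1.0
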