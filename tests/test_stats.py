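"""Contingency statistics: exact test, window tables, threshold scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from istex import (
    ContingencyTable,
    LengthWindow,
    compare_genotypes,
    extension_table,
    fisher_exact,
    length_sorted_table,
    percent_extended,
    scan_threshold,
)
from oracles import all_point_probs, enumeration_fisher_p


def random_table(r, max_margin=30):
    a, b, c, d = (int(r.integers(0, max_margin // 2 + 1)) for _ in range(4))
    return ContingencyTable(a, b, c, d)


class TestFisherExact:
    def test_vs_enumeration_oracle(self, rng):
        for _ in range(60):
            t = random_table(rng)
            ours = fisher_exact(t).p_two_sided
            oracle = enumeration_fisher_p(t.n11, t.n12, t.n21, t.n22)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_vs_scipy(self, rng):
        for _ in range(60):
            t = random_table(rng)
            ours = fisher_exact(t).p_two_sided
            ref = scipy_fisher([[t.n11, t.n12], [t.n21, t.n22]]).pvalue
            assert ours == pytest.approx(float(ref), rel=1e-7, abs=1e-12)

    def test_symmetric_table_is_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)).p_two_sided == 1.0

    def test_perfectly_discordant_closed_form(self):
        # margins 10/10/10: only x=0 and x=10 are as extreme as observed
        from math import comb

        t = ContingencyTable(0, 10, 10, 0)
        expected = 2 / comb(20, 10)
        assert fisher_exact(t).p_two_sided == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(
            enumeration_fisher_p(0, 10, 10, 0), rel=1e-12
        )

    def test_degenerate_margin_is_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 3, 7)).p_two_sided == 1.0
        assert fisher_exact(ContingencyTable(3, 0, 7, 0)).p_two_sided == 1.0

    def test_haldane_odds_ratio_with_zero_cell(self):
        r = fisher_exact(ContingencyTable(0, 10, 10, 0))
        assert r.odds_ratio == pytest.approx(0.5 * 0.5 / (10.5 * 10.5))

    def test_invariant_under_transpose_and_swaps(self, rng):
        for _ in range(30):
            t = random_table(rng)
            p = fisher_exact(t).p_two_sided
            variants = [
                ContingencyTable(t.n11, t.n21, t.n12, t.n22),  # transpose
                ContingencyTable(t.n21, t.n22, t.n11, t.n12),  # row swap
                ContingencyTable(t.n12, t.n11, t.n22, t.n21),  # column swap
            ]
            for v in variants:
                assert fisher_exact(v).p_two_sided == pytest.approx(p, rel=1e-9)

    def test_point_masses_sum_to_one(self, rng):
        for _ in range(30):
            r1, r2 = int(rng.integers(1, 31)), int(rng.integers(1, 31))
            c1 = int(rng.integers(1, r1 + r2))
            assert float(sum(all_point_probs(r1, r2, c1))) == pytest.approx(
                1.0, abs=1e-10
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestPercentExtended:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(2, 32, 6.3), (65, 136, 47.8), (2, 13, 15.4), (51, 115, 44.3),
         (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_rounding_half_up(self, k, n, expected):
        assert percent_extended(k, n) == expected

    def test_complement_sums_to_hundred(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            total = percent_extended(k, n) + percent_extended(n - k, n)
            assert total == pytest.approx(100.0, abs=0.1)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_extended(0, 0)


def toy_calls(lengths, extended, excluded=None):
    n = len(lengths)
    return pd.DataFrame(
        {
            "clone_id": [f"c{i:03d}" for i in range(n)],
            "undiverged_len": lengths,
            "wt_div_len": 0,
            "mutant_div_len": 0,
            "extended": extended,
            "excluded": excluded if excluded is not None else [False] * n,
        }
    )


class TestExtensionTable:
    def test_counts_match_direct_tally(self, rng):
        lens = rng.integers(5, 120, 200)
        ext = rng.random(200) < 0.4
        exc = rng.random(200) < 0.1
        calls = toy_calls(lens, ext, exc)
        tab = extension_table(calls, 44, LengthWindow(44, 86))
        keep = ~exc
        assert tab.n11 == int(((lens < 44) & ext & keep).sum())
        assert tab.n12 == int(((lens < 44) & ~ext & keep).sum())
        assert tab.n21 == int(((lens >= 44) & (lens <= 86) & ext & keep).sum())
        assert tab.n22 == int(((lens >= 44) & (lens <= 86) & ~ext & keep).sum())

    def test_all_extended_gives_zero_unextended_cells(self):
        calls = toy_calls([10, 20, 50, 60], [True] * 4)
        tab = extension_table(calls, 40, None)
        assert tab.n12 == 0 and tab.n22 == 0

    def test_clones_above_upper_bound_omitted(self):
        calls = toy_calls([10, 50, 90], [True] * 3)
        tab = extension_table(calls, 40, 86)
        assert tab.total == 2


class TestCompareGenotypes:
    def test_identical_sets_give_p_one(self):
        calls = toy_calls([10, 20, 30, 35], [True, False, True, False])
        assert compare_genotypes(calls, calls, 40).p_two_sided == 1.0

    def test_no_subthreshold_clones_is_run_error(self):
        a = toy_calls([10, 20], [False, False])
        b = toy_calls([80, 90], [True, True])
        with pytest.raises(RuntimeError):
            compare_genotypes(a, b, 40)


class TestScanThreshold:
    def test_step_function_recovers_breakpoint(self):
        lengths = [l for l in range(10, 60) for _ in range(2)]
        extended = [l >= 30 for l in lengths]
        scan = scan_threshold(toy_calls(lengths, extended))
        assert scan.best_threshold == 30

    def test_null_data_rarely_significant(self):
        """Uniform 50% extension: min scan p stays >= 0.05 in most seeds."""
        quiet = 0
        for s in range(20):
            r = np.random.default_rng(100 + s)
            calls = toy_calls(r.integers(10, 110, 60), r.random(60) < 0.5)
            try:
                scan = scan_threshold(calls)
                p_min = min(p for _, _, p in scan.entries)
            except RuntimeError:
                p_min = 1.0
            quiet += p_min >= 0.05
        assert quiet >= 15

    def test_too_few_calls_is_run_error(self):
        with pytest.raises(RuntimeError):
            scan_threshold(toy_calls([10, 50], [False, True]))


class TestLengthSortedTable:
    def test_sorted_output_is_permutation_and_monotone(self, rng):
        calls = toy_calls(rng.integers(5, 120, 50), rng.random(50) < 0.4)
        out = length_sorted_table(calls)
        assert sorted(out["clone_id"]) == sorted(calls["clone_id"])
        lens = out["undiverged_len"].to_numpy()
        assert (np.diff(lens) <= 0).all()

    def test_ties_break_by_clone_id(self):
        calls = toy_calls([50, 50, 50], [False] * 3)
        out = length_sorted_table(calls)
        assert list(out["clone_id"]) == ["c000", "c001", "c002"]
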