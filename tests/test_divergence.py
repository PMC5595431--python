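"""Divergence-point detection, clone calling and experiment processing."""

import numpy as np
import pandas as pd
import pytest

from istex import (
    AnchorSpec,
    DivergenceParams,
    SegmentClass,
    SimConfig,
    TelomereClone,
    build_consensus,
    call_clone,
    find_divergence,
    process_experiment,
    simulate_experiment,
    trim_anchor,
)
from istex.divergence import AnchorNotFoundError

from conftest import clones_of, run_calls

ANCHOR = AnchorSpec("V-R", "GATCACGCTAAGCTACGATCCTTACAGCAG")
REF = "TGGTG" * 16  # 80 bp tract shared by the toy clones below


def clone(seq, cid="c1"):
    return TelomereClone(cid, "V-R", "PIF1", seq)


class TestTrimAnchor:
    def test_exact_anchor(self):
        tel = "TGTGGTGTGG"
        assert trim_anchor(clone(ANCHOR.anchor_seq + tel), ANCHOR) == tel

    def test_one_substitution_tolerated(self):
        mutated = "A" + ANCHOR.anchor_seq[1:]
        assert trim_anchor(clone(mutated + "TGTGG"), ANCHOR) == "TGTGG"

    def test_missing_anchor_rejected(self):
        with pytest.raises(AnchorNotFoundError):
            trim_anchor(clone("TG" * 40), ANCHOR)

    def test_locus_mismatch(self):
        other = TelomereClone("c", "VI-R", "PIF1", "TGTG")
        with pytest.raises(ValueError):
            trim_anchor(other, ANCHOR)


class TestConsensus:
    def test_identical_sequences(self):
        prof = build_consensus(["TGTGG"] * 3)
        assert prof.bases == "TGTGG"
        assert prof.depth == [3] * 5

    def test_common_prefix_with_mutant_tails(self):
        common = REF[:30]
        seqs = [common + "ATTTGG", common + "TGGATTTGG", common + "TGTGGATTTGG"]
        prof = build_consensus(seqs)
        assert prof.bases[:30] == common

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            build_consensus(["TGTGG"])

    def test_matches_simulated_baseline_where_shared(self):
        cfg = SimConfig(n_clones=40, seq_error_rate=0.0, seed=11)
        exp = simulate_experiment(cfg)
        tels = [c.seq[len(cfg.anchor_seq):] for c in exp.clones]
        prof = build_consensus(tels)
        for i, (b, d) in enumerate(zip(prof.bases, prof.depth)):
            if d >= 2:
                assert b == exp.master[i]


class TestFindDivergence:
    def test_identical_to_reference(self):
        assert find_divergence(REF, REF) == len(REF) + 1

    @pytest.mark.parametrize("params", [DivergenceParams(6, 4), DivergenceParams()])
    def test_mutant_tail_at_41(self, params):
        tel = REF[:40] + "ATTTGG" * 5
        assert find_divergence(tel, REF, params) == 41

    def test_single_substitution_tolerated(self):
        tel = REF[:19] + ("G" if REF[19] == "T" else "T") + REF[20:]
        assert find_divergence(tel, REF) == len(REF) + 1

    def test_eroded_clone_matches(self):
        assert find_divergence(REF[:30], REF) == 31

    def test_extension_beyond_reference_counts_as_mismatch(self):
        tel = REF + "TGGTGTGGTGTGG"
        assert find_divergence(tel, REF) == len(REF) + 1


class TestCallClone:
    def test_no_divergence(self):
        call = call_clone(clone(REF), REF)
        assert not call.extended and not call.excluded
        assert call.undiverged_len == len(REF)
        assert call.div_class is SegmentClass.NONE

    def test_mutant_tail(self):
        tail = "ATTTGGTGTGG"
        call = call_clone(clone(REF[:35] + tail), REF)
        assert call.extended and not call.excluded
        assert call.undiverged_len == 35
        assert call.mutant_div_len == len(tail)
        assert call.wt_div_len == 0

    def test_blocks_before_terminator_are_mutant(self):
        # ref continues "GT..." after the junction, so the block tail
        # mismatches immediately and the whole tail is the mutant segment
        ref2 = "TG" * 40
        tail = "TGGATTTGG"
        call = call_clone(clone(ref2[:31] + tail), ref2)
        assert call.extended
        assert call.undiverged_len == 31
        assert call.mutant_div_len == len(tail)
        assert call.wt_div_len == 0
        assert call.div_class is SegmentClass.MUTANT

    def test_wildtype_only_divergence_excluded(self):
        tail = "GGTTGGGTTGGGTG"  # diverges from REF frame, has GGG, no A
        call = call_clone(clone(REF[:35] + tail), REF)
        assert not call.extended and call.excluded
        assert call.wt_div_len == len(tail)
        assert call.div_class is SegmentClass.WILDTYPE

    def test_mixed_divergence_split(self):
        ref2 = "TG" * 40
        wt_part = "TTGGGTTGGG"  # wild-type divergence: GGG runs, no A
        mut_part = "TGGATTTGG"  # mutant block + terminator
        call = call_clone(clone(ref2[:31] + wt_part + mut_part), ref2)
        assert call.extended and not call.excluded
        assert call.undiverged_len == 31
        assert call.wt_div_len == len(wt_part)
        assert call.mutant_div_len == len(mut_part)
        assert call.div_class is SegmentClass.MIXED

    def test_ambiguous_tail_is_no_event(self):
        # 5 bp tail below min_call_len that parses under both grammars
        tail = "GGTGG"
        call = call_clone(clone(REF[:40] + tail), REF,
                          DivergenceParams(window_w=6, window_k=3))
        if call.undiverged_len < 40 + len(tail):
            assert not call.extended and not call.excluded
            assert call.div_class is SegmentClass.AMBIGUOUS

    def test_appending_mutant_repeats_is_monotone(self):
        base = REF[:35] + "ATTTGG"
        c0 = call_clone(clone(base), REF)
        c1 = call_clone(clone(base + "TGGATTTGG"), REF)
        assert c1.undiverged_len == c0.undiverged_len
        assert c1.mutant_div_len >= c0.mutant_div_len + 9


class TestProcessExperiment:
    def test_empty_list(self):
        with pytest.raises(ValueError):
            process_experiment([], ANCHOR)

    def test_mixed_locus(self):
        cs = [
            TelomereClone("a", "V-R", "PIF1", "TG"),
            TelomereClone("b", "VI-R", "PIF1", "TG"),
        ]
        with pytest.raises(ValueError, match="loci"):
            process_experiment(cs, {"V-R": ANCHOR})

    def test_rejects_logged_not_fatal(self):
        good = clone(ANCHOR.anchor_seq + REF, "good")
        bad = clone("C" * 60, "bad")
        calls, rejections = process_experiment(
            [good, bad], ANCHOR, mode="reference", reference=REF
        )
        assert len(calls) == 1 and len(rejections) == 1
        assert "bad" in rejections[0]

    def test_noise_free_reference_mode_matches_truth(self):
        cfg = SimConfig(n_clones=60, seq_error_rate=0.0, seed=5)
        calls, exp = run_calls(
            cfg, DivergenceParams(window_w=12, window_k=1), mode="reference"
        )
        truth = exp.truth_table()
        m = calls.merge(truth, on="clone_id")
        tail = m["total_len"] - (m["div_pos"] - 1)
        sel = tail >= 6
        assert (m["extended_x"] == m["extended_y"])[sel].all()
        assert (m["undiverged_len"] == m["div_pos"] - 1)[sel].all()

    def test_noisy_consensus_mode_mostly_accurate(self):
        cfg = SimConfig(n_clones=100, seq_error_rate=0.002, seed=6)
        calls, exp = run_calls(cfg)
        truth = exp.truth_table()
        m = calls.merge(truth, on="clone_id")
        flag_acc = (m["extended_x"] == m["extended_y"]).mean()
        assert flag_acc >= 0.9
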