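import numpy as np
import pytest

from telodiverge import (
    DivergenceRules,
    RepeatGrammar,
    SimulationConfig,
    TechnicalErrorModel,
    call_divergence,
    call_set,
    call_truncations,
    emit_clone_set,
    evaluate_calls,
    sample_telomere,
    select_reference,
)
from telodiverge.caller import (
    DivergenceCall,
    align_clone,
    align_sequences,
    call_set_detailed,
    PairwiseAlignment,
)

from conftest import make_clone, make_set

RULES = DivergenceRules()


def _call(ref: str, clone: str, rules: DivergenceRules = RULES) -> DivergenceCall:
    cols, score, tail = align_sequences(ref, clone)
    aln = PairwiseAlignment("ref", "clone", cols, score, tail)
    return call_divergence(aln, rules)


@pytest.fixture
def anchored_repeat(rng):
    """Repeat sequence with an embedded unique (non-repeat) block so planted
    indels have an unambiguous position."""
    left = sample_telomere(RepeatGrammar(), 100, rng)
    right = sample_telomere(RepeatGrammar(), 193, rng)
    return left + "ACATACA" + right  # unique block at 0-based 100..107


class TestIndelBoundary:
    def test_6nt_insertion_tolerated(self, repeat_seq):
        clone = repeat_seq[:100] + "ACACAC" + repeat_seq[100:]
        call = _call(repeat_seq, clone)
        assert not call.diverged
        assert call.reason == "tolerated_indel"
        assert call.undiverged_length_nt == len(repeat_seq)

    def test_7nt_insertion_diverges_at_breakpoint(self, repeat_seq):
        clone = repeat_seq[:100] + "ACACACA" + repeat_seq[100:]
        call = _call(repeat_seq, clone)
        assert call.diverged and call.reason == "diverged_long_indel"
        assert call.divergence_point_1based == 101
        assert call.undiverged_length_nt == 100

    def test_6nt_deletion_tolerated(self, anchored_repeat):
        clone = anchored_repeat[:100] + anchored_repeat[106:]
        call = _call(anchored_repeat, clone)
        assert not call.diverged and call.reason == "tolerated_indel"

    def test_7nt_deletion_diverges(self, anchored_repeat):
        clone = anchored_repeat[:100] + anchored_repeat[107:]
        call = _call(anchored_repeat, clone)
        assert call.diverged and call.divergence_point_1based == 101

    def test_split_indel_cannot_evade_length_rule(self, anchored_repeat):
        # 4-nt plus 3-nt deletions near each other total 7 nt: divergent even
        # though each fragment alone would pass
        clone = anchored_repeat[:98] + anchored_repeat[102:104] + anchored_repeat[107:]
        call = _call(anchored_repeat, clone)
        assert call.diverged and call.reason == "diverged_long_indel"


class TestSubstitutions:
    def test_isolated_substitutions_unbounded_in_number(self, repeat_seq):
        clone = list(repeat_seq)
        for i in range(20, 280, 20):
            clone[i] = "A" if clone[i] != "A" else "C"
        call = _call(repeat_seq, "".join(clone))
        assert not call.diverged and call.reason == "tolerated_substitutions"

    def test_adjacent_substitution_pair_diverges(self, repeat_seq):
        # not a transposition: both positions changed to non-repeat bases
        clone = repeat_seq[:150] + "AC" + repeat_seq[152:]
        assert repeat_seq[150:152] not in ("AC", "CA")
        call = _call(repeat_seq, clone)
        assert call.diverged and call.reason == "diverged_substitution_run"
        assert call.divergence_point_1based == 151

    def test_mismatch_disallowed_when_substitutions_off(self, repeat_seq):
        clone = repeat_seq[:150] + "A" + repeat_seq[151:]
        rules = DivergenceRules(allow_isolated_substitutions=False)
        call = _call(repeat_seq, clone, rules)
        assert call.diverged and call.divergence_point_1based == 151


class TestUnalignableTail:
    def test_replaced_tail_diverges_at_junction(self, rng, repeat_seq):
        tail = sample_telomere(RepeatGrammar(), 150, rng)
        clone = repeat_seq[:150] + tail
        call = _call(repeat_seq + sample_telomere(RepeatGrammar(), 10, rng), clone)
        assert call.diverged
        assert abs(call.divergence_point_1based - 151) <= 5

    def test_low_identity_window(self, repeat_seq):
        # maximally foreign tail: poly-A shares no identity with any window
        clone = repeat_seq[:150] + "A" * 100
        call = _call(repeat_seq, clone)
        assert call.diverged and call.divergence_point_1based == 151


class TestPerfectAndShorter:
    def test_perfect_identity(self, repeat_seq):
        call = _call(repeat_seq, repeat_seq)
        assert (not call.diverged and call.reason == "perfect"
                and call.undiverged_length_nt == len(repeat_seq))

    def test_shortening_staircase_all_non_diverged(self, repeat_seq):
        seqs = {f"c{i:02d}": repeat_seq[: 300 - 3 * i] for i in range(10)}
        calls = call_set(make_set(seqs))
        assert not any(c.diverged for c in calls)
        by_id = {c.clone_id: c for c in calls}
        for cid, seq in seqs.items():
            assert by_id[cid].undiverged_length_nt == len(seq)
        shorter = [c for c in calls if c.clone_length_nt < 300]
        assert all(c.reason == "shorter_matching" for c in shorter)


class TestTruncationCounting:
    @pytest.mark.parametrize(
        "lengths,expected", [((124, 125, 126), 1), ((200, 250, 300), 0), ((0, 124, 124), 3)]
    )
    def test_strict_125_threshold(self, lengths, expected):
        calls = [
            DivergenceCall(f"c{i}", n, True, n + 1, n < 125, "diverged_unalignable_tail")
            for i, n in enumerate(lengths)
        ]
        assert call_truncations(calls) == expected


class TestSelectReference:
    def test_equal_length_tie_breaks_lexicographically(self):
        seqs = {f"c{i}": "TGGTGGGTGG" * 15 for i in range(6, 0, -1)}
        assert select_reference(make_set(seqs)) == "c1"

    def test_longest_wins_for_prefix_family(self, repeat_seq):
        ts = make_set({"a_long": repeat_seq[:250], "b_short": repeat_seq[:240]})
        assert select_reference(ts) == "a_long"

    def test_divergent_longest_candidate_demoted(self, rng, repeat_seq):
        # the longest clone carries its own proximal divergence event: every
        # other clone appears diverged against it at the same point, so it
        # must not serve as the reference
        common = repeat_seq
        bad = common[:140] + sample_telomere(RepeatGrammar(), 180, rng)
        seqs = {f"c{i}": common for i in range(1, 6)}
        seqs["z_long"] = bad
        assert select_reference(make_set(seqs)) == "c1"

    def test_fewer_than_two_clones_rejected(self, repeat_seq):
        with pytest.raises(ValueError):
            select_reference(make_set({"c1": repeat_seq}))


class TestCallSet:
    def test_identical_clones_all_full_length(self, repeat_seq):
        calls = call_set(make_set({f"c{i}": repeat_seq for i in range(10)}))
        assert len(calls) == 10
        assert all(not c.diverged for c in calls)
        assert all(c.undiverged_length_nt == len(repeat_seq) for c in calls)

    def test_sorted_by_undiverged_length(self, rng, repeat_seq):
        cfg = SimulationConfig(seed=5, clones_per_set=40, divergence_rate=0.02)
        res = emit_clone_set(cfg, TechnicalErrorModel())
        calls = call_set(res.telomere_set)
        lengths = [c.undiverged_length_nt for c in calls]
        assert lengths == sorted(lengths, reverse=True)

    def test_planted_events_called_at_planted_positions(self, rng, repeat_seq):
        # two clones with distal replacements beyond tolerance, the rest clean
        seqs = {f"c{i:02d}": repeat_seq for i in range(18)}
        seqs["e1"] = repeat_seq[:120] + sample_telomere(RepeatGrammar(), 170, rng)
        seqs["e2"] = repeat_seq[:200] + sample_telomere(RepeatGrammar(), 95, rng)

        def effective_junction(planted: int) -> int:
            # fresh repeats can coincidentally reproduce the first replaced
            # bases; the observable junction is the first actual difference
            clone = seqs["e1"] if planted == 120 else seqs["e2"]
            k = planted
            while clone[k] == repeat_seq[k]:
                k += 1
            return k + 1

        calls = {c.clone_id: c for c in call_set(make_set(seqs))}
        diverged = {cid for cid, c in calls.items() if c.diverged}
        assert diverged == {"e1", "e2"}
        assert abs(calls["e1"].divergence_point_1based - effective_junction(120)) <= 2
        assert abs(calls["e2"].divergence_point_1based - effective_junction(200)) <= 2

    def test_monotone_tolerance(self):
        cfg = SimulationConfig(seed=9, clones_per_set=60, divergence_rate=0.02)
        res = emit_clone_set(cfg, TechnicalErrorModel())
        counts = []
        for max_indel, max_run in [(6, 1), (10, 1), (10, 2), (20, 3)]:
            rules = DivergenceRules(max_indel_nt=max_indel, max_substitution_run=max_run)
            counts.append(sum(c.diverged for c in call_set(res.telomere_set, rules)))
        assert counts == sorted(counts, reverse=True)


class TestSimulatedEndToEnd:
    def test_zero_false_positives_on_tolerated_class_errors(self):
        cfg = SimulationConfig(seed=21, clones_per_set=300, divergence_rate=0.0)
        res = emit_clone_set(cfg, TechnicalErrorModel(p_artifact=0.0))
        calls = call_set(res.telomere_set)
        assert sum(c.diverged for c in calls) == 0

    def test_detection_of_planted_tails(self):
        cfg = SimulationConfig(seed=22, clones_per_set=300, divergence_rate=0.01)
        res = emit_clone_set(cfg, TechnicalErrorModel())
        ref_id, ref_seq, calls = call_set_detailed(res.telomere_set)
        stats = evaluate_calls(calls, res.truth, res.founder, ref_seq)
        assert stats.precision == 1.0
        assert stats.n_detected / stats.n_true_events >= 0.9
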