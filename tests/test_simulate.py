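import re

import numpy as np
import pytest

from telodiverge import (
    RepeatGrammar,
    SenescenceProfile,
    SimulationConfig,
    TechnicalErrorModel,
    call_set,
    emit_clone_set,
    emit_density_fixture,
    evolve_lineage,
    sample_telomere,
)
from telodiverge.simulate import rng_streams, write_clone_set

GRAMMAR_RE = re.compile(r"(TG{1,3})*(TG{0,3})?")


class TestRepeatGrammar:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            RepeatGrammar(0.5, 0.5, 0.5)

    def test_degenerate_grammar_is_periodic(self, rng):
        assert sample_telomere(RepeatGrammar(0, 1, 0), 12, rng) == "TGGTGGTGGTGG"

    def test_output_matches_grammar(self, rng):
        for length in (1, 2, 17, 300):
            seq = sample_telomere(RepeatGrammar(), length, rng)
            assert len(seq) == length
            assert GRAMMAR_RE.fullmatch(seq), seq

    def test_unit_frequencies_within_3_sigma(self, rng):
        g = RepeatGrammar()
        n_units = 100_000
        seq = sample_telomere(g, int(n_units * 3.2), rng)
        counts = {1: 0, 2: 0, 3: 0}
        for m in re.finditer(r"TG{1,3}", seq):
            counts[len(m.group()) - 1] += 1
        total = sum(counts.values())
        for k, p in zip((1, 2, 3), g.probs):
            sigma = np.sqrt(p * (1 - p) * total)
            assert abs(counts[k] - p * total) < 3 * sigma


class TestEvolveLineage:
    def test_shortening_only_bounds(self, rng):
        cfg = SimulationConfig(divergence_rate=0.0, generations=30)
        seq, events, prefix, eroded = evolve_lineage(cfg, rng)
        total = len(cfg.proximal_anchor) + cfg.initial_length_nt
        assert total - 120 <= len(seq) <= total - 90
        assert events == [] and prefix == len(seq) and not eroded

    def test_forced_event(self, rng):
        cfg = SimulationConfig(divergence_rate=1.0, generations=1)
        _, events, _, _ = evolve_lineage(cfg, rng)
        assert [e.kind for e in events] == ["divergence"]

    def test_event_counts_binomial(self, rng):
        g, r, n = 10, 0.2, 3000
        cfg = SimulationConfig(divergence_rate=r, generations=g)
        counts = np.array(
            [sum(e.kind == "divergence" for e in evolve_lineage(cfg, rng)[1]) for _ in range(n)]
        )
        assert counts.min() >= 0 and counts.max() <= g
        mean_se = np.sqrt(g * r * (1 - r) / n)
        assert abs(counts.mean() - g * r) < 4 * mean_se
        var_target = g * r * (1 - r)
        assert abs(counts.var() - var_target) < 0.15 * var_target

    def test_erosion_floors_at_anchor(self, rng):
        cfg = SimulationConfig(initial_length_nt=20, generations=30, divergence_rate=0.0)
        seq, _, _, eroded = evolve_lineage(cfg, rng)
        assert eroded and seq == cfg.proximal_anchor

    def test_divergence_fraction_matches_closed_form(self, rng):
        # fraction of lineages with >=1 event vs 1-(1-r)^g
        r, g, n = 0.02, 20, 4000
        cfg = SimulationConfig(divergence_rate=r, generations=g)
        hits = sum(
            bool(evolve_lineage(cfg, rng)[1]) for _ in range(n)
        )
        expect = 1 - (1 - r) ** g
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(hits / n - expect) < 3 * sigma


class TestEmitCloneSet:
    def test_null_pipeline_produces_prefix_family(self):
        cfg = SimulationConfig(seed=3, clones_per_set=30, divergence_rate=0.0)
        res = emit_clone_set(cfg, error_model=None)
        assert all(res.founder.startswith(c.bases) for c in res.telomere_set.clones)
        calls = call_set(res.telomere_set)
        assert sum(c.diverged for c in calls) == 0
        assert not any(t.true_diverged for t in res.truth)

    def test_truth_consistent_with_sequences(self):
        cfg = SimulationConfig(seed=4, clones_per_set=60, divergence_rate=0.05)
        res = emit_clone_set(cfg, error_model=None)
        clones = {c.clone_id: c.bases for c in res.telomere_set.clones}
        for t in res.truth:
            seq = clones[t.clone_id]
            assert t.final_length_nt == len(seq)
            assert seq[: t.undiverged_prefix_nt] == res.founder[: t.undiverged_prefix_nt]
            if t.true_diverged:
                p = t.undiverged_prefix_nt
                assert p == len(seq) or p >= len(res.founder) or seq[p] != res.founder[p]

    def test_artifact_layer_fraction(self):
        cfg = SimulationConfig(seed=6, clones_per_set=1500, divergence_rate=0.0)
        res = emit_clone_set(cfg, TechnicalErrorModel(p_artifact=0.04))
        frac = np.mean([t.event_type == "technical" for t in res.truth])
        sigma = np.sqrt(0.04 * 0.96 / 1500)
        assert abs(frac - 0.04) < 3 * sigma

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=11, clones_per_set=25, divergence_rate=0.01)
        outs = []
        for sub in ("a", "b"):
            res = emit_clone_set(cfg, TechnicalErrorModel())
            paths = write_clone_set(res, tmp_path / sub)
            outs.append({k: p.read_bytes() for k, p in paths.items()})
        assert outs[0] == outs[1]
        res_other = emit_clone_set(
            SimulationConfig(seed=12, clones_per_set=25, divergence_rate=0.01),
            TechnicalErrorModel(),
        )
        paths = write_clone_set(res_other, tmp_path / "c")
        assert paths["fasta"].read_bytes() != outs[0]["fasta"]

    def test_rng_streams_independent_and_reproducible(self):
        a1, b1 = rng_streams(99, 2)
        a2, b2 = rng_streams(99, 2)
        assert a1.integers(0, 1000, 5).tolist() == a2.integers(0, 1000, 5).tolist()
        assert b1.integers(0, 1000, 5).tolist() == b2.integers(0, 1000, 5).tolist()


class TestTelomerasePositive:
    def test_reextension_produces_distal_divergence(self):
        cfg = SimulationConfig(
            seed=8,
            telomerase_active=True,
            initial_length_nt=220,
            reextension_threshold_nt=160,
            mean_extension_nt=80,
            generations=35,
            clones_per_set=40,
            divergence_rate=0.0,
        )
        res = emit_clone_set(cfg, error_model=None)
        diverged = [t for t in res.truth if t.true_diverged]
        assert len(diverged) > 0
        anchor = len(cfg.proximal_anchor)
        # undiverged region ends no lower than threshold minus one generation
        # of shortening (plus any coincidental agreement of fresh repeats)
        for t in diverged:
            assert t.undiverged_prefix_nt >= anchor + cfg.reextension_threshold_nt - 4

    def test_planted_truncations_recovered_by_caller(self):
        cfg = SimulationConfig(
            seed=13,
            telomerase_active=True,
            truncation_rate=0.01,
            generations=35,
            clones_per_set=80,
            divergence_rate=0.0,
        )
        res = emit_clone_set(cfg, error_model=None)
        truncated = {t.clone_id for t in res.truth if t.true_truncation}
        assert truncated, "fixture should contain planted truncations"
        calls = call_set(res.telomere_set)
        called = {c.clone_id for c in calls if c.truncation}
        assert called == truncated


class TestDensityFixture:
    def test_seeding_contract(self):
        prof = SenescenceProfile.from_trough_pd("g", "S", 40.0, 7, 3, 10, noise_sd=0.5)
        t1 = emit_density_fixture([prof], np.random.default_rng(5))
        t2 = emit_density_fixture([prof], np.random.default_rng(5))
        t3 = emit_density_fixture([prof], np.random.default_rng(6))
        assert t1.equals(t2) and not t1.equals(t3)
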