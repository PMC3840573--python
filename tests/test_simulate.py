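"""Simulator: transcript structure, event mechanics, truth bookkeeping."""

import math

import numpy as np
import pytest

from retrotrace.annotate import GenomicInterval, detect_polyA_signals, kozak_conserved
from retrotrace.simulate import (
    Genome,
    PlannedEvent,
    SimulationConfig,
    duplicate_locus,
    ladder_tree,
    random_genome,
    replay_copy,
    retropose,
    simulate_dataset,
    simulate_parental_transcript,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestParentalTranscript:
    def test_paper_shaped_geometry(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        assert len(t.sequence) == 3475
        assert (t.cds_start, t.cds_end) == (377, 994)
        assert t.cds_length == 618

    def test_cds_structure_and_kozak(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        cds = t.cds_sequence
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")
        internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in internal)
        assert kozak_conserved(t.sequence, t.cds_start)

    def test_polya_signals_planted_in_utr3(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        in_utr3 = [p for p in t.polyA_signal_positions if p > t.cds_end]
        assert len(in_utr3) >= 1
        # recorded positions are actual occurrences
        found = {pos for _, pos in detect_polyA_signals(t.sequence)}
        assert set(t.polyA_signal_positions) == found

    def test_no_room_for_kozak_context_rejected(self):
        cfg = SimulationConfig(utr5_len=0)
        with pytest.raises(ValueError, match="Kozak"):
            simulate_parental_transcript(cfg, _rng())

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            SimulationConfig(cds_len=100)

    def test_same_seed_same_sequence(self):
        cfg = SimulationConfig(seed=5)
        t1 = simulate_parental_transcript(cfg, _rng(5))
        t2 = simulate_parental_transcript(cfg, _rng(5))
        assert t1.sequence == t2.sequence


class TestRetropose:
    def test_full_utr5_truncation(self, paper_shaped_transcript):
        cfg = SimulationConfig(seed=2, chromosome_length=4000)
        genome = random_genome(cfg, _rng(2))
        new, rec = retropose(
            paper_shaped_transcript, genome, cfg, _rng(3), trunc5=376, strand="+"
        )
        expected = paper_shaped_transcript.sequence[376:] + "A" * cfg.polyA_tail_len
        extracted = new.chroms[rec.insertion_chromosome][
            rec.insertion_position - 1 : rec.insertion_position - 1 + rec.length
        ]
        assert extracted == expected  # CDS + 3'UTR, no 5'UTR, tailed
        assert rec.trunc5_extent == 376
        assert rec.has_polyA_tail and not rec.retains_introns

    def test_zero_truncation_mean_keeps_full_length(self, paper_shaped_transcript):
        cfg = SimulationConfig(seed=2, trunc5_mean=0.0)
        genome = random_genome(cfg, _rng(2))
        _, rec = retropose(paper_shaped_transcript, genome, cfg, _rng(4))
        assert rec.trunc5_extent == 0
        assert rec.length == paper_shaped_transcript.length + cfg.polyA_tail_len

    def test_truth_replay_reproduces_copy(self, paper_shaped_transcript):
        cfg = SimulationConfig(seed=9, chromosome_length=3000)
        genome = random_genome(cfg, _rng(9))
        new, rec = retropose(paper_shaped_transcript, genome, cfg, _rng(10))
        extracted = new.chroms[rec.insertion_chromosome][
            rec.insertion_position - 1 : rec.insertion_position - 1 + rec.length
        ]
        copy = paper_shaped_transcript.sequence[rec.trunc5_extent :] + "A" * cfg.polyA_tail_len
        if rec.strand == "-":
            copy = copy.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert extracted == copy

    def test_empty_genome_rejected(self, paper_shaped_transcript):
        cfg = SimulationConfig()
        with pytest.raises(ValueError, match="empty"):
            retropose(paper_shaped_transcript, Genome(chroms={}), cfg, _rng())


class TestDuplicateLocus:
    def test_copy_lands_within_window(self):
        cfg = SimulationConfig(seed=1, nearby_window=1000, chromosome_length=50_000)
        genome = random_genome(cfg, _rng(1))
        locus = GenomicInterval("chr1", 10_000, 10_499)
        new, rec = duplicate_locus(genome, locus, cfg, _rng(2))
        assert rec.insertion_chromosome == "chr1"
        assert abs(rec.insertion_position - 1 - locus.end) <= cfg.nearby_window
        assert len(new.chroms["chr1"]) == 50_500

    def test_zero_window_is_adjacent(self):
        cfg = SimulationConfig(seed=1, nearby_window=0, chromosome_length=5000)
        genome = random_genome(cfg, _rng(1))
        locus = GenomicInterval("chr2", 100, 199)
        new, rec = duplicate_locus(genome, locus, cfg, _rng(2))
        assert rec.insertion_position == 200
        assert new.chroms["chr2"][199:299] == genome.chroms["chr2"][99:199]

    def test_processed_source_keeps_polya_flag(self, paper_shaped_transcript):
        cfg = SimulationConfig(seed=4, chromosome_length=8000, nearby_window=500)
        genome = random_genome(cfg, _rng(4))
        genome2, retro_rec = retropose(
            paper_shaped_transcript, genome, cfg, _rng(5), strand="+"
        )
        locus = GenomicInterval(
            retro_rec.insertion_chromosome,
            retro_rec.insertion_position,
            retro_rec.insertion_position + retro_rec.length - 1,
        )
        _, dup_rec = duplicate_locus(
            genome2, locus, cfg, _rng(6), source_record=retro_rec
        )
        assert dup_rec.has_polyA_tail
        assert not dup_rec.retains_introns

    def test_out_of_bounds_locus_rejected(self):
        cfg = SimulationConfig(chromosome_length=1000)
        genome = random_genome(cfg, _rng(0))
        with pytest.raises(ValueError, match="bounds"):
            duplicate_locus(genome, GenomicInterval("chr1", 900, 2000), cfg, _rng(1))


class TestEvolveAlongTree:
    def test_rates_zero_copies_identical_and_gapless(self, small_config_rates0):
        res = simulate_dataset(
            small_config_rates0,
            events=[PlannedEvent("retroposition", branch="root", name="P1")],
        )
        rows = {k: v for k, v in res.alignment.items() if k.endswith("|P1")}
        assert len(rows) == small_config_rates0.n_taxa
        assert len(set(rows.values())) == 1
        assert all("-" not in v for v in rows.values())

    def test_rates_zero_replay_matches_construction(self, sim_rates0):
        res = sim_rates0
        t = res.transcript
        for rec in res.truth:
            if rec.event_kind != "retroposition":
                continue
            expected = t.sequence[rec.trunc5_extent :] + "A" * res.config.polyA_tail_len
            for taxon in res.tree.leaf_names:
                if res.presence.loc[taxon, rec.copy_id] != "present":
                    continue
                seq = replay_copy(res, taxon, rec.copy_id)
                locs = res.copy_locations
                strand = locs[
                    (locs.taxon == taxon) & (locs.copy_id == rec.copy_id)
                ].iloc[0].strand
                if strand == "-":
                    seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                assert seq == expected

    def test_forced_loss_marks_clade_absent(self, small_config_rates0):
        tree = ladder_tree(4)
        # n2 subtends T1, T2, T3's sibling...: losses on n2 remove the copy
        events = [
            PlannedEvent("retroposition", branch="root", name="PX"),
            PlannedEvent("loss", branch="n2", source_copy="PX"),
        ]
        res = simulate_dataset(small_config_rates0, tree=tree, events=events)
        lost_taxa = {l.name for l in tree.nodes["n2"].leaves()}
        for taxon in tree.leaf_names:
            expected = "absent" if taxon in lost_taxa else "present"
            assert res.presence.loc[taxon, "PX"] == expected
        assert any(r.event_kind == "loss" for r in res.truth)

    def test_substitution_counts_match_poisson_rate(self):
        # one 100-My branch; mean drawn count over 200 runs within 3 SD
        cfg = SimulationConfig(
            seed=0, n_taxa=2, utr5_len=30, cds_len=150, utr3_len=120,
            n_polya_signals=1, chromosome_length=1500, n_chromosomes=2,
            subst_rate=0.22, indel_rate=0.0, trunc5_mean=0.0, polyA_tail_len=0,
        )
        tree = ladder_tree(2, root_age=100.0)
        counts = []
        for seed in range(200):
            res = simulate_dataset(
                SimulationConfig(**{**cfg.__dict__, "seed": seed}),
                tree=tree,
                events=[PlannedEvent("retroposition", branch="root", name="PX")],
            )
            counts.append(res.branch_substitutions.get(("T1", "PX"), 0))
        copy_len = 300  # full transcript, no tail
        lam = 0.22 / 100.0 * 100.0 * copy_len
        mean = float(np.mean(counts))
        assert abs(mean - lam) <= 3.0 * math.sqrt(lam / 200.0)

    def test_seed_reproducibility_byte_identical(self, small_config_rates0):
        a = simulate_dataset(small_config_rates0)
        b = simulate_dataset(small_config_rates0)
        assert a.genomes["T1"].chroms == b.genomes["T1"].chroms
        assert a.alignment == b.alignment
        assert a.presence.equals(b.presence)
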