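"""Classification rules and coding-potential feature detectors."""

import numpy as np
import pytest

from retrotrace.annotate import (
    GenomicInterval,
    annotate_candidate,
    assess_orf,
    classify,
    detect_polyA_signals,
    detect_polyA_trait,
    distance_to_nearest_gene,
    kozak_conserved,
)
from retrotrace.screen import PseudogeneCandidate, search_hits


PARENT = GenomicInterval("chr3", 50_000, 53_000, name="parent")


class TestClassify:
    def test_processed_hallmarks(self):
        c = GenomicInterval("chr7", 100, 700)
        assert classify(c, PARENT, has_introns=False, polyA_trait=True,
                        utr5_truncated=True) == "processed"

    def test_introns_near_source_duplicated(self):
        c = GenomicInterval("chr3", 60_000, 63_000)
        assert classify(c, PARENT, has_introns=True, polyA_trait=False,
                        utr5_truncated=False) == "duplicated"

    def test_duplicated_rule_wins_near_existing_pseudogene(self):
        # an intronless, truncated copy 10 kb from an older pseudogene on the
        # same chromosome is a tandem duplication of it, not a new insertion
        older = GenomicInterval("chr12", 200_000, 203_000, name="P10")
        c = GenomicInterval("chr12", 213_000, 216_000)
        call = classify(c, PARENT, paralog_loci=[older], has_introns=False,
                        polyA_trait=True, utr5_truncated=True)
        assert call == "duplicated"

    def test_neither_rule_reports_ambiguous(self):
        # same chromosome as the parent but far beyond the window
        c = GenomicInterval("chr3", 5_000_000, 5_000_600)
        call = classify(c, PARENT, has_introns=False, polyA_trait=True,
                        utr5_truncated=True, nearby_window=1_000_000)
        assert call == "ambiguous"

    def test_paralog_order_invariance(self):
        c = GenomicInterval("chr12", 213_000, 216_000)
        loci = [GenomicInterval("chr12", 200_000, 203_000),
                GenomicInterval("chr5", 1, 100),
                GenomicInterval("chr12", 900_000, 901_000)]
        calls = {
            classify(c, PARENT, paralog_loci=p, has_introns=False,
                     polyA_trait=True, utr5_truncated=True)
            for p in (loci, loci[::-1], [loci[2], loci[0], loci[1]])
        }
        assert calls == {"duplicated"}


class TestPolyA:
    def test_a_run_detected(self):
        found, pos = detect_polyA_trait("TGCAAAAAAAAAG", min_run=8)
        assert found and pos == 4

    def test_no_run_in_gc_sequence(self):
        assert detect_polyA_trait("G" * 50) == (False, None)

    def test_window_smaller_than_run_rejected(self):
        with pytest.raises(ValueError):
            detect_polyA_trait("A" * 50, min_run=8, window=4)

    def test_signal_positions(self):
        assert detect_polyA_signals("GGATTAAAGG") == [("ATTAAA", 3)]

    def test_overlapping_signals_both_reported(self):
        assert detect_polyA_signals("AATAAATTAAA") == [
            ("AATAAA", 1), ("ATTAAA", 6)
        ]

    def test_planted_tails_detected_on_simulation(self, sim_rates0):
        res = sim_rates0
        for taxon in res.tree.leaf_names:
            hits = search_hits(res.genomes[taxon], res.transcript, taxon=taxon)
            locs = res.copy_locations
            retro = locs[(locs.taxon == taxon) & (locs.kind == "retroposition")]
            for row in retro.itertuples():
                h = next(
                    h for h in hits
                    if h.chromosome == row.chromosome
                    and not (h.end < row.start or h.start > row.end)
                )
                found, _ = detect_polyA_trait(h.downstream_sequence(res.genomes[taxon].chroms))
                assert found  # recall 1 at zero mutation rates


class TestKozak:
    def test_canonical_context(self):
        assert kozak_conserved("GCCACCATGG", 7)

    def test_weak_context(self):
        assert not kozak_conserved("GCCTCCATGC", 7)

    def test_insufficient_context_false_with_warning(self):
        with pytest.warns(UserWarning):
            assert not kozak_conserved("ATGG", 1)

    def test_simulated_parental_always_conserved(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        assert kozak_conserved(t.sequence, t.cds_start)


def _cds_copy_candidate(transcript, mutate=None):
    """Candidate aligned 1:1 over the whole transcript, optionally mutated.

    ``mutate`` maps 0-based transcript positions to replacement bases, or
    deletes them when the value is None.
    """
    seq = list(transcript.sequence)
    pairs = []
    out = []
    for i, base in enumerate(seq):
        if mutate and i in mutate:
            if mutate[i] is None:
                continue
            base = mutate[i]
        out.append(base)
        pairs.append((i + 1, len(out)))
    return PseudogeneCandidate(
        id="c", taxon="", chromosome="chr9", start=1, end=len(out), strand="+",
        sequence="".join(out), aligned_pairs=pairs,
    )


class TestAssessOrf:
    def test_identical_copy_intact(self, paper_shaped_transcript):
        cand = _cds_copy_candidate(paper_shaped_transcript)
        assert assess_orf(cand, paper_shaped_transcript) == ("intact", [])

    def test_single_deletion_is_frameshift(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        pos = t.cds_start - 1 + 9  # CDS position 10, 0-based
        cand = _cds_copy_candidate(t, mutate={pos: None})
        status, where = assess_orf(cand, t)
        assert status == "frameshift"
        assert where == [4]  # disruption lands in codon 4 (position 10)

    def test_point_stop_at_codon_50(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        c0 = t.cds_start - 1 + 49 * 3  # codon 50, 0-based start
        cand = _cds_copy_candidate(t, mutate={c0: "T", c0 + 1: "G", c0 + 2: "A"})
        status, where = assess_orf(cand, t)
        assert status == "premature_stop"
        assert where == [50]

    def test_lost_start_is_no_orf(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        cand = _cds_copy_candidate(t, mutate={t.cds_start - 1: "C"})
        assert assess_orf(cand, t)[0] == "no_orf"

    def test_no_cds_alignment_is_no_orf(self, paper_shaped_transcript):
        t = paper_shaped_transcript
        pairs = [(q, q - t.cds_end) for q in range(t.cds_end + 1, t.length + 1)]
        cand = PseudogeneCandidate(
            id="c", taxon="", chromosome="chr9", start=1,
            end=len(pairs), strand="+",
            sequence=t.sequence[t.cds_end:], aligned_pairs=pairs,
        )
        assert assess_orf(cand, t) == ("no_orf", [])


class TestGeneDistance:
    GENES = [
        GenomicInterval("chr1", 300, 400, name="geneA"),
        GenomicInterval("chr1", 150, 250, name="oldP", is_pseudogene=True),
        GenomicInterval("chr2", 1, 100, name="geneB"),
    ]

    def test_edge_to_edge(self):
        c = GenomicInterval("chr1", 100, 200)
        assert distance_to_nearest_gene(c, [self.GENES[0]]) == 99

    def test_overlap_is_zero(self):
        c = GenomicInterval("chr1", 350, 450)
        assert distance_to_nearest_gene(c, self.GENES) == 0

    def test_pseudogene_neighbor_ignored_even_if_closer(self):
        c = GenomicInterval("chr1", 100, 200)
        assert distance_to_nearest_gene(c, self.GENES) == 99

    def test_no_gene_on_chromosome_is_missing(self):
        c = GenomicInterval("chr9", 100, 200)
        assert distance_to_nearest_gene(c, self.GENES) is None


class TestClosedLoopClassification:
    def test_accuracy_one_at_zero_rates(self, sim_rates0):
        """Every simulated copy is classified to its true mechanism."""
        res = sim_rates0
        locs = res.copy_locations
        truth_kind = {r.copy_id: r.event_kind for r in res.truth
                      if r.event_kind in ("retroposition", "duplication")}
        order = [r.copy_id for r in res.truth
                 if r.event_kind in ("retroposition", "duplication")]
        n_checked = 0
        for taxon in res.tree.leaf_names:
            hits = search_hits(res.genomes[taxon], res.transcript, taxon=taxon)
            here = locs[locs.taxon == taxon]
            parent_row = here[here.copy_id == "parental"].iloc[0]
            parent = GenomicInterval(parent_row.chromosome,
                                     int(parent_row.start), int(parent_row.end))
            for row in here[here.kind != "parental_gene"].itertuples():
                hit = next(
                    (h for h in hits
                     if h.chromosome == row.chromosome
                     and not (h.end < row.start or h.start > row.end)),
                    None,
                )
                assert hit is not None
                # loci of copies that existed before this one arose
                earlier = [
                    GenomicInterval(r.chromosome, int(r.start), int(r.end))
                    for r in here[here.kind != "parental_gene"].itertuples()
                    if order.index(r.copy_id) < order.index(row.copy_id)
                ]
                ann = annotate_candidate(
                    hit, res.genomes[taxon].chroms, res.transcript,
                    parent, paralog_loci=earlier, nearby_window=20_000,
                )
                expected = {"retroposition": "processed",
                            "duplication": "duplicated"}[truth_kind[row.copy_id]]
                assert ann.classification == expected, (taxon, row.copy_id)
                n_checked += 1
        assert n_checked >= 6
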