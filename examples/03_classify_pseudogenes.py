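"""Classify screened candidates as processed or duplicated pseudogenes.

Processed copies show the retroposition hallmarks (intronless, truncated
5'UTR, genomic polyA tract, away from the source locus); duplicated
copies sit near their source or retain introns — and that rule wins when
both could apply.
"""
from retrotrace import (
    GenomicInterval, SimulationConfig, annotate_candidate, search_hits,
    simulate_dataset,
)

config = SimulationConfig(
    seed=7, n_taxa=4, utr5_len=60, cds_len=300, utr3_len=240,
    n_polya_signals=2, chromosome_length=5000,
    subst_rate=0.0, indel_rate=0.0,
)
result = simulate_dataset(config)
taxon = "T4"  # this lineage also carries the tandem duplicate P1dup
locs = result.copy_locations
here = locs[locs.taxon == taxon]
prow = here[here.copy_id == "parental"].iloc[0]
parent = GenomicInterval(prow.chromosome, int(prow.start), int(prow.end))

hits = search_hits(result.genomes[taxon], result.transcript, taxon=taxon)
known = []
for hit in hits:
    ann = annotate_candidate(
        hit, result.genomes[taxon].chroms, result.transcript, parent,
        paralog_loci=known, nearby_window=20_000,
    )
    known.append(GenomicInterval(hit.chromosome, hit.start, hit.end))
    print(f"{hit.id}: {hit.chromosome}:{hit.start}-{hit.end}({hit.strand}) "
          f"-> {ann.classification:10s} ORF={ann.orf_status} "
          f"polyA={ann.polyA_trait} 5'trunc={ann.utr5_truncated}")
print("\nThe two exon fragments of the parental gene classify as duplicated "
      "(same chromosome, near the source); retroposed copies as processed; "
      "the tandem duplicate of a processed copy as duplicated.")
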