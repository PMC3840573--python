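"""Screen a simulated genome for copies of the parental mRNA.

Hits are found by k-mer seeding plus local alignment, then passed through
the two retention filters: the permissive retrieval filter
(similarity > 60%, mRNA coverage > 35%) and the stricter filter for
sequences entering a phylogenetic alignment (CDS coverage > 85%).
"""
from retrotrace import SimulationConfig, simulate_dataset, search_hits
from retrotrace import filter_retrieval, filter_phylo_set
from retrotrace.screen import candidates_to_table

config = SimulationConfig(
    seed=7, n_taxa=4, utr5_len=60, cds_len=300, utr3_len=240,
    n_polya_signals=2, chromosome_length=5000, subst_rate=0.1, trunc5_mean=40,
)
result = simulate_dataset(config)
hits = search_hits(result.genomes["T1"], result.transcript, taxon="T1")
print(candidates_to_table(hits).to_string(index=False))
print(f"\nretrieval filter keeps {len(filter_retrieval(hits))} of {len(hits)}")
print(f"phylogeny-set filter keeps {len(filter_phylo_set(hits))} of {len(hits)}")
print("\nSimilarity is percent identical aligned columns; the coverages are "
      "percent of the mRNA and of its CDS touched by the alignment.")
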