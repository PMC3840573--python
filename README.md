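# retrotrace

Tools for tracing the life history of retroposed gene copies — the
"processed pseudogenes" created when a mature mRNA is reverse-transcribed
and reinserted into the genome. The package grew out of the study of the
PPP1R2 (protein phosphatase 1 inhibitor-2) pseudogene family, where ten
human copies (PPP1R2P1–P10) span origins from before the
marsupial–placental split to a human-specific tandem duplication, and
where two of the derived proteins are detectable in human sperm. It is a
library for molecular evolutionists who want each stage of that kind of
analysis as a testable, scriptable unit rather than a chain of web tools.

## What it does

* **Simulate** (`retrotrace.simulate`) — generate a parental mRNA
  (UTRs, Kozak-context CDS, polyA signals), a host genome, retroposition
  with 5′-truncation and polyA-tail addition, tandem duplication,
  and lineage evolution along a dated tree (HKY-like substitutions,
  indels, Alu/L1-sized repeat insertions, losses) with machine-readable
  truth for every event — so every downstream stage can be scored.
* **Screen** (`retrotrace.screen`) — find candidate copies by k-mer
  seeded Smith–Waterman alignment against the parental mRNA, with the
  two classic retention filters: similarity > 60% and mRNA coverage
  > 35% for retrieval; CDS coverage > 85% for the phylogenetic set.
* **Classify** (`retrotrace.annotate`) — processed vs duplicated
  pseudogene calls (intronlessness, 5′UTR truncation, polyA trait,
  distance to the source locus), plus coding-potential features:
  ORF walk (frameshifts, premature stops), Kozak context,
  polyadenylation signals, distance to the nearest gene.
* **Phylogeny** (`retrotrace.phylo`) — K2P/JC distances with pairwise
  gap deletion, deterministic neighbor-joining, column bootstrap, strict
  50% majority-rule consensus, and support mapping onto a best tree.
* **Date** (`retrotrace.dating`) — Dollo presence/absence dating on a
  dated species tree: each copy's origin is bracketed by the carriers'
  crown age and the stem split above it, `[t_crown, t_stem]` in Mya, and
  losses are placed on the minimal set of branches explaining absences.
  Dated primate and mammal fixture trees with literature split times
  ship with the package.
* **Selection** (`retrotrace.selection`) — a SLAC-style counting test:
  Fitch parsimony ancestors, Nei–Gojobori site counting per branch, and
  binomial p-values per codon for dN > dS (positive) and dN < dS
  (negative) selection, with ω = dN/dS; plus the consensus rule for
  combining reports from FEL/REL/FUBAR/MEME (p < 0.1, posterior > 0.9,
  Bayes factor > 50; a site is called when ≥ 2 methods agree).
* **Proteomics** (`retrotrace.proteomics`) — map identified peptides
  onto proteins, compute residue-union coverage, and recompute
  theoretical monoisotopic m/z per charge state,
  `(M + z·1.007276)/z`, with variable Met oxidation.

## Worked example

Dating each pseudogene from its carriers on the packaged trees
(`python examples/05_date_origins.py`):

```
primate-specific pseudogenes (Mya):
            lower_mya  upper_mya origin_branch  open_ended losses
P1               42.6       65.2   Simiiformes        True
P2               29.2       42.6    Catarrhini       False
P3               20.6       29.2    Hominoidea       False
P10              42.6       65.2   Simiiformes        True

mammal-wide pseudogenes (Mya):
P7               94.4      163.9      Eutheria       False  Glires
P9              163.9      167.4        Theria        True
```

Reading it: P2 is carried by all Catarrhini but no New World monkey, so
its retroposition happened after the Platyrrhini split (42.6 Mya) and
before crown Catarrhini (29.2 Mya). P7 is present across placentals but
missing from all Glires, which Dollo parsimony explains with a single
loss on the Glires stem. P9 is carried by the opossum too, so it
predates the marsupial–placental split — the oldest copy still present
in humans.

Verifying the peptide identification table
(`python examples/07_peptide_verification.py`) recomputes every
theoretical m/z to within 0.01 Th of the measured value — the two
Met-containing peptides only after one oxidation (+15.995 Da) — and
reports 8 distinct peptides, 23 spectra, 37.1% residue coverage.

The other examples cover simulation (`01`), screening and filtering
(`02`), classification (`03`), bootstrap phylogenetics (`04`) and the
selection scan (`06`). A thin CLI mirrors the stages:
`retrotrace simulate|screen|annotate|tree|date|select|pepcheck`.

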