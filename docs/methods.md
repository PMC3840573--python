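# Methods

This note documents the models behind each `retrotrace` stage, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that matter for reproducing
output exactly.

## The retroposition model

A processed pseudogene is modelled as a copy of the mature parental
mRNA that (i) lost a 5′ prefix, because reverse transcriptase starts at
the polyA tail and often dissociates before reaching the cap; (ii)
gained a genomic polyA tract at its 3′ end; (iii) carries no introns;
and (iv) landed at a position unrelated to the source locus. A
duplicated pseudogene is a segmental copy: it stays near its source and
retains whatever introns the source had.

The simulator draws the 5′-truncation length from a geometric
distribution (support ≥ 1, configurable mean, default 200 nt), capped so
that at least half of the CDS survives. The geometric form encodes a
constant per-nucleotide dissociation risk during reverse transcription —
a one-parameter choice consistent with monotone 5′ loss; the truncation
literature does not pin down a distribution. Support starts at 1 rather
than 0 because an untruncated copy would lack the very hallmark the
downstream classifier keys on; `trunc5_mean = 0` disables truncation
explicitly. Target-site duplications are not modelled (nothing
downstream consumes them).

Insertion points are uniform over the genome, except that the simulator
avoids the source locus' neighbourhood (`nearby_window`, default 1 Mb;
in the toy-scale default genome this excludes the parent's chromosome
when another exists). In a real genome the probability of landing within
1 Mb of the source is of order 10⁻³, so a uniform draw over a ~30 kb toy
genome would grossly over-produce "nearby" insertions and with them
classification conflicts that real retroposition essentially never
creates.

## Lineage evolution

Copies evolve along an ultrametric dated tree (ages in Mya, leaves at
0). Per branch of length `b` (My) and copy of length `L`:

* substitutions ~ Poisson(`subst_rate`/100 · b · L), HKY-like with
  transition:transversion ratio `ts_tv_ratio` (default 2.0, a typical
  mammalian value; the original model choice this stands in for is
  unreported). Default `subst_rate` 0.22/site/100 My ≈ the mammalian
  neutral rate of 2.2 × 10⁻⁹/site/year.
* indels ~ Poisson(`indel_rate`/100 · b · L), default 0.02 — roughly a
  tenth of the substitution rate — with geometric lengths (mean 3).
* repeat insertions ~ Poisson(`repeat_insert_rate`/100 · b) per copy:
  opaque random-sequence intervals of Alu-like (300 nt) or L1-like
  (6000 nt) length, recorded in the truth log. Only their positions and
  lengths matter downstream (ORF disruption, annotation truth), so no
  attempt is made at realistic repeat sequence content.
* whole-copy losses ~ Poisson(`loss_rate`/100 · b), default 0; losses
  can also be planted explicitly on named branches.

Copies are tracked as sequences of homologous columns, so the emitted
multiple alignment is exact by construction (insertions open fresh
columns, deletions remove them). Background (non-copy) genomic sequence
is held fixed during lineage evolution: every downstream stage consumes
the copies, and mutating the flanks would only slow the closed-loop
tests without exercising extra logic. This is the simulator's main
departure from reality, along with: no recombination, no gene
conversion, no rate variation among sites or lineages. Consequently,
passing closed-loop tests demonstrates correctness of the bookkeeping
and inference logic under the stated model, not robustness to the
rate heterogeneity and homoplasy of real genomic data.

The parental gene is planted on chromosome 1 with `n_introns`
(default 2) random introns of 300 nt inside its CDS, so that segmental
duplications of the gene exhibit the intron-retention signature.

## Screening

Candidates are located by exact k-mer seeds (default k = 11) shared with
the parental mRNA, grouped by alignment diagonal (band 100), with groups
of ≥ 2 seeds extended by local Smith–Waterman alignment (match +1,
mismatch −1, gap open −2, gap extend −1; biopython's PairwiseAligner)
and kept at score ≥ 40. Both strands are searched; minus-strand hits are
reported in mRNA orientation with plus-strand genomic coordinates.
Overlapping hits are resolved greedily by score. No alignment
statistics (E-values, bit scores) are computed.

Similarity is percent identical aligned columns, gap columns excluded
(the percent-identity convention of standard local-alignment tools).
"Coverage" is percent of distinct parental positions aligned — computed
against the whole mRNA for the retrieval filter (> 35%, strict) and
against the CDS window for the phylogeny filter (> 85%, strict); which
denominator the original retrieval filter used is ambiguous in its
one-line description, and the mRNA (query) denominator follows the
convention of the search tool it invokes. All intervals are 1-based
inclusive on the plus strand.

## Classification and coding potential

Duplicated: same chromosome as the parent or an existing paralog and
within `nearby_window` (default 1 Mb — deliberately generous; observed
tandem pairs sit ~10 kb apart), and/or introns present. Processed:
different chromosome from the parent, polyA trait, truncated 5′UTR, no
introns. The duplicated rule takes precedence, because a tandem
duplicate of a processed pseudogene satisfies every processed hallmark
yet arose by duplication; anything matching neither rule is reported
`ambiguous`, never coerced. The classifier is deterministic and
order-independent in its paralog list.

The polyA trait is detected as a run of ≥ 8 consecutive A within 50 nt
downstream of the aligned 3′ end — a reproducible, dependency-free
stand-in for a dedicated polyA predictor, with both parameters exposed;
it is a surrogate, and output columns should be read with that in mind.
Polyadenylation signals are all AATAAA/ATTAAA occurrences, overlaps
included. Kozak conservation is the minimal purine −3 / G +4 check.
The ORF walk follows the parental reading frame through the alignment:
any indel event whose net length is not a multiple of 3 is a
frameshift (reported at the codon of the first affected base); with the
frame intact, the reconstructed ORF is translated and an in-frame stop
ahead of the parental stop is reported with its codon index; a missing
or mutated start ATG is `no_orf`. Intron presence is inferred from
insertions ≥ 50 nt, which cannot distinguish a retained intron from a
later mobile-element insertion — callers with annotation truth can pass
`has_introns` explicitly (the simulator's closed-loop tests do not need
to, because their planted events make the two cases disjoint).

Gene distances are edge-to-edge under 1-based inclusive intervals
(adjacent intervals are 0 apart only when touching; `[100,200]` to
`[300,400]` is 99), pseudogene neighbours excluded; BED input (0-based
half-open) is converted on read.

## Phylogenetics

Distances are Kimura two-parameter by default (Jukes–Cantor optional),
with pairwise deletion of gap columns — per pair, P and Q are computed
over the columns where both sequences have an unambiguous base, which
keeps the maximum usable signal in indel-rich pseudogene alignments.
Saturated pairs raise an error naming the pair rather than returning a
truncated distance. Neighbor-joining uses the Saitou–Nei Q criterion
with ties broken by the lexicographic order of cluster labels (each
cluster labelled by its smallest leaf name), making the tree a pure
function of the input matrix. Bootstrap replicates resample aligned
columns with replacement under a seeded generator. The majority-rule
consensus includes exactly the bipartitions occurring in strictly more
than the threshold fraction (default 0.5) of input trees — no greedy
completion — and `map_support` annotates a best tree's edges with their
replicate frequencies, masking values below 50% at rendering only.

This distance+NJ stack deliberately replaces ML tree search and model
selection. Claims about any particular published ML topology are
therefore out of scope here; what is guaranteed (and property-tested)
is exact recovery from additive distance matrices and exact consensus
arithmetic.

## Dollo dating

Retroposition is treated as unique and irreversible: one gain, any
number of losses. Given a presence/absence/unknown column and a dated
tree, the gain sits on the stem edge of the carriers' MRCA, giving the
origin interval [age(MRCA), age(parent of MRCA)]. Unknown cells
(unsequenced or poorly assembled genomes) are first-class: they are
ignored for the MRCA and carry no cost in loss placement. Losses are
placed on the stems of the maximal subtrees whose known leaves are all
absent — the minimum-cardinality explanation (verified against subset
enumeration in tests).

The packaged primate and mammal trees store one nominal age per node —
the younger bound of the literature range where a range is quoted —
plus an `age_upper` for nodes with a quoted range. When the carriers'
MRCA is the root, the interval's upper end uses the root's `age_upper`
and the result is flagged open-ended (the gain may predate the root).
Two fixture caveats are documented rather than resolved: the
Platyrrhini–Catarrhini split is quoted both as 42.6 and 43.4 Mya in the
source literature (the fixture stores 42.6), and the published lower
bound of 0.6 Mya for the youngest primate copy corresponds to no node
of the fixture tree (the fixture yields the Hominoidea crown, 20.6).
Ages not individually quoted (e.g. hominid internal splits, the
Boreoeutheria node) are standard TimeTree-era values chosen once for
ultrametric consistency. Dating from branch lengths (molecular clocks)
and probabilistic gain/loss models are out of scope.

## Selection scan

The counting test follows the SLAC design: ancestral sequences by
nucleotide-level Fitch parsimony (ambiguity in the top-down pass
resolved toward a designated parental taxon's state when available,
else alphabetically — a fixed, documented tie-break), then per-branch
Nei–Gojobori accounting at each codon: expected synonymous/
non-synonymous site fractions averaged over the parent and child codon
(summing to 3 per branch); observed changes averaged over all minimal
mutational pathways, ignoring pathways through stop codons unless all
are blocked; mutations *to* stop codons count as non-synonymous.
dN = ON/EN, dS = OS/ES, ω = dN/dS (undefined at dS = 0).

Each site's test is binomial: with n = OS + ON observed events, each is
non-synonymous with probability p = ω̂·EN/(ω̂·EN + ES), where ω̂ is the
whole-alignment ratio (at ω̂ = 1 this is the neutral expectation
EN/(ES + EN)); p_positive = P(X ≥ ON), p_negative = P(X ≤ ON).
Fractional counts (from pathway averaging) use the regularized
incomplete beta continuation of the binomial tails. Alignments with
fewer than 10 sequences are refused end-to-end: below that, site-wise
counts are too sparse for the test to mean anything. Sites with
in-frame stops or ambiguity characters are skipped with a warning.

Richer likelihood methods (FEL, REL, FUBAR, MEME) are not
re-implemented; their per-site outputs enter as report tables and only
the thresholding (p < 0.1; posterior > 0.9; Bayes factor > 50 — all
strict) and the two-method consensus are computed. Consensus requires
the supporting methods to agree in direction; whether the original rule
required same-direction agreement is not documented, and mixing
directions would make a "consensus" self-contradictory, so
same-direction is enforced (and stated here as an assumption). The
genetic code is the universal one, taken from biopython's code tables.

## Peptide-level verification

Monoisotopic peptide mass = Σ residue masses + 18.010565 (water), with
the residue table shipped as versioned data; m/z = (M + z·1.007276)/z.
The only variable modification considered is Met oxidation
(+15.99491 Da), the one modification required to reconcile the
Met-containing rows of the packaged identification table; the best
0..n_Met fit per row is reported. Mapping is exact substring search
(all occurrences; a tryptic-context flag is informational, never a
filter; peptides matching several input proteins are flagged ambiguous
since they cannot identify a single gene product). Coverage is the
residue-union fraction; the packaged table's printed ranges union to
75/202 = 37.1% while its printed coverage is 36.5% (≈ 74/202) — an
off-by-one against the vendor software's unknown counting convention,
reported as a deviation rather than reconciled by guessing. pI is
computed by bisection on the Henderson–Hasselbalch net-charge curve
with the EMBOSS pKa set (shipped as data); vendor pI values derive from
other pKa sets and agree only to a few tenths of a unit.

The packaged protein FASTA is a synthetic 202-aa scaffold embedding the
eight identified peptides at their reported ranges (filler elsewhere);
the real protein sequence is not distributed with the package, so
sequence-global quantities (total mass, pI, whole-protein identity) are
computed but not meaningful for comparison.

## Problem sizes and determinism

Default test/workload sizes are deliberately modest — toy genomes of
3 × 5–10 kb, transcripts of 0.6–3.5 knt, 4–13 taxa, bootstrap counts of
25–200 in examples (1000 remains the CLI default), 200 neutral codons
for the type-I-error check — sizes at which every closed loop and every
oracle comparison is exact or tightly bounded. All randomness flows
from explicit `numpy.random.default_rng` seeds; with a fixed seed every
output is byte-identical across runs.
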