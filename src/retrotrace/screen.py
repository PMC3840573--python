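"""Finding retroposed copies of a parental mRNA in genomic sequence.

Candidates are located by exact k-mer seeding on both strands followed by
local (Smith–Waterman) alignment of the parental mRNA against the seeded
window; each hit carries its aligned column pairs plus percent similarity
and coverage of the mRNA and of its CDS. Two retention filters mirror the
two stages of a database screen: a permissive retrieval filter
(similarity > 60 and mRNA coverage > 35, both strict) and a stricter
filter for sequences entering a phylogenetic alignment (CDS coverage > 85
and similarity > 60).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

_NUCS = set("ACGT")


@dataclass
class ParentalTranscript:
    """Parental mRNA with its CDS interval (1-based inclusive) and polyA signals."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    polyA_signal_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not (1 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"CDS interval [{self.cds_start}, {self.cds_end}] outside "
                f"transcript of length {len(self.sequence)}"
            )
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    def cds_coverage_of_mrna(self) -> float:
        """Percent of the mRNA occupied by the CDS (e.g. 618/3475 -> 17.78)."""
        return 100.0 * self.cds_length / self.length


@dataclass
class PseudogeneCandidate:
    """A genomic hit to the parental mRNA.

    ``aligned_pairs`` maps 1-based parental mRNA positions to 1-based
    positions in ``sequence``, the genomic segment re-oriented to read in
    parental-mRNA direction. ``genomic_interval`` stays in plus-strand
    chromosome coordinates.
    """

    id: str
    taxon: str
    chromosome: str
    start: int  # 1-based inclusive, plus strand
    end: int
    strand: str  # '+' or '-'
    sequence: str  # oriented genomic segment covering the alignment
    aligned_pairs: list[tuple[int, int]]
    score: float = 0.0
    similarity: float = 0.0
    coverage_mrna: float = 0.0
    coverage_cds: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_q = prev_s = 0
        for q, s in self.aligned_pairs:
            if q <= prev_q or s <= prev_s:
                raise ValueError("aligned positions must be strictly increasing")
            prev_q, prev_s = q, s

    def downstream_sequence(self, genome: Mapping[str, str], n: int = 50) -> str:
        """Genomic sequence immediately 3' of the hit, in mRNA orientation."""
        chrom = _as_chroms(genome)[self.chromosome]
        if self.strand == "+":
            return chrom[self.end : self.end + n]
        seg = chrom[max(0, self.start - 1 - n) : self.start - 1]
        return str(Seq(seg).reverse_complement())

    def first_aligned_mrna_position(self) -> int:
        return self.aligned_pairs[0][0]

    def last_aligned_mrna_position(self) -> int:
        return self.aligned_pairs[-1][0]


def _as_chroms(genome) -> dict[str, str]:
    if hasattr(genome, "chroms"):
        genome = genome.chroms
    return {name: str(seq).upper() for name, seq in dict(genome).items()}


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= _NUCS:
            index.setdefault(kmer, []).append(i)
    return index


def _seed_clusters(
    chrom_seq: str, index: dict[str, list[int]], k: int, band: int, tlen: int
) -> list[list[tuple[int, int]]]:
    """Group (genome_pos, transcript_pos) seeds by diagonal and locality."""
    seeds: list[tuple[int, int, int]] = []  # (diag, gpos, qpos)
    for g in range(len(chrom_seq) - k + 1):
        kmer = chrom_seq[g : g + k]
        for q in index.get(kmer, ()):
            seeds.append((g - q, g, q))
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    last_diag = last_g = None
    for diag, g, q in seeds:
        if (
            current
            and abs(diag - last_diag) <= band
            and g - last_g <= tlen
        ):
            current.append((g, q))
        else:
            if current:
                clusters.append(current)
            current = [(g, q)]
        last_diag, last_g = diag, g
    if current:
        clusters.append(current)
    return clusters


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def search_hits(
    genome,
    transcript: ParentalTranscript,
    seed_k: int = 11,
    min_score: float = 40.0,
    min_seeds: int = 2,
    taxon: str = "",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    band: int = 100,
) -> list[PseudogeneCandidate]:
    """Candidate pseudogene loci in a genome, both strands.

    Seeds are exact ``seed_k``-mers shared with the parental mRNA, grouped
    by alignment diagonal; groups with at least ``min_seeds`` seeds are
    extended by local alignment and kept when the alignment score reaches
    ``min_score``. Overlapping hits are resolved greedily, highest score
    first. Hits on the minus strand are reported in mRNA orientation with
    plus-strand genomic intervals.
    """
    if seed_k < 8:
        raise ValueError("seed_k must be >= 8")
    chroms = _as_chroms(genome)
    tseq = transcript.sequence
    index = _kmer_index(tseq, seed_k)
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    raw: list[PseudogeneCandidate] = []
    for chrom_name in sorted(chroms):
        chrom_seq = chroms[chrom_name]
        L = len(chrom_seq)
        for strand in "+-":
            oriented = (
                chrom_seq if strand == "+" else str(Seq(chrom_seq).reverse_complement())
            )
            for cluster in _seed_clusters(
                oriented, index, seed_k, band, transcript.length
            ):
                if len(cluster) < min_seeds:
                    continue
                g_lo = min(g for g, _ in cluster)
                g_hi = max(g for g, _ in cluster) + seed_k
                q_lo = min(q for _, q in cluster)
                q_hi = max(q for _, q in cluster) + seed_k
                margin = 100
                w_start = max(0, g_lo - q_lo - margin)
                w_end = min(len(oriented), g_hi + (transcript.length - q_hi) + margin)
                window = oriented[w_start:w_end]
                alignments = aligner.align(window, tseq)
                try:
                    # len() can overflow: co-optimal paths grow combinatorially
                    aln = alignments[0]
                except IndexError:
                    continue
                if aln.score < min_score:
                    continue
                pairs: list[tuple[int, int]] = []  # (mrna 1-based, oriented-genome 0-based)
                for (t0, t1), (q0, q1) in zip(*aln.aligned):
                    for off in range(t1 - t0):
                        pairs.append((q0 + off + 1, w_start + t0 + off))
                if not pairs:
                    continue
                seg_lo = pairs[0][1]
                seg_hi = pairs[-1][1] + 1
                segment = oriented[seg_lo:seg_hi]
                rel_pairs = [(q, g - seg_lo + 1) for q, g in pairs]
                if strand == "+":
                    start, end = seg_lo + 1, seg_hi
                else:
                    start, end = L - seg_hi + 1, L - seg_lo
                cand = PseudogeneCandidate(
                    id="",
                    taxon=taxon,
                    chromosome=chrom_name,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=segment,
                    aligned_pairs=rel_pairs,
                    score=float(aln.score),
                )
                (
                    cand.similarity,
                    cand.coverage_mrna,
                    cand.coverage_cds,
                ) = similarity_and_coverage(cand, transcript)
                raw.append(cand)
    # greedy non-overlap resolution, highest score first
    raw.sort(key=lambda c: (-c.score, c.chromosome, c.start, c.strand))
    kept: list[PseudogeneCandidate] = []
    for cand in raw:
        clash = any(
            k.chromosome == cand.chromosome
            and not (cand.end < k.start or cand.start > k.end)
            for k in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.chromosome, c.start))
    for i, cand in enumerate(kept, start=1):
        cand.id = f"{taxon + '_' if taxon else ''}hit{i}"
    return kept


def similarity_and_coverage(
    candidate: PseudogeneCandidate, transcript: ParentalTranscript
) -> tuple[float, float, float]:
    """(similarity, mRNA coverage, CDS coverage), all percentages.

    Similarity counts identical aligned columns over aligned columns (gap
    columns excluded); coverage counts distinct parental positions aligned,
    against the mRNA length and the CDS length respectively.
    """
    if not candidate.aligned_pairs:
        raise ValueError("candidate has no aligned pairs")
    ident = 0
    qpos_seen: set[int] = set()
    for q, s in candidate.aligned_pairs:
        qpos_seen.add(q)
        if transcript.sequence[q - 1] == candidate.sequence[s - 1]:
            ident += 1
    similarity = 100.0 * ident / len(candidate.aligned_pairs)
    coverage_mrna = 100.0 * len(qpos_seen) / transcript.length
    cds_positions = sum(
        1 for q in qpos_seen if transcript.cds_start <= q <= transcript.cds_end
    )
    coverage_cds = 100.0 * cds_positions / transcript.cds_length
    return similarity, coverage_mrna, coverage_cds


def filter_retrieval(
    candidates: Iterable[PseudogeneCandidate],
) -> list[PseudogeneCandidate]:
    """Retrieval filter: similarity > 60 and mRNA coverage > 35 (strict)."""
    return [c for c in candidates if c.similarity > 60.0 and c.coverage_mrna > 35.0]


def filter_phylo_set(
    candidates: Iterable[PseudogeneCandidate],
) -> list[PseudogeneCandidate]:
    """Alignment-set filter: CDS coverage > 85 and similarity > 60 (strict)."""
    return [c for c in candidates if c.coverage_cds > 85.0 and c.similarity > 60.0]


def candidates_to_table(candidates: Sequence[PseudogeneCandidate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": c.id, "taxon": c.taxon, "chr": c.chromosome,
                "start": c.start, "end": c.end, "strand": c.strand,
                "score": c.score,
                "similarity": round(c.similarity, 2),
                "coverage_mrna": round(c.coverage_mrna, 2),
                "coverage_cds": round(c.coverage_cds, 2),
            }
            for c in candidates
        ]
    )
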