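"""Classifying pseudogene candidates and assessing their coding potential.

A retroposed (processed) copy is recognized by the hallmarks of
reverse transcription of a mature mRNA: no introns, a truncated 5'UTR
(the reverse transcriptase rarely reaches the cap) and a genomic polyA
tract, landing on a chromosome away from the source gene. A segmental
(duplicated) copy instead lies near its source or retains introns — and
that rule wins when both could fire, because tandem duplication of an
existing processed pseudogene produces exactly such a conflicted copy.

Coding potential is assessed by walking the parental reading frame
through the candidate's alignment (frameshifts, premature stops, lost
start), by the Kozak context of the start codon, and by the presence of
polyadenylation signals (AATAAA/ATTAAA) and a downstream A-run standing
in for a dedicated polyA-site predictor.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .screen import ParentalTranscript, PseudogeneCandidate

POLYA_MOTIFS = ("AATAAA", "ATTAAA")
_POLYA_RE = re.compile(r"(?=(AATAAA|ATTAAA))")

PROCESSED = "processed"
DUPLICATED = "duplicated"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named chromosome."""

    chromosome: str
    start: int
    end: int
    name: str = ""
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge separation in bp; 0 when overlapping; None across chromosomes."""
        if self.chromosome != other.chromosome:
            return None
        if self.end < other.start:
            return other.start - self.end - 1
        if other.end < self.start:
            return self.start - other.end - 1
        return 0


@dataclass
class PseudogeneAnnotation:
    candidate_id: str
    classification: str
    intronless: bool
    polyA_trait: bool
    polyA_trait_position: int | None
    utr5_truncated: bool
    utr5_truncation_extent: int
    utr3_extent: int
    same_chromosome_as_parent: bool
    distance_to_parent_or_paralog: int | None
    polyA_signals: list[tuple[str, int]]
    kozak_conserved: bool
    orf_status: str
    disabling_positions: list[int]
    distance_to_nearest_gene: int | None = None


def classify(
    candidate_interval: GenomicInterval,
    parent_locus: GenomicInterval,
    paralog_loci: Sequence[GenomicInterval] = (),
    *,
    has_introns: bool,
    polyA_trait: bool,
    utr5_truncated: bool,
    nearby_window: int = 1_000_000,
) -> str:
    """Processed / duplicated / ambiguous call for one candidate.

    Duplicated: same chromosome as the parent or an existing paralog and
    within ``nearby_window`` bp of it, and/or introns present. Processed:
    different chromosome from the parent, polyA trait, truncated 5'UTR,
    no introns. The duplicated rule takes precedence; when neither rule
    fires the candidate is reported ambiguous, never silently coerced.
    """
    near_source = False
    for locus in [parent_locus, *paralog_loci]:
        d = candidate_interval.distance_to(locus)
        if d is not None and d <= nearby_window:
            near_source = True
            break
    if near_source or has_introns:
        return DUPLICATED
    if (
        candidate_interval.chromosome != parent_locus.chromosome
        and polyA_trait
        and utr5_truncated
        and not has_introns
    ):
        return PROCESSED
    return AMBIGUOUS


def detect_polyA_trait(
    downstream_seq: str, min_run: int = 8, window: int = 50
) -> tuple[bool, int | None]:
    """A-run test for a genomic polyA tract downstream of the aligned 3' end.

    True iff a run of >= ``min_run`` consecutive A occurs within the first
    ``window`` nt; returns the 1-based start of the first such run. This is
    a reproducible stand-in for a dedicated polyA-site predictor.
    """
    if window < min_run:
        raise ValueError("window must be >= min_run")
    hay = downstream_seq.upper()[:window]
    pos = hay.find("A" * min_run)
    return (pos >= 0, pos + 1 if pos >= 0 else None)


def detect_polyA_signals(seq: str) -> list[tuple[str, int]]:
    """All AATAAA/ATTAAA occurrences (overlaps included), 1-based starts."""
    return [(m.group(1), m.start() + 1) for m in _POLYA_RE.finditer(seq.upper())]


def kozak_conserved(seq: str, atg_pos: int) -> bool:
    """Kozak context check at a start codon: A/G at -3 and G at +4.

    ``atg_pos`` is the 1-based position of the A of ATG; positions are
    numbered with A = +1, so -3 is three bases upstream and +4 the base
    after the codon. Insufficient flanking context yields False with a
    warning rather than an error.
    """
    seq = seq.upper()
    if atg_pos < 4 or atg_pos + 3 > len(seq):
        warnings.warn("insufficient context around ATG for a Kozak call")
        return False
    return seq[atg_pos - 4] in "AG" and seq[atg_pos + 2] == "G"


def distance_to_nearest_gene(
    candidate: GenomicInterval, genes: Iterable[GenomicInterval]
) -> int | None:
    """Edge-to-edge bp to the closest non-pseudogene gene on the chromosome.

    Pseudogene neighbors are ignored even when closer. Returns None (a
    missing value, not zero) when the chromosome carries no eligible gene.
    """
    dists = [
        candidate.distance_to(g)
        for g in genes
        if not g.is_pseudogene and g.chromosome == candidate.chromosome
    ]
    dists = [d for d in dists if d is not None]
    return min(dists) if dists else None


def read_genes_bed(path, pseudogene_names: set[str] | None = None) -> list[GenomicInterval]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    out = []
    pseudogene_names = pseudogene_names or set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            out.append(
                GenomicInterval(
                    chromosome=chrom,
                    start=start + 1,  # BED start is 0-based
                    end=end,  # BED end is exclusive == 1-based inclusive end
                    name=name,
                    is_pseudogene=name in pseudogene_names or "pseudogene" in name.lower(),
                )
            )
    return out


def _cds_alignment_events(
    pairs: Sequence[tuple[int, int]], cds_start: int, cds_end: int
) -> list[tuple[int, int]]:
    """Pairs restricted to the parental CDS window."""
    return [(q, s) for q, s in pairs if cds_start <= q <= cds_end]


def assess_orf(
    candidate: PseudogeneCandidate, transcript: ParentalTranscript
) -> tuple[str, list[int]]:
    """Walk the parental reading frame through the candidate's alignment.

    Returns (status, disabling codon indices). Indels whose lengths differ
    by a non-multiple of 3 shift the frame (``frameshift``); an in-frame
    stop before the parental stop is ``premature_stop`` with its codon
    index; a lost or mutated start ATG is ``no_orf``; otherwise ``intact``.
    """
    pairs = _cds_alignment_events(
        candidate.aligned_pairs, transcript.cds_start, transcript.cds_end
    )
    if not pairs:
        return "no_orf", []
    # frame disruptions: net indel length per event must be a multiple of 3
    frameshifts: list[int] = []
    prev_q, prev_s = pairs[0]
    for q, s in pairs[1:]:
        dq = q - prev_q - 1  # parental bases deleted from the candidate
        ds = s - prev_s - 1  # candidate bases inserted
        if (dq - ds) % 3 != 0:
            # codon of the first affected parental base
            codon = (prev_q + 1 - transcript.cds_start) // 3 + 1
            frameshifts.append(codon)
        prev_q, prev_s = q, s
    if frameshifts:
        return "frameshift", frameshifts
    # start codon must be present and be ATG
    if pairs[0][0] != transcript.cds_start:
        return "no_orf", []
    smap = dict(pairs)
    start_bases = [smap.get(transcript.cds_start + i) for i in range(3)]
    if any(b is None for b in start_bases):
        return "no_orf", []
    if "".join(candidate.sequence[s - 1] for s in start_bases) != "ATG":
        return "no_orf", []
    # reconstruct the candidate ORF (in-frame indels preserved)
    orf_chars: list[str] = [candidate.sequence[pairs[0][1] - 1]]
    prev_q, prev_s = pairs[0]
    for q, s in pairs[1:]:
        if s - prev_s > 1:  # in-frame insertion
            orf_chars.extend(candidate.sequence[prev_s : s - 1])
        orf_chars.append(candidate.sequence[s - 1])
        prev_q, prev_s = q, s
    orf = "".join(orf_chars)
    orf = orf[: len(orf) // 3 * 3]
    protein = str(Seq(orf).translate())
    reaches_parental_stop = pairs[-1][0] == transcript.cds_end
    stop_at = protein.find("*")
    if stop_at == -1:
        return "intact", []
    if reaches_parental_stop and stop_at == len(protein) - 1:
        return "intact", []
    return "premature_stop", [stop_at + 1]


def has_intron_like_insertions(
    pairs: Sequence[tuple[int, int]], min_intron_len: int = 50
) -> bool:
    """Insertions >= ``min_intron_len`` nt relative to the mRNA suggest introns."""
    prev_s = None
    for _, s in pairs:
        if prev_s is not None and s - prev_s - 1 >= min_intron_len:
            return True
        prev_s = s
    return False


def annotate_candidate(
    candidate: PseudogeneCandidate,
    genome: Mapping[str, str],
    transcript: ParentalTranscript,
    parent_locus: GenomicInterval,
    paralog_loci: Sequence[GenomicInterval] = (),
    genes: Sequence[GenomicInterval] = (),
    *,
    nearby_window: int = 1_000_000,
    polyA_min_run: int = 8,
    polyA_window: int = 50,
    min_intron_len: int = 50,
    has_introns: bool | None = None,
) -> PseudogeneAnnotation:
    """Full feature annotation + classification of one screened candidate.

    ``has_introns`` may be supplied from external evidence; by default
    intron presence is inferred from intron-sized insertions in the
    alignment (which cannot tell a retained intron from a later mobile
    element insertion — supply the flag when that distinction matters).
    """
    interval = GenomicInterval(candidate.chromosome, candidate.start, candidate.end)
    if has_introns is None:
        has_introns = has_intron_like_insertions(
            candidate.aligned_pairs, min_intron_len
        )
    trait, trait_pos = detect_polyA_trait(
        candidate.downstream_sequence(genome, polyA_window),
        polyA_min_run,
        polyA_window,
    )
    first_q = candidate.first_aligned_mrna_position()
    utr5_truncated = first_q > 1
    utr3_extent = max(0, candidate.last_aligned_mrna_position() - transcript.cds_end)
    # polyA signal occurrences mapped back to parental-mRNA coordinates
    q_by_s = {s: q for q, s in candidate.aligned_pairs}
    signals: list[tuple[str, int]] = []
    for motif, seg_pos in detect_polyA_signals(candidate.sequence):
        q = q_by_s.get(seg_pos)
        if q is not None:
            signals.append((motif, q))
    smap = dict(candidate.aligned_pairs)
    atg_s = smap.get(transcript.cds_start)
    kozak = kozak_conserved(candidate.sequence, atg_s) if atg_s else False
    orf_status, disabling = assess_orf(candidate, transcript)
    dists = [
        d
        for locus in [parent_locus, *paralog_loci]
        if (d := interval.distance_to(locus)) is not None
    ]
    classification = classify(
        interval,
        parent_locus,
        paralog_loci,
        has_introns=has_introns,
        polyA_trait=trait,
        utr5_truncated=utr5_truncated,
        nearby_window=nearby_window,
    )
    return PseudogeneAnnotation(
        candidate_id=candidate.id,
        classification=classification,
        intronless=not has_introns,
        polyA_trait=trait,
        polyA_trait_position=trait_pos,
        utr5_truncated=utr5_truncated,
        utr5_truncation_extent=first_q - 1,
        utr3_extent=utr3_extent,
        same_chromosome_as_parent=candidate.chromosome == parent_locus.chromosome,
        distance_to_parent_or_paralog=min(dists) if dists else None,
        polyA_signals=signals,
        kozak_conserved=kozak,
        orf_status=orf_status,
        disabling_positions=disabling,
        distance_to_nearest_gene=distance_to_nearest_gene(interval, genes)
        if genes
        else None,
    )
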