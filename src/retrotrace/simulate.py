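"""Retroposition simulator: synthetic transcripts, genomes and lineages.

Generates the full study scenario end to end with machine-readable truth:
a parental mRNA with UTRs, a Kozak-context CDS and polyadenylation
signals; a host genome carrying the parental gene (with introns);
retroposition events that insert 5'-truncated, polyA-tailed, intronless
copies at random positions; tandem duplications near existing loci; and
lineage evolution along a dated species tree with HKY-like substitutions,
indels, opaque labelled repeat insertions (Alu/L1-sized) and whole-copy
losses. Every event is recorded, and a gap-consistent true alignment of
all surviving copies is emitted, so each downstream stage (screening,
classification, phylogeny, dating, selection) can be scored against truth.

Rates are expressed per 100 My of branch length, the natural scale for
the multi-million-year divergences being emulated.
"""

from __future__ import annotations

import copy as _copylib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dating import DatedTree, TreeNode
from .screen import ParentalTranscript
from .annotate import GenomicInterval
from .selection import is_stop

_NUCS = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_REPEAT_FAMILIES = {"Alu": 300, "L1": 6000}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Transcript geometry defaults to the parental mRNA being emulated
    (376 nt 5'UTR + 618 nt CDS + 2481 nt 3'UTR = 3475 nt, four polyA
    signals). Substitution/indel rates are per site per 100 My; the
    substitution rate default (0.22) matches a typical mammalian neutral
    rate of ~2.2e-9 substitutions/site/year.
    """

    seed: int = 0
    n_taxa: int = 8
    utr5_len: int = 376
    cds_len: int = 618
    utr3_len: int = 2481
    n_polya_signals: int = 4
    trunc5_mean: float = 200.0
    polyA_tail_len: int = 30
    subst_rate: float = 0.22
    indel_rate: float = 0.02
    indel_mean_len: float = 3.0
    repeat_insert_rate: float = 0.0
    loss_rate: float = 0.0
    dup_probability: float = 0.1
    nearby_window: int = 1_000_000
    ts_tv_ratio: float = 2.0
    n_chromosomes: int = 3
    chromosome_length: int = 10_000
    n_introns: int = 2
    intron_len: int = 300

    def __post_init__(self) -> None:
        if self.cds_len % 3 != 0:
            raise ValueError(
                f"cds_len must be divisible by 3, got {self.cds_len}: codons "
                "are triplets and a partial codon has no reading frame"
            )
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError("lengths must be non-negative")
        for name in ("subst_rate", "indel_rate", "repeat_insert_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Genome:
    """Plain nucleotide chromosomes keyed by name."""

    chroms: dict[str, str]

    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())


@dataclass
class TruthRecord:
    """Ground truth for one simulated event."""

    event_id: int
    event_kind: str  # retroposition | duplication | loss | repeat_insertion | deletion
    donor_branch: str
    copy_id: str
    insertion_chromosome: str | None = None
    insertion_position: int | None = None  # 1-based
    trunc5_extent: int = 0
    has_polyA_tail: bool = False
    retains_introns: bool = False
    strand: str = "+"
    length: int = 0
    detail: str = ""

    def __post_init__(self) -> None:
        if self.event_kind == "retroposition":
            assert not self.retains_introns and self.has_polyA_tail

    def to_row(self) -> dict:
        return {
            "event_id": self.event_id,
            "event_kind": self.event_kind,
            "donor_branch": self.donor_branch,
            "copy_id": self.copy_id,
            "insertion_chromosome": self.insertion_chromosome,
            "insertion_position": self.insertion_position,
            "trunc5_extent": self.trunc5_extent,
            "has_polyA_tail": self.has_polyA_tail,
            "retains_introns": self.retains_introns,
            "strand": self.strand,
            "length": self.length,
            "detail": self.detail,
        }


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NUCS), size=n)) if n else ""


def _random_nonstop_codon(rng: np.random.Generator, first_base: str | None = None) -> str:
    while True:
        codon = (first_base or rng.choice(list(_NUCS))) + _random_seq(rng, 2)
        if codon not in _STOPS:
            return codon


def simulate_parental_transcript(
    config: SimulationConfig, rng: np.random.Generator
) -> ParentalTranscript:
    """Random parental mRNA with the configured UTR/CDS geometry.

    The CDS starts with ATG in a Kozak context (A/G at -3, G at +4), ends
    with a stop codon and contains no internal in-frame stop; the 3'UTR
    carries the configured number of polyadenylation signals, the last of
    them near the transcript terminus. All signal occurrences (planted or
    arising by chance) are scanned and recorded.
    """
    if config.utr5_len < 3:
        raise ValueError("utr5_len must be >= 3: the Kozak context needs 3 nt upstream of ATG")
    if config.cds_len < 9:
        raise ValueError("cds_len must be >= 9 (start + one codon + stop)")
    utr5 = list(_random_seq(rng, config.utr5_len))
    utr5[-3] = rng.choice(["A", "G"])  # Kozak -3 purine
    n_codons = config.cds_len // 3
    codons = ["ATG", _random_nonstop_codon(rng, first_base="G")]  # Kozak +4 G
    for _ in range(n_codons - 3):
        codons.append(_random_nonstop_codon(rng))
    codons.append(rng.choice(list(_STOPS)))
    cds = "".join(codons)
    utr3 = list(_random_seq(rng, config.utr3_len))
    if config.n_polya_signals > 0:
        if config.utr3_len < 10 * config.n_polya_signals:
            raise ValueError("utr3_len too short for the requested polyA signals")
        # space signals through the 3'UTR, last one near the terminus
        anchors = np.linspace(
            config.utr3_len // 3, config.utr3_len - 8, config.n_polya_signals
        ).astype(int)
        for a in anchors:
            motif = rng.choice(["AATAAA", "ATTAAA"])
            utr3[a : a + 6] = list(motif)
    sequence = "".join(utr5) + cds + "".join(utr3)
    from .annotate import detect_polyA_signals

    positions = [pos for _, pos in detect_polyA_signals(sequence)]
    return ParentalTranscript(
        id="parental_mRNA",
        sequence=sequence,
        cds_start=config.utr5_len + 1,
        cds_end=config.utr5_len + config.cds_len,
        polyA_signal_positions=positions,
    )


def random_genome(config: SimulationConfig, rng: np.random.Generator) -> Genome:
    return Genome(
        chroms={
            f"chr{i + 1}": _random_seq(rng, config.chromosome_length)
            for i in range(config.n_chromosomes)
        }
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def draw_truncation(config: SimulationConfig, transcript: ParentalTranscript,
                    rng: np.random.Generator) -> int:
    """5'-truncation length: geometric (support >= 1), capped to keep >= 50% CDS."""
    if config.trunc5_mean <= 0:
        return 0
    cap = (transcript.cds_start - 1) + transcript.cds_length // 2
    t = int(rng.geometric(min(1.0, 1.0 / config.trunc5_mean)))
    return min(t, cap)


def retropose(
    transcript: ParentalTranscript,
    genome: Genome,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    trunc5: int | None = None,
    strand: str | None = None,
    avoid: GenomicInterval | None = None,
    donor_branch: str = "root",
    copy_id: str = "retro1",
    event_id: int = 1,
) -> tuple[Genome, TruthRecord]:
    """Insert one processed copy (truncated 5', polyA tail) into the genome.

    The insertion point is uniform over the genome; when ``avoid`` is given
    positions within ``nearby_window`` of that locus are rejected, emulating
    the near-zero probability of landing next to the source in a genome
    many orders of magnitude larger than the simulated one.
    """
    if not genome.chroms or genome.total_length() == 0:
        raise ValueError("genome is empty")
    if trunc5 is None:
        trunc5 = draw_truncation(config, transcript, rng)
    copy_seq = transcript.sequence[trunc5:] + "A" * config.polyA_tail_len
    if strand is None:
        strand = rng.choice(["+", "-"])
    names = sorted(genome.chroms)
    for _ in range(200):
        chrom = names[int(rng.integers(0, len(names)))]
        pos = int(rng.integers(0, len(genome.chroms[chrom]) + 1))
        if avoid is not None and avoid.chromosome == chrom:
            lo = avoid.start - config.nearby_window
            hi = avoid.end + config.nearby_window
            if lo <= pos + 1 <= hi:
                continue
        break
    inserted = copy_seq if strand == "+" else _revcomp(copy_seq)
    seq = genome.chroms[chrom]
    new = dict(genome.chroms)
    new[chrom] = seq[:pos] + inserted + seq[pos:]
    record = TruthRecord(
        event_id=event_id,
        event_kind="retroposition",
        donor_branch=donor_branch,
        copy_id=copy_id,
        insertion_chromosome=chrom,
        insertion_position=pos + 1,
        trunc5_extent=trunc5,
        has_polyA_tail=True,
        retains_introns=False,
        strand=strand,
        length=len(copy_seq),
    )
    return Genome(chroms=new), record


def duplicate_locus(
    genome: Genome,
    locus: GenomicInterval,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    source_record: TruthRecord | None = None,
    source_has_introns: bool = False,
    donor_branch: str = "root",
    copy_id: str = "dup1",
    event_id: int = 1,
) -> tuple[Genome, TruthRecord]:
    """Tandem-duplicate a locus to within ``nearby_window`` bp on its chromosome."""
    seq = genome.chroms.get(locus.chromosome)
    if seq is None or locus.end > len(seq):
        raise ValueError(f"locus {locus} outside genome bounds")
    segment = seq[locus.start - 1 : locus.end]
    offset = int(rng.integers(-config.nearby_window, config.nearby_window + 1))
    pos = locus.end + offset
    pos = max(0, min(len(seq), pos))
    if locus.start - 1 < pos < locus.end:
        pos = locus.end  # never split the source: fall back to adjacent
    new = dict(genome.chroms)
    new[locus.chromosome] = seq[:pos] + segment + seq[pos:]
    retains = source_has_introns or (
        source_record is not None and source_record.retains_introns
    )
    record = TruthRecord(
        event_id=event_id,
        event_kind="duplication",
        donor_branch=donor_branch,
        copy_id=copy_id,
        insertion_chromosome=locus.chromosome,
        insertion_position=pos + 1,
        trunc5_extent=source_record.trunc5_extent if source_record else 0,
        has_polyA_tail=source_record.has_polyA_tail if source_record else False,
        retains_introns=retains,
        strand=source_record.strand if source_record else "+",
        length=len(segment),
    )
    return Genome(chroms=new), record


# ---------------------------------------------------------------------------
# lineage evolution with column-tracked copies


@dataclass
class _CopyState:
    copy_id: str
    kind: str  # parental_gene | retroposition | duplication
    strand: str
    cols: list[list]  # [column_id, base]
    has_introns: bool
    has_polyA_tail: bool
    trunc5_extent: int
    lost: bool = False


@dataclass
class PlannedEvent:
    """An event scheduled on a named branch ('root' = in the ancestor)."""

    kind: str  # retroposition | duplication | loss
    branch: str
    name: str | None = None
    source_copy: str | None = None


@dataclass
class AncestralGenome:
    """Root-lineage state: background chromosome pieces + tracked copies."""

    segments: dict[str, list]  # chrom -> list of str | _CopyState
    transcript: ParentalTranscript
    master_columns: list[int]
    next_column: int
    parent_locus: GenomicInterval


@dataclass
class SimulationResult:
    genomes: dict[str, Genome]
    copy_locations: pd.DataFrame
    alignment: dict[str, str]
    presence: pd.DataFrame
    truth: list[TruthRecord]
    branch_substitutions: dict[tuple[str, str], int]
    tree: DatedTree
    transcript: ParentalTranscript
    config: SimulationConfig

    def presence_states(self, copy_id: str) -> dict[str, str]:
        return self.presence[copy_id].to_dict()


def build_ancestral_genome(
    transcript: ParentalTranscript,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AncestralGenome:
    """Host genome whose chr1 carries the parental gene (CDS split by introns)."""
    genome = random_genome(config, rng)
    L = transcript.length
    master = list(range(L))
    next_col = L
    gene_cols: list[list] = [[i, transcript.sequence[i]] for i in range(L)]
    # insert introns inside the CDS (fresh columns)
    if config.n_introns > 0:
        cds0 = transcript.cds_start - 1
        cut_points = np.linspace(
            cds0 + 30, transcript.cds_end - 30, config.n_introns
        ).astype(int)
        for cut in sorted(cut_points, reverse=True):
            intron_ids = list(range(next_col, next_col + config.intron_len))
            intron = [[cid, b] for cid, b in zip(intron_ids, _random_seq(rng, config.intron_len))]
            anchor_idx = master.index(gene_cols[cut - 1][0]) + 1
            master[anchor_idx:anchor_idx] = intron_ids
            next_col += config.intron_len
            gene_cols[cut:cut] = intron
    gene = _CopyState(
        copy_id="parental",
        kind="parental_gene",
        strand="+",
        cols=gene_cols,
        has_introns=config.n_introns > 0,
        has_polyA_tail=False,
        trunc5_extent=0,
    )
    chr1 = genome.chroms["chr1"]
    pos = len(chr1) // 2
    segments: dict[str, list] = {
        name: [seq] for name, seq in genome.chroms.items()
    }
    segments["chr1"] = [chr1[:pos], gene, chr1[pos:]]
    parent_locus = GenomicInterval(
        "chr1", pos + 1, pos + len(gene_cols), name="parental", is_pseudogene=False
    )
    return AncestralGenome(
        segments=segments,
        transcript=transcript,
        master_columns=master,
        next_column=next_col,
        parent_locus=parent_locus,
    )


def _lineage_copies(segments: dict[str, list]) -> dict[str, _CopyState]:
    out = {}
    for parts in segments.values():
        for part in parts:
            if isinstance(part, _CopyState):
                out[part.copy_id] = part
    return out


class _Evolver:
    def __init__(self, ancestor: AncestralGenome, tree: DatedTree,
                 config: SimulationConfig, rng: np.random.Generator):
        self.tree = tree
        self.config = config
        self.rng = rng
        self.transcript = ancestor.transcript
        self.master = list(ancestor.master_columns)
        self.next_col = ancestor.next_column
        self.truth: list[TruthRecord] = []
        self.branch_subs: dict[tuple[str, str], int] = {}
        self.leaf_segments: dict[str, dict[str, list]] = {}
        self.event_counter = 0
        self.copy_counter = 0
        self.ever_created: list[str] = []
        self._ancestor = ancestor
        self._parent_chrom = ancestor.parent_locus.chromosome

    # -- low-level helpers ------------------------------------------------
    def _new_event_id(self) -> int:
        self.event_counter += 1
        return self.event_counter

    def _fresh_cols(self, n: int, anchor: int | None) -> list[int]:
        ids = list(range(self.next_col, self.next_col + n))
        self.next_col += n
        if anchor is None:
            idx = 0
        else:
            idx = self.master.index(anchor) + 1
        self.master[idx:idx] = ids
        return ids

    def _substitute_base(self, base: str) -> str:
        kappa = self.config.ts_tv_ratio
        if self.rng.random() < kappa / (kappa + 2.0):
            return _TRANSITION[base] if base in _TRANSITION else base
        choices = [b for b in _NUCS if b != base and b != _TRANSITION.get(base)]
        return choices[int(self.rng.integers(0, len(choices)))]

    def _mutate_copy(self, cp: _CopyState, branch: str, blen: float) -> None:
        cfg, rng = self.config, self.rng
        L = len(cp.cols)
        if L == 0:
            return
        n_sub = int(rng.poisson(cfg.subst_rate / 100.0 * blen * L))
        for _ in range(n_sub):
            i = int(rng.integers(0, len(cp.cols)))
            cp.cols[i][1] = self._substitute_base(cp.cols[i][1])
        key = (branch, cp.copy_id)
        self.branch_subs[key] = self.branch_subs.get(key, 0) + n_sub
        n_indel = int(rng.poisson(cfg.indel_rate / 100.0 * blen * L))
        for _ in range(n_indel):
            if not cp.cols:
                break
            length = int(rng.geometric(min(1.0, 1.0 / cfg.indel_mean_len)))
            i = int(rng.integers(0, len(cp.cols)))
            if rng.random() < 0.5:  # deletion
                removed = cp.cols[i : i + length]
                del cp.cols[i : i + length]
                self.truth.append(TruthRecord(
                    event_id=self._new_event_id(), event_kind="deletion",
                    donor_branch=branch, copy_id=cp.copy_id,
                    length=len(removed), detail=f"at_index={i}",
                ))
            else:  # insertion
                anchor = cp.cols[i - 1][0] if i > 0 else None
                ids = self._fresh_cols(length, anchor)
                cp.cols[i:i] = [[cid, b] for cid, b in zip(ids, _random_seq(rng, length))]
        n_rep = int(rng.poisson(cfg.repeat_insert_rate / 100.0 * blen))
        for _ in range(n_rep):
            family = ["Alu", "L1"][int(rng.integers(0, 2))]
            length = _REPEAT_FAMILIES[family]
            i = int(rng.integers(0, len(cp.cols) + 1))
            anchor = cp.cols[i - 1][0] if i > 0 else None
            ids = self._fresh_cols(length, anchor)
            cp.cols[i:i] = [[cid, b] for cid, b in zip(ids, _random_seq(rng, length))]
            self.truth.append(TruthRecord(
                event_id=self._new_event_id(), event_kind="repeat_insertion",
                donor_branch=branch, copy_id=cp.copy_id,
                length=length, detail=family,
            ))

    def _insert_copy(self, segments: dict[str, list], cp: _CopyState,
                     avoid_parent: bool) -> tuple[str, int]:
        """Place a copy into a lineage's segment lists at a random point."""
        rng = self.rng
        names = sorted(segments)
        # toy-scale surrogate for "far from the source locus": in a genome
        # orders of magnitude smaller than a real one, a uniform draw would
        # often land beside the parental gene, so the parent's chromosome is
        # excluded whenever another chromosome exists
        if avoid_parent and len(names) > 1:
            names = [n for n in names if n != self._parent_chrom]
        for _ in range(200):
            chrom = names[int(rng.integers(0, len(names)))]
            parts = segments[chrom]
            bg_idx = [k for k, p in enumerate(parts) if isinstance(p, str)]
            if not bg_idx:
                continue
            k = bg_idx[int(rng.integers(0, len(bg_idx)))]
            off = int(rng.integers(0, len(parts[k]) + 1))
            parts[k : k + 1] = [parts[k][:off], cp, parts[k][off:]]
            pos = sum(
                len(p) if isinstance(p, str) else len(p.cols)
                for p in parts[: k + 1]
            )
            return chrom, pos + 1
        raise RuntimeError("could not place copy")

    def _new_retro_copy(self, branch: str, name: str | None) -> _CopyState:
        self.copy_counter += 1
        cid = name or f"retro{self.copy_counter}"
        trunc = draw_truncation(self.config, self.transcript, self.rng)
        cols = [[i, self.transcript.sequence[i]] for i in range(trunc, self.transcript.length)]
        tail_ids = self._fresh_cols(self.config.polyA_tail_len,
                                    anchor=self.transcript.length - 1)
        cols += [[cid_, "A"] for cid_ in tail_ids]
        strand = self.rng.choice(["+", "-"])
        return _CopyState(
            copy_id=cid, kind="retroposition", strand=strand, cols=cols,
            has_introns=False, has_polyA_tail=True, trunc5_extent=trunc,
        )

    def _apply_event(self, ev: PlannedEvent, segments: dict[str, list]) -> None:
        branch = ev.branch
        if ev.kind == "retroposition":
            cp = self._new_retro_copy(branch, ev.name)
            chrom, pos = self._insert_copy(segments, cp, avoid_parent=True)
            self.ever_created.append(cp.copy_id)
            self.truth.append(TruthRecord(
                event_id=self._new_event_id(), event_kind="retroposition",
                donor_branch=branch, copy_id=cp.copy_id,
                insertion_chromosome=chrom, insertion_position=pos,
                trunc5_extent=cp.trunc5_extent, has_polyA_tail=True,
                retains_introns=False, strand=cp.strand, length=len(cp.cols),
            ))
        elif ev.kind == "duplication":
            copies = _lineage_copies(segments)
            src = copies[ev.source_copy]
            self.copy_counter += 1
            cid = ev.name or f"dup{self.copy_counter}"
            dup = _CopyState(
                copy_id=cid, kind="duplication", strand=src.strand,
                cols=[[c, b] for c, b in src.cols],
                has_introns=src.has_introns, has_polyA_tail=src.has_polyA_tail,
                trunc5_extent=src.trunc5_extent,
            )
            # place adjacent to the source (same chromosome, nearby)
            for chrom, parts in segments.items():
                if src in parts:
                    parts.insert(parts.index(src) + 1, dup)
                    pos = sum(len(p) if isinstance(p, str) else len(p.cols)
                              for p in parts[: parts.index(dup)])
                    self.ever_created.append(cid)
                    self.truth.append(TruthRecord(
                        event_id=self._new_event_id(), event_kind="duplication",
                        donor_branch=ev.branch, copy_id=cid,
                        insertion_chromosome=chrom, insertion_position=pos + 1,
                        trunc5_extent=src.trunc5_extent,
                        has_polyA_tail=src.has_polyA_tail,
                        retains_introns=src.has_introns, strand=src.strand,
                        length=len(dup.cols),
                    ))
                    return
            raise ValueError(f"source copy {ev.source_copy!r} not in lineage")
        elif ev.kind == "loss":
            copies = _lineage_copies(segments)
            cp = copies[ev.source_copy]
            cp.lost = True
            for parts in segments.values():
                if cp in parts:
                    parts.remove(cp)
            self.truth.append(TruthRecord(
                event_id=self._new_event_id(), event_kind="loss",
                donor_branch=ev.branch, copy_id=cp.copy_id,
            ))
        else:
            raise ValueError(f"unknown planned event kind {ev.kind!r}")

    # -- main walk --------------------------------------------------------
    def run(self, events: Sequence[PlannedEvent]) -> None:
        by_branch: dict[str, list[PlannedEvent]] = {}
        for ev in events:
            by_branch.setdefault(ev.branch, []).append(ev)
        root_segments = _copylib.deepcopy(self._ancestor.segments)
        for ev in by_branch.get("root", []):
            self._apply_event(ev, root_segments)

        def descend(node: TreeNode, segments: dict[str, list]) -> None:
            if node.is_leaf:
                self.leaf_segments[node.name] = segments
                return
            for child in node.children:
                child_segments = _copylib.deepcopy(segments)
                blen = node.age - child.age
                for ev in by_branch.get(child.name, []):
                    self._apply_event(ev, child_segments)
                # stochastic losses, then sequence evolution
                for cp in list(_lineage_copies(child_segments).values()):
                    if self.config.loss_rate > 0 and self.rng.poisson(
                        self.config.loss_rate / 100.0 * blen
                    ) > 0:
                        self._apply_event(
                            PlannedEvent("loss", child.name, source_copy=cp.copy_id),
                            child_segments,
                        )
                for cp in _lineage_copies(child_segments).values():
                    self._mutate_copy(cp, child.name, blen)
                descend(child, child_segments)

        descend(self.tree.root, root_segments)


def evolve_along_tree(
    ancestor: AncestralGenome,
    tree: DatedTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    events: Sequence[PlannedEvent] = (),
) -> SimulationResult:
    """Evolve the ancestral genome down a dated tree and emit all truth.

    Planned events fire on their named branches ('root' = in the common
    ancestor, so every taxon inherits the copy); substitutions, indels,
    repeat insertions and losses are Poisson in branch length. The tree
    must be a :class:`~retrotrace.dating.DatedTree` (ultrametric by
    construction; any other input is rejected by its validator).
    """
    ev = _Evolver(ancestor, tree, config, rng)
    ev.run(events)
    # assemble leaf genomes and bookkeeping
    genomes: dict[str, Genome] = {}
    loc_rows = []
    presence_rows = {}
    copy_ids = list(dict.fromkeys(ev.ever_created))
    surviving: dict[tuple[str, str], _CopyState] = {}
    for taxon in tree.leaf_names:
        segments = ev.leaf_segments[taxon]
        chroms = {}
        for chrom in sorted(segments):
            pieces = []
            cursor = 0
            for part in segments[chrom]:
                if isinstance(part, str):
                    pieces.append(part)
                    cursor += len(part)
                else:
                    seq = "".join(b for _, b in part.cols)
                    if part.strand == "-":
                        seq = _revcomp(seq)
                    if part.kind != "parental_gene":
                        surviving[(taxon, part.copy_id)] = part
                    loc_rows.append({
                        "taxon": taxon, "copy_id": part.copy_id,
                        "kind": part.kind, "chromosome": chrom,
                        "start": cursor + 1, "end": cursor + len(seq),
                        "strand": part.strand,
                    })
                    pieces.append(seq)
                    cursor += len(seq)
            chroms[chrom] = "".join(pieces)
        genomes[taxon] = Genome(chroms=chroms)
        copies_here = _lineage_copies(segments)
        presence_rows[taxon] = {
            cid: "present" if cid in copies_here else "absent" for cid in copy_ids
        }
    presence = pd.DataFrame.from_dict(presence_rows, orient="index")
    presence.index.name = "taxon"
    # true alignment over the union of surviving copy columns
    used_cols = sorted(
        {c for cp in surviving.values() for c, _ in cp.cols},
        key=ev.master.index,
    )
    col_index = {c: i for i, c in enumerate(used_cols)}
    alignment: dict[str, str] = {}
    for (taxon, cid), cp in sorted(surviving.items()):
        row = ["-"] * len(used_cols)
        for c, b in cp.cols:
            row[col_index[c]] = b
        alignment[f"{taxon}|{cid}"] = "".join(row)
    parental_row = ["-"] * len(used_cols)
    for c in used_cols:
        if c < ancestor.transcript.length:
            parental_row[col_index[c]] = ancestor.transcript.sequence[c]
    alignment["parental|mRNA"] = "".join(parental_row)
    return SimulationResult(
        genomes=genomes,
        copy_locations=pd.DataFrame(loc_rows),
        alignment=alignment,
        presence=presence,
        truth=ev.truth,
        branch_substitutions=ev.branch_subs,
        tree=tree,
        transcript=ancestor.transcript,
        config=config,
    )


def ladder_tree(n_taxa: int, root_age: float = 100.0) -> DatedTree:
    """Deterministic ladder-shaped dated tree with evenly spaced node ages."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    leaves = [TreeNode(name=f"T{i + 1}", age=0.0) for i in range(n_taxa)]
    node = leaves[0]
    for i in range(1, n_taxa):
        age = root_age * i / (n_taxa - 1)
        parent = TreeNode(name=f"n{i}", age=age, children=[node, leaves[i]])
        node.parent = parent
        leaves[i].parent = parent
        node = parent
    return DatedTree(node)


def simulate_dataset(
    config: SimulationConfig,
    tree: DatedTree | None = None,
    events: Sequence[PlannedEvent] | None = None,
) -> SimulationResult:
    """One-call scenario: transcript, host genome, default events, evolution.

    With ``events`` unset, a copy is retroposed in the common ancestor
    (present in every taxon) and a second on the oldest internal branch,
    and the first copy is tandem-duplicated on the last leaf branch —
    a miniature of the gain histories the pipeline is meant to recover.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = ladder_tree(config.n_taxa)
    transcript = simulate_parental_transcript(config, rng)
    ancestor = build_ancestral_genome(transcript, config, rng)
    if events is None:
        internal = [
            n.name for n in tree.preorder() if not n.is_leaf and n.parent is not None
        ]
        events = [PlannedEvent("retroposition", branch="root", name="P1")]
        if internal:
            events.append(
                PlannedEvent("retroposition", branch=internal[0], name="P2")
            )
        last_leaf = tree.leaf_names[-1]
        events.append(
            PlannedEvent("duplication", branch=last_leaf, name="P1dup", source_copy="P1")
        )
    return evolve_along_tree(ancestor, tree, config, rng, events=events)


def replay_copy(result: SimulationResult, taxon: str, copy_id: str) -> str:
    """Extract a copy from the emitted genome by its recorded coordinates."""
    locs = result.copy_locations
    row = locs[(locs.taxon == taxon) & (locs.copy_id == copy_id)]
    if row.empty:
        raise KeyError(f"no copy {copy_id!r} in {taxon!r}")
    r = row.iloc[0]
    return result.genomes[taxon].chroms[r.chromosome][r.start - 1 : r.end]


def simulate_neutral_codon_alignment(
    tree: DatedTree,
    n_codons: int,
    rng: np.random.Generator,
    subst_rate: float = 0.3,
) -> dict[str, str]:
    """Codon alignment evolved with no selective constraint (omega = 1).

    Pure nucleotide substitution (every position equally mutable) with
    stop-creating changes redrawn, so extant sequences stay readable as
    codons while synonymous and non-synonymous changes occur at their
    neutral expectation. ``subst_rate`` is per site per 100 My.
    """
    root = "".join(
        _random_nonstop_codon(rng) for _ in range(n_codons)
    )
    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: str) -> None:
        if node.is_leaf:
            out[node.name] = seq
            return
        for child in node.children:
            blen = node.age - child.age
            s = list(seq)
            n_sub = int(rng.poisson(subst_rate / 100.0 * blen * len(s)))
            applied = 0
            guard = 0
            while applied < n_sub and guard < 100 * n_sub + 100:
                guard += 1
                i = int(rng.integers(0, len(s)))
                old = s[i]
                new = "ACGT"[int(rng.integers(0, 4))]
                if new == old:
                    continue
                s[i] = new
                codon_start = (i // 3) * 3
                if is_stop("".join(s[codon_start : codon_start + 3])):
                    s[i] = old
                    continue
                applied += 1
            descend(child, "".join(s))

    descend(tree.root, root)
    return out
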