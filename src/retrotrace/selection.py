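"""Site-wise selection scan on codon alignments (counting test + consensus).

The in-repo test is a SLAC-style counting procedure: ancestral sequences
are reconstructed by nucleotide-level Fitch parsimony on a given tree,
synonymous/non-synonymous opportunities are apportioned per branch with
Nei–Gojobori fractional site counting, and each codon site gets binomial
p-values for an excess (positive selection, dN > dS) or scarcity
(negative selection, dN < dS) of non-synonymous change.

Outputs of richer likelihood methods (FEL, REL, FUBAR, MEME) are consumed
as tabular site reports; only the published thresholding and the
two-methods consensus rule are applied to them here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.special import betainc

from .phylo import Clade, tree_from_newick

_NUCS = "ACGT"


def _codon_to_aa() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


_AA = _codon_to_aa()


def is_stop(codon: str) -> bool:
    return _AA.get(codon) == "*"


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment plus the tree relating its sequences."""

    sequences: dict[str, str]
    tree: Clade

    def __post_init__(self) -> None:
        if isinstance(self.tree, str):
            self.tree = tree_from_newick(self.tree)
        self.sequences = {n: s.upper() for n, s in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        if self.tree.leaf_names() != frozenset(self.sequences):
            raise ValueError("tree leaves must match alignment names")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def stop_violations(self) -> list[tuple[str, int]]:
        """(taxon, 1-based codon site) pairs with an in-frame stop codon."""
        out = []
        for name, seq in self.sequences.items():
            for site in range(self.n_sites):
                codon = seq[3 * site : 3 * site + 3]
                if is_stop(codon):
                    out.append((name, site + 1))
        return out


@dataclass
class Reconstruction:
    """Tree with every node (internal ones named anc1, anc2, ...) assigned a sequence."""

    tree: Clade
    states: dict[str, str]
    n_substitutions: int

    def branches(self) -> Iterable[tuple[str, str]]:
        """(parent name, child name) for every edge, preorder."""

        def walk(node: Clade):
            for c in node.children:
                yield node.name, c.name
                yield from walk(c)

        yield from walk(self.tree)


def _check_resolved(tree: Clade) -> None:
    def walk(node: Clade, is_root: bool) -> None:
        if node.children:
            limit = 3 if is_root else 2
            if len(node.children) > limit:
                raise ValueError("tree contains unresolved polytomies")
            for c in node.children:
                walk(c, False)

    walk(tree, True)


def ancestral_states(
    alignment: Mapping[str, str],
    tree: Clade | str,
    parental_taxon: str | None = None,
) -> Reconstruction:
    """Fitch parsimony ancestral sequences, one nucleotide column at a time.

    The down-pass assignment resolves ambiguity toward the state carried by
    ``parental_taxon`` at that column when it is an option, else toward the
    alphabetically smallest state; the total substitution count attains the
    parsimony minimum per column (a property of the Fitch algorithm).
    """
    if isinstance(tree, str):
        tree = tree_from_newick(tree)
    _check_resolved(tree)
    seqs = {n: s.upper() for n, s in alignment.items()}
    if tree.leaf_names() != frozenset(seqs):
        raise ValueError("tree leaves must match alignment names")
    length = len(next(iter(seqs.values())))
    # name internal nodes deterministically
    counter = 0

    def name_nodes(node: Clade) -> None:
        nonlocal counter
        if not node.is_leaf and node.name is None:
            counter += 1
            node.name = f"anc{counter}"
        for c in node.children:
            name_nodes(c)

    name_nodes(tree)
    states: dict[str, list[str]] = {
        name: (list(seqs[name]) if name in seqs else ["?"] * length)
        for name in [n.name for n in _all_nodes(tree)]
    }
    total_subs = 0
    for col in range(length):
        sets: dict[str, frozenset[str]] = {}

        def up(node: Clade) -> frozenset[str]:
            # a trifurcating (unrooted) root is folded left-to-right, which
            # equals Fitch on an arbitrary binary rooting: same minimum count
            nonlocal total_subs
            if node.is_leaf:
                base = seqs[node.name][col]
                s = frozenset([base]) if base in _NUCS else frozenset(_NUCS)
                sets[node.name] = s
                return s
            child_sets = [up(c) for c in node.children]
            s = child_sets[0]
            for cs in child_sets[1:]:
                inter = s & cs
                if inter:
                    s = inter
                else:
                    s = s | cs
                    total_subs += 1
            sets[node.name] = s
            return s

        up(tree)
        parental_base = (
            seqs[parental_taxon][col] if parental_taxon in seqs else None
        )

        def down(node: Clade, parent_state: str | None) -> None:
            s = sets[node.name]
            if node.is_leaf:
                return
            if parent_state is not None and parent_state in s:
                choice = parent_state
            elif parental_base is not None and parental_base in s:
                choice = parental_base
            else:
                choice = min(s)
            states[node.name][col] = choice
            for c in node.children:
                down(c, choice)

        down(tree, None)
    # exact minimum-substitution count: recount changes along edges is not
    # valid for Fitch (assignments may differ); keep the union-event count.
    rec = Reconstruction(
        tree=tree,
        states={k: "".join(v) for k, v in states.items()},
        n_substitutions=total_subs,
    )
    return rec


def _all_nodes(tree: Clade) -> list[Clade]:
    out = [tree]
    for c in tree.children:
        out.extend(_all_nodes(c))
    return out


def synonymous_sites(codon: str) -> float:
    """Nei–Gojobori fractional count of synonymous sites in one codon.

    For each position, the fraction of the three possible point changes
    that preserve the amino acid; changes creating a stop codon count as
    non-synonymous.
    """
    aa = _AA[codon]
    syn = 0.0
    for pos in range(3):
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if _AA[mutated] == aa and not is_stop(mutated):
                syn += 1.0 / 3.0
    return syn


def _pathway_counts(parent: str, child: str) -> tuple[float, float]:
    """Average (synonymous, non-synonymous) step counts over minimal pathways.

    All orders of applying the differing positions are enumerated; pathways
    passing through a stop codon at an intermediate step are ignored (unless
    every pathway does, in which case all are used).
    """
    diff = [i for i in range(3) if parent[i] != child[i]]
    if not diff:
        return 0.0, 0.0
    allowed: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        current = parent
        syn = non = 0
        through_stop = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + child[pos] + current[pos + 1 :]
            if step < len(order) - 1 and is_stop(nxt):
                through_stop = True
            if _AA[current] == _AA[nxt]:
                syn += 1
            else:
                non += 1
            current = nxt
        (blocked if through_stop else allowed).append((syn, non))
    use = allowed if allowed else blocked
    syn_avg = sum(s for s, _ in use) / len(use)
    non_avg = sum(n for _, n in use) / len(use)
    return syn_avg, non_avg


@dataclass
class SiteCounts:
    """Observed/expected synonymous and non-synonymous change at one codon site."""

    site: int  # 1-based codon index
    ES: float
    EN: float
    OS: float
    ON: float

    @property
    def dS(self) -> float:
        return self.OS / self.ES if self.ES > 0 else float("nan")

    @property
    def dN(self) -> float:
        return self.ON / self.EN if self.EN > 0 else float("nan")

    @property
    def omega(self) -> float | None:
        if self.OS == 0 or self.ES == 0:
            return None
        ds = self.dS
        return None if ds == 0 else self.dN / ds


class AmbiguousSiteError(ValueError):
    pass


def count_site(rec: Reconstruction, site: int) -> SiteCounts:
    """Per-branch NG86 accounting at one codon site, summed over the tree.

    Expected synonymous/non-synonymous opportunities per branch are the
    fractional site counts averaged over the parent and child codons (they
    sum to 3 per branch); observed changes average over minimal mutational
    pathways. ``site`` is 1-based.
    """
    start = 3 * (site - 1)
    es = en = os_ = on = 0.0
    for parent_name, child_name in rec.branches():
        p = rec.states[parent_name][start : start + 3]
        c = rec.states[child_name][start : start + 3]
        if any(b not in _NUCS for b in p + c):
            raise AmbiguousSiteError(
                f"ambiguity characters at codon site {site}; site skipped"
            )
        sp, sc = synonymous_sites(p), synonymous_sites(c)
        es_b = 0.5 * (sp + sc)
        es += es_b
        en += 3.0 - es_b
        syn, non = _pathway_counts(p, c)
        os_ += syn
        on += non
    return SiteCounts(site=site, ES=es, EN=en, OS=os_, ON=on)


def slac_site_test(
    counts: SiteCounts, global_omega: float = 1.0
) -> tuple[float, float]:
    """Binomial p-values for positive (dN>dS) and negative (dN<dS) selection.

    Each observed substitution is non-synonymous with probability
    p = ω·EN / (ω·EN + ES) under the whole-alignment rate ω (ω=1 gives the
    neutral expectation EN/(ES+EN)). With n = OS+ON observed events,
    p_positive = P(X >= ON) and p_negative = P(X <= ON); fractional counts
    use the continuous (regularized incomplete beta) binomial tails.
    """
    n = counts.OS + counts.ON
    if n < 1e-12:
        return 1.0, 1.0
    p = (global_omega * counts.EN) / (global_omega * counts.EN + counts.ES)
    on, os_ = counts.ON, counts.OS
    p_pos = 1.0 if on <= 0 else float(betainc(on, os_ + 1.0, p))
    p_neg = 1.0 if os_ <= 0 else float(betainc(os_, on + 1.0, 1.0 - p))
    return p_pos, p_neg


def global_omega_estimate(all_counts: Sequence[SiteCounts]) -> float:
    """Whole-alignment dN/dS from summed observed and expected counts."""
    es = sum(c.ES for c in all_counts)
    en = sum(c.EN for c in all_counts)
    os_ = sum(c.OS for c in all_counts)
    on = sum(c.ON for c in all_counts)
    if os_ == 0 or es == 0 or en == 0:
        return 1.0
    return (on / en) / (os_ / es)


def slac_scan(
    aln: CodonAlignment,
    parental_taxon: str | None = None,
    global_omega: float | None = None,
    min_sequences: int = 10,
) -> pd.DataFrame:
    """End-to-end counting scan: ancestors, per-site counts, p-values.

    Fewer than ``min_sequences`` sequences are refused — small samples do
    not support site-wise selection inference. Sites containing in-frame
    stop codons or ambiguity characters are reported with NaN statistics.
    """
    if len(aln.sequences) < min_sequences:
        raise ValueError(
            f"{len(aln.sequences)} sequences; at least {min_sequences} are "
            "required to detect signatures of selection robustly"
        )
    violations = aln.stop_violations()
    if violations:
        warnings.warn(
            f"in-frame stop codons at {len(violations)} (taxon, site) pairs; "
            "those sites are skipped"
        )
    bad_sites = {site for _, site in violations}
    rec = ancestral_states(aln.sequences, aln.tree, parental_taxon=parental_taxon)
    counts: list[SiteCounts | None] = []
    for site in range(1, aln.n_sites + 1):
        if site in bad_sites:
            counts.append(None)
            continue
        try:
            counts.append(count_site(rec, site))
        except AmbiguousSiteError:
            counts.append(None)
    valid = [c for c in counts if c is not None]
    omega = global_omega if global_omega is not None else global_omega_estimate(valid)
    rows = []
    for site, c in enumerate(counts, start=1):
        if c is None:
            rows.append(
                {"site": site, "ES": np.nan, "EN": np.nan, "OS": np.nan,
                 "ON": np.nan, "dS": np.nan, "dN": np.nan, "omega": np.nan,
                 "p_positive": np.nan, "p_negative": np.nan, "skipped": True}
            )
            continue
        p_pos, p_neg = slac_site_test(c, global_omega=omega)
        rows.append(
            {"site": site, "ES": c.ES, "EN": c.EN, "OS": c.OS, "ON": c.ON,
             "dS": c.dS, "dN": c.dN,
             "omega": np.nan if c.omega is None else c.omega,
             "p_positive": p_pos, "p_negative": p_neg, "skipped": False}
        )
    df = pd.DataFrame(rows)
    df.attrs["global_omega"] = omega
    return df


# ---------------------------------------------------------------------------
# multi-method report thresholding and consensus

METHOD_THRESHOLDS = {
    "SLAC": ("p_value", "lt", 0.1),
    "FEL": ("p_value", "lt", 0.1),
    "MEME": ("p_value", "lt", 0.1),
    "FUBAR": ("posterior", "gt", 0.9),
    "REL": ("bayes_factor", "gt", 50.0),
}


@dataclass(frozen=True)
class SiteReport:
    """One method's evidence at one codon site."""

    method: str
    site: int
    stat_kind: str
    value: float
    direction: str  # positive | negative


@dataclass(frozen=True)
class ConsensusCall:
    site: int
    direction: str
    supporting_methods: tuple[str, ...]


def method_supports(report: SiteReport) -> bool:
    """Does this report pass its method's published threshold (strict)?"""
    if report.method not in METHOD_THRESHOLDS:
        raise ValueError(f"unknown method name {report.method!r}")
    expected_kind, op, cut = METHOD_THRESHOLDS[report.method]
    if report.stat_kind != expected_kind:
        raise ValueError(
            f"{report.method} reports {expected_kind}, got {report.stat_kind!r}"
        )
    return report.value < cut if op == "lt" else report.value > cut


def consensus_calls(
    reports: Iterable[SiteReport] | pd.DataFrame,
) -> list[ConsensusCall]:
    """Sites supported by at least two distinct methods in the same direction.

    Thresholds are the published ones (p < 0.1 for the p-value methods,
    posterior > 0.9 for FUBAR, Bayes factor > 50 for REL), all strict.
    The result is order-invariant and idempotent over duplicate rows.
    """
    if isinstance(reports, pd.DataFrame):
        reports = [
            SiteReport(
                method=str(r.method), site=int(r.site),
                stat_kind=str(r.stat_kind), value=float(r.value),
                direction=str(r.direction),
            )
            for r in reports.itertuples()
        ]
    support: dict[tuple[int, str], set[str]] = {}
    for rep in reports:
        if rep.direction not in ("positive", "negative"):
            raise ValueError(f"unknown direction {rep.direction!r}")
        if method_supports(rep):
            support.setdefault((rep.site, rep.direction), set()).add(rep.method)
    calls = [
        ConsensusCall(site=site, direction=direction,
                      supporting_methods=tuple(sorted(methods)))
        for (site, direction), methods in support.items()
        if len(methods) >= 2
    ]
    calls.sort(key=lambda c: (c.site, c.direction))
    return calls


def load_site_reports(path) -> list[SiteReport]:
    """Read a site-report TSV (columns: method, site, stat_kind, value, direction)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SiteReport(str(r.method), int(r.site), str(r.stat_kind),
                   float(r.value), str(r.direction))
        for r in df.itertuples()
    ]
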