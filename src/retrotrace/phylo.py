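"""Distance-based phylogenetics for pseudogene/parental alignments.

The tree machinery here is deliberately simple and fully deterministic:
Kimura two-parameter (or Jukes–Cantor) distances with pairwise deletion
of gap columns, Saitou–Nei neighbor-joining with a documented lexicographic
tie rule, nonparametric bootstrap over alignment columns, and a strict
majority-rule consensus with bipartition supports. It stands in for a
full ML tree search where one is not needed or not reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

_NUCS = set("ACGT")
_PURINES = {"A", "G"}


def _as_dict(alignment) -> dict[str, str]:
    """Accept dict, list of pairs, or SeqRecord-likes; return name -> sequence."""
    if isinstance(alignment, Mapping):
        items = list(alignment.items())
    else:
        items = []
        for entry in alignment:
            if isinstance(entry, tuple):
                items.append(entry)
            else:  # SeqRecord or similar
                items.append((entry.id, str(entry.seq)))
    out = {name: str(seq).upper() for name, seq in items}
    lengths = {len(s) for s in out.values()}
    if len(out) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    return out


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def _pair_proportions(s1: str, s2: str) -> tuple[float, float, int]:
    """Transition (P) and transversion (Q) proportions over shared ungapped columns."""
    shared = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in _NUCS or b not in _NUCS:
            continue
        shared += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if shared == 0:
        raise ValueError("no shared ungapped columns")
    return ts / shared, tv / shared, shared


def pairwise_distance(alignment, model: str = "k2p") -> DistanceMatrix:
    """Pairwise distances under K2P (default) or Jukes–Cantor.

    Gap handling is pairwise deletion: each pair's P/Q proportions are
    computed over the columns where both sequences carry an unambiguous
    base. Saturated pairs (logarithm argument <= 0) raise, naming the pair.
    """
    seqs = _as_dict(alignment)
    taxa = list(seqs)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q, _ = _pair_proportions(seqs[taxa[i]], seqs[taxa[j]])
            if model == "k2p":
                a1, a2 = 1 - 2 * p - q, 1 - 2 * q
                if a1 <= 0 or a2 <= 0:
                    raise ValueError(
                        f"saturated pair ({taxa[i]}, {taxa[j]}): K2P undefined"
                    )
                dist = -0.5 * math.log(a1) - 0.25 * math.log(a2)
            elif model == "jc":
                arg = 1 - 4.0 / 3.0 * (p + q)
                if arg <= 0:
                    raise ValueError(
                        f"saturated pair ({taxa[i]}, {taxa[j]}): JC undefined"
                    )
                dist = -0.75 * math.log(arg)
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d)


@dataclass
class Clade:
    """A node of a (possibly unrooted) tree; leaves carry names."""

    name: str | None = None
    length: float = 0.0
    children: list["Clade"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_names()
        return frozenset(out)

    def to_newick(self, hide_support_below: float | None = None) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None and (
                hide_support_below is None or node.support >= hide_support_below
            ):
                label = f"{node.support:.4g}"
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});" if self.children else f"{self.name};"


def tree_from_newick(text: str) -> Clade:
    """Parse a newick string into a :class:`Clade` (supports kept as labels)."""
    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> Clade:
        name = dnode.taxon.label.replace(" ", "_") if dnode.taxon else None
        support = None
        if dnode.label is not None and not dnode.is_leaf():
            try:
                support = float(dnode.label)
            except ValueError:
                pass
        return Clade(
            name=name,
            length=dnode.edge.length or 0.0,
            children=[convert(c) for c in dnode.child_nodes()],
            support=support,
        )

    return convert(dtree.seed_node)


def nj_tree(matrix: DistanceMatrix) -> Clade:
    """Neighbor-joining (Saitou–Nei Q criterion) with deterministic ties.

    Ties in the Q criterion are broken by the lexicographic order of the
    candidate pair's canonical labels (the smallest leaf name in each
    cluster). The returned tree is unrooted, represented with a trifurcating
    root. Requires at least 3 taxa.
    """
    taxa = list(matrix.taxa)
    if len(taxa) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    # cluster key -> Clade; key is the smallest leaf label in the cluster
    nodes: dict[str, Clade] = {t: Clade(name=t) for t in taxa}
    dist: dict[str, dict[str, float]] = {
        a: {b: matrix.get(a, b) for b in taxa if b != a} for a in taxa
    }
    while len(nodes) > 3:
        keys = sorted(nodes)
        n = len(keys)
        r = {k: sum(dist[k].values()) for k in keys}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                q = (n - 2) * dist[a][b] - r[a] - r[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        dab = dist[a][b]
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        vb = dab - va
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = va, vb
        new_key = min(a, b)
        new = Clade(children=[ca, cb])
        new_d = {}
        for k in nodes:
            dk = 0.5 * (dist[a][k] + dist[b][k] - dab)
            new_d[k] = dk
            dist[k].pop(a, None)
            dist[k].pop(b, None)
            dist[k][new_key] = dk
        dist.pop(a)
        dist.pop(b)
        dist[new_key] = new_d
        nodes[new_key] = new
    # join the final three around a central node (three-point formulas)
    x, y, z = sorted(nodes)
    dxy, dxz, dyz = dist[x][y], dist[x][z], dist[y][z]
    nodes[x].length = 0.5 * (dxy + dxz - dyz)
    nodes[y].length = 0.5 * (dxy + dyz - dxz)
    nodes[z].length = 0.5 * (dxz + dyz - dxy)
    return Clade(children=[nodes[x], nodes[y], nodes[z]])


def path_distances(tree: Clade) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (oracle for additivity checks)."""
    leaves: list[str] = sorted(tree.leaf_names())
    index = {t: i for i, t in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def walk(node: Clade) -> dict[str, float]:
        """Distances from every leaf under ``node`` up to ``node``."""
        if node.is_leaf:
            return {node.name: 0.0}
        below: dict[str, float] = {}
        child_maps = []
        for c in node.children:
            cm = {t: dd + c.length for t, dd in walk(c).items()}
            child_maps.append(cm)
        for i, cm1 in enumerate(child_maps):
            for cm2 in child_maps[i + 1 :]:
                for t1, d1 in cm1.items():
                    for t2, d2 in cm2.items():
                        d[index[t1], index[t2]] = d[index[t2], index[t1]] = d1 + d2
            below.update(cm1)
        return below

    walk(tree)
    return DistanceMatrix(leaves, d)


def bipartitions(tree: Clade) -> dict[frozenset[str], Clade]:
    """Nontrivial bipartitions of an unrooted tree, canonically encoded.

    Each internal edge splits the leaves in two; the side *not* containing
    the alphabetically first leaf is the canonical representative.
    """
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    out: dict[frozenset[str], Clade] = {}

    def walk(node: Clade) -> None:
        for c in node.children:
            ls = c.leaf_names()
            if 2 <= len(ls) <= len(all_leaves) - 2:
                side = ls if ref not in ls else all_leaves - ls
                out[side] = c
            walk(c)

    walk(tree)
    return out


def bootstrap_trees(
    alignment, n_replicates: int, seed: int, model: str = "k2p"
) -> list[Clade]:
    """NJ trees from column-resampled replicates (seed-reproducible)."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    seqs = _as_dict(alignment)
    names = list(seqs)
    arr = np.array([list(seqs[n]) for n in names])
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    trees = []
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {n: "".join(arr[i, cols]) for i, n in enumerate(names)}
        trees.append(nj_tree(pairwise_distance(resampled, model=model)))
    return trees


@dataclass
class SupportTree:
    """A tree whose internal edges carry bootstrap support percentages."""

    root: Clade
    supports: dict[frozenset[str], float]

    def to_newick(self, hide_below: float | None = None) -> str:
        return self.root.to_newick(hide_support_below=hide_below)


def _check_same_leaves(trees: Sequence[Clade]) -> frozenset[str]:
    leaf_sets = {t.leaf_names() for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("input trees have mismatched leaf sets")
    return next(iter(leaf_sets))


def majority_consensus(trees: Sequence[Clade], threshold: float = 0.5) -> SupportTree:
    """Strict majority-rule consensus of equally-leaved unrooted trees.

    A bipartition enters the consensus iff it occurs in strictly more than
    ``threshold`` of the input trees (exactly half is excluded at the
    default). No greedy completion with lower-frequency compatible
    bipartitions is performed. Supports are percentages of input trees.
    """
    if not trees:
        raise ValueError("no trees")
    leaves = _check_same_leaves(trees)
    ref = min(leaves)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    kept = {bp: c / n for bp, c in counts.items() if c / n > threshold}
    # build rooted-at-reference clade structure; clades are the sides not
    # containing the reference leaf (majority bipartitions are compatible)
    clades = sorted(kept, key=lambda s: (-len(s), sorted(s)))
    root = Clade(children=[])
    placed: list[tuple[frozenset[str], Clade]] = [(leaves, root)]
    for cl in clades:
        host_set, host = min(
            ((s, node) for s, node in placed if cl <= s),
            key=lambda sn: len(sn[0]),
        )
        node = Clade(support=round(100.0 * kept[cl], 10))
        # re-parent any existing children now nested inside this clade
        keep, move = [], []
        for child in host.children:
            (move if child.leaf_names() <= cl else keep).append(child)
        node.children = move
        host.children = keep + [node]
        placed.append((cl, node))
    # attach leaves under the smallest containing clade
    for leaf in sorted(leaves):
        host_set, host = min(
            ((s, node) for s, node in placed if leaf in s),
            key=lambda sn: len(sn[0]),
        )
        host.children.append(Clade(name=leaf))
    supports = {bp: round(100.0 * f, 10) for bp, f in kept.items()}
    return SupportTree(root=root, supports=supports)


def map_support(
    best_tree: Clade, replicate_trees: Sequence[Clade], hide_below: float = 50.0
) -> SupportTree:
    """Annotate each internal edge of ``best_tree`` with its bootstrap frequency.

    Supports below ``hide_below`` are masked at rendering time only
    (``SupportTree.to_newick(hide_below=...)``); the data keeps all values.
    """
    _check_same_leaves([best_tree, *replicate_trees])
    n = len(replicate_trees)
    if n == 0:
        raise ValueError("no replicate trees")
    counts: dict[frozenset[str], int] = {}
    for t in replicate_trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    supports: dict[frozenset[str], float] = {}
    for bp, clade in bipartitions(best_tree).items():
        freq = 100.0 * counts.get(bp, 0) / n
        clade.support = round(freq, 10)
        supports[bp] = round(freq, 10)
    return SupportTree(root=best_tree, supports=supports)
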