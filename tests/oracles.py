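"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration or direct
construction — and shares no code path with the implementations it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from retrotrace.dating import DatedTree, TreeNode
from retrotrace.phylo import Clade


# -- random structures -------------------------------------------------------

def random_binary_clade(rng: np.random.Generator, n_leaves: int,
                        min_len: float = 0.1, max_len: float = 1.0) -> Clade:
    """Random unrooted binary tree with random branch lengths."""
    nodes = [Clade(name=f"L{i}", length=float(rng.uniform(min_len, max_len)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Clade(length=float(rng.uniform(min_len, max_len)),
                           children=[a, b]))
    return Clade(children=nodes)


def random_dated_tree(rng: np.random.Generator, n_leaves: int) -> DatedTree:
    """Random rooted dated tree (leaves at 0, parent strictly older)."""
    nodes = [TreeNode(name=f"L{i}", age=0.0) for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        counter += 1
        age = max(a.age, b.age) + float(rng.uniform(1.0, 10.0))
        parent = TreeNode(name=f"N{counter}", age=age, children=[a, b])
        a.parent = parent
        b.parent = parent
        nodes.append(parent)
    return DatedTree(nodes[0])


# -- Dollo dating ------------------------------------------------------------

def origin_by_enumeration(presence: dict[str, str], tree: DatedTree) -> str:
    """The unique shallowest node whose subtree holds every carrier."""
    carriers = {t for t, s in presence.items() if s == "present"}
    best = None
    for name, node in tree.nodes.items():
        below = {l.name for l in node.leaves()}
        if carriers <= below and (best is None or len(below) < len(best[1])):
            best = (name, below)
    return best[0]


def losses_by_enumeration(
    presence: dict[str, str], tree: DatedTree, origin: str
) -> list[set[str]]:
    """All minimum-cardinality loss-branch sets explaining the absences.

    A set of branches (named by child node) is valid iff, for every leaf
    below the origin with a known state, the leaf is absent exactly when
    it sits under at least one loss branch. Unknown leaves are free.
    """
    origin_node = tree.nodes[origin]
    subtree_nodes = []

    def collect(node):
        subtree_nodes.append(node)
        for c in node.children:
            collect(c)

    collect(origin_node)
    names = [n.name for n in subtree_nodes]
    known = {
        l.name: presence[l.name]
        for l in origin_node.leaves()
        if presence.get(l.name, "unknown") != "unknown"
    }
    under = {
        n.name: {l.name for l in n.leaves()} for n in subtree_nodes
    }

    def valid(loss_set) -> bool:
        covered = set()
        for b in loss_set:
            covered |= under[b]
        for leaf, state in known.items():
            if (state == "absent") != (leaf in covered):
                return False
        return True

    for size in range(len(names) + 1):
        hits = [set(c) for c in combinations(names, size) if valid(c)]
        if hits:
            return hits
    return []


# -- parsimony ---------------------------------------------------------------

def parsimony_by_enumeration(column: dict[str, str], tree: Clade) -> int:
    """Minimum substitution count over all internal-node state assignments."""
    internals: list[Clade] = []

    def collect(node: Clade):
        if not node.is_leaf:
            internals.append(node)
        for c in node.children:
            collect(c)

    collect(tree)
    best = None
    for assignment in product("ACGT", repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}

        def state(node: Clade) -> str:
            return column[node.name] if node.is_leaf else states[id(node)]

        def changes(node: Clade) -> int:
            total = 0
            for c in node.children:
                total += (state(node) != state(c)) + changes(c)
            return total

        cost = changes(tree)
        if best is None or cost < best:
            best = cost
    return best


# -- peptide mass ------------------------------------------------------------

MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


def hand_summed_mass(peptide: str) -> float:
    return sum(MONO[a] for a in peptide) + 18.010565
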