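"""Dating retroposition events from presence/absence on a dated species tree.

A processed pseudogene is created once (a retroposition is effectively
irreversible, so a Dollo model applies: one gain, any number of losses).
If a dated species tree is available, the carriers of a copy bracket the
gain in time: it happened no later than the crown age of the carriers'
most recent common ancestor and no earlier than the split of that
ancestor from its sister lineage. Losses are then the minimal set of
branches below the gain on which single deletions explain all absences.

Node ages are calendar ages in millions of years (Mya), leaves at 0.
Fixture trees with literature split times for primates and mammals ship
with the package (:func:`load_primate_tree`, :func:`load_mammal_tree`);
where the literature reports an age range for one split, the nominal age
stores the younger bound and ``age_upper`` the older one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

_STATE_ALIASES = {
    "present": PRESENT, "1": PRESENT, 1: PRESENT, True: PRESENT,
    "absent": ABSENT, "0": ABSENT, 0: ABSENT, False: ABSENT,
    "unknown": UNKNOWN, "?": UNKNOWN, "na": UNKNOWN, "": UNKNOWN,
}


def _norm_state(x) -> str:
    if isinstance(x, str):
        x = x.strip().lower()
    try:
        return _STATE_ALIASES[x]
    except (KeyError, TypeError):
        raise ValueError(f"unknown presence state {x!r}") from None


@dataclass
class TreeNode:
    name: str
    age: float
    age_upper: float | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class DatedTree:
    """Rooted species tree with node ages in Mya (ultrametric, leaves at 0)."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.name in self.nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        self._validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        newick: str | Path,
        ages: Mapping[str, float] | pd.DataFrame | str | Path,
    ) -> "DatedTree":
        """Build from a newick topology with named internal nodes plus ages.

        ``ages`` maps internal-node labels to ages (leaves default to 0);
        a DataFrame/TSV with columns node, age[, age_upper] is also accepted.
        """
        text = str(newick)
        if isinstance(newick, Path) or (isinstance(newick, str) and Path(newick).exists()):
            text = Path(newick).read_text()
        upper: dict[str, float] = {}
        if isinstance(ages, (str, Path)):
            ages = pd.read_csv(ages, sep="\t")
        if isinstance(ages, pd.DataFrame):
            df = ages
            if "age_upper" in df.columns:
                upper = {
                    r.node: float(r.age_upper)
                    for r in df.itertuples()
                    if pd.notna(r.age_upper)
                }
            ages = {r.node: float(r.age) for r in df.itertuples()}
        dtree = dendropy.Tree.get(data=text, schema="newick")
        counter = 0

        def convert(dnode) -> TreeNode:
            nonlocal counter
            label = (
                dnode.taxon.label.replace(" ", "_")
                if dnode.taxon is not None
                else (dnode.label or "")
            )
            if not label:
                counter += 1
                label = f"node{counter}"
            age = float(ages.get(label, 0.0))
            node = TreeNode(name=label, age=age, age_upper=upper.get(label))
            for child in dnode.child_nodes():
                cn = convert(child)
                cn.parent = node
                node.children.append(cn)
            return node

        return cls(convert(dtree.seed_node))

    def _validate(self) -> None:
        for node in self.preorder():
            if node.is_leaf and node.age != 0.0:
                raise ValueError(f"leaf {node.name!r} must have age 0")
            for c in node.children:
                if node.age <= c.age:
                    raise ValueError(
                        f"node {node.name!r} (age {node.age}) must be older than "
                        f"child {c.name!r} (age {c.age})"
                    )

    # -- traversal ------------------------------------------------------
    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[TreeNode]:
        out = list(self.preorder())
        return reversed(out)

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def branch_length(self, node: TreeNode) -> float:
        """Length (Mya) of the branch above ``node``; 0 for the root."""
        return 0.0 if node.parent is None else node.parent.age - node.age

    def to_clade(self):
        """Convert to a :class:`~retrotrace.phylo.Clade` with branch lengths in My."""
        from .phylo import Clade

        def conv(node: TreeNode):
            return Clade(
                name=node.name if node.is_leaf else None,
                length=self.branch_length(node),
                children=[conv(c) for c in node.children],
            )

        return conv(self.root)

    def mrca(self, taxa: Iterable[str]) -> TreeNode:
        taxa = set(taxa)
        missing = taxa - set(self.leaf_names)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        if not taxa:
            raise ValueError("empty taxon set")
        # postorder: first node whose leaf set covers all taxa
        for node in self.postorder():
            if taxa <= {l.name for l in node.leaves()}:
                return node
        raise AssertionError("unreachable: root covers all leaves")


@dataclass
class OriginInterval:
    """Time window (Mya) bracketing a single gain event."""

    pseudogene: str
    lower: float
    upper: float
    origin_branch: str  # named by the child node of the stem edge
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.lower < 0 or self.lower >= self.upper:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")


def _presence_states(column: Mapping[str, object]) -> dict[str, str]:
    return {taxon: _norm_state(state) for taxon, state in column.items()}


def dollo_origin_interval(
    presence_column: Mapping[str, object],
    tree: DatedTree,
    pseudogene: str = "",
) -> OriginInterval:
    """Origin bracket for one copy under a single-gain (Dollo) model.

    Carriers are the leaves marked present; unknown leaves are ignored.
    The gain sits on the stem edge of the carriers' MRCA, so the interval
    is [age(MRCA), age(parent of MRCA)]. When the MRCA is the root the
    upper end is the root's older age bound (its ``age_upper`` if stored)
    and the interval is flagged open-ended.
    """
    states = _presence_states(presence_column)
    carriers = [t for t, s in states.items() if s == PRESENT]
    if not carriers:
        raise ValueError("no carriers: cannot place a gain")
    mrca = tree.mrca(carriers)
    if mrca.parent is None:
        upper = mrca.age_upper if mrca.age_upper is not None else mrca.age
        if upper <= mrca.age:
            upper = mrca.age * (1 + 1e-9) + 1e-9
        return OriginInterval(pseudogene, mrca.age, upper, mrca.name, open_ended=True)
    return OriginInterval(pseudogene, mrca.age, mrca.parent.age, mrca.name)


def infer_losses(
    presence_column: Mapping[str, object],
    tree: DatedTree,
    origin_branch: str,
) -> list[str]:
    """Minimal loss branches explaining all absences below the origin.

    Under Dollo parsimony a loss is placed on the stem of every maximal
    subtree (within the carrier clade) whose known leaves are all absent;
    unknown leaves carry no cost and never force or veto a loss on their
    own. Branches are named by their child node.
    """
    states = _presence_states(presence_column)
    origin = tree.nodes[origin_branch]

    def known_leaf_states(node: TreeNode) -> list[str]:
        return [
            states[l.name]
            for l in node.leaves()
            if states.get(l.name, UNKNOWN) != UNKNOWN
        ]

    losses: list[str] = []

    def walk(node: TreeNode) -> None:
        ks = known_leaf_states(node)
        if ks and all(s == ABSENT for s in ks):
            losses.append(node.name)
            return
        for c in node.children:
            walk(c)

    walk(origin)
    return losses


def date_all(
    presence: pd.DataFrame, tree: DatedTree
) -> pd.DataFrame:
    """Origin interval + losses for every pseudogene column.

    ``presence`` is indexed by taxon with one column per pseudogene
    (values present/absent/unknown, or 1/0/?). Columns with no carriers
    are flagged rather than fatal.
    """
    rows = []
    for pg in presence.columns:
        column = presence[pg].to_dict()
        try:
            interval = dollo_origin_interval(column, tree, pseudogene=pg)
        except ValueError:
            rows.append(
                {
                    "pseudogene": pg, "lower_mya": None, "upper_mya": None,
                    "origin_branch": None, "open_ended": None,
                    "losses": None, "flag": "no_carriers",
                }
            )
            continue
        losses = infer_losses(column, tree, interval.origin_branch)
        rows.append(
            {
                "pseudogene": pg,
                "lower_mya": interval.lower,
                "upper_mya": interval.upper,
                "origin_branch": interval.origin_branch,
                "open_ended": interval.open_ended,
                "losses": ",".join(losses),
                "flag": "",
            }
        )
    return pd.DataFrame(rows).set_index("pseudogene")


def load_presence(path: str | Path) -> pd.DataFrame:
    """Read a presence/absence TSV (rows taxa, columns pseudogenes)."""
    return pd.read_csv(path, sep="\t", index_col="taxon")


def _fixture(name: str):
    return resources.files("retrotrace.data").joinpath(name)


def load_primate_tree() -> DatedTree:
    """Dated primate tree with literature split times (Mya)."""
    with _fixture("primate_tree.nwk").open() as fh:
        newick = fh.read()
    with _fixture("primate_node_ages.tsv").open() as fh:
        ages = pd.read_csv(fh, sep="\t")
    return DatedTree.from_newick(newick, ages)


def load_mammal_tree() -> DatedTree:
    """Dated mammal tree (opossum outgroup) with literature split times."""
    with _fixture("mammal_tree.nwk").open() as fh:
        newick = fh.read()
    with _fixture("mammal_node_ages.tsv").open() as fh:
        ages = pd.read_csv(fh, sep="\t")
    return DatedTree.from_newick(newick, ages)


def load_primate_presence() -> pd.DataFrame:
    with _fixture("primate_presence.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="taxon")


def load_mammal_presence() -> pd.DataFrame:
    with _fixture("mammal_presence.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="taxon")
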