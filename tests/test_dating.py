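"""Dollo presence/absence dating on dated species trees."""

import numpy as np
import pandas as pd
import pytest

from oracles import losses_by_enumeration, origin_by_enumeration, random_dated_tree

from retrotrace.dating import (
    DatedTree,
    TreeNode,
    date_all,
    dollo_origin_interval,
    infer_losses,
    load_mammal_presence,
    load_primate_presence,
)
from retrotrace.simulate import PlannedEvent, SimulationConfig, ladder_tree, simulate_dataset

CATARRHINI = ["Hosa", "Patr", "Gogo", "Poab", "Nole", "Mamu", "Chae"]
HOMINOIDEA = ["Hosa", "Patr", "Gogo", "Poab", "Nole"]


def _column(tree, carriers, absent_value="absent"):
    return {t: ("present" if t in carriers else absent_value) for t in tree.leaf_names}


class TestFixtureBrackets:
    def test_catarrhini_carriers_bracket(self, primate_tree):
        iv = dollo_origin_interval(_column(primate_tree, CATARRHINI), primate_tree)
        assert (iv.lower, iv.upper) == (29.2, 42.6)
        assert iv.origin_branch == "Catarrhini"
        assert not iv.open_ended

    def test_hominoidea_carriers_bracket(self, primate_tree):
        iv = dollo_origin_interval(_column(primate_tree, HOMINOIDEA), primate_tree)
        assert iv.upper == 29.2
        assert iv.origin_branch == "Hominoidea"

    def test_all_mammals_bracket_open_ended(self, mammal_tree):
        iv = dollo_origin_interval(_column(mammal_tree, mammal_tree.leaf_names), mammal_tree)
        assert (iv.lower, iv.upper) == (163.9, 167.4)
        assert iv.open_ended

    def test_glires_absence_places_one_stem_loss(self, mammal_tree):
        absent = {"Modo", "Orcu", "Mumu", "Rano"}
        col = _column(mammal_tree, set(mammal_tree.leaf_names) - absent)
        iv = dollo_origin_interval(col, mammal_tree)
        assert (iv.lower, iv.upper) == (94.4, 163.9)
        assert infer_losses(col, mammal_tree, iv.origin_branch) == ["Glires"]


class TestOriginInterval:
    def test_single_carrier_leaf(self, primate_tree):
        iv = dollo_origin_interval(_column(primate_tree, ["Hosa"]), primate_tree)
        assert iv.lower == 0.0
        assert iv.upper == 6.7  # its stem split
        assert iv.origin_branch == "Hosa"

    def test_no_carriers_rejected(self, primate_tree):
        with pytest.raises(ValueError, match="carriers"):
            dollo_origin_interval(_column(primate_tree, []), primate_tree)

    def test_unknowns_excluded_from_mrca(self, primate_tree):
        col = _column(primate_tree, HOMINOIDEA, absent_value="unknown")
        iv = dollo_origin_interval(col, primate_tree)
        assert iv.origin_branch == "Hominoidea"

    def test_matches_enumeration_oracle_on_random_patterns(self):
        rng = np.random.default_rng(99)
        trials = 0
        while trials < 500:
            tree = random_dated_tree(rng, int(rng.integers(3, 11)))
            leaves = tree.leaf_names
            states = {
                t: ["present", "absent", "unknown"][int(rng.integers(0, 3))]
                for t in leaves
            }
            if not any(s == "present" for s in states.values()):
                continue
            trials += 1
            iv = dollo_origin_interval(states, tree)
            assert iv.origin_branch == origin_by_enumeration(states, tree)

    def test_adding_a_carrier_never_decreases_upper(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            tree = random_dated_tree(rng, int(rng.integers(4, 9)))
            leaves = tree.leaf_names
            k = int(rng.integers(1, len(leaves)))
            carriers = list(rng.choice(leaves, size=k, replace=False))
            non = [t for t in leaves if t not in carriers]
            if not non:
                continue
            before = dollo_origin_interval(_column(tree, carriers), tree)
            extra = carriers + [non[0]]
            after = dollo_origin_interval(_column(tree, extra), tree)
            assert after.upper >= before.upper

    def test_taxon_order_invariance(self, mammal_tree):
        col = _column(mammal_tree, ["Hosa", "Mamu", "Caja"])
        shuffled = dict(reversed(list(col.items())))
        a = dollo_origin_interval(col, mammal_tree)
        b = dollo_origin_interval(shuffled, mammal_tree)
        assert (a.lower, a.upper, a.origin_branch) == (b.lower, b.upper, b.origin_branch)


class TestInferLosses:
    def test_all_present_no_losses(self, primate_tree):
        col = _column(primate_tree, primate_tree.leaf_names)
        assert infer_losses(col, primate_tree, "Simiiformes") == []

    def test_one_absent_clade_single_stem_loss(self, primate_tree):
        col = _column(primate_tree, set(primate_tree.leaf_names) - {"Mamu", "Chae"})
        iv = dollo_origin_interval(col, primate_tree)
        assert infer_losses(col, primate_tree, iv.origin_branch) == ["Cercopithecoidea"]

    def test_unknown_only_clade_gets_no_loss(self, primate_tree):
        col = _column(primate_tree, set(primate_tree.leaf_names) - {"Mamu", "Chae"})
        col["Mamu"] = col["Chae"] = "unknown"
        iv = dollo_origin_interval(col, primate_tree)
        assert infer_losses(col, primate_tree, iv.origin_branch) == []

    def test_matches_minimal_enumeration_on_random_patterns(self):
        rng = np.random.default_rng(7)
        trials = 0
        while trials < 100:
            tree = random_dated_tree(rng, int(rng.integers(3, 9)))
            states = {
                t: ["present", "absent", "unknown"][int(rng.integers(0, 3))]
                for t in tree.leaf_names
            }
            if not any(s == "present" for s in states.values()):
                continue
            trials += 1
            iv = dollo_origin_interval(states, tree)
            got = set(infer_losses(states, tree, iv.origin_branch))
            minimal_sets = losses_by_enumeration(states, tree, iv.origin_branch)
            assert got in minimal_sets or (not minimal_sets and not got)


class TestDateAll:
    def test_fixture_tables(self, primate_tree, mammal_tree):
        table = date_all(load_primate_presence(), primate_tree)
        assert table.loc["P2", "upper_mya"] == 42.6
        assert table.loc["P2", "lower_mya"] == 29.2
        assert table.loc["P3", "upper_mya"] == 29.2
        assert table.loc["P10", "upper_mya"] == 65.2  # root range, open-ended
        mtable = date_all(load_mammal_presence(), mammal_tree)
        assert mtable.loc["P9", "lower_mya"] == 163.9
        assert mtable.loc["P7", "losses"] == "Glires"

    def test_no_carrier_column_flagged_not_fatal(self, primate_tree):
        df = pd.DataFrame(
            {"ok": ["present"] * 8, "empty": ["absent"] * 8},
            index=primate_tree.leaf_names,
        )
        table = date_all(df, primate_tree)
        assert table.loc["empty", "flag"] == "no_carriers"
        assert table.loc["ok", "flag"] == ""

    def test_row_order_invariance(self, primate_tree):
        df = load_primate_presence()
        t1 = date_all(df, primate_tree)
        t2 = date_all(df.sample(frac=1, random_state=0), primate_tree)
        pd.testing.assert_frame_equal(t1, t2)


class TestTreeValidation:
    def test_child_older_than_parent_rejected(self):
        child = TreeNode(name="x", age=0.0)
        other = TreeNode(name="z", age=0.0)
        root = TreeNode(name="r", age=5.0, children=[child, other])
        child.age = 9.0
        child.children = [TreeNode(name="y", age=0.0)]
        with pytest.raises(ValueError, match="older"):
            DatedTree(root)

    def test_nonzero_leaf_age_rejected(self):
        a = TreeNode(name="a", age=1.0)
        b = TreeNode(name="b", age=0.0)
        with pytest.raises(ValueError, match="age 0"):
            DatedTree(TreeNode(name="r", age=5.0, children=[a, b]))


class TestSimulationClosedLoop:
    def test_planted_origin_branch_recovered(self, small_config_rates0):
        tree = ladder_tree(6)
        events = [PlannedEvent("retroposition", branch="n3", name="PX")]
        res = simulate_dataset(small_config_rates0, tree=tree, events=events)
        iv = dollo_origin_interval(res.presence_states("PX"), tree)
        assert iv.origin_branch == "n3"
        # bracket is [crown of n3, its stem split]
        assert iv.lower == tree.nodes["n3"].age
        assert iv.upper == tree.nodes["n3"].parent.age
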