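"""Gain/loss parsimony: worked example, oracle equivalence, properties."""

from __future__ import annotations

import itertools

import pytest

from intronarch.parsimony import (
    ABSENT,
    DEFAULT_TREE_NEWICK,
    MISSING,
    PRESENT,
    LineageTree,
    PresencePattern,
    ScenarioConstraint,
    bfg_pattern,
    brute_force_events,
    compare_scenarios,
    min_events,
)

from conftest import tree_shapes

TREE = LineageTree.from_newick(DEFAULT_TREE_NEWICK)


class TestWorkedExample:
    """Intron shared by FU-b, FU-f, FU-g of Tectipleura only: a single
    ancestral gain needs 12 events, independent recent gains need 3."""

    def test_ancestral_gain_needs_twelve_events(self):
        tally = min_events(bfg_pattern(), TREE, ScenarioConstraint("ancestral_gain"))
        assert tally.total == 12
        assert (tally.gains, tally.losses) == (1, 11)

    def test_free_gains_needs_three(self):
        tally = min_events(bfg_pattern(), TREE, ScenarioConstraint("free_gains"))
        assert tally.total == 3
        assert (tally.gains, tally.losses) == (3, 0)
        assert all(b == "Tectipleura" for (b, _, k) in tally.events)

    def test_recent_gains_preferred(self):
        comp = compare_scenarios(bfg_pattern(), TREE)
        assert comp["preferred"] == "free_gains"
        assert comp["totals"] == {"ancestral_gain": 12, "free_gains": 3}

    def test_brute_force_agrees(self):
        for mode in ("ancestral_gain", "free_gains"):
            sc = ScenarioConstraint(mode)
            assert (
                min_events(bfg_pattern(), TREE, sc).total
                == brute_force_events(bfg_pattern(), TREE, sc).total
            )


class TestTrivialPatterns:
    def test_all_present_single_origin(self):
        states = {
            (ln, fu): PRESENT
            for ln in TREE.leaf_names
            for fu in "ab"
        }
        pat = PresencePattern(states)
        free = min_events(pat, TREE, ScenarioConstraint("free_gains"))
        # one gain on the stem per FU
        assert (free.gains, free.losses) == (2, 0)
        anc = min_events(pat, TREE, ScenarioConstraint("ancestral_gain"))
        assert anc.total == 1  # the single precursor gain, no losses

    def test_all_present_one_fu_is_tie(self):
        states = {(ln, "a"): PRESENT for ln in TREE.leaf_names}
        comp = compare_scenarios(PresencePattern(states), TREE)
        assert comp["preferred"] == "tie"
        assert comp["totals"] == {"ancestral_gain": 1, "free_gains": 1}

    def test_two_leaf_tree_single_difference(self):
        tree = LineageTree.from_newick("(A:1,B:1)R:1;")
        pat = PresencePattern({("A", "x"): PRESENT, ("B", "x"): ABSENT})
        tally = min_events(pat, tree, ScenarioConstraint("free_gains"))
        assert tally.total == 1

    def test_missing_fu_is_unconstrained(self):
        # FU missing in one lineage should never force an extra event
        pat = PresencePattern(
            {
                ("Tectipleura", "h"): PRESENT,
                ("Vetigastropoda", "h"): PRESENT,
                ("Cephalopoda", "h"): MISSING,
            }
        )
        tally = min_events(pat, TREE, ScenarioConstraint("free_gains"))
        assert tally.total == 1


class TestErrors:
    def test_unknown_lineage_rejected(self):
        pat = PresencePattern({("Atlantis", "a"): PRESENT})
        with pytest.raises(ValueError, match="Atlantis"):
            min_events(pat, TREE, ScenarioConstraint("free_gains"))

    def test_all_absent_pattern_rejected(self):
        with pytest.raises(ValueError, match="nothing to explain"):
            PresencePattern({("Tectipleura", "a"): ABSENT})

    def test_big_tree_refused_by_brute_force(self):
        tree = tree_shapes(6)[0]
        big = LineageTree(
            root=type(tree.root)(
                name="",
                children=[tree.root, tree_shapes(6, prefix="M")[0].root],
            ),
            stem_length=1.0,
        )
        pat = PresencePattern({("L0", "a"): PRESENT})
        with pytest.raises(ValueError, match="8 leaves"):
            brute_force_events(pat, big, ScenarioConstraint("free_gains"))


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_exhaustive_small_trees(self, n_leaves):
        # full sweep over all shapes x all 2-FU patterns x both scenarios
        # (the 5- and 6-leaf sweep runs in the acceptance suite)
        for tree in tree_shapes(n_leaves):
            leaves = tree.leaf_names
            for states in itertools.product(
                (PRESENT, ABSENT), repeat=2 * n_leaves
            ):
                d = {
                    (ln, fu): states[2 * i + j]
                    for i, ln in enumerate(leaves)
                    for j, fu in enumerate(("f1", "f2"))
                }
                if not any(v == PRESENT for v in d.values()):
                    continue
                pat = PresencePattern(d)
                for mode in ("ancestral_gain", "free_gains"):
                    sc = ScenarioConstraint(mode)
                    assert (
                        min_events(pat, tree, sc).total
                        == brute_force_events(pat, tree, sc).total
                    )

    def test_missing_states_spot_checks(self):
        tree = tree_shapes(4)[0]
        leaves = tree.leaf_names
        for states in itertools.product((PRESENT, ABSENT, MISSING), repeat=4):
            d = {(ln, "a"): s for ln, s in zip(leaves, states)}
            if not any(v == PRESENT for v in d.values()):
                continue
            pat = PresencePattern(d)
            for mode in ("ancestral_gain", "free_gains"):
                sc = ScenarioConstraint(mode)
                assert (
                    min_events(pat, tree, sc).total
                    == brute_force_events(pat, tree, sc).total
                )


class TestProperties:
    def test_event_list_explains_pattern(self):
        """Replaying min_events' per-branch events reproduces the leaf
        states (ignoring missing FUs)."""
        for tree in tree_shapes(4):
            leaves = tree.leaf_names
            for states in itertools.product((PRESENT, ABSENT), repeat=4):
                d = {(ln, "a"): s for ln, s in zip(leaves, states)}
                if not any(v == PRESENT for v in d.values()):
                    continue
                pat = PresencePattern(d)
                for mode in ("ancestral_gain", "free_gains"):
                    sc = ScenarioConstraint(mode)
                    tally = min_events(pat, tree, sc)
                    by_branch = {}
                    for (b, fu, kind) in tally.events:
                        if fu in {"a", "*"}:
                            by_branch.setdefault(b, []).append(kind)

                    def walk(node, state):
                        for kind in by_branch.get(node.name, []):
                            state = 1 if kind == "gain" else 0
                        if node.is_leaf:
                            want = pat.state(node.name, "a")
                            if want != MISSING:
                                assert state == (1 if want == PRESENT else 0)
                        for child in node.children:
                            walk(child, state)

                    top = sc.stem_top_state
                    for kind in by_branch.get("stem", []):
                        top = 1 if kind == "gain" else 0
                    walk(tree.root, top)

    def test_grafting_a_present_leaf_never_decreases_free_gains_total(self):
        from intronarch.parsimony import TreeNode

        for tree in tree_shapes(4):
            leaves = tree.leaf_names
            for states in itertools.product((PRESENT, ABSENT), repeat=4):
                d = {(ln, "a"): s for ln, s in zip(leaves, states)}
                if not any(v == PRESENT for v in d.values()):
                    continue
                base = min_events(
                    PresencePattern(d), tree, ScenarioConstraint("free_gains")
                ).total
                grown = LineageTree(
                    root=TreeNode(
                        name="",
                        children=[tree.root, TreeNode(name="X", length=1.0)],
                    ),
                    stem_length=1.0,
                )
                d2 = dict(d)
                d2[("X", "a")] = PRESENT
                extended = min_events(
                    PresencePattern(d2), grown, ScenarioConstraint("free_gains")
                ).total
                assert extended >= base

    def test_simulated_gain_truth_lower_bounded_by_parsimony(self):
        """Free-gains parsimony never needs more events than the simulator
        actually performed for a position."""
        from collections import defaultdict

        from intronarch.synthetic_data import SimulationConfig, simulate_family

        truth = simulate_family(SimulationConfig(loss_rate=0.0), 3)
        tree = LineageTree.from_newick(DEFAULT_TREE_NEWICK)
        gains_per_pos = defaultdict(int)
        for ev in truth.events:
            if ev.kind == "gain":
                gains_per_pos[ev.cds_offset] += 1
        for off, n_true in gains_per_pos.items():
            states = {}
            for gid, arch in truth.architectures.items():
                present = any(i.cds_offset == off for i in arch.introns)
                states[(arch.lineage, "x")] = PRESENT if present else ABSENT
            if not any(v == PRESENT for v in states.values()):
                continue
            tally = min_events(
                PresencePattern(states), tree, ScenarioConstraint("free_gains")
            )
            assert tally.total <= n_true
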