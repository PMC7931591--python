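"""Minimal intron gain/loss counting on a lineage tree (Sankoff parsimony).

The question: an intron observed at the same splice-site position in
several functional units and/or lineages — is it the relic of a single
ancestral gain in the mono-domain precursor (followed by losses), or the
product of recent independent gains?  Both scenarios are scored by the
minimum number of unit-cost gain/loss events needed to explain the
per-(lineage, FU) presence/absence pattern on a rooted species tree.

The tree carries a *stem branch* above its root: the lineage segment
between the completed multi-FU ancestor gene and the radiation of the
compared lineages.  Fixing the state at the top of the stem is how the two
scenarios differ:

* ``ancestral_gain`` — stem-top state is *present* for every FU, further
  gains are prohibited (Dollo-style), and exactly one gain (in the
  mono-domain precursor) is added to the tally regardless of FU count.
  Losses on the stem set the radiation-root state, so a loss "in a common
  ancestor" is counted once.
* ``free_gains`` — stem-top state is *absent*; gains and losses both cost 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

INF = float("inf")

PRESENT, ABSENT, MISSING = "present", "absent", "missing"


@dataclass
class TreeNode:
    name: str
    length: float = 1.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]


@dataclass
class LineageTree:
    """Rooted binary species tree with a stem branch above the root."""

    root: TreeNode
    stem_length: float = 1.0

    def __post_init__(self) -> None:
        names = [l.name for l in self.root.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")
        for n in self.root.postorder():
            if n.children and len(n.children) != 2:
                raise ValueError("tree must be binary")

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")
        counter = itertools.count()

        def conv(nd) -> TreeNode:
            name = (
                nd.taxon.label
                if nd.taxon is not None
                else (nd.label or f"node{next(counter)}")
            )
            return TreeNode(
                name=name.replace(" ", "_"),
                length=nd.edge.length if nd.edge.length is not None else 1.0,
                children=[conv(c) for c in nd.child_nodes()],
            )

        root = conv(t.seed_node)
        stem = t.seed_node.edge.length
        return cls(root=root, stem_length=stem if stem is not None else 1.0)


@dataclass
class ScenarioConstraint:
    """How the state at the top of the stem branch is constrained."""

    mode: str  # "ancestral_gain" | "free_gains"
    gain_cost: float = 1.0
    loss_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in {"ancestral_gain", "free_gains"}:
            raise ValueError(f"unknown scenario mode {self.mode!r}")

    @property
    def stem_top_state(self) -> int:
        return 1 if self.mode == "ancestral_gain" else 0

    @property
    def effective_gain_cost(self) -> float:
        # gains prohibited once the ancestral intron exists
        return INF if self.mode == "ancestral_gain" else self.gain_cost


@dataclass
class PresencePattern:
    """Per-(lineage, FU) intron presence; ``missing`` = FU absent in lineage."""

    states: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for v in self.states.values():
            if v not in {PRESENT, ABSENT, MISSING}:
                raise ValueError(f"bad state {v!r}")
        if not any(v == PRESENT for v in self.states.values()):
            raise ValueError("pattern contains no present entry: nothing to explain")

    @property
    def fus(self) -> list[str]:
        return sorted({fu for (_, fu) in self.states})

    @property
    def lineages(self) -> list[str]:
        return sorted({ln for (ln, _) in self.states})

    def state(self, lineage: str, fu: str) -> str:
        return self.states.get((lineage, fu), MISSING)

    @classmethod
    def from_tsv(cls, path) -> "PresencePattern":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {(str(r.lineage), str(r.fu)): str(r.state) for r in df.itertuples()}
        )


@dataclass
class EventTally:
    gains: int
    losses: int
    events: list[tuple[str, str, str]] = field(default_factory=list)
    # (branch = child-node name or "stem"/"precursor", fu_id, "gain"|"loss")

    @property
    def total(self) -> int:
        return self.gains + self.losses


def _leaf_cost(state: str) -> list[float]:
    if state == PRESENT:
        return [INF, 0.0]
    if state == ABSENT:
        return [0.0, INF]
    return [0.0, 0.0]  # missing FU: unconstrained


def _trans_cost(parent: int, child: int, gain: float, loss: float) -> float:
    if parent == child:
        return 0.0
    return gain if child == 1 else loss


def _sankoff_one_fu(
    tree: LineageTree, pattern: PresencePattern, fu: str, scenario: ScenarioConstraint
) -> tuple[int, int, list[tuple[str, str, str]]]:
    gain = scenario.effective_gain_cost
    loss = scenario.loss_cost
    cost: dict[int, list[float]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            st = pattern.state(node.name, fu)
            cost[id(node)] = _leaf_cost(st)
        else:
            c = [0.0, 0.0]
            for s in (0, 1):
                for child in node.children:
                    c[s] += min(
                        cost[id(child)][t] + _trans_cost(s, t, gain, loss)
                        for t in (0, 1)
                    )
            cost[id(node)] = c

    top = scenario.stem_top_state
    best_root = min(
        (0, 1),
        key=lambda s: (cost[id(tree.root)][s] + _trans_cost(top, s, gain, loss), s),
    )
    total = cost[id(tree.root)][best_root] + _trans_cost(top, best_root, gain, loss)
    if total == INF:
        raise ValueError(f"pattern for FU {fu} unexplainable under {scenario.mode}")

    # backtrack; ties prefer keeping the parent's state (deterministic)
    events: list[tuple[str, str, str]] = []
    gains = losses = 0
    if best_root != top:
        if best_root == 1:
            gains += 1
            events.append(("stem", fu, "gain"))
        else:
            losses += 1
            events.append(("stem", fu, "loss"))

    def walk(node: TreeNode, state: int) -> None:
        nonlocal gains, losses
        for child in node.children:
            cand = sorted(
                (0, 1),
                key=lambda t: (
                    cost[id(child)][t] + _trans_cost(state, t, gain, loss),
                    t != state,
                ),
            )
            t = cand[0]
            if t != state:
                if t == 1:
                    gains += 1
                    events.append((child.name, fu, "gain"))
                else:
                    losses += 1
                    events.append((child.name, fu, "loss"))
            walk(child, t)

    walk(tree.root, best_root)
    return gains, losses, events


def _check_pattern(pattern: PresencePattern, tree: LineageTree) -> None:
    unknown = set(pattern.lineages) - set(tree.leaf_names)
    if unknown:
        raise ValueError(f"pattern lineages not in tree: {sorted(unknown)}")


def min_events(
    pattern: PresencePattern, tree: LineageTree, scenario: ScenarioConstraint
) -> EventTally:
    """Minimal gain/loss tally explaining ``pattern`` under ``scenario``.

    Per FU, binary-state Sankoff dynamic programming with the stem-top state
    fixed by the scenario; FU tallies are summed.  In ``ancestral_gain``
    mode exactly one gain — the origin of the intron in the mono-domain
    precursor — is added regardless of the number of FUs.
    """
    _check_pattern(pattern, tree)
    gains = losses = 0
    events: list[tuple[str, str, str]] = []
    for fu in pattern.fus:
        g, l, ev = _sankoff_one_fu(tree, pattern, fu, scenario)
        gains += g
        losses += l
        events.extend(ev)
    if scenario.mode == "ancestral_gain":
        gains += 1
        events.insert(0, ("precursor", "*", "gain"))
    return EventTally(gains=gains, losses=losses, events=events)


def brute_force_events(
    pattern: PresencePattern, tree: LineageTree, scenario: ScenarioConstraint
) -> EventTally:
    """Exhaustive-enumeration oracle for :func:`min_events` (<= 8 leaves)."""
    _check_pattern(pattern, tree)
    if len(tree.leaf_names) > 8:
        raise ValueError("brute force restricted to trees with <= 8 leaves")
    gain = scenario.effective_gain_cost
    loss = scenario.loss_cost
    internals = [n for n in tree.root.postorder() if not n.is_leaf]

    tot_gains = tot_losses = 0
    for fu in pattern.fus:
        best = INF
        best_gl = (0, 0)
        leaf_states = {
            l.name: pattern.state(l.name, fu) for l in tree.root.leaves()
        }
        leaf_choices = {
            name: ((1,) if s == PRESENT else (0,) if s == ABSENT else (0, 1))
            for name, s in leaf_states.items()
        }
        leaves = tree.root.leaves()
        for internal_assign in itertools.product((0, 1), repeat=len(internals)):
            states = {id(n): s for n, s in zip(internals, internal_assign)}
            for leaf_assign in itertools.product(
                *(leaf_choices[l.name] for l in leaves)
            ):
                for l, s in zip(leaves, leaf_assign):
                    states[id(l)] = s
                g = l_ = 0
                c = _trans_cost(
                    scenario.stem_top_state, states[id(tree.root)], gain, loss
                )
                if states[id(tree.root)] != scenario.stem_top_state:
                    if states[id(tree.root)] == 1:
                        g += 1
                    else:
                        l_ += 1
                ok = c < INF
                if ok:
                    for node in tree.root.postorder():
                        for child in node.children:
                            tc = _trans_cost(
                                states[id(node)], states[id(child)], gain, loss
                            )
                            c += tc
                            if c == INF:
                                ok = False
                                break
                            if states[id(child)] != states[id(node)]:
                                if states[id(child)] == 1:
                                    g += 1
                                else:
                                    l_ += 1
                        if not ok:
                            break
                if ok and c < best:
                    best = c
                    best_gl = (g, l_)
        if best == INF:
            raise ValueError(f"pattern for FU {fu} unexplainable under {scenario.mode}")
        tot_gains += best_gl[0]
        tot_losses += best_gl[1]
    if scenario.mode == "ancestral_gain":
        tot_gains += 1
    return EventTally(gains=tot_gains, losses=tot_losses)


def compare_scenarios(
    pattern: PresencePattern, tree: LineageTree
) -> dict[str, object]:
    """Score both scenarios and flag the more parsimonious one."""
    tallies = {
        mode: min_events(pattern, tree, ScenarioConstraint(mode=mode))
        for mode in ("ancestral_gain", "free_gains")
    }
    totals = {m: t.total for m, t in tallies.items()}
    if totals["ancestral_gain"] == totals["free_gains"]:
        preferred = "tie"
    else:
        preferred = min(totals, key=totals.get)
    return {"tallies": tallies, "totals": totals, "preferred": preferred}


# ---------------------------------------------------------------------------
# the lineage pattern discussed for FU-b/f/g (worked example of the analysis)

DEFAULT_TREE_NEWICK = (
    "(Cephalopoda:2.0,(Vetigastropoda:1.0,Tectipleura:1.0)Gastropoda:1.0)"
    "Mollusca:1.0;"
)


def bfg_pattern(fus: Iterable[str] = "abcdefgh") -> PresencePattern:
    """Intron present in FU-b, FU-f, FU-g of Tectipleura only; FU-h missing
    in Cephalopoda (cephalopod hemocyanins lack FU-h)."""
    states: dict[tuple[str, str], str] = {}
    for fu in fus:
        for lineage in ("Cephalopoda", "Vetigastropoda", "Tectipleura"):
            if lineage == "Cephalopoda" and fu == "h":
                states[(lineage, fu)] = MISSING
            elif lineage == "Tectipleura" and fu in {"b", "f", "g"}:
                states[(lineage, fu)] = PRESENT
            else:
                states[(lineage, fu)] = ABSENT
    return PresencePattern(states)


def tally_to_json(tally: EventTally) -> dict:
    return {
        "gains": tally.gains,
        "losses": tally.losses,
        "total": tally.total,
        "events": [
            {"branch": b, "fu": f, "kind": k} for (b, f, k) in tally.events
        ],
    }
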