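"""Maximum-parsimony ancestral reconstruction of binary domain presence.

Leaves of the target-gene tree carry 0/1 traits — presence of a tailoring
domain (e.g. CYP705A, CYP708A, CYP702A, ACT_IIIa) in the leaf's genome
neighbourhood. The Fitch bottom-up pass yields the parsimony score (number
of union events = minimum number of state changes); the full set of
most-parsimonious states per internal node is computed by a unit-cost
min-change dynamic programme over the tree (down costs by postorder, up
costs by preorder), which is exact under ties. Branches whose parent and
child state sets are disjoint singletons are gains (0 to 1) or losses
(1 to 0); branches touching a node that admits both states are reported
as ambiguous rather than forced by an acceleration/delay heuristic.

Before reconstruction the tree is pruned of leaves whose GN is too small,
and GNs represented by several leaves (multi-target neighbourhoods) are
reduced to one representative leaf chosen by DSS.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

_INF = float("inf")


@dataclass
class TraitTree:
    """Rooted tree plus a leaf x domain 0/1 trait matrix."""

    tree: dendropy.Tree
    traits: pd.DataFrame  # index = leaf names, columns = domains, values 0/1
    leaf_to_gn: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        leaves = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = leaves - set(self.traits.index)
        if missing:
            raise ValueError(f"leaves without a trait row: {sorted(missing)}")
        bad = set(self.traits.values.ravel()) - {0, 1}
        if bad:
            raise ValueError(f"traits must be 0/1, found {sorted(bad)}")


@dataclass(frozen=True)
class BranchEvent:
    child: str  # node label identifying the branch by its child node
    domain: str
    event: str  # "gain" | "loss" | "none" | "ambiguous"
    state_parent: str
    state_child: str


@dataclass
class EventMap:
    domain: str
    events: list[BranchEvent]
    gains: int
    losses: int
    n_ambiguous: int
    parsimony_score: int


@dataclass
class FitchResult:
    domain: str
    score: int
    state_sets: dict[str, frozenset[int]]  # node label -> MPR states
    tree: dendropy.Tree


def root_tree(tree: dendropy.Tree, outgroup: str | None = None) -> dendropy.Tree:
    """Root at a named outgroup leaf, else at the midpoint."""
    tree = tree.clone(depth=1)
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup leaf {outgroup!r} not in tree")
        tree.to_outgroup_position(node, update_bipartitions=False)
    else:
        tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def prune_for_reconstruction(
    tree: dendropy.Tree,
    leaf_to_gn: Mapping[str, str],
    gn_sizes: Mapping[str, int],
    min_genes: int = 11,
) -> dendropy.Tree:
    """Remove leaves whose GN holds fewer than ``min_genes`` genes.

    Unary internal nodes left by the pruning are suppressed with their
    branch lengths summed. Pruning to fewer than 2 leaves is an error.
    """
    drop = []
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        gn = leaf_to_gn.get(name)
        if gn is None:
            raise ValueError(f"leaf {name!r} has no GN mapping")
        if gn_sizes[gn] < min_genes:
            drop.append(name)
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves - len(drop) < 2:
        raise ValueError("pruning would leave fewer than 2 leaves")
    pruned = tree.clone(depth=1)
    if drop:
        pruned.prune_taxa_with_labels(drop)
        logger.info("pruned %d leaves with GN < %d genes", len(drop), min_genes)
    return pruned


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for ta, tb in itertools.combinations(tree.taxon_namespace, 2):
        d = pdm.patristic_distance(ta, tb)
        out[(ta.label, tb.label)] = d
        out[(tb.label, ta.label)] = d
    return out


def select_representative_leaves(
    tree: dendropy.Tree,
    leaf_to_gn: Mapping[str, str],
    dss: Mapping[tuple[str, str], float] | Callable[[str, str], float],
    mode: str = "all",
    k: int = 4,
) -> dendropy.Tree:
    """Keep one representative leaf per GN mapped by several leaves.

    The representative maximises the mean DSS between its GN and the GNs
    of the comparison leaves — all other retained leaves (``mode="all"``,
    leaves sharing the same GN excluded) or the ``k`` nearest leaves by
    patristic distance (``mode="nearest"``). Ties break by leaf name
    (lexicographically first kept); non-representative leaves are pruned.
    """
    lookup = dss if callable(dss) else lambda a, b: dss[(a, b)] if a != b else 1.0
    leaves = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    by_gn: dict[str, list[str]] = {}
    for name in leaves:
        by_gn.setdefault(leaf_to_gn[name], []).append(name)

    dists = patristic_distances(tree) if mode == "nearest" else None

    drop: list[str] = []
    for gn, members in sorted(by_gn.items()):
        if len(members) == 1:
            continue

        def mean_dss(name: str) -> float:
            if mode == "all":
                others = [o for o in leaves if leaf_to_gn[o] != gn]
            elif mode == "nearest":
                ranked = sorted(
                    (o for o in leaves if o != name), key=lambda o: (dists[(name, o)], o)
                )
                others = ranked[:k]
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if not others:
                return 0.0
            return sum(lookup(gn, leaf_to_gn[o]) for o in others) / len(others)

        keep = min(members, key=lambda n: (-mean_dss(n), n))
        drop.extend(m for m in members if m != keep)
    pruned = tree.clone(depth=1)
    if drop:
        pruned.prune_taxa_with_labels(drop)
    return pruned


def _node_label(node: dendropy.Node, index: int) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{index}"


def _prepare(tree: dendropy.Tree) -> dendropy.Tree:
    """Clone, label internal nodes, and resolve multifurcations to binary
    with zero-length branches (logged) so the Fitch recurrence is
    well-posed."""
    tree = tree.clone(depth=1)
    poly = [n for n in tree.preorder_node_iter() if len(n.child_nodes()) > 2]
    if poly:
        logger.warning("resolving %d multifurcations with zero-length branches", len(poly))
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
    for i, node in enumerate(tree.preorder_node_iter()):
        if not node.is_leaf() and not node.label:
            node.label = f"node{i}"
    return tree


def fitch_parsimony(trait_tree: TraitTree, domain: str) -> FitchResult:
    """Fitch parsimony for one binary trait.

    The score comes from the classic bottom-up union/intersection pass;
    the per-node most-parsimonious state sets come from the unit-cost
    min-change DP, so a node's set holds every state attainable in *some*
    maximally parsimonious labeling (nodes with both states are
    ambiguous).
    """
    if domain not in trait_tree.traits.columns:
        raise ValueError(f"domain {domain!r} has no trait column")
    states = trait_tree.traits[domain]
    bad = set(states) - {0, 1}
    if bad:
        raise ValueError(f"non-binary trait values {sorted(bad)} for {domain}")
    tree = _prepare(trait_tree.tree)

    # bottom-up Fitch: count union events
    prelim: dict[int, frozenset[int]] = {}
    score = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            prelim[id(node)] = frozenset({int(states[node.taxon.label])})
        else:
            sets = [prelim[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                prelim[id(node)] = inter
            else:
                prelim[id(node)] = frozenset.union(*sets)
                score += 1

    # unit-cost min-change DP for exact MPR sets
    down: dict[int, dict[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = int(states[node.taxon.label])
            down[id(node)] = {s: 0.0, 1 - s: _INF}
        else:
            costs = {}
            for s in (0, 1):
                total = 0.0
                for c in node.child_nodes():
                    dc = down[id(c)]
                    total += min(dc[t] + (s != t) for t in (0, 1))
                costs[s] = total
            down[id(node)] = costs

    root = tree.seed_node
    best = min(down[id(root)].values())
    assert best == score, "Fitch union count and min-change DP disagree"

    up: dict[int, dict[int, float]] = {id(root): {0: 0.0, 1: 0.0}}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for c in children:
            sib_cost = {}
            for s in (0, 1):
                total = up[id(node)][s]
                for b in children:
                    if b is c:
                        continue
                    db = down[id(b)]
                    total += min(db[t] + (s != t) for t in (0, 1))
                sib_cost[s] = total
            up[id(c)] = {
                s: min(sib_cost[sp] + (sp != s) for sp in (0, 1)) for s in (0, 1)
            }

    state_sets: dict[str, frozenset[int]] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        label = _node_label(node, i)
        mpr = frozenset(
            s for s in (0, 1) if down[id(node)][s] + up[id(node)][s] == best
        )
        state_sets[label] = mpr
    return FitchResult(domain=domain, score=score, state_sets=state_sets, tree=tree)


def _fmt(states: frozenset[int]) -> str:
    return "/".join(str(s) for s in sorted(states))


def map_events(result: FitchResult) -> EventMap:
    """Classify every branch of the reconstruction as gain/loss/none/ambiguous.

    A branch is an unambiguous gain (0 -> 1) or loss (1 -> 0) only when
    both endpoint state sets are singletons and disjoint; if either
    endpoint admits both states, the branch is ambiguous.
    """
    events: list[BranchEvent] = []
    gains = losses = ambiguous = 0
    for i, node in enumerate(result.tree.preorder_node_iter()):
        parent = node.parent_node
        if parent is None:
            continue
        child_label = _node_label(node, i)
        pset = result.state_sets[_node_label(parent, -1) if parent.is_leaf() else parent.label]
        cset = result.state_sets[child_label]
        if len(pset) > 1 or len(cset) > 1:
            event = "ambiguous"
            ambiguous += 1
        elif pset == cset:
            event = "none"
        elif pset == frozenset({0}):
            event = "gain"
            gains += 1
        else:
            event = "loss"
            losses += 1
        events.append(
            BranchEvent(child_label, result.domain, event, _fmt(pset), _fmt(cset))
        )
    return EventMap(
        domain=result.domain,
        events=events,
        gains=gains,
        losses=losses,
        n_ambiguous=ambiguous,
        parsimony_score=result.score,
    )


def events_to_dataframe(event_maps: Sequence[EventMap]) -> pd.DataFrame:
    rows = [
        {
            "domain": ev.domain,
            "branch": ev.child,
            "event": ev.event,
            "state_parent": ev.state_parent,
            "state_child": ev.state_child,
        }
        for em in event_maps
        for ev in em.events
    ]
    return pd.DataFrame(
        rows, columns=["domain", "branch", "event", "state_parent", "state_child"]
    )


def annotated_newick(result: FitchResult) -> str:
    """Newick export with MPR state sets in comment brackets on nodes."""
    tree = result.tree.clone(depth=1)
    for i, node in enumerate(tree.preorder_node_iter()):
        label = _node_label(node, i)
        states = result.state_sets.get(label)
        if states is None:
            continue
        tag = f"[&states={_fmt(states)}]"
        if node.is_leaf():
            node.taxon.label = node.taxon.label + tag
        else:
            node.label = (node.label or "") + tag
    return tree.as_string(schema="newick", suppress_rooting=True)
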