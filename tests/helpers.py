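"""Independent oracles and random-input generators for the test suite.

Everything here deliberately avoids the library's own tree machinery:
bipartitions come straight from dendropy, LCA/depth from explicit
parent-path walks, parsimony from exhaustive enumeration, and
duplication mapping from a from-scratch node scan.  These are the
reference answers the package is checked against.
"""

from __future__ import annotations

import itertools
from typing import Optional

import dendropy
import numpy as np


# -- random trees -------------------------------------------------------------


def random_binary_newick(
    rng: np.random.Generator,
    labels: list[str],
    with_supports: bool = True,
    with_lengths: bool = True,
    support_range: tuple[float, float] = (0.0, 100.0),
) -> str:
    """Random rooted binary topology over ``labels`` by iterative joining."""
    pieces = list(labels)
    while len(pieces) > 1:
        i, j = sorted(rng.choice(len(pieces), size=2, replace=False))
        b = pieces.pop(j)
        a = pieces.pop(i)
        sup = ""
        if with_supports:
            lo, hi = support_range
            sup = f"{rng.integers(int(lo), int(hi) + 1)}"
        ln = f":{rng.uniform(0.1, 1.0):.3f}" if with_lengths else ""
        pieces.append(f"({a}{ln},{b}{ln}){sup}")
    out = pieces[0] + ";"
    # the two root-child edges are one unrooted bipartition; make their
    # support annotations agree, as any real bootstrap tree would
    t = dendropy.Tree.get(data=out, schema="newick",
                          suppress_internal_node_taxa=True, preserve_underscores=True)
    kids = [k for k in t.seed_node.child_nodes() if not k.is_leaf()]
    if len(kids) == 2:
        kids[1].label = kids[0].label
    return t.as_string(schema="newick", suppress_rooting=True).strip()


# -- bipartitions via dendropy (round-trip oracle) ----------------------------


def dendropy_bipartitions(newick: str) -> dict[frozenset, Optional[float]]:
    """Unrooted non-trivial bipartitions -> internal-label support.

    Each bipartition is keyed by the smaller-side leaf set (ties broken
    lexicographically) so rooted placement does not matter.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out: dict[frozenset, Optional[float]] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if not other:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        if len(key) <= 1:
            continue  # trivial leaf-edge bipartition
        support = float(node.label) if node.label is not None else None
        # both children of a binary root describe the same bipartition;
        # keep a defined support if either side has one
        if key not in out or out[key] is None:
            out[key] = support
    return out


# -- parent-path oracles ------------------------------------------------------


def walk_depth(tree, node_id: int) -> int:
    node = tree.node(node_id)
    path = 0
    while node.parent is not None:
        node, path = node.parent, path + 1
    return path


def ancestor_ids(tree, node) -> list[int]:
    out = []
    while node is not None:
        out.append(node.node_id)
        node = node.parent
    return out


def lca_by_intersection(tree, labels) -> int:
    """LCA as the deepest node common to every leaf's ancestor path."""
    common: Optional[set[int]] = None
    for label in labels:
        anc = set(ancestor_ids(tree, tree.leaf(label)))
        common = anc if common is None else common & anc
    assert common
    return max(common, key=lambda nid: walk_depth(tree, nid))


def clade_sets(tree) -> dict[int, frozenset]:
    """node_id -> leaf-label set, by independent recursion."""
    out = {}

    def rec(node) -> frozenset:
        if not node.children:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(rec(c) for c in node.children))
        out[node.node_id] = s
        return s

    rec(tree.root)
    return out


def monophyly_by_bipartitions(newick: str, target: set) -> bool:
    """Target (restricted to sampled leaves) is a clade iff it equals one
    side of some bipartition, the full leaf set, or has <= 1 member."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    present = frozenset(target) & leaves
    if len(present) <= 1 or present == leaves:
        return True
    sides = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.add(side)
        sides.add(leaves - side)
    return present in sides


# -- brute-force parsimony ----------------------------------------------------


def brute_force_parsimony(tree, tip_sets: dict[str, frozenset], states: list[str],
                          cost=None) -> tuple[float, dict[int, set]]:
    """Minimum changes over all internal labelings; exponential, tiny trees only.

    Returns (score, MPR state sets per internal node id).
    """
    internal = [n for n in tree.nodes if n.children]
    leaves = [n for n in tree.nodes if not n.children]

    def edge_cost(a: str, b: str) -> float:
        if cost is not None:
            return cost[a][b]
        return 0.0 if a == b else 1.0

    best = float("inf")
    mpr: dict[int, set] = {n.node_id: set() for n in internal}
    leaf_choices = [sorted(tip_sets[l.label]) for l in leaves]
    for internal_assign in itertools.product(states, repeat=len(internal)):
        lab = {n.node_id: s for n, s in zip(internal, internal_assign)}
        # minimize over leaf ambiguity independently per leaf (parent fixed)
        total = 0.0
        for leaf, choices in zip(leaves, leaf_choices):
            total += min(edge_cost(lab[leaf.parent.node_id], c) for c in choices)
        for n in internal:
            if n.parent is not None:
                total += edge_cost(lab[n.parent.node_id], lab[n.node_id])
        if total < best - 1e-9:
            best = total
            mpr = {nid: {s} for nid, s in lab.items()}
        elif abs(total - best) <= 1e-9:
            for nid, s in lab.items():
                mpr[nid].add(s)
    return best, mpr


# -- brute-force duplication mapping ------------------------------------------


def brute_force_events(gene_tree, species_tree, min_support: float,
                       min_shared: int, depth_tolerance: int) -> list[tuple]:
    """Accepted duplication events by exhaustive scan, coded from scratch.

    Returns tuples (gene_node_id, mapped_species_node_id, type_label)
    sorted for comparison.
    """
    gclades = clade_sets(gene_tree)
    sclades = clade_sets(species_tree)
    events = []
    for node in gene_tree.nodes:
        if len(node.children) != 2:
            continue
        if node.parent is None:
            support = 100.0 if node.support is None else node.support
        else:
            support = node.support
        if support is None or support <= min_support:
            continue
        left = {l.split("|")[0] for l in gclades[node.children[0].node_id]}
        right = {l.split("|")[0] for l in gclades[node.children[1].node_id]}
        if len(left & right) < min_shared:
            continue
        l1 = lca_by_intersection(species_tree, left)
        l2 = lca_by_intersection(species_tree, right)
        if abs(walk_depth(species_tree, l1) - walk_depth(species_tree, l2)) > depth_tolerance:
            continue
        mapped = lca_by_intersection(species_tree, left | right)
        events.append((node.node_id, mapped, _bf_type(species_tree, sclades, mapped, left, right)))
    return sorted(events)


def _bf_type(species_tree, sclades, mapped: int, left: set, right: set) -> str:
    node = species_tree.node(mapped)
    if len(sclades[mapped]) < 3 or len(node.children) != 2:
        return "NA"
    a = sclades[node.children[0].node_id]
    b = sclades[node.children[1].node_id]
    big, small = sorted([a, b], key=lambda s: (-len(s), sorted(s)))
    in_big = sum(1 for s in (left, right) if s & big)
    in_small = sum(1 for s in (left, right) if s & small)
    if in_big == 2 and in_small == 2:
        return "I"
    if in_small == 1 and in_big == 2:
        return "II"
    if in_big == 1 and in_small == 2:
        return "III"
    return "NA"
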