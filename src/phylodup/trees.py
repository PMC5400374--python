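"""Rooted-tree data model and primitives for gene-tree / species-tree work.

Trees carry optional branch lengths, internal-node support values on a
0-100 scale (bootstrap percentages), and deterministic post-order node
identifiers.  Newick parsing is delegated to dendropy; writing is done
here so output is byte-deterministic.

Support semantics follow bootstrap conventions: values are stored on
0-100 (inputs on 0-1 are rescaled when the maximum is <= 1) and every
threshold comparison in this package is strict (``support > threshold``).
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "NewickParseError",
    "ValidationError",
    "RootingError",
    "parse_newick",
    "write_newick",
    "node_depth",
    "lca",
    "is_monophyletic",
    "supported_conflict",
    "root_by_outgroup",
    "make_gene_label",
    "split_gene_label",
]


class TreeError(Exception):
    """Base class for tree-related errors."""


class NewickParseError(TreeError):
    pass


class ValidationError(TreeError):
    pass


class RootingError(TreeError):
    """Raised when an outgroup is not separable on the unrooted topology."""


class Node:
    """A single tree node.

    ``support`` is meaningful on internal nodes only (it annotates the
    edge to the parent); ``label`` is the leaf name on leaves.
    """

    __slots__ = ("children", "parent", "branch_length", "support", "label", "node_id")

    def __init__(
        self,
        label: Optional[str] = None,
        branch_length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.branch_length = branch_length
        self.support = support
        self.label = label
        self.node_id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.label!r}" if self.is_leaf else f"internal ({len(self.children)} ch)"
        return f"<Node {self.node_id} {kind}>"


class Tree:
    """A rooted tree with stable post-order node ids.

    The node list is frozen at construction; any structural change goes
    through an operation that builds a new ``Tree``.
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self.nodes: list[Node] = []
        self._index_postorder()
        self._leaf_by_label: dict[str, Node] = {}
        self._validate()
        self._leafsets: Optional[list[frozenset[str]]] = None

    # -- construction helpers -------------------------------------------------

    def _index_postorder(self) -> None:
        self.nodes = list(_postorder(self.root))
        for i, node in enumerate(self.nodes):
            node.node_id = i

    def _validate(self) -> None:
        for node in self.nodes:
            if node.is_leaf:
                if node.label is None:
                    raise ValidationError("leaf without a label")
                if node.label in self._leaf_by_label:
                    raise ValidationError(f"duplicate leaf label {node.label!r}")
                self._leaf_by_label[node.label] = node
            elif node.support is not None and not (0.0 <= node.support <= 100.0):
                raise ValidationError(
                    f"support {node.support} outside [0, 100] at node {node.node_id}"
                )
            if node.branch_length is not None and node.branch_length < 0:
                raise ValidationError(f"negative branch length at node {node.node_id}")

    # -- basic accessors ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> Node:
        try:
            return self.nodes[node_id]
        except IndexError:
            raise KeyError(f"unknown node id {node_id}") from None

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return set(self._leaf_by_label)

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise KeyError(f"unknown leaf label {label!r}") from None

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.nodes if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    def leafset(self, node: Node) -> frozenset[str]:
        """Leaf labels below ``node`` (cached per tree)."""
        if self._leafsets is None:
            sets: list[frozenset[str]] = [frozenset()] * len(self.nodes)
            for n in self.nodes:  # post-order: children first
                if n.is_leaf:
                    sets[n.node_id] = frozenset((n.label,))
                else:
                    acc: set[str] = set()
                    for c in n.children:
                        acc.update(sets[c.node_id])
                    sets[n.node_id] = frozenset(acc)
            self._leafsets = sets
        return self._leafsets[node.node_id]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.nodes if not n.is_leaf)

    def require_binary_species_tree(self) -> None:
        """Species trees must be fully bifurcating for depth steps to be
        well defined; polytomies raise a validation error."""
        bad = [n.node_id for n in self.nodes if n.children and len(n.children) != 2]
        if bad:
            raise ValidationError(
                f"species tree has non-binary internal nodes (ids {bad}); "
                "depth steps require a fully resolved tree"
            )

    def copy(self) -> "Tree":
        return parse_newick(write_newick(self))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __hash__(self) -> int:  # trees are mutable in principle; identity hash
        return id(self)


def _postorder(root: Node) -> Iterator[Node]:
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))


# -- Newick I/O ---------------------------------------------------------------


def parse_newick(text: str, support_convention: str = "internal_label") -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Parameters
    ----------
    text:
        Newick string, one tree.
    support_convention:
        ``"internal_label"`` reads numeric internal-node labels as
        bootstrap supports (RAxML dialect); ``"comment"`` reads the first
        numeric bracketed comment attached to an internal node.
    """
    if support_convention not in ("internal_label", "comment"):
        raise ValueError(f"unknown support convention {support_convention!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy error messages carry line/column info
        if "duplicate" in str(exc).lower():
            raise ValidationError(str(exc)) from None
        raise NewickParseError(f"malformed newick: {exc}") from None

    def convert(dnode: dendropy.Node) -> Node:
        node = Node()
        node.branch_length = dnode.edge.length
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if node.label is None:
                raise NewickParseError("leaf without a label")
        else:
            raw: Optional[str] = None
            if support_convention == "internal_label":
                raw = dnode.label
            else:
                for comment in dnode.comments or []:
                    raw = comment
                    break
            if raw is not None:
                try:
                    node.support = float(raw)
                except ValueError:
                    pass  # non-numeric internal label: not a support, ignored
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    _rescale_supports(root)
    return Tree(root)


def _rescale_supports(root: Node) -> None:
    """Supports given as fractions (max <= 1) are rescaled to 0-100."""
    supports = [n.support for n in _postorder(root) if n.support is not None]
    if supports and max(supports) <= 1.0:
        for n in _postorder(root):
            if n.support is not None:
                n.support *= 100.0


def _fmt_num(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(round(x, 10))


def write_newick(tree: Tree) -> str:
    """Serialize with supports as internal-node labels."""
    out = io.StringIO()

    def emit(node: Node) -> None:
        if node.is_leaf:
            out.write(node.label)
        else:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                emit(child)
            out.write(")")
            if node.support is not None:
                out.write(_fmt_num(node.support))
        if node.branch_length is not None:
            out.write(":" + _fmt_num(node.branch_length))

    emit(tree.root)
    out.write(";")
    return out.getvalue()


# -- primitives ---------------------------------------------------------------


def node_depth(tree: Tree, node_id: int) -> int:
    """Number of edges from the root ("steps"); the root is at depth 0."""
    node = tree.node(node_id)
    depth = 0
    while node.parent is not None:
        node = node.parent
        depth += 1
    return depth


def lca(tree: Tree, leaves: Iterable[str]) -> int:
    """Node id of the last common ancestor of a set of leaf labels."""
    target = set(leaves)
    if not target:
        raise ValueError("lca of an empty leaf set is undefined")
    missing = sorted(target - tree.leaf_labels())
    if missing:
        raise KeyError(f"leaves not in tree: {missing}")
    if len(target) == 1:
        return tree.leaf(next(iter(target))).node_id
    node = tree.root
    while True:
        for child in node.children:
            if target <= tree.leafset(child):
                node = child
                break
        else:
            return node.node_id


def is_monophyletic(tree: Tree, target: Iterable[str]) -> bool:
    """True iff the target labels present in the tree form a clade.

    Evaluated relative to the taxa sampled in this tree: absent members
    are ignored, and groups with <= 1 sampled member are vacuously
    monophyletic.
    """
    present = set(target) & tree.leaf_labels()
    if not present:
        warnings.warn("monophyly query with no target leaves in tree", stacklevel=2)
        return True
    if len(present) == 1:
        return True
    anc = tree.node(lca(tree, present))
    return tree.leafset(anc) == frozenset(present)


def supported_conflict(tree: Tree, target: Iterable[str], min_support: float) -> bool:
    """Does a well-supported clade contradict monophyly of ``target``?

    True iff some internal node with support strictly above
    ``min_support`` subtends a clade that overlaps the target set while
    neither containing it nor being contained in it.  Monophyletic
    targets can never conflict; unsupported (or root) nodes never count.
    """
    present = frozenset(set(target) & tree.leaf_labels())
    if len(present) <= 1:
        return False
    for node in tree.internal_nodes():
        if node.support is None or not node.support > min_support:
            continue
        clade = tree.leafset(node)
        inter = clade & present
        if inter and not clade <= present and not present <= clade:
            return True
    return False


def root_by_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Re-root so the root separates the outgroup from everything else.

    The outgroup must be separable (monophyletic on the unrooted
    topology); otherwise :class:`RootingError` is raised and the caller
    decides whether to skip the family.  Supports stay attached to their
    unrooted bipartitions.
    """
    labels = tree.leaf_labels()
    og = frozenset(set(outgroup) & labels)
    if not og:
        raise RootingError("outgroup shares no leaves with the tree")
    if og == labels:
        raise RootingError("outgroup equals the full leaf set")
    complement = frozenset(labels - og)

    edge_child: Optional[Node] = None
    for node in tree.nodes:
        if node is tree.root:
            continue
        ls = tree.leafset(node)
        if ls == og or ls == complement:
            edge_child = node
            break
    if edge_child is None:
        raise RootingError(
            f"outgroup {sorted(og)} is not separable on the unrooted topology"
        )

    parent = edge_child.parent
    assert parent is not None

    def neighbors(node: Node) -> list[Node]:
        out = list(node.children)
        if node.parent is not None:
            out.append(node.parent)
        return out

    def build_away(node: Node, come_from: Node) -> Node:
        """Rebuild the subtree hanging off ``node`` away from ``come_from``.

        Edge attributes between ``node`` and a neighbour are stored on
        whichever of the two is the child in the *old* orientation.
        """
        new = Node(label=node.label)
        for nb in neighbors(node):
            if nb is come_from:
                continue
            sub = build_away(nb, node)
            if nb is node.parent:
                sub.support, sub.branch_length = node.support, node.branch_length
            else:
                sub.support, sub.branch_length = nb.support, nb.branch_length
            new.children.append(sub)
            sub.parent = new
        return new

    half = None if edge_child.branch_length is None else edge_child.branch_length / 2.0
    side_a = build_away(edge_child, parent)
    side_a.support, side_a.branch_length = edge_child.support, half
    side_b = build_away(parent, edge_child)
    side_b.support, side_b.branch_length = edge_child.support, half

    new_root = Node()
    new_root.add_child(side_a)
    new_root.add_child(side_b)
    _suppress_unary(new_root)
    return Tree(new_root)


def _suppress_unary(root: Node) -> None:
    """Splice out internal nodes with a single child (old binary roots)."""
    for node in list(_postorder(root)):
        if node.is_leaf or len(node.children) != 1 or node.parent is None:
            continue
        child = node.children[0]
        if node.branch_length is not None or child.branch_length is not None:
            child.branch_length = (node.branch_length or 0.0) + (child.branch_length or 0.0)
        if child.support is None:
            child.support = node.support
        idx = node.parent.children.index(node)
        node.parent.children[idx] = child
        child.parent = node.parent
    # the root itself may be unary after rerooting a two-leaf tree; leave it.


def prune_to_leaves(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restrict a tree to a subset of leaves, splicing out pass-through
    nodes (branch lengths summed, the surviving child's support kept)."""
    keep_set = set(keep)
    missing = sorted(keep_set - tree.leaf_labels())
    if missing:
        raise KeyError(f"leaves not in tree: {missing}")
    if not keep_set:
        raise ValueError("cannot prune to an empty leaf set")

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label not in keep_set:
                return None
            out = Node(label=node.label, branch_length=node.branch_length)
            return out
        kept = [c2 for c in node.children if (c2 := rec(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            if node.branch_length is not None or only.branch_length is not None:
                only.branch_length = (node.branch_length or 0.0) + (only.branch_length or 0.0)
            return only
        fresh = Node(branch_length=node.branch_length, support=node.support)
        for c in kept:
            fresh.add_child(c)
        return fresh

    new_root = rec(tree.root)
    assert new_root is not None
    new_root.parent = None
    return Tree(new_root)


# -- gene leaf labels ---------------------------------------------------------


def make_gene_label(species_id: str, gene_id: str) -> str:
    """Serialize a gene-tree leaf as ``species|gene``."""
    for token, name in ((species_id, "species_id"), (gene_id, "gene_id")):
        if "|" in token or any(ch.isspace() for ch in token):
            raise ValueError(f"{name} {token!r} contains '|' or whitespace")
    return f"{species_id}|{gene_id}"


def split_gene_label(label: str) -> tuple[str, str]:
    species_id, sep, gene_id = label.partition("|")
    if not sep or not species_id or not gene_id:
        raise ValueError(f"not a species|gene label: {label!r}")
    return species_id, gene_id


def gene_tree_species(tree: Tree, node: Node) -> frozenset[str]:
    """Species represented among the gene leaves below ``node``."""
    return frozenset(split_gene_label(l)[0] for l in tree.leafset(node))
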