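"""Whole-genome-duplication detection by gene-tree / species-tree mapping.

A duplication node is a well-supported gene-tree node whose two child
subtrees share species; it is placed on the species tree at the last
common ancestor (LCA) of the union of those species, provided the two
subclade LCAs sit at the same or nearly the same depth (depth = edge
steps from the species-tree root).  A burst of gene families mapping to
one species-tree node is the phylogenomic signature of a WGD.

Each mapped event is further classified by paralog retention relative to
the two descendant lineages of the mapped node (ordered big/small by
species count): type I keeps both gene copies in both lineages, type II
lacks duplicates for the entire small lineage, type III for the entire
large lineage.  Type I events carry the strongest WGD evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .families import GeneFamily
from .trees import Node, Tree, gene_tree_species, lca, node_depth, split_gene_label

__all__ = [
    "MappingConfig",
    "DuplicationEvent",
    "NodeDuplicationSummary",
    "detect_duplication_nodes",
    "map_duplication",
    "classify_type",
    "map_family",
    "summarize_per_node",
    "run_mapping",
]


@dataclass(frozen=True)
class MappingConfig:
    """Thresholds of the duplication-mapping rule.

    ``min_support``: bootstrap threshold, strict ``>`` (default 50).
    ``min_shared_species``: minimum species shared by the two subclades.
    ``depth_tolerance``: maximum allowed difference in species-tree depth
    between the two subclade LCAs (steps).
    ``count_family_once_per_node``: deduplicate a family within a node
    when counting duplicated families.
    """

    min_support: float = 50.0
    min_shared_species: int = 2
    depth_tolerance: int = 1
    count_family_once_per_node: bool = True

    def __post_init__(self) -> None:
        if self.min_shared_species < 1:
            raise ValueError("min_shared_species must be >= 1")
        if self.depth_tolerance < 0:
            raise ValueError("depth_tolerance must be >= 0")


@dataclass(frozen=True)
class Candidate:
    node_id: int
    support: float  # root carries 100.0 by convention
    left_species: frozenset[str]
    right_species: frozenset[str]
    is_root: bool

    @property
    def shared(self) -> frozenset[str]:
        return self.left_species & self.right_species


@dataclass(frozen=True)
class DuplicationEvent:
    family_id: str
    gene_node: int
    support: float
    left_species: frozenset[str]
    right_species: frozenset[str]
    lca_left: int
    lca_right: int
    depth_left: int
    depth_right: int
    mapped_node: int
    topology_type: str = "NA"  # "I" | "II" | "III" | "NA"
    is_root: bool = False


def detect_duplication_nodes(gene_tree: Tree, config: MappingConfig) -> list[Candidate]:
    """Gene-tree nodes passing the support and shared-species rules.

    Only binary internal nodes can be duplication nodes (polytomies are
    unresolved, not duplications).  The root has no bootstrap value and
    is treated as maximally supported; it is flagged in the output.
    """
    if not gene_tree.leaf_labels():
        raise ValueError("empty gene tree")
    out: list[Candidate] = []
    for node in gene_tree.internal_nodes():
        if len(node.children) != 2:
            continue
        is_root = node is gene_tree.root
        support = 100.0 if is_root and node.support is None else node.support
        if support is None or not support > config.min_support:
            continue
        left = gene_tree_species(gene_tree, node.children[0])
        right = gene_tree_species(gene_tree, node.children[1])
        if len(left & right) >= config.min_shared_species:
            out.append(Candidate(node.node_id, support, left, right, is_root))
    return out


def map_duplication(
    family_id: str, candidate: Candidate, species_tree: Tree, config: MappingConfig
) -> tuple[Optional[DuplicationEvent], Optional[str]]:
    """Place a candidate on the species tree, or reject it.

    Returns ``(event, None)`` on acceptance and ``(None, reason)`` on
    rejection.  The mapped node is the shallower of the two subclade
    LCAs, equivalently the LCA of the union of species.
    """
    missing = sorted(
        (candidate.left_species | candidate.right_species) - species_tree.leaf_labels()
    )
    if missing:
        raise KeyError(f"species not in species tree: {missing}")
    l1 = lca(species_tree, candidate.left_species)
    l2 = lca(species_tree, candidate.right_species)
    d1 = node_depth(species_tree, l1)
    d2 = node_depth(species_tree, l2)
    if abs(d1 - d2) > config.depth_tolerance:
        return None, "depth_mismatch"
    mapped = lca(species_tree, candidate.left_species | candidate.right_species)
    event = DuplicationEvent(
        family_id=family_id,
        gene_node=candidate.node_id,
        support=candidate.support,
        left_species=candidate.left_species,
        right_species=candidate.right_species,
        lca_left=l1,
        lca_right=l2,
        depth_left=d1,
        depth_right=d2,
        mapped_node=mapped,
        is_root=candidate.is_root,
    )
    return event, None


def _big_small(species_tree: Tree, mapped_node: int) -> tuple[frozenset[str], frozenset[str]]:
    """Child-lineage species sets of a species-tree node, big first.

    Ties on species count break toward the lexicographically smaller
    sorted species list being "big" (only affects the II/III labels).
    """
    node = species_tree.node(mapped_node)
    a, b = (species_tree.leafset(c) for c in node.children)
    ka = (-len(a), sorted(a))
    kb = (-len(b), sorted(b))
    return (a, b) if ka <= kb else (b, a)


def classify_type(event: DuplicationEvent, species_tree: Tree) -> str:
    """Retention class of a mapped duplication (needs >= 3 species)."""
    node = species_tree.node(event.mapped_node)
    if len(species_tree.leafset(node)) < 3 or len(node.children) != 2:
        return "NA"
    big, small = _big_small(species_tree, event.mapped_node)
    subclades = (event.left_species, event.right_species)
    hits_big = sum(1 for s in subclades if s & big)
    hits_small = sum(1 for s in subclades if s & small)
    if hits_big == 2 and hits_small == 2:
        return "I"
    if hits_small == 1 and hits_big == 2:
        return "II"
    if hits_big == 1 and hits_small == 2:
        return "III"
    return "NA"  # degenerate: only reachable when the subclades share no species


def map_family(
    family: GeneFamily, species_tree: Tree, config: MappingConfig
) -> tuple[list[DuplicationEvent], list[tuple[int, str]]]:
    """All accepted (classified) events for one family, plus rejections."""
    if family.tree is None:
        raise ValueError(f"family {family.family_id} has no tree")
    events: list[DuplicationEvent] = []
    rejected: list[tuple[int, str]] = []
    for cand in detect_duplication_nodes(family.tree, config):
        event, reason = map_duplication(family.family_id, cand, species_tree, config)
        if event is None:
            rejected.append((cand.node_id, reason))
            continue
        event = DuplicationEvent(
            **{**event.__dict__, "topology_type": classify_type(event, species_tree)}
        )
        events.append(event)
    return events, rejected


@dataclass
class NodeDuplicationSummary:
    node_id: int
    depth: int
    n_species: int
    n_informative: int = 0
    n_dup_families: int = 0
    n_pairs: int = 0
    type_counts: dict[str, int] = field(default_factory=lambda: {"I": 0, "II": 0, "III": 0, "NA": 0})

    @property
    def pct(self) -> float:
        if self.n_informative == 0:
            return 0.0
        return round(100.0 * self.n_dup_families / self.n_informative, 2)


def summarize_per_node(
    events: Iterable[DuplicationEvent],
    families: Sequence[GeneFamily],
    species_tree: Tree,
    config: MappingConfig = MappingConfig(),
) -> dict[int, NodeDuplicationSummary]:
    """Per species-tree internal node: informative-family denominator,
    duplicated-family count/percentage, paralog-pair count, type mix.

    A family is informative for a node when it contains at least one gene
    from each of the node's two child lineages; the percentage is taken
    over these families only.
    """
    summaries: dict[int, NodeDuplicationSummary] = {}
    internal = [n for n in species_tree.internal_nodes() if len(n.children) == 2]
    child_sets = {
        n.node_id: tuple(species_tree.leafset(c) for c in n.children) for n in internal
    }
    for n in internal:
        summaries[n.node_id] = NodeDuplicationSummary(
            node_id=n.node_id,
            depth=node_depth(species_tree, n.node_id),
            n_species=len(species_tree.leafset(n)),
        )
    for fam in families:
        sp = fam.species
        for node_id, (left, right) in child_sets.items():
            if sp & left and sp & right:
                summaries[node_id].n_informative += 1
    seen_family_at_node: set[tuple[int, str]] = set()
    for ev in events:
        s = summaries[ev.mapped_node]
        s.n_pairs += 1
        s.type_counts[ev.topology_type] += 1
        key = (ev.mapped_node, ev.family_id)
        if not config.count_family_once_per_node:
            s.n_dup_families += 1
        elif key not in seen_family_at_node:
            seen_family_at_node.add(key)
            s.n_dup_families += 1
    return summaries


def events_table(events: Sequence[DuplicationEvent]) -> pd.DataFrame:
    rows = [
        {
            "family_id": ev.family_id,
            "gene_node": ev.gene_node,
            "support": ev.support,
            "shared_n": len(ev.left_species & ev.right_species),
            "L1_depth": ev.depth_left,
            "L2_depth": ev.depth_right,
            "mapped_node": ev.mapped_node,
            "type": ev.topology_type,
            "is_root": int(ev.is_root),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "gene_node", "support", "shared_n",
            "L1_depth", "L2_depth", "mapped_node", "type", "is_root",
        ],
    )


def summary_table(
    summaries: dict[int, NodeDuplicationSummary], min_pct: float = 0.0
) -> pd.DataFrame:
    rows = []
    for node_id in sorted(summaries):
        s = summaries[node_id]
        if s.pct < min_pct:
            continue
        rows.append(
            {
                "node": s.node_id,
                "depth": s.depth,
                "n_species": s.n_species,
                "n_informative": s.n_informative,
                "n_dup_families": s.n_dup_families,
                "pct": s.pct,
                "n_pairs": s.n_pairs,
                "type_I": s.type_counts["I"],
                "type_II": s.type_counts["II"],
                "type_III": s.type_counts["III"],
                "type_NA": s.type_counts["NA"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "node", "depth", "n_species", "n_informative", "n_dup_families",
            "pct", "n_pairs", "type_I", "type_II", "type_III", "type_NA",
        ],
    )


def run_mapping(
    families: Sequence[GeneFamily],
    species_tree: Tree,
    config: MappingConfig = MappingConfig(),
    outgroup: Optional[Iterable[str]] = None,
    out_dir: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Map every family, summarize per node, optionally write tables.

    Families without a tree are skipped and tallied.  When ``outgroup``
    is given, each gene tree is re-rooted on the outgroup species first;
    families whose outgroup is absent or not separable are skipped (a
    wrong root manufactures spurious deep duplications, so we refuse to
    guess).
    """
    from .trees import RootingError, root_by_outgroup

    species_tree.require_binary_species_tree()
    skip_counts = {"no_tree": 0, "no_outgroup": 0, "unrootable": 0}
    all_events: list[DuplicationEvent] = []
    used_families: list[GeneFamily] = []
    og = set(outgroup) if outgroup is not None else None
    for fam in sorted(families, key=lambda f: f.family_id):
        if fam.tree is None:
            skip_counts["no_tree"] += 1
            continue
        tree = fam.tree
        if og is not None:
            gene_og = {l for l in tree.leaf_labels() if split_gene_label(l)[0] in og}
            if not gene_og or gene_og == tree.leaf_labels():
                skip_counts["no_outgroup"] += 1
                continue
            try:
                tree = root_by_outgroup(tree, gene_og)
            except RootingError:
                skip_counts["unrootable"] += 1
                continue
            fam = GeneFamily.from_tree(fam.family_id, tree)
        events, _ = map_family(fam, species_tree, config)
        events.sort(key=lambda e: (e.family_id, e.gene_node))
        all_events.extend(events)
        used_families.append(fam)
    summaries = summarize_per_node(all_events, used_families, species_tree, config)
    ev_df = events_table(all_events)
    sum_df = summary_table(summaries)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ev_df.to_csv(out / "events.tsv", sep="\t", index=False)
        sum_df.to_csv(out / "node_summary.tsv", sep="\t", index=False)
    return ev_df, sum_df, skip_counts
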