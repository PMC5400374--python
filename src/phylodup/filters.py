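"""Staged ortholog curation against hidden paralogs.

The marker-selection logic proceeds in stages: cheap per-family filters
(sequence length in reference genomes, taxon coverage on a panel, copy
number caps in recently polyploid species) followed by hierarchical
topology-consistency screening, which removes families whose
well-supported gene-tree clades contradict monophyly of taxonomic
groups at successively finer ranks (order, then subfamily, then tribe).
Genes surviving every stage are the ones least likely to be hidden
paralogs - duplicates returned to single copy by differential loss,
which masquerade as orthologs and distort species-tree inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .families import GeneFamily, GeneMember
from .taxonomy import TaxonomyTable
from .trees import Tree, is_monophyletic, lca, node_depth, prune_to_leaves, supported_conflict

__all__ = [
    "FilterOutcome",
    "FilterStage",
    "TopologyAlternative",
    "filter_length",
    "filter_coverage",
    "filter_copy_number",
    "topology_stage",
    "run_hierarchical_filter",
    "HierarchicalFilterResult",
    "tally_alternatives",
    "reduce_to_single_copy",
    "ReduceResult",
]


@dataclass
class FilterOutcome:
    retained: list[GeneFamily]
    removed: list[tuple[str, str]]  # (family_id, reason)


def filter_length(
    families: Sequence[GeneFamily], min_len: int, required_species: Iterable[str]
) -> FilterOutcome:
    """Keep families whose copies in every required species are all at
    least ``min_len`` bp; a family missing a required species is dropped
    (reason ``missing_required``).  The boundary counts: exactly
    ``min_len`` passes."""
    required = sorted(set(required_species))
    retained, removed = [], []
    for fam in families:
        if any(sp not in fam.species for sp in required):
            removed.append((fam.family_id, "missing_required"))
            continue
        lengths = [l for sp in required for l in fam.lengths_of(sp)]
        if any(l is None for l in lengths):
            raise ValueError(
                f"family {fam.family_id}: missing sequence length for a required species"
            )
        if all(l >= min_len for l in lengths):
            retained.append(fam)
        else:
            removed.append((fam.family_id, "short_sequence"))
    return FilterOutcome(retained, removed)


def filter_coverage(
    families: Sequence[GeneFamily],
    panel: Sequence[str],
    min_present: Optional[int] = None,
    min_fraction: Optional[float] = None,
) -> FilterOutcome:
    """Keep families present in at least ``min_present`` of the panel
    species (or at least ``ceil(min_fraction * |panel|)`` in fraction
    mode)."""
    if not panel:
        raise ValueError("panel must be non-empty")
    if (min_present is None) == (min_fraction is None):
        raise ValueError("give exactly one of min_present / min_fraction")
    threshold = min_present if min_present is not None else math.ceil(min_fraction * len(panel))
    panel_set = set(panel)
    retained, removed = [], []
    for fam in families:
        if len(fam.species & panel_set) >= threshold:
            retained.append(fam)
        else:
            removed.append((fam.family_id, "low_coverage"))
    return FilterOutcome(retained, removed)


def filter_copy_number(
    families: Sequence[GeneFamily], species_caps: Mapping[str, int]
) -> FilterOutcome:
    """Keep families whose copy count in each capped species does not
    exceed its cap; species absent from a family count zero and pass."""
    retained, removed = [], []
    for fam in families:
        counts = fam.copy_numbers()
        if all(counts.get(sp, 0) <= cap for sp, cap in species_caps.items()):
            retained.append(fam)
        else:
            removed.append((fam.family_id, "copy_number"))
    return FilterOutcome(retained, removed)


# -- hierarchical topology screening ------------------------------------------


@dataclass(frozen=True)
class FilterStage:
    """One screening stage.

    ``conflict_reject`` fails a family when a well-supported gene-tree
    clade contradicts monophyly of some group at ``rank`` (or of an
    explicitly listed clade); ``clade_require`` fails when a named clade
    sampled with >= 2 species is not monophyletic at all.
    """

    stage_name: str
    mode: str = "conflict_reject"  # or "clade_require"
    rank: Optional[str] = None
    clades: Optional[Mapping[str, frozenset[str]]] = None  # name -> species set
    min_support: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("conflict_reject", "clade_require"):
            raise ValueError(f"unknown stage mode {self.mode!r}")
        if (self.rank is None) == (self.clades is None):
            raise ValueError("give exactly one of rank / clades")

    def groups(self, taxonomy: TaxonomyTable) -> dict[str, set[str]]:
        if self.rank is not None:
            return taxonomy.groups(self.rank)
        return {name: set(sp) for name, sp in self.clades.items()}


def _group_leaves(tree: Tree, group_species: set[str]) -> tuple[set[str], set[str]]:
    """(leaf labels, species sampled) of a species group in a gene tree."""
    leaves, sampled = set(), set()
    for label in tree.leaf_labels():
        sp = label.partition("|")[0] if "|" in label else label
        if sp in group_species:
            leaves.add(label)
            sampled.add(sp)
    return leaves, sampled


def topology_stage(
    family: GeneFamily, taxonomy: TaxonomyTable, stage: FilterStage
) -> tuple[bool, list[str]]:
    """Screen one family at one stage; returns (passed, offending groups)."""
    if family.tree is None:
        raise ValueError(f"family {family.family_id} has no tree")
    offending: list[str] = []
    for name, group_species in sorted(stage.groups(taxonomy).items()):
        leaves, sampled = _group_leaves(family.tree, group_species)
        if len(sampled) < 2:
            continue  # monophyly vacuous for singleton sampling
        if stage.mode == "conflict_reject":
            if supported_conflict(family.tree, leaves, stage.min_support):
                offending.append(name)
        else:
            if not is_monophyletic(family.tree, leaves):
                offending.append(name)
    return (not offending, offending)


@dataclass
class HierarchicalFilterResult:
    stages: list[FilterStage]
    retained_sets: list[list[GeneFamily]]  # index 0 = input, then per stage
    removals: pd.DataFrame  # family_id, stage, reason, offending_groups

    @property
    def final(self) -> list[GeneFamily]:
        return self.retained_sets[-1]

    def removal_counts(self) -> dict[str, int]:
        return {
            st.stage_name: int((self.removals["stage"] == st.stage_name).sum())
            for st in self.stages
        }


def run_hierarchical_filter(
    families: Sequence[GeneFamily],
    taxonomy: TaxonomyTable,
    stages: Sequence[FilterStage],
) -> HierarchicalFilterResult:
    """Apply stages in order (coarse to fine); each stage screens only
    the survivors of the previous one, so the retained sets are nested
    and a family failing several stages is charged to the first."""
    current = list(families)
    retained_sets = [current]
    rows = []
    for stage in stages:
        nxt = []
        for fam in current:
            passed, offending = topology_stage(fam, taxonomy, stage)
            if passed:
                nxt.append(fam)
            else:
                rows.append(
                    {
                        "family_id": fam.family_id,
                        "stage": stage.stage_name,
                        "reason": stage.mode,
                        "offending_groups": ";".join(offending),
                    }
                )
        retained_sets.append(nxt)
        current = nxt
    removals = pd.DataFrame(rows, columns=["family_id", "stage", "reason", "offending_groups"])
    return HierarchicalFilterResult(list(stages), retained_sets, removals)


# -- alternative-topology tallies ---------------------------------------------


@dataclass(frozen=True)
class TopologyAlternative:
    """An alternative resolved by monophyly of a defining clade.

    ``groups`` are taxonomy group labels (any rank) or bare species ids;
    the alternative holds in a tree when the union of their species is
    monophyletic there and subtended by a well-supported node.  E.g.
    "Dryadoideae basal" is defined by the clade {Rosoideae,
    Amygdaloideae}.
    """

    name: str
    groups: tuple[str, ...]


def tally_alternatives(
    trees: Sequence[Tree],
    alternatives: Sequence[TopologyAlternative],
    taxonomy: TaxonomyTable,
    min_support: float = 50.0,
) -> dict[str, int]:
    """Assign each tree to at most one alternative; the rest are
    ``unresolved``.  Counts always sum to the number of input trees."""
    names = [a.name for a in alternatives]
    if len(set(names)) != len(names):
        raise ValueError("duplicate alternative names")
    counts = {a.name: 0 for a in alternatives}
    counts["unresolved"] = 0
    alt_species = {a.name: [taxonomy.species_of_groups([g]) for g in a.groups] for a in alternatives}
    for tree in trees:
        matches = []
        for alt in alternatives:
            per_group = alt_species[alt.name]
            leaves_per_group = [_group_leaves(tree, gs) for gs in per_group]
            if any(not sampled for _, sampled in leaves_per_group):
                continue  # a defining group is unsampled: not assessable
            target = set().union(*(leaves for leaves, _ in leaves_per_group))
            if len(target) < 2 or len(target) == len(tree.leaf_labels()):
                continue
            if not is_monophyletic(tree, target):
                continue
            node = tree.node(lca(tree, target))
            if node.support is not None and node.support > min_support:
                matches.append(alt.name)
        if len(matches) > 1:
            raise ValueError(
                f"overlapping alternative definitions: tree matches {matches}"
            )
        if matches:
            counts[matches[0]] += 1
        else:
            counts["unresolved"] += 1
    return counts


# -- copy reduction for near-single-copy marker sets --------------------------


@dataclass
class ReduceResult:
    family: GeneFamily
    rule: str  # "single_copy_majority" | "clade_retained"
    tie: bool = False
    dropped_genes: list[str] = field(default_factory=list)


def _duplication_split(tree: Tree) -> Optional[int]:
    """Node id of the paralog split closest to the root: the shallowest
    binary node whose two child subtrees share a species."""
    best: Optional[tuple[int, int]] = None
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            continue
        left = {l.partition("|")[0] for l in tree.leafset(node.children[0])}
        right = {l.partition("|")[0] for l in tree.leafset(node.children[1])}
        if left & right:
            key = (node_depth(tree, node.node_id), node.node_id)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def reduce_to_single_copy(
    family: GeneFamily,
    ingroup: Optional[Iterable[str]] = None,
    majority_fraction: float = 0.5,
) -> ReduceResult:
    """Reduce a family to at most one copy per species.

    If more than ``majority_fraction`` of the (ingroup) species are
    single copy, the family is kept and recent species-specific
    duplicates are collapsed to one representative (lexicographically
    smallest gene id).  Otherwise only the child clade with more species
    at the basal-most paralog split is retained; a tie goes to the clade
    with the lexicographically smaller species list and is flagged.
    """
    if family.tree is None:
        raise ValueError(f"family {family.family_id} has no tree")
    tree = family.tree
    scored = family.species if ingroup is None else family.species & set(ingroup)
    if not scored:
        raise ValueError("no species to score (ingroup disjoint from family)")
    counts = family.copy_numbers()
    single = sum(1 for sp in scored if counts[sp] == 1)
    tie = False
    if single / len(scored) > majority_fraction:
        rule = "single_copy_majority"
        keep_labels = set(tree.leaf_labels())
    else:
        rule = "clade_retained"
        split = _duplication_split(tree)
        assert split is not None  # some species is multi-copy, so a split exists
        node = tree.node(split)
        sides = []
        for child in node.children:
            leaves = tree.leafset(child)
            species = sorted({l.partition("|")[0] for l in leaves})
            sides.append((leaves, species))
        (la, sa), (lb, sb) = sides
        if len(sa) != len(sb):
            keep_labels = set(la if len(sa) > len(sb) else lb)
        else:
            tie = True
            keep_labels = set(la if sa <= sb else lb)

    # collapse remaining multi-copy species to the smallest gene id
    best_gene: dict[str, str] = {}
    for label in sorted(keep_labels):
        sp, _, gene = label.partition("|")
        if sp not in best_gene or gene < best_gene[sp]:
            best_gene[sp] = gene
    final_labels = {f"{sp}|{g}" for sp, g in best_gene.items()}
    dropped = sorted(set(tree.leaf_labels()) - final_labels)
    reduced_tree = prune_to_leaves(tree, final_labels)
    members = [
        m for m in family.members if f"{m.species_id}|{m.gene_id}" in final_labels
    ]
    reduced = GeneFamily(family.family_id, members, reduced_tree)
    return ReduceResult(reduced, rule, tie, dropped)
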