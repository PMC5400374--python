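"""Synthetic gene families under duplication-loss with planted WGDs.

The generator emulates the statistical structure a transcriptome-scale
WGD screen consumes: gene-family trees arise by evolving one ancestral
gene lineage down a known species tree, with background duplications as
a Poisson process (rate ``dup_rate`` per lineage per unit branch
length), losses with exponential hazard ``loss_rate``, and optional
whole-genome duplications planted at chosen species-tree nodes where
every surviving lineage duplicates with retention probability ``r``.
Bootstrap-like supports are assigned afterwards from a constant or
two-point model, and a family can be corrupted with a single NNI to
mimic hidden-paralog-like topological noise.

Every family is reproducible on its own: family ``i`` draws from a
substream seeded by ``(seed, i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .families import GeneFamily, GeneMember, write_families
from .taxonomy import TaxonomyTable
from .trees import Node, Tree, make_gene_label, parse_newick, write_newick

__all__ = [
    "SupportModel",
    "SimulationConfig",
    "TruthEvent",
    "SimulatedFamily",
    "simulate_gene_tree",
    "assign_supports",
    "simulate_family",
    "simulate_families",
    "simulate_character",
    "build_fixture",
    "write_truth",
]


@dataclass(frozen=True)
class SupportModel:
    """Constant supports, or a two-point mixture of low/high values."""

    kind: str = "constant"  # "constant" | "two_point"
    value: float = 100.0
    p_low: float = 0.0
    low_value: float = 20.0
    high_value: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "two_point"):
            raise ValueError(f"unknown support model {self.kind!r}")
        if not 0.0 <= self.p_low <= 1.0:
            raise ValueError("p_low must lie in [0, 1]")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            return self.value
        return self.low_value if rng.random() < self.p_low else self.high_value

    @property
    def low(self) -> float:
        return self.value if self.kind == "constant" else self.low_value


@dataclass
class SimulationConfig:
    species_tree: Tree
    n_families: int
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    wgd_events: Sequence[tuple[int, float]] = ()  # (species node_id, retention prob)
    support_model: SupportModel = field(default_factory=SupportModel)
    perturb_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative and finite")
        if not np.isfinite(self.dup_rate) or not np.isfinite(self.loss_rate):
            raise ValueError("rates must be finite")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if not 0.0 <= self.perturb_prob <= 1.0:
            raise ValueError("perturb_prob must lie in [0, 1]")
        self.species_tree.require_binary_species_tree()
        n = len(self.species_tree.nodes)
        for node_id, r in self.wgd_events:
            if not 0 <= node_id < n:
                raise ValueError(f"WGD node id {node_id} not in species tree")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention probability {r} outside [0, 1]")


@dataclass(frozen=True)
class TruthEvent:
    event_type: str  # "background" | "wgd"
    species_node: int
    detectable: bool  # both daughter lineages left surviving descendants


@dataclass
class SimulatedFamily:
    family_id: str
    family_index: int
    tree: Optional[Tree]
    truth: list[TruthEvent]
    extinct: bool = False
    perturbed: bool = False

    def to_gene_family(self) -> GeneFamily:
        if self.tree is None:
            return GeneFamily(self.family_id)
        return GeneFamily.from_tree(self.family_id, self.tree)


def _family_rng(seed: int, family_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, family_index, stream]))


def simulate_gene_tree(config: SimulationConfig, family_index: int) -> SimulatedFamily:
    """Evolve one gene family down the species tree (no supports yet)."""
    rng = _family_rng(config.seed, family_index, stream=0)
    sp = config.species_tree
    wgd_map = dict(config.wgd_events)
    lam, mu = config.dup_rate, config.loss_rate
    events: list[tuple[str, int, Node]] = []
    leaves_of: dict[str, list[Node]] = {}

    def evolve(lineage: Node, t_remaining: float, sp_node_id: int) -> list[Node]:
        """One lineage along one species branch; returns bottom survivors."""
        t_dup = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        t_loss = rng.exponential(1.0 / mu) if mu > 0 else np.inf
        t = min(t_dup, t_loss)
        if t >= t_remaining:
            return [lineage]
        if t_loss <= t_dup:
            return []  # lost before reaching the bottom of the branch
        left, right = Node(), Node()
        lineage.add_child(left)
        lineage.add_child(right)
        events.append(("background", sp_node_id, lineage))
        out = evolve(left, t_remaining - t, sp_node_id)
        out += evolve(right, t_remaining - t, sp_node_id)
        return out

    def descend(sp_node: Node, entering: list[Node]) -> None:
        t = sp_node.branch_length if sp_node.branch_length is not None else 0.0
        survivors: list[Node] = []
        for lin in entering:
            survivors.extend(evolve(lin, t, sp_node.node_id))
        if sp_node.node_id in wgd_map:
            r = wgd_map[sp_node.node_id]
            post: list[Node] = []
            for lin in survivors:
                if rng.random() < r:
                    a, b = Node(), Node()
                    lin.add_child(a)
                    lin.add_child(b)
                    events.append(("wgd", sp_node.node_id, lin))
                    post.extend((a, b))
                else:
                    post.append(lin)
            survivors = post
        if sp_node.is_leaf:
            leaves_of.setdefault(sp_node.label, []).extend(survivors)
            return
        for sp_child in sp_node.children:
            entering_child = []
            for lin in survivors:
                c = Node()
                lin.add_child(c)
                entering_child.append(c)
            descend(sp_child, entering_child)

    origin = Node()
    descend(sp.root, [origin])

    # name surviving copies species|g1, species|g2, ...
    for species, lins in leaves_of.items():
        for k, lin in enumerate(lins, start=1):
            lin.label = make_gene_label(species, f"g{k}")

    family_id = f"fam{family_index:04d}"
    pruned = _prune_extinct(origin)
    truth = [
        TruthEvent(kind, sp_id, _n_surviving_sides(gnode) == 2)
        for kind, sp_id, gnode in events
    ]
    if pruned is None:
        return SimulatedFamily(family_id, family_index, None, truth, extinct=True)
    return SimulatedFamily(family_id, family_index, Tree(pruned), truth)


def _has_survivor(node: Node) -> bool:
    if node.is_leaf:
        return node.label is not None
    return any(_has_survivor(c) for c in node.children)


def _n_surviving_sides(node: Node) -> int:
    return sum(1 for c in node.children if _has_survivor(c))


def _prune_extinct(root: Node) -> Optional[Node]:
    """Drop extinct subtrees and splice out pass-through nodes."""

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node.label is not None else None
        kept = [c2 for c in node.children if (c2 := rec(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        fresh = Node()
        for c in kept:
            fresh.add_child(c)
        return fresh

    out = rec(root)
    if out is not None:
        out.parent = None
    return out


def assign_supports(
    family: SimulatedFamily, config: SimulationConfig, force_perturb: bool = False
) -> SimulatedFamily:
    """Assign supports to internal nodes; optionally apply one random NNI.

    The root keeps no support (a bootstrap annotates bipartitions, and the
    root edge is not one).  A perturbed family has a single random
    internal edge rearranged and that node's support pinned to the
    model's low value, creating the kind of well-supported-elsewhere
    conflict the hierarchical filter is built to catch.
    """
    if family.tree is None:
        return family
    rng = _family_rng(config.seed, family.family_index, stream=1)
    root = parse_newick(write_newick(family.tree)).root  # private copy

    internals = [n for n in _postorder_nodes(root) if n.children and n.parent is not None]
    for node in internals:
        node.support = config.support_model.draw(rng)

    perturbed = False
    do_perturb = force_perturb or (config.perturb_prob > 0 and rng.random() < config.perturb_prob)
    if do_perturb:
        eligible = [
            n
            for n in internals
            if len(n.children) == 2 and n.parent is not None and len(n.parent.children) == 2
        ]
        if eligible:
            v = eligible[rng.integers(len(eligible))]
            p = v.parent
            sibling = p.children[0] if p.children[1] is v else p.children[1]
            b = v.children[1]
            # exchange v's second child with v's sibling
            v.children[1] = sibling
            sibling.parent = v
            p.children = [v, b]
            b.parent = p
            v.support = config.support_model.low
            perturbed = True

    return replace(family, tree=Tree(root), perturbed=perturbed)


def _postorder_nodes(root: Node) -> list[Node]:
    out: list[Node] = []

    def rec(n: Node) -> None:
        for c in n.children:
            rec(c)
        out.append(n)

    rec(root)
    return out


def simulate_family(config: SimulationConfig, family_index: int) -> SimulatedFamily:
    """Gene tree plus supports/perturbation for one family."""
    return assign_supports(simulate_gene_tree(config, family_index), config)


def simulate_families(config: SimulationConfig) -> list[SimulatedFamily]:
    return [simulate_family(config, i) for i in range(config.n_families)]


# -- discrete characters ------------------------------------------------------


def simulate_character(
    tree: Tree,
    n_states: int,
    rate: float,
    seed: int,
    root_state: Optional[int] = None,
) -> dict[str, int]:
    """Evolve a symmetric k-state Markov character root-to-tips.

    ``rate`` is the total substitution rate per unit branch length; at a
    substitution the chain jumps uniformly to one of the other k-1
    states.  The root state is uniform unless given.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if rate <= 0:
        raise ValueError("rate must be positive")
    for node in tree.nodes:
        if node is not tree.root and node.branch_length is None:
            raise ValueError("simulate_character requires branch lengths on all edges")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n_states)) if root_state is None else int(root_state)
    if not 0 <= start < n_states:
        raise ValueError("root_state outside the state alphabet")

    states: dict[str, int] = {}

    def walk(node: Node, state: int) -> None:
        if node is not tree.root:
            n_jumps = rng.poisson(rate * node.branch_length)
            for _ in range(n_jumps):
                shift = 1 + int(rng.integers(n_states - 1))
                state = (state + shift) % n_states
        if node.is_leaf:
            states[node.label] = state
        else:
            for child in node.children:
                walk(child, state)

    walk(tree.root, start)
    return states


# -- canned fixtures ----------------------------------------------------------

_MINI_SPECIES_NEWICK = (
    "((Cucumis_sativus:0.5,Medicago_truncatula:0.5):2.5,"
    "((Dryas_a:1.0,Cercocarpus_a:1.0):1.2,"
    "(((Rubus_a:0.4,Rubus_b:0.4):0.9,"
    "((Rosa_a:0.5,Rosa_b:0.5):0.5,(Potentilla_a:0.6,Fragaria_a:0.6):0.4):0.3):0.7,"
    "((Prunus_a:0.5,Prunus_b:0.5):1.1,"
    "(Spiraea_a:1.3,(Malus_a:0.7,(Pyrus_a:0.35,Crataegus_a:0.35):0.35):0.6):0.3):0.4):0.2):0.8):0.0;"
)

_MINI_TAXONOMY = [
    # species_id, genus, tribe, subfamily, family, order
    ("Cucumis_sativus", "Cucumis", "", "", "Cucurbitaceae", "Cucurbitales"),
    ("Medicago_truncatula", "Medicago", "", "", "Fabaceae", "Fabales"),
    ("Dryas_a", "Dryas", "Dryadeae", "Dryadoideae", "Rosaceae", "Rosales"),
    ("Cercocarpus_a", "Cercocarpus", "Dryadeae", "Dryadoideae", "Rosaceae", "Rosales"),
    ("Rubus_a", "Rubus", "Rubeae", "Rosoideae", "Rosaceae", "Rosales"),
    ("Rubus_b", "Rubus", "Rubeae", "Rosoideae", "Rosaceae", "Rosales"),
    ("Rosa_a", "Rosa", "Roseae", "Rosoideae", "Rosaceae", "Rosales"),
    ("Rosa_b", "Rosa", "Roseae", "Rosoideae", "Rosaceae", "Rosales"),
    ("Potentilla_a", "Potentilla", "Potentilleae", "Rosoideae", "Rosaceae", "Rosales"),
    ("Fragaria_a", "Fragaria", "Potentilleae", "Rosoideae", "Rosaceae", "Rosales"),
    ("Prunus_a", "Prunus", "Amygdaleae", "Amygdaloideae", "Rosaceae", "Rosales"),
    ("Prunus_b", "Prunus", "Amygdaleae", "Amygdaloideae", "Rosaceae", "Rosales"),
    ("Spiraea_a", "Spiraea", "Spiraeeae", "Amygdaloideae", "Rosaceae", "Rosales"),
    ("Malus_a", "Malus", "Maleae", "Amygdaloideae", "Rosaceae", "Rosales"),
    ("Pyrus_a", "Pyrus", "Maleae", "Amygdaloideae", "Rosaceae", "Rosales"),
    ("Crataegus_a", "Crataegus", "Maleae", "Amygdaloideae", "Rosaceae", "Rosales"),
]

FRUIT_STATES = ("achenetum", "drupetum", "pome")

_FIXTURE_SEED = 20917  # fixed so canned bundles are byte-identical across calls


@dataclass
class FixtureBundle:
    name: str
    species_tree: Tree
    taxonomy: TaxonomyTable
    families: list[SimulatedFamily]
    character_matrix: pd.DataFrame  # species x characters, state names
    config: SimulationConfig
    wgd_node: Optional[int] = None  # planted WGD species node, if any
    outgroup: tuple[str, ...] = ()


def mini_species_tree() -> Tree:
    return parse_newick(_MINI_SPECIES_NEWICK)


def mini_taxonomy() -> TaxonomyTable:
    return TaxonomyTable.from_records(
        [dict(zip(("species_id", "genus", "tribe", "subfamily", "family", "order"), row))
         for row in _MINI_TAXONOMY]
    )


def build_fixture(name: str) -> FixtureBundle:
    """Deterministic canned datasets.

    ``rosaceae_mini``: 16-species tree (14 rosaceous + 2 outgroups), 200
    families under background duplication-loss, one planted WGD at the
    Maleae crown (r = 0.6), heterogeneous supports, and a 3-state fruit
    character.  ``filter_bench``: 200 noise-free families of which the
    first 30 are NNI-perturbed, for exercising the hierarchical filter.
    """
    known = ("rosaceae_mini", "filter_bench")
    if name not in known:
        raise KeyError(f"unknown fixture {name!r}; available: {known}")

    sp = mini_species_tree()
    tax = mini_taxonomy()
    from .trees import lca  # local import avoids cycle in module docs

    maleae_crown = lca(sp, ["Malus_a", "Pyrus_a", "Crataegus_a"])

    if name == "rosaceae_mini":
        config = SimulationConfig(
            species_tree=sp,
            n_families=200,
            dup_rate=0.05,
            loss_rate=0.01,
            wgd_events=[(maleae_crown, 0.6)],
            support_model=SupportModel("two_point", p_low=0.1, low_value=30.0, high_value=98.0),
            perturb_prob=0.0,
            seed=_FIXTURE_SEED,
        )
        families = simulate_families(config)
        wgd_node = maleae_crown
    else:
        config = SimulationConfig(
            species_tree=sp,
            n_families=200,
            dup_rate=0.0,
            loss_rate=0.0,
            wgd_events=[],
            support_model=SupportModel("two_point", p_low=0.0, low_value=20.0, high_value=98.0),
            perturb_prob=0.0,
            seed=_FIXTURE_SEED + 1,
        )
        families = [
            assign_supports(
                simulate_gene_tree(config, i), config, force_perturb=(i < 30)
            )
            for i in range(config.n_families)
        ]
        wgd_node = None

    tip_states = simulate_character(
        sp, n_states=len(FRUIT_STATES), rate=0.25, seed=_FIXTURE_SEED + 2, root_state=0
    )
    matrix = pd.DataFrame(
        {"fruit_type": {label: FRUIT_STATES[s] for label, s in sorted(tip_states.items())}}
    )
    matrix.index.name = "unit"

    return FixtureBundle(
        name=name,
        species_tree=sp,
        taxonomy=tax,
        families=families,
        character_matrix=matrix,
        config=config,
        wgd_node=wgd_node,
        outgroup=("Cucumis_sativus", "Medicago_truncatula"),
    )


def write_truth(families: Sequence[SimulatedFamily], path: str | Path) -> None:
    rows = [
        {
            "family_id": fam.family_id,
            "event_type": ev.event_type,
            "species_node": ev.species_node,
            "detectable": int(ev.detectable),
        }
        for fam in families
        for ev in fam.truth
    ]
    pd.DataFrame(rows, columns=["family_id", "event_type", "species_node", "detectable"]).to_csv(
        path, sep="\t", index=False
    )


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> None:
    """Serialize a fixture bundle (species tree, taxonomy, families, truth,
    character matrix) under ``out_dir`` in plain-text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "species_tree.nwk").write_text(write_newick(bundle.species_tree) + "\n")
    bundle.taxonomy.to_tsv(out / "taxonomy.tsv")
    write_families([f.to_gene_family() for f in bundle.families], out)
    write_truth(bundle.families, out / "truth.tsv")
    bundle.character_matrix.to_csv(out / "characters.tsv", sep="\t")
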