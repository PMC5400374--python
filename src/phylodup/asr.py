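"""Parsimony ancestral-state reconstruction of discrete characters.

Characters (fruit type, habit, carpel number, ...) are scored on units -
monophyletic genera, or clade-level splits of non-monophyletic genera -
and traced on the fixed species topology.  Unordered (Fitch) parsimony
is the default; weighted/ordered characters go through Sankoff dynamic
programming with an explicit cost matrix.  Reported node states are full
MPR sets: every state attained at that node in at least one
most-parsimonious reconstruction, not an arbitrary single resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTable
from .trees import Node, Tree, is_monophyletic, lca, prune_to_leaves

__all__ = [
    "CharacterMatrix",
    "ASRResult",
    "collapse_to_units",
    "genus_units",
    "fitch",
    "sankoff",
    "reconstruct_all",
]

_MISSING = {"", "?", "-", "NA", "nan"}


class CharacterMatrix:
    """Units x characters table of discrete states.

    Cells hold a state symbol, a ``/``-separated ambiguity set, or a
    missing marker (empty, ``?``, ``-``).  The alphabet of a character is
    the set of symbols observed in its column (at most 32).
    """

    def __init__(self, table: pd.DataFrame) -> None:
        if table.index.duplicated().any():
            raise ValueError("duplicate unit ids in character matrix")
        self.table = table.astype(str)
        for char in self.characters:
            if len(self.alphabet(char)) > 32:
                raise ValueError(f"character {char!r} has more than 32 states")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
        return cls(df)

    @classmethod
    def from_nexus(cls, path: str | Path) -> "CharacterMatrix":
        import dendropy

        mat = dendropy.StandardCharacterMatrix.get(path=str(Path(path)), schema="nexus")
        rows = {}
        for taxon in mat.taxon_namespace:
            seq = mat[taxon]
            rows[taxon.label] = [str(c) for c in seq.symbols_as_list()]
        n_chars = max(len(v) for v in rows.values())
        cols = [f"char{i+1}" for i in range(n_chars)]
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=cols))

    @property
    def units(self) -> list[str]:
        return list(self.table.index)

    @property
    def characters(self) -> list[str]:
        return list(self.table.columns)

    def cell(self, unit: str, character: str) -> Optional[frozenset[str]]:
        raw = str(self.table.at[unit, character]).strip()
        if raw in _MISSING:
            return None
        states = frozenset(s.strip() for s in raw.split("/") if s.strip())
        return states or None

    def alphabet(self, character: str) -> frozenset[str]:
        out: set[str] = set()
        for unit in self.units:
            cell = self.cell(unit, character)
            if cell:
                out |= cell
        return frozenset(out)

    def column(self, character: str) -> dict[str, Optional[frozenset[str]]]:
        return {unit: self.cell(unit, character) for unit in self.units}


@dataclass
class ASRResult:
    character: str
    score: float  # integer-valued under unit costs
    alphabet: tuple[str, ...]
    node_states: dict[int, frozenset[str]]  # internal node id -> MPR set
    ambiguous: set[int] = field(default_factory=set)

    def root_states(self, tree: Tree) -> frozenset[str]:
        return self.node_states[tree.root.node_id]


def _tip_sets(
    tree: Tree, column: Mapping[str, Optional[frozenset[str]]], alphabet: frozenset[str]
) -> dict[int, frozenset[str]]:
    """Leaf id -> allowed state set; missing/unscored tips get the full
    alphabet (standard treatment)."""
    out = {}
    for leaf in tree.leaves():
        cell = column.get(leaf.label)
        if cell is None:
            if leaf.label not in column:
                warnings.warn(f"unit {leaf.label!r} absent from matrix; treated as missing")
            out[leaf.node_id] = alphabet
        else:
            unknown = cell - alphabet
            if unknown:
                raise ValueError(f"tip {leaf.label!r} has states outside the alphabet: {sorted(unknown)}")
            out[leaf.node_id] = cell
    return out


def fitch(
    tree: Tree, column: Mapping[str, Optional[frozenset[str]]], character: str = "char"
) -> ASRResult:
    """Unordered parsimony on a binary tree.

    The bottom-up pass is Fitch's intersection/union rule, phrased as
    Hartigan-style majority counting so that ambiguity sets and missing
    tips (which are hard constraints, not free states) are handled
    exactly; the top-down pass combines each node's child sets with an
    "outside" set to yield true MPR sets.  With unit costs every message
    along an edge is two-valued (optimum, or optimum + 1), which is why
    pure set arithmetic suffices.
    """
    # unary pass-through nodes (degenerate one-leaf trees) are tolerated;
    # real polytomies are not
    if any(len(n.children) > 2 for n in tree.nodes):
        raise ValueError("fitch requires a binary tree")
    alphabet = frozenset().union(*(c for c in column.values() if c)) if column else frozenset()
    if not alphabet:
        raise ValueError("character has no observed states")

    def argmax_count(sets: list[frozenset[str]]) -> frozenset[str]:
        best, out = -1, set()
        for s in alphabet:
            c = sum(1 for ss in sets if s in ss)
            if c > best:
                best, out = c, {s}
            elif c == best:
                out.add(s)
        return frozenset(out)

    # bottom-up: D[v] = argmin set of the message v sends to its parent
    down: dict[int, frozenset[str]] = dict(_tip_sets(tree, column, alphabet))
    score = 0
    for node in tree.nodes:  # post-order
        if node.is_leaf:
            continue
        child_sets = [down[c.node_id] for c in node.children]
        if len(child_sets) == 2:
            inter = child_sets[0] & child_sets[1]
            if inter:
                down[node.node_id] = inter
            else:
                down[node.node_id] = child_sets[0] | child_sets[1]
                score += 1
        else:
            down[node.node_id] = child_sets[0]

    # top-down: U[v] = argmin set of the outside-of-v message
    up: dict[int, frozenset[str]] = {tree.root.node_id: alphabet}
    for node in reversed(tree.nodes):  # pre-order
        if node.is_leaf:
            continue
        for child in node.children:
            others = [down[c.node_id] for c in node.children if c is not child]
            up[child.node_id] = argmax_count(others + [up[node.node_id]])

    internal = {
        n.node_id: argmax_count([down[c.node_id] for c in n.children] + [up[n.node_id]])
        for n in tree.internal_nodes()
    }
    return ASRResult(
        character=character,
        score=score,
        alphabet=tuple(sorted(alphabet)),
        node_states=internal,
        ambiguous={nid for nid, s in internal.items() if len(s) > 1},
    )


def sankoff(
    tree: Tree,
    column: Mapping[str, Optional[frozenset[str]]],
    cost: pd.DataFrame,
    character: str = "char",
) -> ASRResult:
    """Weighted parsimony by dynamic programming.

    ``cost`` is a square states x states matrix with zero diagonal and
    nonnegative entries.  With all-ones off-diagonal costs this
    reproduces Fitch scores and MPR sets exactly.
    """
    states = list(cost.index)
    if list(cost.columns) != states:
        raise ValueError("cost matrix rows and columns must agree")
    c = cost.to_numpy(dtype=float)
    if c.shape[0] != c.shape[1] or np.any(np.diag(c) != 0) or np.any(c < 0):
        raise ValueError("cost matrix must be square, zero-diagonal, nonnegative")
    alphabet = frozenset(states)
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    tips = _tip_sets(tree, column, alphabet)
    INF = np.inf

    g: dict[int, np.ndarray] = {}
    for node in tree.nodes:
        if node.is_leaf:
            vec = np.full(k, INF)
            for s in tips[node.node_id]:
                vec[idx[s]] = 0.0
            g[node.node_id] = vec
        else:
            vec = np.zeros(k)
            for child in node.children:
                vec = vec + np.min(c + g[child.node_id][None, :], axis=1)
            g[node.node_id] = vec
    score = float(np.min(g[tree.root.node_id]))

    # outside costs: o[v][s] = best cost of everything outside v's subtree
    o: dict[int, np.ndarray] = {tree.root.node_id: np.zeros(k)}
    for node in reversed(tree.nodes):  # pre-order
        if node.is_leaf:
            continue
        base = o[node.node_id]
        child_mins = [np.min(c + g[ch.node_id][None, :], axis=1) for ch in node.children]
        total_min = np.sum(child_mins, axis=0)
        for ci, child in enumerate(node.children):
            parent_vec = base + total_min - child_mins[ci]  # cost at parent sans this child
            o[child.node_id] = np.min(c + parent_vec[:, None], axis=0)

    internal = {}
    for node in tree.internal_nodes():
        tot = g[node.node_id] + o[node.node_id]
        best = np.min(tot)
        internal[node.node_id] = frozenset(
            s for s in states if tot[idx[s]] <= best + 1e-9
        )
    return ASRResult(
        character=character,
        score=score,
        alphabet=tuple(states),
        node_states=internal,
        ambiguous={nid for nid, s in internal.items() if len(s) > 1},
    )


# -- unit trees ---------------------------------------------------------------


def genus_units(taxonomy: TaxonomyTable) -> dict[str, set[str]]:
    """Default unit spec: one unit per genus (species lacking a genus
    annotation become their own unit)."""
    units: dict[str, set[str]] = {}
    for row in taxonomy.rows.itertuples(index=False):
        key = row.genus or row.species_id
        units.setdefault(key, set()).add(row.species_id)
    return units


def collapse_to_units(
    species_tree: Tree,
    taxonomy: TaxonomyTable,
    unit_spec: Optional[Mapping[str, Iterable[str]]] = None,
) -> tuple[Tree, pd.DataFrame]:
    """Collapse each declared unit's clade to a single leaf.

    Every unit sampled with >= 2 species must be monophyletic in the
    species tree; otherwise the error names the interdigitating taxa so
    the caller can split the unit into clades (the standard treatment of
    non-monophyletic genera).
    """
    units = {u: set(sp) for u, sp in (unit_spec or genus_units(taxonomy)).items()}
    present = species_tree.leaf_labels()
    rep_to_unit: dict[str, str] = {}
    rows = []
    for unit in sorted(units):
        sampled = sorted(units[unit] & present)
        if not sampled:
            continue
        if len(sampled) >= 2 and not is_monophyletic(species_tree, sampled):
            clade = species_tree.leafset(species_tree.node(lca(species_tree, sampled)))
            intruders = sorted(clade - units[unit])
            raise ValueError(
                f"unit {unit!r} is not monophyletic; interdigitating taxa: {intruders}"
            )
        rep = sampled[0]
        rep_to_unit[rep] = unit
        rows.append({"unit": unit, "n_species": len(sampled), "representative": rep})
    unassigned = present - set().union(*units.values()) if units else present
    for sp in sorted(unassigned):
        rep_to_unit[sp] = sp
        rows.append({"unit": sp, "n_species": 1, "representative": sp})

    pruned = prune_to_leaves(species_tree, rep_to_unit.keys())
    for leaf in pruned.leaves():
        leaf.label = rep_to_unit[leaf.label]
    unit_tree = Tree(pruned.root)  # re-index and re-validate renamed leaves
    report = pd.DataFrame(rows, columns=["unit", "n_species", "representative"])
    return unit_tree, report


def reconstruct_all(
    tree: Tree, matrix: CharacterMatrix
) -> tuple[pd.DataFrame, dict[str, ASRResult]]:
    """Fitch reconstruction of every character; long-format table with
    one row per (character, internal node)."""
    results: dict[str, ASRResult] = {}
    rows = []
    for char in matrix.characters:
        res = fitch(tree, matrix.column(char), character=char)
        results[char] = res
        for node_id in sorted(res.node_states):
            rows.append(
                {
                    "character": char,
                    "node": node_id,
                    "mpr_states": "/".join(sorted(res.node_states[node_id])),
                    "ambiguous": int(node_id in res.ambiguous),
                    "score": res.score,
                }
            )
    table = pd.DataFrame(rows, columns=["character", "node", "mpr_states", "ambiguous", "score"])
    return table, results
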