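"""Gene-family container and manifest I/O.

A family bundles its member genes (species, gene id, sequence length)
with an optional gene tree whose leaves are ``species|gene`` labels.
Families are read and written through a TSV manifest pointing at one
Newick file per family, mirroring how orthogroup pipelines hand trees
around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .trees import Tree, parse_newick, split_gene_label, write_newick


@dataclass(frozen=True)
class GeneMember:
    species_id: str
    gene_id: str
    length: Optional[int] = None  # bp; None when sequences are not tracked

    def __post_init__(self) -> None:
        if self.length is not None and self.length <= 0:
            raise ValueError(f"non-positive length for {self.species_id}|{self.gene_id}")


@dataclass
class GeneFamily:
    family_id: str
    members: list[GeneMember] = field(default_factory=list)
    tree: Optional[Tree] = None

    def __post_init__(self) -> None:
        seen = set()
        for m in self.members:
            key = (m.species_id, m.gene_id)
            if key in seen:
                raise ValueError(f"duplicate member {key} in family {self.family_id}")
            seen.add(key)

    @classmethod
    def from_tree(cls, family_id: str, tree: Tree) -> "GeneFamily":
        members = [
            GeneMember(*split_gene_label(label)) for label in sorted(tree.leaf_labels())
        ]
        return cls(family_id, members, tree)

    @property
    def species(self) -> set[str]:
        return {m.species_id for m in self.members}

    def copy_number(self, species_id: str) -> int:
        return sum(1 for m in self.members if m.species_id == species_id)

    def copy_numbers(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.species_id] = out.get(m.species_id, 0) + 1
        return out

    def lengths_of(self, species_id: str) -> list[int]:
        return [m.length for m in self.members if m.species_id == species_id]


# -- manifest I/O -------------------------------------------------------------

MANIFEST_COLUMNS = ["family_id", "path", "n_genes", "extinct_flag"]


def write_families(
    families: Iterable[GeneFamily], out_dir: str | Path, tree_subdir: str = "trees"
) -> Path:
    """Write one Newick per family plus a manifest TSV; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / tree_subdir).mkdir(parents=True, exist_ok=True)
    rows = []
    for fam in families:
        rel = None
        extinct = fam.tree is None or not fam.members
        if fam.tree is not None:
            rel = f"{tree_subdir}/{fam.family_id}.nwk"
            (out_dir / rel).write_text(write_newick(fam.tree) + "\n")
        rows.append(
            {
                "family_id": fam.family_id,
                "path": rel or "",
                "n_genes": len(fam.members),
                "extinct_flag": int(extinct),
            }
        )
    manifest = out_dir / "families.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_families(manifest_path: str | Path) -> list[GeneFamily]:
    """Load families listed in a manifest; extinct families come back empty."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype={"family_id": str, "path": str})
    out: list[GeneFamily] = []
    for row in df.itertuples(index=False):
        if int(row.extinct_flag) or not isinstance(row.path, str) or not row.path:
            out.append(GeneFamily(str(row.family_id)))
            continue
        tree = parse_newick((base / row.path).read_text())
        out.append(GeneFamily.from_tree(str(row.family_id), tree))
    return out
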